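"""Site-frequency-spectrum estimators and neutrality tests.

All statistics operate on *folded* spectra (minor-allele counts, no
outgroup/ancestral call): Watterson's theta, nucleotide diversity (pi),
Tajima's D and the Fu-Li D* test (the no-outgroup variant, with singletons
defined as minor-allele count 1).

Sample size is always the number of sequences (haploid genomes), ``n_seq``;
callers working with diploid individuals convert via ``n_seq = 2 * s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InvalidSampleSizeError",
    "StatisticUndefinedError",
    "SiteFrequencySpectrum",
    "TajimaConstants",
    "FuLiConstants",
    "harmonic_numbers",
    "tajima_constants",
    "fu_li_constants",
    "watterson_theta",
    "nucleotide_diversity",
    "tajima_D",
    "fu_li_D_star",
    "sfs_from_genotypes",
]


class InvalidSampleSizeError(ValueError):
    """Raised when a statistic is requested for too few sequences."""


class StatisticUndefinedError(ValueError):
    """A statistic has no value for this input (e.g. S = 0).

    Deliberately distinct from returning 0.0: per-gene statistics on small
    subsamples are frequently undefined and must never be silently treated
    as evidence of neutrality.
    """


@dataclass(frozen=True)
class SiteFrequencySpectrum:
    """Folded SFS for one site class.

    Parameters
    ----------
    n_seq
        Number of sequences (haploid genomes) sampled; >= 2.
    counts
        ``counts[m - 1]`` is the number of segregating sites whose minor
        allele occurs ``m`` times, m = 1 .. floor(n_seq / 2).
    n_sites
        Total surveyed sites (monomorphic included), for per-site scaling.
    site_class
        One of {"synonymous", "nonsynonymous", "neutral", "constrained",
        "unlabeled"}.
    """

    n_seq: int
    counts: np.ndarray
    n_sites: float
    site_class: str = "unlabeled"

    _CLASSES = ("synonymous", "nonsynonymous", "neutral", "constrained", "unlabeled")

    def __post_init__(self) -> None:
        if self.n_seq < 2:
            raise InvalidSampleSizeError(f"n_seq must be >= 2, got {self.n_seq}")
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 1 or counts.shape[0] != self.n_seq // 2:
            raise ValueError(
                f"counts must have length floor(n_seq/2) = {self.n_seq // 2}, "
                f"got shape {counts.shape}"
            )
        if (counts < 0).any():
            raise ValueError("SFS counts must be non-negative")
        if self.n_sites < 0:
            raise ValueError("n_sites must be non-negative")
        if counts.sum() > self.n_sites:
            raise ValueError("segregating sites exceed surveyed sites")
        if self.site_class not in self._CLASSES:
            raise ValueError(f"unknown site_class {self.site_class!r}")
        object.__setattr__(self, "counts", counts)

    @property
    def S(self) -> int:
        """Number of segregating sites."""
        return int(self.counts.sum())

    @property
    def singletons(self) -> int:
        """Sites whose minor allele occurs exactly once."""
        return int(self.counts[0]) if self.counts.size else 0


@dataclass(frozen=True)
class TajimaConstants:
    """Variance constants of Tajima's D test (Tajima 1989, eqs. 3-38)."""

    n_seq: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


@dataclass(frozen=True)
class FuLiConstants:
    """Variance constants of the Fu-Li D* test (no outgroup).

    u_D and v_D follow Fu & Li (1993) p.701 with the published corrections
    (Simonsen, Churchill & Aquadro 1995):

        c_n  = 2 (n a_n - 2(n-1)) / ((n-1)(n-2))
        d_n  = c_n + (n-2)/(n-1)^2 + (2/(n-1)) (3/2 - (2 a_{n+1} - 3)/(n-2) - 1/n)
        v_D* = [ (n/(n-1))^2 b_n + a_n^2 d_n - 2 n a_n (a_n+1)/(n-1)^2 ]
               / (a_n^2 + b_n)
        u_D* = (n/(n-1)) (a_n - n/(n-1)) - v_D*

    with a_n = sum_{i<n} 1/i, b_n = sum_{i<n} 1/i^2, a_{n+1} = a_n + 1/n.
    """

    n_seq: int
    a_n: float
    u_D: float
    v_D: float


def harmonic_numbers(n_seq: int) -> tuple[float, float]:
    """Return (a1, a2) = (sum_{i=1}^{n-1} 1/i, sum_{i=1}^{n-1} 1/i^2)."""
    if int(n_seq) != n_seq or n_seq < 2:
        raise InvalidSampleSizeError(f"n_seq must be an integer >= 2, got {n_seq}")
    i = np.arange(1, int(n_seq), dtype=np.float64)
    return float(np.sum(1.0 / i)), float(np.sum(1.0 / i**2))


def tajima_constants(n_seq: int) -> TajimaConstants:
    """Constants of Tajima's D for ``n_seq`` sequences (n >= 3)."""
    if n_seq < 3:
        raise InvalidSampleSizeError("Tajima's D requires n_seq >= 3")
    n = float(n_seq)
    a1, a2 = harmonic_numbers(n_seq)
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(n_seq, a1, a2, b1, b2, c1, c2, e1, e2)


def fu_li_constants(n_seq: int) -> FuLiConstants:
    """Corrected D* constants for ``n_seq`` sequences (n >= 4).

    n = 3 is degenerate for the folded statistic: every segregating site is
    a singleton, the numerator vanishes identically and u* = v* = 0.
    """
    if n_seq < 4:
        raise InvalidSampleSizeError("Fu-Li D* requires n_seq >= 4")
    n = float(n_seq)
    a_n, b_n = harmonic_numbers(n_seq)
    a_n1 = a_n + 1.0 / n
    c_n = 2.0 * (n * a_n - 2.0 * (n - 1.0)) / ((n - 1.0) * (n - 2.0))
    d_n = (
        c_n
        + (n - 2.0) / (n - 1.0) ** 2
        + (2.0 / (n - 1.0)) * (1.5 - (2.0 * a_n1 - 3.0) / (n - 2.0) - 1.0 / n)
    )
    v_D = ((n / (n - 1.0)) ** 2 * b_n + a_n**2 * d_n
           - 2.0 * n * a_n * (a_n + 1.0) / (n - 1.0) ** 2) / (a_n**2 + b_n)
    u_D = (n / (n - 1.0)) * (a_n - n / (n - 1.0)) - v_D
    return FuLiConstants(n_seq, a_n, u_D, v_D)


def watterson_theta(sfs: SiteFrequencySpectrum) -> float:
    """Per-site Watterson estimator theta_W = (S / a1) / n_sites."""
    if sfs.n_sites <= 0:
        raise StatisticUndefinedError("theta_W undefined on an empty region")
    if sfs.S == 0:
        return 0.0
    a1, _ = harmonic_numbers(sfs.n_seq)
    return (sfs.S / a1) / sfs.n_sites


def nucleotide_diversity(sfs: SiteFrequencySpectrum) -> float:
    """Per-site pi from the folded SFS.

    pi = [ sum_m counts[m] * m (n - m) / C(n, 2) ] / n_sites, which equals
    the mean pairwise Hamming distance per site over the sample.
    """
    if sfs.n_sites <= 0:
        raise StatisticUndefinedError("pi undefined on an empty region")
    n = sfs.n_seq
    m = np.arange(1, n // 2 + 1, dtype=np.float64)
    pairs = n * (n - 1) / 2.0
    k = float(np.sum(sfs.counts * m * (n - m)) / pairs)
    return k / sfs.n_sites


def tajima_D(sfs: SiteFrequencySpectrum) -> float:
    """Tajima's D from a folded SFS.

    D = (k - S/a1) / sqrt(e1 S + e2 S (S-1)) with k the per-locus mean
    pairwise difference. Raises :class:`StatisticUndefinedError` for S = 0.
    """
    if sfs.n_seq < 3:
        raise InvalidSampleSizeError("Tajima's D requires n_seq >= 3")
    S = sfs.S
    if S == 0:
        raise StatisticUndefinedError("Tajima's D undefined with no segregating sites")
    c = tajima_constants(sfs.n_seq)
    k = nucleotide_diversity(sfs) * sfs.n_sites
    var = c.e1 * S + c.e2 * S * (S - 1)
    return (k - S / c.a1) / np.sqrt(var)


def fu_li_D_star(sfs: SiteFrequencySpectrum) -> float:
    """Fu-Li D* (no outgroup) from a folded SFS.

    Uses the total segregating sites as eta and the minor-allele singleton
    count as eta_s. Raises :class:`StatisticUndefinedError` for eta = 0.
    """
    eta = sfs.S
    if eta == 0:
        raise StatisticUndefinedError("Fu-Li D* undefined with no segregating sites")
    c = fu_li_constants(sfs.n_seq)
    n = float(sfs.n_seq)
    eta_s = sfs.singletons
    num = (n / (n - 1.0)) * eta - c.a_n * eta_s
    den = np.sqrt(c.u_D * eta + c.v_D * eta**2)
    return num / den


def sfs_from_genotypes(
    genotypes: np.ndarray,
    ploidy: int = 2,
    site_class: str = "unlabeled",
    site_mask: np.ndarray | None = None,
) -> SiteFrequencySpectrum:
    """Fold a dosage matrix (sites x samples) into a SiteFrequencySpectrum.

    Dosages are alternate-allele counts in ``{0 .. ploidy}``; ``NaN`` marks a
    missing call. Sites with any missing call are dropped from both the
    counts and ``n_sites`` (listwise per site). Monomorphic sites contribute
    to ``n_sites`` only.

    Parameters
    ----------
    site_mask
        Optional boolean selector over rows (e.g. one functional class).
    """
    g = np.asarray(genotypes, dtype=np.float64)
    if g.ndim != 2:
        raise ValueError("genotypes must be a sites x samples matrix")
    if site_mask is not None:
        g = g[np.asarray(site_mask, dtype=bool)]
    finite = np.isfinite(g)
    keep = finite.all(axis=1)
    g = g[keep]
    if g.size and ((g < 0) | (g > ploidy) | (g != np.floor(g))).any():
        raise ValueError(f"dosages must be integers in 0..{ploidy} (bi-allelic)")
    n_samples = g.shape[1]
    n_seq = ploidy * n_samples
    alt = g.sum(axis=1).astype(np.int64)
    minor = np.minimum(alt, n_seq - alt)
    minor = minor[(alt > 0) & (alt < n_seq)]
    counts = np.bincount(minor, minlength=n_seq // 2 + 1)[1:]
    return SiteFrequencySpectrum(
        n_seq=n_seq, counts=counts, n_sites=int(g.shape[0]), site_class=site_class
    )
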