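"""Synthetic exome-SNV generator.

Emits GeneTable inputs with the statistical shape of a large human exome
panel: ~10^2..10^4 protein-coding genes with synonymous/nonsynonymous site
totals, per-gene dN/dS in [0, 1) with dN, dS <= 0.8, Poisson divergence
counts, and bi-allelic SNVs whose population frequencies follow a 1/i law
optionally tilted toward singletons.

The singleton tilt is a one-parameter modelling convenience: a fraction of
the probability mass of bins m >= 2 is moved to m = 1, with the
nonsynonymous tilt growing as dN/dS shrinks. It reproduces the qualitative
rare-variant excess that population growth and purifying selection create
in real exomes, without asserting any particular DFE-to-SFS map. Genotypes
are Hardy-Weinberg binomial draws (no inbreeding, no structure, no LD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .popgen import SiteFrequencySpectrum
from .sweep import GENE_COLUMNS, GeneTable

__all__ = ["SynthConfig", "generate_gene_table", "planted_sfs_table"]


@dataclass(frozen=True)
class SynthConfig:
    """Generator knobs.

    ``sfs_model`` is one of "neutral" (pure 1/i), "growth-skewed"
    (singleton tilt ``base_skew`` in both classes) or "selection-skewed"
    (additionally tilts nonsynonymous SNVs by ``constraint_skew * (1 -
    dN/dS)``). SNV densities are expected segregating sites per site.
    """

    n_individuals: int = 1_008
    n_genes: int = 500
    syn_sites: int = 300
    nonsyn_sites: int = 900
    dnds_beta: tuple[float, float] = (1.0, 1.0)  # Beta params for dN/dS
    sfs_model: str = "selection-skewed"
    base_skew: float = 0.15
    constraint_skew: float = 0.35
    snv_density_syn: float = 0.03
    snv_density_nonsyn: float = 0.015
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sfs_model not in ("neutral", "growth-skewed", "selection-skewed"):
            raise ValueError(f"unknown sfs_model {self.sfs_model!r}")
        if not (0 <= self.base_skew < 1 and 0 <= self.constraint_skew < 1):
            raise ValueError("skew weights must be in [0, 1)")
        if self.n_individuals < 1 or self.n_genes < 1:
            raise ValueError("need at least one individual and one gene")


def _tilted_pmf(base: np.ndarray, tilt: float) -> np.ndarray:
    """Move fraction ``tilt`` of the mass at population counts >= 2 to the
    singleton bin."""
    p = base.copy()
    moved = tilt * p[1:].sum()
    p[1:] *= 1.0 - tilt
    p[0] += moved
    return p


def generate_gene_table(config: SynthConfig) -> GeneTable:
    """Draw a full GeneTable from the generator model (seed-deterministic)."""
    rng = np.random.default_rng(config.seed)
    n_ind = config.n_individuals
    n_hap = 2 * n_ind
    # neutral 1/i law over population derived-allele counts 1 .. 2n-1
    i = np.arange(1, n_hap, dtype=np.float64)
    base = (1.0 / i) / np.sum(1.0 / i)

    a, b = config.dnds_beta
    gene_rows, snv_rows, dosage_blocks = [], [], []
    for g in range(config.n_genes):
        gid = f"gene{g:05d}"
        dnds = float(rng.beta(a, b))
        dS = float(rng.uniform(0.1, 0.6))
        dN = dnds * dS
        div_n = int(rng.poisson(dN * config.nonsyn_sites))
        div_s = int(rng.poisson(dS * config.syn_sites))
        gene_rows.append(
            {
                "gene_id": gid,
                "dN": dN,
                "dS": dS,
                "dn_ds": dnds,
                "div_n": div_n,
                "div_s": div_s,
                "syn_sites": config.syn_sites,
                "nonsyn_sites": config.nonsyn_sites,
            }
        )
        if config.sfs_model == "neutral":
            tilt_syn = tilt_non = 0.0
        elif config.sfs_model == "growth-skewed":
            tilt_syn = tilt_non = config.base_skew
        else:
            tilt_syn = config.base_skew
            tilt_non = config.base_skew + config.constraint_skew * (1.0 - dnds)
        for label, n_sites, density, tilt in (
            ("synonymous", config.syn_sites, config.snv_density_syn, tilt_syn),
            ("nonsynonymous", config.nonsyn_sites, config.snv_density_nonsyn, tilt_non),
        ):
            m = min(int(rng.poisson(density * n_sites)), n_sites)
            if m == 0:
                continue
            pmf = _tilted_pmf(base, tilt)
            pop_count = 1 + rng.choice(n_hap - 1, size=m, p=pmf)
            freq = pop_count / n_hap
            dosages = rng.binomial(2, freq[:, None], size=(m, n_ind)).astype(np.int8)
            pos = np.sort(rng.choice(n_sites, size=m, replace=False))
            for p_ in pos:
                snv_rows.append({"gene_id": gid, "pos": int(p_), "site_class": label})
            dosage_blocks.append(dosages)

    genes = pd.DataFrame(gene_rows, columns=GENE_COLUMNS)
    snv = pd.DataFrame(snv_rows, columns=["gene_id", "pos", "site_class"])
    dosages = (
        np.concatenate(dosage_blocks, axis=0)
        if dosage_blocks
        else np.zeros((0, n_ind), dtype=np.int8)
    )
    samples = [f"ind{j:04d}" for j in range(n_ind)]
    return GeneTable(genes=genes, snv=snv, dosages=dosages, samples=samples)


def planted_sfs_table(
    sfs_by_class: dict[str, SiteFrequencySpectrum],
) -> GeneTable:
    """Deterministic GeneTable whose pooled per-class SFS is exactly the
    planted one (exact-recovery fixture for the sweep pipeline).

    All spectra must share ``n_seq`` (even, = 2 x individuals). A site with
    minor count m places the minor allele on haplotypes 0..m-1, so
    individual j receives dosage ``clip(m - 2j, 0, 2)``.
    """
    n_seqs = {s.n_seq for s in sfs_by_class.values()}
    if len(n_seqs) != 1:
        raise ValueError("all planted spectra must share n_seq")
    n_seq = n_seqs.pop()
    if n_seq % 2:
        raise ValueError("n_seq must be even (diploid individuals)")
    n_ind = n_seq // 2
    sites = {"synonymous": 0, "nonsynonymous": 0}
    snv_rows, dosage_rows = [], []
    for label in ("synonymous", "nonsynonymous"):
        sfs = sfs_by_class.get(label)
        if sfs is None:
            sites[label] = 1  # keep n_sites positive for per-site scaling
            continue
        if sfs.S > sfs.n_sites:
            raise ValueError(f"planted {label} SFS has more sites than surveyed")
        sites[label] = int(sfs.n_sites)
        pos = 0
        for m, c in enumerate(np.asarray(sfs.counts), start=1):
            for _ in range(int(c)):
                j = np.arange(n_ind)
                dosage_rows.append(np.clip(m - 2 * j, 0, 2).astype(np.int8))
                snv_rows.append(
                    {"gene_id": "planted00000", "pos": pos, "site_class": label}
                )
                pos += 1
    genes = pd.DataFrame(
        [
            {
                "gene_id": "planted00000",
                "dN": 0.2,
                "dS": 0.4,
                "dn_ds": 0.5,
                "div_n": 10,
                "div_s": 10,
                "syn_sites": sites["synonymous"],
                "nonsyn_sites": sites["nonsynonymous"],
            }
        ],
        columns=GENE_COLUMNS,
    )
    snv = pd.DataFrame(snv_rows, columns=["gene_id", "pos", "site_class"])
    dosages = (
        np.vstack(dosage_rows) if dosage_rows else np.zeros((0, n_ind), dtype=np.int8)
    )
    samples = [f"ind{j:04d}" for j in range(n_ind)]
    return GeneTable(genes=genes, snv=snv, dosages=dosages, samples=samples)
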