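"""Subsampling sweep: the sample-size analysis over an exome-shaped dataset.

Individuals are partitioned into disjoint sample-size classes (16, 32, 64,
128, 256, 512 exomes by default), and for every class the folded SFS of
synonymous and nonsynonymous sites is pooled across genes to give theta_W,
pi, Tajima's D, Fu-Li D*, the nonsynonymous SNV fraction, and the MK-based
Neutrality Index and alpha. Genes can additionally be binned by dN/dS to
relate the magnitude of purifying selection to the size of the sample-size
bias. Series are summarised by log2-log2 OLS slopes, large-vs-small deltas
and ratios, and Pearson/Kendall correlations.

Pooling happens on counts, not on per-gene statistics: per-gene spectra at
n = 16 are mostly empty, and exome-wide values imply pooled counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .mk import MKCounts, alpha_adaptive, neutrality_index
from .popgen import (
    InvalidSampleSizeError,
    SiteFrequencySpectrum,
    StatisticUndefinedError,
    fu_li_D_star,
    nucleotide_diversity,
    tajima_D,
    watterson_theta,
)

__all__ = [
    "GeneTable",
    "SweepResult",
    "PartitionError",
    "partition_samples",
    "pooled_class_sfs",
    "stats_by_size",
    "bin_genes_by_dnds",
    "loglog_slope",
    "delta_and_ratio",
    "correlation_tests",
    "run_sweep",
]

SITE_CLASSES = ("synonymous", "nonsynonymous")
GENE_COLUMNS = [
    "gene_id", "dN", "dS", "dn_ds", "div_n", "div_s", "syn_sites", "nonsyn_sites",
]
DEFAULT_BIN_EDGES = tuple(np.round(np.arange(0.0, 1.01, 0.1), 10))


class PartitionError(ValueError):
    """Requested groups cannot be carved out of the available samples."""


@dataclass
class GeneTable:
    """Per-gene records plus the SNV genotype matrix.

    ``genes`` has one row per gene with columns ``GENE_COLUMNS``;
    ``snv`` has one row per SNV (``gene_id``, ``pos``, ``site_class``)
    aligned with the rows of ``dosages`` (SNVs x individuals, diploid
    alternate-allele dosages 0/1/2); ``samples`` names the columns.
    """

    genes: pd.DataFrame
    snv: pd.DataFrame
    dosages: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        missing = [c for c in GENE_COLUMNS if c not in self.genes.columns]
        if missing:
            raise ValueError(f"gene table missing columns: {missing}")
        self.dosages = np.asarray(self.dosages)
        if self.dosages.shape != (len(self.snv), len(self.samples)):
            raise ValueError("dosage matrix shape does not match snv x samples")
        bad = set(self.snv["site_class"]) - set(SITE_CLASSES)
        if bad:
            raise ValueError(f"unknown site classes: {sorted(bad)}")

    @property
    def n_individuals(self) -> int:
        return len(self.samples)


@dataclass
class SweepResult:
    """Tidy sweep output.

    ``by_size_class``: one row per (redraw, sample_size, site_class, bin)
    with the pooled SFS statistics (bin = "all" for the unbinned sweep).
    ``by_size``: one row per (redraw, sample_size) with the nSNV fraction
    and the MK table / NI / alpha.
    ``summary``: mean +/- SD across redraws of slopes, deltas and ratios.
    """

    by_size_class: pd.DataFrame
    by_size: pd.DataFrame
    summary: pd.DataFrame
    sample_size_unit: str = "exomes (diploid individuals)"


def partition_samples(
    sample_ids: list[str],
    sizes: tuple[int, ...],
    n_redraws: int = 1,
    seed: int = 0,
) -> list[list[list[str]]]:
    """Disjoint random groups of the requested sizes, one set per redraw.

    Each redraw is a uniformly random partition drawn from its own
    substream; groups within a redraw never share an individual.
    """
    ids = list(sample_ids)
    if sum(sizes) > len(ids):
        raise PartitionError(
            f"requested {sum(sizes)} samples but only {len(ids)} available"
        )
    redraws = []
    for r in range(n_redraws):
        rng = np.random.default_rng([seed, r])
        perm = rng.permutation(len(ids))
        groups, offset = [], 0
        for size in sizes:
            groups.append([ids[i] for i in perm[offset : offset + size]])
            offset += size
        redraws.append(groups)
    return redraws


def pooled_class_sfs(
    table: GeneTable,
    members: list[str],
    gene_ids: np.ndarray | None = None,
) -> dict[str, SiteFrequencySpectrum]:
    """Fold the group's genotypes into one SFS per site class, pooled over
    genes (optionally restricted to ``gene_ids``)."""
    col_idx = [table.samples.index(s) for s in members]
    n_seq = 2 * len(col_idx)
    snv = table.snv
    genes = table.genes
    if gene_ids is not None:
        keep_genes = set(gene_ids)
        row_mask = snv["gene_id"].isin(keep_genes).to_numpy()
        gene_rows = genes[genes["gene_id"].isin(keep_genes)]
    else:
        row_mask = np.ones(len(snv), dtype=bool)
        gene_rows = genes
    alt = table.dosages[np.ix_(row_mask, col_idx)].sum(axis=1)
    classes = snv.loc[row_mask, "site_class"].to_numpy()
    out = {}
    for label, sites_col in (("synonymous", "syn_sites"), ("nonsynonymous", "nonsyn_sites")):
        sel = classes == label
        a = alt[sel]
        a = a[(a > 0) & (a < n_seq)]
        minor = np.minimum(a, n_seq - a)
        counts = np.bincount(minor.astype(np.int64), minlength=n_seq // 2 + 1)[1:]
        out[label] = SiteFrequencySpectrum(
            n_seq=n_seq,
            counts=counts,
            n_sites=float(gene_rows[sites_col].sum()),
            site_class=label,
        )
    return out


def _sfs_stat_row(sfs: SiteFrequencySpectrum) -> dict:
    row = {
        "S": sfs.S,
        "singletons": sfs.singletons,
        "n_sites": sfs.n_sites,
        "theta_w": watterson_theta(sfs) if sfs.n_sites > 0 else np.nan,
        "pi": nucleotide_diversity(sfs) if sfs.n_sites > 0 else np.nan,
    }
    for name, fn in (("tajima_D", tajima_D), ("fu_li_D_star", fu_li_D_star)):
        try:
            row[name] = fn(sfs)
        except (StatisticUndefinedError, InvalidSampleSizeError):
            row[name] = np.nan
    return row


def stats_by_size(
    table: GeneTable,
    groups: list[list[str]],
    gene_ids: np.ndarray | None = None,
    bin_label: str = "all",
    redraw: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class and per-group statistics for one set of disjoint groups."""
    if gene_ids is not None:
        genes = table.genes[table.genes["gene_id"].isin(set(gene_ids))]
    else:
        genes = table.genes
    D_n = int(genes["div_n"].sum())
    D_s = int(genes["div_s"].sum())
    class_rows, group_rows = [], []
    for members in groups:
        n_ind = len(members)
        sfs = pooled_class_sfs(table, members, gene_ids)
        for label in SITE_CLASSES:
            class_rows.append(
                {
                    "redraw": redraw,
                    "bin": bin_label,
                    "sample_size": n_ind,
                    "site_class": label,
                    **_sfs_stat_row(sfs[label]),
                }
            )
        nS = sfs["nonsynonymous"].S
        sS = sfs["synonymous"].S
        tot = nS + sS
        frac = nS / tot if tot else np.nan
        se = np.sqrt(frac * (1 - frac) / tot) if tot else np.nan
        mk = MKCounts(P_n=nS, P_s=sS, D_n=D_n, D_s=D_s)
        try:
            ni = neutrality_index(mk)
            al = alpha_adaptive(mk)
        except StatisticUndefinedError:
            ni = al = np.nan
        group_rows.append(
            {
                "redraw": redraw,
                "bin": bin_label,
                "sample_size": n_ind,
                "nsnv_fraction": frac,
                "nsnv_se": se,
                "P_n": nS,
                "P_s": sS,
                "D_n": D_n,
                "D_s": D_s,
                "NI": ni,
                "alpha": al,
            }
        )
    return pd.DataFrame(class_rows), pd.DataFrame(group_rows)


def bin_genes_by_dnds(
    table: GeneTable, edges: tuple[float, ...] = DEFAULT_BIN_EDGES
) -> dict[str, np.ndarray]:
    """Half-open dN/dS bins [lo, hi); genes at or above the last edge join
    the top bin. Returns {label: gene_id array}, labels like "0.1-0.2"."""
    dnds = table.genes["dn_ds"].to_numpy()
    gid = table.genes["gene_id"].to_numpy()
    out: dict[str, np.ndarray] = {}
    for lo, hi in zip(edges[:-1], edges[1:]):
        label = f"{lo:g}-{hi:g}"
        if hi == edges[-1]:
            mask = (dnds >= lo)
        else:
            mask = (dnds >= lo) & (dnds < hi)
        out[label] = gid[mask]
    return out


def loglog_slope(
    sizes: np.ndarray, values: np.ndarray
) -> tuple[float, float]:
    """OLS slope (and its standard error) of log2(value) on log2(size).

    Non-positive values are excluded; fewer than 3 usable points raises
    :class:`~sfsweep.popgen.StatisticUndefinedError`.
    """
    sizes = np.asarray(sizes, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values) & (values > 0)
    if ok.sum() < 3:
        raise StatisticUndefinedError("log-log slope needs >= 3 positive points")
    res = sps.linregress(np.log2(sizes[ok]), np.log2(values[ok]))
    return float(res.slope), float(res.stderr)


def delta_and_ratio(
    series: dict[int, float], n_lo: int = 16, n_hi: int = 512
) -> tuple[float, float]:
    """delta = value(n_hi) - value(n_lo); ratio = value(n_hi) / value(n_lo)."""
    if n_lo not in series or n_hi not in series:
        raise KeyError(f"series lacks sample sizes {n_lo} and/or {n_hi}")
    lo, hi = series[n_lo], series[n_hi]
    delta = hi - lo
    ratio = hi / lo if lo != 0 else np.nan
    return float(delta), float(ratio)


def correlation_tests(
    sizes: np.ndarray, values: np.ndarray
) -> tuple[float, float, float, float]:
    """(pearson_r, p, kendall_tau, p): Pearson on log2-log2, Kendall on raw."""
    sizes = np.asarray(sizes, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(sizes) < 3:
        raise StatisticUndefinedError("correlation needs >= 3 points")
    if np.all(values == values[0]):
        raise StatisticUndefinedError("correlation undefined for constant series")
    pr = sps.pearsonr(np.log2(sizes), np.log2(values))
    kt = sps.kendalltau(sizes, values)
    return float(pr.statistic), float(pr.pvalue), float(kt.statistic), float(kt.pvalue)


def _summarize(by_size_class: pd.DataFrame, by_size: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD across redraws of the headline series summaries."""
    rows = []

    def add(measure, series_label, values):
        values = [v for v in values if np.isfinite(v)]
        if not values:
            return
        rows.append(
            {
                "measure": measure,
                "series": series_label,
                "mean": float(np.mean(values)),
                "sd": float(np.std(values, ddof=1)) if len(values) > 1 else np.nan,
                "n_redraws": len(values),
            }
        )

    main = by_size_class[by_size_class["bin"] == "all"]
    for label in SITE_CLASSES:
        sub = main[main["site_class"] == label]
        for stat in ("theta_w", "pi"):
            slopes = []
            for _, g in sub.groupby("redraw"):
                try:
                    slopes.append(loglog_slope(g["sample_size"], g[stat])[0])
                except StatisticUndefinedError:
                    slopes.append(np.nan)
            add(f"loglog_slope[{stat}]", label, slopes)
        for stat in ("tajima_D", "fu_li_D_star", "theta_w"):
            deltas, ratios = [], []
            for _, g in sub.groupby("redraw"):
                series = dict(zip(g["sample_size"], g[stat]))
                lo, hi = min(series), max(series)
                d, r = delta_and_ratio(series, lo, hi)
                deltas.append(d)
                ratios.append(r)
            add(f"delta[{stat}]", label, deltas)
            if stat == "theta_w":
                add(f"ratio[{stat}]", label, ratios)

    # theta_N / theta_S per sample size
    wide = main.pivot_table(
        index=["redraw", "sample_size"], columns="site_class", values="theta_w"
    )
    wide["theta_ns_ratio"] = wide["nonsynonymous"] / wide["synonymous"]
    for n, g in wide.groupby("sample_size"):
        add("theta_N/theta_S", f"n={n}", list(g["theta_ns_ratio"]))

    for stat in ("NI", "alpha", "nsnv_fraction"):
        for n, g in by_size.groupby("sample_size"):
            add(stat, f"n={n}", list(g[stat]))
    return pd.DataFrame(rows)


def run_sweep(
    table: GeneTable,
    sizes: tuple[int, ...] = (16, 32, 64, 128, 256, 512),
    n_redraws: int = 10,
    seed: int = 0,
    bin_edges: tuple[float, ...] | None = DEFAULT_BIN_EDGES,
) -> SweepResult:
    """The full analysis: partition, per-class statistics, dN/dS bins,
    summaries averaged over redraws."""
    redraws = partition_samples(table.samples, sizes, n_redraws, seed)
    class_frames, group_frames = [], []
    for r, groups in enumerate(redraws):
        cf, gf = stats_by_size(table, groups, redraw=r)
        class_frames.append(cf)
        group_frames.append(gf)
        if bin_edges is not None:
            for label, gene_ids in bin_genes_by_dnds(table, bin_edges).items():
                if len(gene_ids) == 0:
                    continue
                cfb, _ = stats_by_size(
                    table, groups, gene_ids=gene_ids, bin_label=label, redraw=r
                )
                class_frames.append(cfb)
    by_size_class = pd.concat(class_frames, ignore_index=True)
    by_size = pd.concat(group_frames, ignore_index=True)
    summary = _summarize(by_size_class, by_size)
    return SweepResult(by_size_class, by_size, summary)
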