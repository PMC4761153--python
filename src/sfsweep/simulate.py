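"""Forward-in-time Wright-Fisher simulation with a gamma DFE.

Simulates a 5 kb non-recombining locus through a two-branch human-like
demography: an ancestral population (N_e = 10,000 diploids) that declines
slightly to N_e = 9,210, after which the sampled branch either stays
constant or grows exponentially to N_e = 512,210. New mutations are neutral
or deleterious with selection coefficients drawn from a gamma distribution
parameterised by the scaled mean gamma_bar = 2 N_e s_bar and shape 0.206.

Selection is genic (haplotype-multiplicative), the random-mating equivalent
of semidominant (h = 0.5) diploid selection: a haplotype carrying mutations
with coefficients s_i has relative weight prod_i (1 - s_i / 2) when parents
are drawn for the next generation.

To run the full-size model at desk scale the standard theta-preserving
rescaling is applied: N -> N / lambda, mu -> mu * lambda, s -> s * lambda,
durations -> durations / lambda, which preserves 4 N mu and 2 N s.

Replicates are independent loci; replicate ``r`` of a run seeded with ``s``
uses the dedicated bit stream ``default_rng([s, r])``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .popgen import (
    SiteFrequencySpectrum,
    nucleotide_diversity,
    watterson_theta,
)

__all__ = [
    "Phase",
    "DemographySchedule",
    "DFEConfig",
    "SimulationConfig",
    "ReplicateSample",
    "ConfigError",
    "constant_schedule",
    "growth_schedule",
    "rescale",
    "run_simulation",
    "replicates_to_frame",
    "mean_theta_by_size",
]

DEFAULT_SAMPLE_SIZES = (16, 32, 64, 128, 256, 512)


class ConfigError(ValueError):
    """Invalid or internally inconsistent simulation configuration."""


@dataclass(frozen=True)
class Phase:
    """One demographic epoch, forward in time.

    ``start_size``/``end_size`` are diploid effective sizes; ``mode`` is
    "constant" (end == start) or "exponential" (size interpolates
    geometrically over ``duration`` generations).
    """

    duration: float
    start_size: float
    end_size: float
    mode: str = "constant"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ConfigError("phase duration must be positive")
        if self.start_size <= 0 or self.end_size <= 0:
            raise ConfigError("population sizes must be positive")
        if self.mode not in ("constant", "exponential"):
            raise ConfigError(f"unknown phase mode {self.mode!r}")
        if self.mode == "constant" and self.start_size != self.end_size:
            raise ConfigError("constant phase must have end_size == start_size")

    def size_at(self, t: float) -> float:
        """Diploid size at forward time ``t`` in [0, duration] within phase."""
        if self.mode == "constant":
            return self.start_size
        return self.start_size * (self.end_size / self.start_size) ** (t / self.duration)


@dataclass(frozen=True)
class DemographySchedule:
    """Ordered forward-time phases; the population is constant at
    ``ancestral_size`` (default: ``phases[0].start_size``) for all time
    before the first phase. An ``ancestral_size`` larger than
    ``phases[0].start_size`` models a mass-conserving population split: the
    sampled daughter starts at its post-split size while lineages older
    than the split coalesce in the merged ancestral population.

    ``branch`` is a label recording which of the two post-split populations
    this schedule describes ("constant-branch" or "exponential-branch");
    the unsampled branch never exchanges migrants and is not simulated.
    """

    phases: tuple[Phase, ...]
    branch: str = "constant-branch"
    ancestral_size: float | None = None

    def __post_init__(self) -> None:
        if not self.phases:
            raise ConfigError("schedule needs at least one phase")
        for prev, nxt in zip(self.phases, self.phases[1:]):
            if abs(prev.end_size - nxt.start_size) > 1e-9 * prev.end_size:
                raise ConfigError("phase sizes must be continuous at boundaries")
        if self.ancestral_size is None:
            object.__setattr__(self, "ancestral_size", self.phases[0].start_size)
        elif self.ancestral_size <= 0:
            raise ConfigError("ancestral size must be positive")

    @property
    def final_size(self) -> float:
        return self.phases[-1].end_size


def constant_schedule(Ne: float, duration: float = 1.0) -> DemographySchedule:
    """A population of constant diploid size ``Ne`` for all time."""
    return DemographySchedule(
        phases=(Phase(duration, Ne, Ne, "constant"),), branch="constant-branch"
    )


def growth_schedule(
    branch: str = "exponential-branch",
    base_Ne: float = 10_000,
    split_fraction: float = 0.5,
    shared_end: float = 9_210,
    final_size: float = 512_210,
    shared_duration: float = 2_040,
    growth_duration: float = 920,
) -> DemographySchedule:
    """The two-branch human growth model.

    An ancestral population of ``base_Ne`` diploids splits into two
    daughters of ``split_fraction * base_Ne`` each; both grow slowly and at
    the same rate to ``shared_end``. Afterwards the exponential branch
    grows to ``final_size`` over ``growth_duration`` generations while the
    constant branch stays at ``shared_end``. Only the sampled branch is
    simulated (no migration after the split).

    Phase durations are a reconstruction from the two-epoch human-growth
    literature (the demographic endpoints do not determine them uniquely)
    and are fully overridable.
    """
    shared = Phase(
        shared_duration, split_fraction * base_Ne, shared_end, "exponential"
    )
    if branch == "exponential-branch":
        tail = Phase(growth_duration, shared_end, final_size, "exponential")
    elif branch == "constant-branch":
        tail = Phase(growth_duration, shared_end, shared_end, "constant")
    else:
        raise ConfigError(f"unknown branch {branch!r}")
    return DemographySchedule(
        phases=(shared, tail), branch=branch, ancestral_size=base_Ne
    )


@dataclass(frozen=True)
class DFEConfig:
    """Distribution of fitness effects for new mutations.

    ``mean_gamma`` is the mean scaled selection coefficient
    gamma_bar = 2 N_e s_bar (against the *unrescaled* base N_e);
    ``shape`` the gamma shape; ``neutral_fraction`` the probability a new
    mutation (equivalently, the fraction of sites) is neutral.
    """

    shape: float = 0.206
    mean_gamma: float = 0.0
    neutral_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.shape <= 0:
            raise ConfigError("gamma shape must be positive")
        if self.mean_gamma < 0:
            raise ConfigError("mean_gamma must be >= 0")
        if not 0.0 <= self.neutral_fraction <= 1.0:
            raise ConfigError("neutral_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    seq_length: int = 5_000
    base_Ne: float = 10_000
    mu: float = 1e-8
    demography: DemographySchedule = field(
        default_factory=lambda: constant_schedule(10_000)
    )
    dfe: DFEConfig = field(default_factory=DFEConfig)
    rescale_lambda: float = 1.0
    applied_lambda: float = 1.0  # product of rescalings already applied
    sample_sizes: tuple[int, ...] = DEFAULT_SAMPLE_SIZES
    n_replicates: int = 1_000
    seed: int = 0
    burn_in_factor: float = 10.0  # burn-in = factor * ancestral N' generations
    prune_interval: int = 25

    def __post_init__(self) -> None:
        if self.rescale_lambda < 1 or self.applied_lambda < 1:
            raise ConfigError("rescaling factor must be >= 1")
        if not self.sample_sizes:
            raise ConfigError("at least one sample size required")
        if min(self.sample_sizes) < 2:
            raise ConfigError("sample sizes must be >= 2 haplotypes")
        object.__setattr__(self, "sample_sizes", tuple(int(n) for n in self.sample_sizes))

    def config_hash(self) -> str:
        payload = json.dumps(_as_jsonable(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _as_jsonable(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _as_jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__}
    if isinstance(obj, (tuple, list)):
        return [_as_jsonable(x) for x in obj]
    return obj


@dataclass
class ReplicateSample:
    """Nested samples from one simulated locus.

    ``sfs[(n, site_class)]`` is the folded spectrum of the first ``n``
    haplotypes of the replicate's sampling permutation, so smaller samples
    are strict subsets of larger ones.
    """

    replicate: int
    sfs: dict[tuple[int, str], SiteFrequencySpectrum]
    config_hash: str
    diagnostics: dict = field(default_factory=dict)


def rescale(config: SimulationConfig) -> SimulationConfig:
    """Apply the theta-preserving rescaling ``rescale_lambda``.

    Returns a config with N / lambda, durations / lambda, mu * lambda and
    ``applied_lambda`` recording the cumulative selection multiplier
    (s values drawn at run time are multiplied by it). The neutral expected
    theta is invariant (see :func:`sfsweep.coalescent.expected_theta_neutral`).
    """
    lam = config.rescale_lambda
    if lam == 1.0:
        return config
    phases = tuple(
        Phase(
            duration=max(1.0, p.duration / lam),
            start_size=p.start_size / lam,
            end_size=p.end_size / lam,
            mode=p.mode,
        )
        for p in config.demography.phases
    )
    demog = DemographySchedule(
        phases=phases,
        branch=config.demography.branch,
        ancestral_size=config.demography.ancestral_size / lam,
    )
    if 2 * int(round(demog.final_size)) < max(config.sample_sizes):
        raise ConfigError(
            f"lambda={lam} shrinks the final population below the largest "
            f"sample ({max(config.sample_sizes)} haplotypes)"
        )
    return replace(
        config,
        demography=demog,
        mu=config.mu * lam,
        rescale_lambda=1.0,
        applied_lambda=config.applied_lambda * lam,
    )


def _size_trajectory(config: SimulationConfig) -> np.ndarray:
    """Haploid population size per generation: burn-in then each phase."""
    demog = config.demography
    sizes: list[int] = []
    n_anc = int(round(demog.ancestral_size))
    burn = int(round(config.burn_in_factor * n_anc))
    sizes.extend([2 * n_anc] * burn)
    sizes.append(2 * int(round(demog.phases[0].start_size)))  # split, if any
    for phase in demog.phases:
        dur = int(round(phase.duration))
        for g in range(1, dur + 1):
            sizes.append(2 * int(round(phase.size_at(g * phase.duration / dur))))
    return np.asarray(sizes, dtype=np.int64)


def _simulate_replicate(config: SimulationConfig, rng: np.random.Generator):
    L = config.seq_length
    u_hap = config.mu * L  # per-haplotype per-generation mutation rate
    dfe = config.dfe
    lam = config.applied_lambda
    # raw (unrescaled) selection coefficients: mean s_bar = gamma_bar / (2 Ne)
    s_scale = (
        dfe.mean_gamma / (2.0 * config.base_Ne * dfe.shape)
        if dfe.mean_gamma > 0
        else 0.0
    )

    # haplotype classes: identical-by-descent genomes share one entry
    counts = np.array([0], dtype=np.int64)
    fitness = np.array([1.0])
    mutsets: list[frozenset[int]] = [frozenset()]

    mut_site: dict[int, int] = {}
    mut_neutral: dict[int, bool] = {}
    occupied: set[int] = set()
    next_id = 0
    n_capped = 0
    n_fixed = 0
    n_redraws = 0

    trajectory = _size_trajectory(config)
    counts[0] = trajectory[0]

    def prune() -> None:
        nonlocal counts, fitness, mutsets, n_fixed
        total = int(counts.sum())
        freq: dict[int, int] = {}
        for c, mset in zip(counts, mutsets):
            for mid in mset:
                freq[mid] = freq.get(mid, 0) + int(c)
        lost = [mid for mid in mut_site if freq.get(mid, 0) == 0]
        fixed = {mid for mid, f in freq.items() if f == total}
        for mid in lost:
            occupied.discard(mut_site.pop(mid))
            mut_neutral.pop(mid, None)
        if fixed:
            # fixed mutations are substitutions: no longer polymorphic, but
            # their sites stay blocked (infinite-sites on a finite grid)
            n_fixed += len(fixed)
            for mid in fixed:
                mut_site.pop(mid, None)
                mut_neutral.pop(mid, None)
            mutsets = [mset - fixed for mset in mutsets]
        # merge classes that have become identical
        merged: dict[frozenset[int], int] = {}
        new_counts: list[int] = []
        new_fitness: list[float] = []
        new_sets: list[frozenset[int]] = []
        for c, w, mset in zip(counts, fitness, mutsets):
            if c == 0:
                continue
            j = merged.get(mset)
            if j is None:
                merged[mset] = len(new_sets)
                new_counts.append(int(c))
                new_fitness.append(w)
                new_sets.append(mset)
            else:
                new_counts[j] += int(c)
        counts = np.asarray(new_counts, dtype=np.int64)
        fitness = np.asarray(new_fitness)
        mutsets = new_sets

    for gen, next_2n in enumerate(trajectory[1:], start=1):
        w = counts * fitness
        counts = rng.multinomial(next_2n, w / w.sum())
        keep = counts > 0
        if not keep.all():
            counts = counts[keep]
            fitness = fitness[keep]
            mutsets = [mutsets[i] for i in np.flatnonzero(keep)]
        n_mut = rng.poisson(next_2n * u_hap)
        for _ in range(n_mut):
            i = int(rng.choice(counts.size, p=counts / counts.sum()))
            site = int(rng.integers(L))
            while site in occupied:
                site = int(rng.integers(L))
                n_redraws += 1
            neutral = rng.random() < dfe.neutral_fraction
            if neutral or s_scale == 0.0:
                s, neutral = 0.0, True
            else:
                s = lam * rng.gamma(dfe.shape, s_scale)
                if s >= 1.0:
                    s = 1.0
                    n_capped += 1
            mid = next_id
            next_id += 1
            mut_site[mid] = site
            mut_neutral[mid] = neutral
            occupied.add(site)
            counts[i] -= 1
            counts = np.append(counts, 1)
            fitness = np.append(fitness, fitness[i] * (1.0 - s / 2.0))
            mutsets.append(mutsets[i] | {mid})
        if gen % config.prune_interval == 0:
            prune()
    prune()

    # --- nested sampling without replacement ------------------------------
    n_max = max(config.sample_sizes)
    total = int(counts.sum())
    hap_classes = np.repeat(np.arange(counts.size), counts)
    sampled = hap_classes[rng.permutation(total)[:n_max]]

    seg_ids = sorted(mut_site)
    id_index = {mid: j for j, mid in enumerate(seg_ids)}
    # class x mutation incidence
    incid = np.zeros((counts.size, len(seg_ids)), dtype=np.int64)
    for ci, mset in enumerate(mutsets):
        for mid in mset:
            incid[ci, id_index[mid]] = 1
    neutral_mask = np.array([mut_neutral[mid] for mid in seg_ids], dtype=bool)

    f = dfe.neutral_fraction
    classes: list[tuple[str, np.ndarray, float]] = []
    if f > 0:
        classes.append(("neutral", neutral_mask, f * L))
    if f < 1:
        classes.append(("constrained", ~neutral_mask, (1.0 - f) * L))

    sfs: dict[tuple[int, str], SiteFrequencySpectrum] = {}
    for n in config.sample_sizes:
        class_counts = np.bincount(sampled[:n], minlength=counts.size)
        allele = class_counts @ incid  # derived-allele count per mutation
        minor = np.minimum(allele, n - allele)
        for label, mask, n_sites in classes:
            m = minor[mask & (allele > 0) & (allele < n)]
            hist = np.bincount(m, minlength=n // 2 + 1)[1:]
            sfs[(n, label)] = SiteFrequencySpectrum(
                n_seq=n, counts=hist, n_sites=n_sites, site_class=label
            )
    diagnostics = {
        "n_capped": n_capped,
        "n_fixed": n_fixed,
        "n_site_redraws": n_redraws,
        "segregating_population": len(seg_ids),
    }
    return sfs, diagnostics


def run_simulation(config: SimulationConfig) -> list[ReplicateSample]:
    """Run all replicates and return per-replicate nested folded spectra."""
    if config.rescale_lambda != 1.0:
        config = rescale(config)
    if 2 * int(round(config.demography.final_size)) < max(config.sample_sizes):
        raise ConfigError("largest sample exceeds the final population")
    chash = config.config_hash()
    out: list[ReplicateSample] = []
    for r in range(config.n_replicates):
        rng = np.random.default_rng([config.seed, r])
        sfs, diag = _simulate_replicate(config, rng)
        out.append(ReplicateSample(r, sfs, chash, diag))
    return out


def replicates_to_frame(samples: Sequence[ReplicateSample]) -> pd.DataFrame:
    """Tidy per-replicate summary: one row per (replicate, n, site_class)."""
    rows = []
    for rep in samples:
        for (n, label), sfs in rep.sfs.items():
            rows.append(
                {
                    "replicate": rep.replicate,
                    "sample_size": n,
                    "site_class": label,
                    "S": sfs.S,
                    "singletons": sfs.singletons,
                    "theta_w": watterson_theta(sfs),
                    "pi": nucleotide_diversity(sfs),
                    "n_sites": sfs.n_sites,
                }
            )
    return pd.DataFrame(rows)


def mean_theta_by_size(
    samples: Sequence[ReplicateSample], site_class: str | None = None
) -> pd.DataFrame:
    """Mean and SE of per-site theta_W and pi across replicates."""
    df = replicates_to_frame(samples)
    if site_class is not None:
        df = df[df["site_class"] == site_class]
    g = df.groupby(["sample_size", "site_class"])
    out = g.agg(
        theta_w_mean=("theta_w", "mean"),
        theta_w_se=("theta_w", lambda x: x.std(ddof=1) / np.sqrt(len(x))),
        pi_mean=("pi", "mean"),
        pi_se=("pi", lambda x: x.std(ddof=1) / np.sqrt(len(x))),
        S_mean=("S", "mean"),
        n_replicates=("S", "size"),
    ).reset_index()
    return out
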