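"""Coalescent expectations for neutral loci under piecewise demography.

Validation oracle for the forward simulator: the expected Watterson
estimator of a neutral sample is E[theta_W] = mu L E[T_total] / a_n, where
T_total is the total branch length of the sample genealogy. For a
time-varying diploid size N(t) the lineage-count process A(t) is a pure
death chain with rate k(k-1)/(4 N(t)) from k to k-1 (time in generations,
backwards), and E[T_total] = integral of E[A(t) ; A(t) >= 2] dt. We solve
the forward Kolmogorov ODE for the lineage-count distribution through the
finite epochs and close the constant ancestral tail analytically
(from k lineages in a constant-N epoch the remaining expected total length
is 4 N a_k).
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp

from .popgen import harmonic_numbers
from .simulate import DemographySchedule

__all__ = ["expected_total_tree_length", "expected_theta_neutral"]


def _harmonics(n: int) -> np.ndarray:
    """H[k] = sum_{i=1}^{k-1} 1/i for k = 0..n (H[0] = H[1] = 0)."""
    h = np.zeros(n + 1)
    h[2:] = np.cumsum(1.0 / np.arange(1, n))
    return h


def expected_total_tree_length(n_seq: int, demography: DemographySchedule) -> float:
    """E[total branch length], in generations, of an ``n_seq`` sample."""
    if n_seq < 2:
        raise ValueError("need at least 2 sequences")
    phases = demography.phases
    sizes = {p.start_size for p in phases} | {p.end_size for p in phases}
    sizes.add(demography.ancestral_size)
    if len(sizes) == 1:
        # constant for all time: E[T_total] = 4 N a_n exactly
        N = phases[0].start_size
        a_n, _ = harmonic_numbers(n_seq)
        return 4.0 * N * a_n

    n = int(n_seq)
    # state: P[k-1] = P(A = k), k = 1..n, plus accumulated E[length]
    y0 = np.zeros(n + 1)
    y0[n - 1] = 1.0
    k = np.arange(1, n + 1, dtype=np.float64)
    pair = k * (k - 1.0)  # 2 * C(k, 2)

    jac_pattern = sparse.lil_matrix((n + 1, n + 1))
    for j in range(n):
        jac_pattern[j, j] = 1
        if j + 1 < n:
            jac_pattern[j, j + 1] = 1
        jac_pattern[n, j] = 1
    jac_pattern = jac_pattern.tocsr()

    def make_rhs(N_of_tau):
        def rhs(t, y):
            rate = pair / (4.0 * N_of_tau(t))
            flux = rate * y[:n]
            dP = -flux
            dP[:-1] += flux[1:]
            dL = float(np.sum(k[1:] * y[1:n]))
            return np.concatenate([dP, [dL]])

        return rhs

    y = y0
    for phase in reversed(phases):
        d = phase.duration

        def N_of_tau(tau, _p=phase, _d=d):
            return _p.size_at(_d - tau)  # backwards time within the phase

        sol = solve_ivp(
            make_rhs(N_of_tau),
            (0.0, d),
            y,
            method="BDF",
            jac_sparsity=jac_pattern,
            rtol=1e-10,
            atol=1e-14,
        )
        if not sol.success:  # pragma: no cover
            raise RuntimeError(f"coalescent ODE failed: {sol.message}")
        y = sol.y[:, -1]

    # constant ancestral tail before the first phase (merged population if
    # the schedule models a split)
    N_anc = demography.ancestral_size
    P = np.clip(y[:n], 0.0, None)
    H = _harmonics(n)
    tail = 4.0 * N_anc * float(np.sum(P[1:] * H[2 : n + 1]))
    return float(y[n]) + tail


def expected_theta_neutral(
    n_seq: int, demography: DemographySchedule, mu: float, L: float
) -> float:
    """Expected per-locus Watterson theta: mu L E[T_total] / a_n."""
    a_n, _ = harmonic_numbers(n_seq)
    return mu * L * expected_total_tree_length(n_seq, demography) / a_n
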