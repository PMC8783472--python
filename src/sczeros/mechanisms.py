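"""Mechanistic generators of biological and sampling zeros.

Biological zeros: a two-state (telegraph) model of transcriptional bursting.
A promoter switches inactive -> active at rate ``k_a`` and active -> inactive
at rate ``k_i``; while active the gene transcribes mRNA at rate ``s_m``; every
mRNA molecule degrades at rate ``delta``. The stationary mRNA copy-number law
is the Beta(k_a/delta, k_i/delta)-mixed Poisson with intensity (s_m/delta)*u
(the "Beta-Poisson" law of bursty transcription); when ``k_a`` is small the
law puts a mode at zero, producing biological zeros.

Sampling zeros: non-linear PCR amplification distorts gene proportions
(per-molecule binomial duplication each cycle), and a finite sequencing depth
then samples reads multinomially, so lowly represented genes drop to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import special, stats

__all__ = [
    "TelegraphParams",
    "Trajectory",
    "simulate_telegraph",
    "telegraph_stationary_pmf",
    "amplify_pcr",
    "sample_sequencing",
]


@dataclass(frozen=True)
class TelegraphParams:
    """Kinetic rates of the two-state transcription model (arbitrary time
    units; ``delta = 1`` is the conventional normalization)."""

    k_a: float  # inactive -> active switching rate
    k_i: float  # active -> inactive switching rate
    s_m: float  # mRNA synthesis rate while active
    delta: float = 1.0  # per-molecule mRNA degradation rate

    def __post_init__(self) -> None:
        for name in ("k_a", "k_i", "s_m", "delta"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be a finite non-negative rate")
        if self.delta <= 0:
            raise ValueError("delta must be positive")


@dataclass
class Trajectory:
    """One stochastic realization of the telegraph model.

    ``event_times[0]`` is the initial time 0 with the initial state; each
    subsequent entry records the state right after an event. ``t_max`` closes
    the final holding interval.
    """

    event_times: np.ndarray
    copy_numbers: np.ndarray
    promoter_states: np.ndarray
    t_max: float

    def _holding(self, burn_in: float = 0.0):
        t0 = burn_in * self.t_max
        times = self.event_times
        holds = np.diff(np.append(times, self.t_max))
        if t0 > 0:
            # clip intervals to [t0, t_max]
            starts = np.maximum(times, t0)
            ends = np.append(times[1:], self.t_max)
            holds = np.maximum(ends - starts, 0.0)
        return holds

    def time_average_copy_number(self, burn_in: float = 0.1) -> float:
        """Time-averaged mRNA copy number after discarding a burn-in fraction."""
        holds = self._holding(burn_in)
        total = holds.sum()
        if total <= 0:
            return float(self.copy_numbers[-1])
        return float(np.dot(holds, self.copy_numbers) / total)

    def occupancy(self, burn_in: float = 0.1) -> np.ndarray:
        """Holding-time-weighted occupancy distribution over copy numbers."""
        holds = self._holding(burn_in)
        k_max = int(self.copy_numbers.max())
        hist = np.bincount(self.copy_numbers, weights=holds, minlength=k_max + 1)
        total = hist.sum()
        return hist / total if total > 0 else hist


@njit(cache=True)
def _ssa_core(k_a, k_i, s_m, delta, t_max, m0, active0, seed):  # pragma: no cover
    np.random.seed(seed)
    cap = 65536
    times = np.empty(cap)
    copies = np.empty(cap, np.int64)
    states = np.empty(cap, np.int8)
    t = 0.0
    m = m0
    a = active0
    times[0] = 0.0
    copies[0] = m
    states[0] = a
    n = 1
    while True:
        r_switch = k_i if a == 1 else k_a
        r_syn = s_m if a == 1 else 0.0
        r_deg = m * delta
        total = r_switch + r_syn + r_deg
        if total <= 0.0:
            break
        t += np.random.exponential(1.0 / total)
        if t > t_max:
            break
        u = np.random.random() * total
        if u < r_switch:
            a = 1 - a
        elif u < r_switch + r_syn:
            m += 1
        else:
            m -= 1
        if n == cap:
            cap *= 2
            new_t = np.empty(cap)
            new_c = np.empty(cap, np.int64)
            new_s = np.empty(cap, np.int8)
            new_t[:n] = times
            new_c[:n] = copies
            new_s[:n] = states
            times, copies, states = new_t, new_c, new_s
        times[n] = t
        copies[n] = m
        states[n] = a
        n += 1
    return times[:n], copies[:n], states[:n]


def simulate_telegraph(
    params: TelegraphParams,
    t_max: float,
    seed: int,
    initial_copies: int = 0,
    initial_active: bool | None = None,
) -> Trajectory:
    """Exact stochastic simulation (Gillespie SSA) of the telegraph model.

    Four reaction channels: activation at ``k_a`` (when inactive),
    inactivation at ``k_i`` (when active), synthesis at ``s_m`` (when
    active), degradation at ``m * delta``. ``initial_active`` defaults to
    True in the always-active limit (``k_i = 0`` with ``k_a > 0``), else
    False.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if initial_copies < 0:
        raise ValueError("initial_copies must be non-negative")
    if initial_active is None:
        initial_active = params.k_i == 0 and params.k_a > 0
    times, copies, states = _ssa_core(
        params.k_a,
        params.k_i,
        params.s_m,
        params.delta,
        float(t_max),
        int(initial_copies),
        1 if initial_active else 0,
        int(seed) % (2**31),
    )
    return Trajectory(times, copies, states, float(t_max))


def telegraph_stationary_pmf(
    params: TelegraphParams, k_max: int | None = None, n_nodes: int = 128
) -> np.ndarray:
    """Stationary copy-number law of the telegraph model.

    Computed from the Beta-Poisson mixture representation: copy number is
    Poisson with intensity (s_m/delta)*U where U ~ Beta(k_a/delta,
    k_i/delta), evaluated by fixed-order Gauss-Jacobi quadrature. The vector
    is extended until the truncated tail mass is below 1e-8.
    """
    c = params.s_m / params.delta
    if params.k_a == 0 or params.s_m == 0:
        return np.array([1.0])
    if params.k_i == 0:
        # always-active limit: plain Poisson(s_m / delta)
        def pmf_upto(km):
            return stats.poisson.pmf(np.arange(km + 1), c)

    else:
        a = params.k_a / params.delta
        b = params.k_i / params.delta
        # Gauss-Jacobi nodes for weight (1-x)^(b-1) (1+x)^(a-1) on [-1, 1]
        with np.errstate(invalid="ignore"):  # benign in scipy's recurrence
            x, w = special.roots_jacobi(n_nodes, b - 1.0, a - 1.0)
        u = (1.0 + x) / 2.0
        const = w / (2.0 ** (a + b - 1.0) * special.beta(a, b))

        def pmf_upto(km):
            k = np.arange(km + 1)
            # pmf_k = sum_i const_i * Poisson(k; c * u_i)
            logp = stats.poisson.logpmf(k[:, None], np.maximum(c * u, 1e-300)[None, :])
            return np.exp(logp) @ const

    km = k_max if k_max is not None else max(16, int(c * 2))
    pmf = pmf_upto(km)
    while pmf.sum() < 1.0 - 1e-8:
        km *= 2
        if km > 10_000_000:
            raise RuntimeError("stationary pmf failed to capture tail mass")
        pmf = pmf_upto(km)
    return pmf


def amplify_pcr(
    cdna_counts,
    efficiencies,
    cycles: int,
    seed: int | None = None,
    deterministic: bool = False,
):
    """PCR amplification: each molecule duplicates independently per cycle.

    A gene with per-cycle efficiency ``e`` multiplies its count by
    ``(1 + e)`` per cycle in expectation; because amplification is
    exponential, unequal efficiencies distort relative gene proportions.
    With ``deterministic=True`` the exact expectation ``count * (1+e)**c``
    is returned (as floats) instead of a stochastic draw.
    """
    counts = np.asarray(cdna_counts)
    eff = np.asarray(efficiencies, dtype=float)
    if counts.shape != eff.shape:
        raise ValueError("cdna_counts and efficiencies must have equal length")
    if np.any(counts < 0):
        raise ValueError("cdna_counts must be non-negative")
    if np.any((eff < 0) | (eff > 1)):
        raise ValueError("efficiencies must lie in [0, 1]")
    if cycles < 0:
        raise ValueError("cycles must be non-negative")
    if deterministic:
        return counts * (1.0 + eff) ** cycles
    rng = np.random.default_rng(seed)
    out = counts.astype(np.int64).copy()
    for _ in range(cycles):
        out = out + rng.binomial(out, eff)
    return out


def sample_sequencing(
    library_counts, depth: int, n_experiments: int, seed: int | None = None
) -> np.ndarray:
    """Sequencing with limited depth: multinomial sampling of reads.

    Each of ``n_experiments`` experiments draws ``depth`` reads with
    probabilities proportional to the library composition. A gene holding
    proportion pi of the library is missed entirely (a sampling zero) with
    probability (1 - pi)**depth per experiment.
    """
    lib = np.asarray(library_counts, dtype=float)
    if np.any(lib < 0):
        raise ValueError("library_counts must be non-negative")
    total = lib.sum()
    if total <= 0:
        raise ValueError("library must contain at least one molecule")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    return rng.multinomial(int(depth), lib / total, size=int(n_experiments))
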