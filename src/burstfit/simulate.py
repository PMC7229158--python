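"""Synthetic single-cell mRNA count data.

Three generators with the statistical structure the inference assumes:

* exact Gillespie simulation of the three-state promoter with reactions
  C->B (alpha), B->C (beta), B->A (lam), A->B (nu), transcription
  A -> A + mRNA (K) and decay mRNA -> 0 (n*delta);
* direct i.i.d. sampling from the zero-inflated negative binomial;
* multi-condition scenario assembly plus injection of artifact
  high-count cells (mimicking hybridisation/imaging artefacts of several
  hundred apparent mRNAs, which the >150-count filter removes).

All randomness flows through explicit seeds; no global RNG state is
touched.  The per-event simulation cores are numba-compiled.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from numba import njit

from .data import CountData
from .zinb import BurstModelParams, ZINBParams, zinb_moments

__all__ = [
    "Trajectory",
    "sample_zinb",
    "simulate_ssa",
    "simulate_population",
    "sample_population_ssa",
    "stationary_state_distribution",
    "default_relaxation_time",
    "inject_artifact_cells",
    "generate_scenario",
]

STATE_C, STATE_B, STATE_A = 0, 1, 2
STATE_NAMES = ("C", "B", "A")
_STATE_INDEX = {"C": STATE_C, "B": STATE_B, "A": STATE_A}


@dataclass
class Trajectory:
    """One stochastic promoter/mRNA trajectory.

    ``times`` are event times (strictly increasing, starting at 0 with the
    initial condition); ``states`` and ``mrna`` give the promoter state
    index (0=C, 1=B, 2=A) and copy number immediately after each event.
    ``t_end`` is the requested horizon (the last interval extends to it).
    """

    times: np.ndarray
    states: np.ndarray
    mrna: np.ndarray
    t_end: float

    def state_occupancy(self, t_start: float = 0.0) -> np.ndarray:
        """Fraction of time in each promoter state over [t_start, t_end]."""
        edges = np.append(self.times, self.t_end)
        occ = np.zeros(3)
        for s in (STATE_C, STATE_B, STATE_A):
            mask = self.states == s
            dur = np.clip(edges[1:], t_start, None) - np.clip(edges[:-1], t_start, None)
            occ[s] = np.sum(dur[mask])
        return occ / (self.t_end - t_start)

    def time_average_mrna(self, t_start: float = 0.0) -> float:
        edges = np.append(self.times, self.t_end)
        dur = np.clip(edges[1:], t_start, None) - np.clip(edges[:-1], t_start, None)
        return float(np.sum(dur * self.mrna) / (self.t_end - t_start))


@njit(cache=True)
def _ssa_events(alpha, beta, lam, nu, K, delta, t_end, state0, m0, seed):
    """Direct-method Gillespie core; returns padded event arrays and count."""
    np.random.seed(seed)
    cap = 1024
    times = np.empty(cap)
    states = np.empty(cap, dtype=np.int8)
    mrna = np.empty(cap, dtype=np.int64)
    t = 0.0
    s = state0
    m = m0
    n_ev = 0
    times[0] = 0.0
    states[0] = s
    mrna[0] = m
    n_ev = 1
    while True:
        a_cb = alpha if s == STATE_C else 0.0
        a_bc = beta if s == STATE_B else 0.0
        a_ba = lam if s == STATE_B else 0.0
        a_ab = nu if s == STATE_A else 0.0
        a_tx = K if s == STATE_A else 0.0
        a_dec = delta * m
        total = a_cb + a_bc + a_ba + a_ab + a_tx + a_dec
        if total == 0.0:
            break  # absorbing: constant trajectory to t_end
        t += np.random.exponential(1.0 / total)
        if t > t_end:
            break
        u = np.random.random() * total
        if u < a_cb:
            s = STATE_B
        elif u < a_cb + a_bc:
            s = STATE_C
        elif u < a_cb + a_bc + a_ba:
            s = STATE_A
        elif u < a_cb + a_bc + a_ba + a_ab:
            s = STATE_B
        elif u < a_cb + a_bc + a_ba + a_ab + a_tx:
            m += 1
        else:
            m -= 1
        if n_ev == cap:
            cap *= 2
            new_times = np.empty(cap)
            new_states = np.empty(cap, dtype=np.int8)
            new_mrna = np.empty(cap, dtype=np.int64)
            new_times[:n_ev] = times
            new_states[:n_ev] = states
            new_mrna[:n_ev] = mrna
            times, states, mrna = new_times, new_states, new_mrna
        times[n_ev] = t
        states[n_ev] = s
        mrna[n_ev] = m
        n_ev += 1
    return times[:n_ev], states[:n_ev], mrna[:n_ev]


@njit(cache=True)
def _ssa_final(alpha, beta, lam, nu, K, delta, t_end, state0, m0):
    """Terminal (state, count) of one trajectory; RNG must be pre-seeded."""
    t = 0.0
    s = state0
    m = m0
    while True:
        a_cb = alpha if s == STATE_C else 0.0
        a_bc = beta if s == STATE_B else 0.0
        a_ba = lam if s == STATE_B else 0.0
        a_ab = nu if s == STATE_A else 0.0
        a_tx = K if s == STATE_A else 0.0
        a_dec = delta * m
        total = a_cb + a_bc + a_ba + a_ab + a_tx + a_dec
        if total == 0.0:
            return s, m
        t += np.random.exponential(1.0 / total)
        if t > t_end:
            return s, m
        u = np.random.random() * total
        if u < a_cb:
            s = STATE_B
        elif u < a_cb + a_bc:
            s = STATE_C
        elif u < a_cb + a_bc + a_ba:
            s = STATE_A
        elif u < a_cb + a_bc + a_ba + a_ab:
            s = STATE_B
        elif u < a_cb + a_bc + a_ba + a_ab + a_tx:
            m += 1
        else:
            m -= 1


@njit(cache=True)
def _population_final(alpha, beta, lam, nu, K, delta, t_end, states0, m0, seeds):
    n = states0.shape[0]
    out_states = np.empty(n, dtype=np.int8)
    out_counts = np.empty(n, dtype=np.int64)
    for i in range(n):
        np.random.seed(seeds[i])
        s, m = _ssa_final(alpha, beta, lam, nu, K, delta, t_end, states0[i], m0)
        out_states[i] = s
        out_counts[i] = m
    return out_states, out_counts


def stationary_state_distribution(rates: BurstModelParams) -> np.ndarray:
    """Exact stationary distribution (pi_C, pi_B, pi_A) of the promoter chain.

    The chain C<->B<->A is a birth-death chain, so detailed balance gives
    pi proportional to (1, alpha/beta, alpha*lam/(beta*nu)); degenerate
    rate combinations are handled by solving the generator null space.
    """
    a, b, l, v = rates.alpha, rates.beta, rates.lam, rates.nu
    Q = np.array(
        [
            [-a, a, 0.0],
            [b, -(b + l), l],
            [0.0, v, -v],
        ]
    )
    # null space of Q^T
    _, _, vt = np.linalg.svd(Q.T)
    pi = np.abs(vt[-1])
    return pi / pi.sum()


def default_relaxation_time(rates: BurstModelParams) -> float:
    """Default horizon 20*max(1/delta, 1/(alpha+beta)) for stationarity."""
    slow = 1.0 / (rates.alpha + rates.beta) if rates.alpha + rates.beta > 0 else 0.0
    return 20.0 * max(1.0 / rates.delta, slow)


def _seed_array(seed: int, n: int) -> np.ndarray:
    ss = np.random.SeedSequence(seed)
    return ss.generate_state(n, dtype=np.uint32).astype(np.int64)


def simulate_ssa(
    rates: BurstModelParams,
    t_end: float,
    initial_state: str = "C",
    initial_mrna: int = 0,
    seed: int = 0,
) -> Trajectory:
    """Exact stochastic simulation of one cell up to time ``t_end``."""
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if initial_mrna < 0:
        raise ValueError("initial_mrna must be non-negative")
    s0 = _STATE_INDEX[initial_state]
    sub_seed = int(_seed_array(seed, 1)[0])
    times, states, mrna = _ssa_events(
        rates.alpha, rates.beta, rates.lam, rates.nu, rates.K, rates.delta,
        float(t_end), s0, int(initial_mrna), sub_seed,
    )
    return Trajectory(times=times, states=states.astype(np.int8), mrna=mrna, t_end=float(t_end))


def simulate_population(
    rates: BurstModelParams,
    n_cells: int,
    t_end: float,
    initial_state: str | None = None,
    initial_mrna: int = 0,
    seed: int = 0,
    condition: str = "ssa",
) -> tuple[CountData, np.ndarray]:
    """Terminal counts of ``n_cells`` independent trajectories.

    Initial promoter states are drawn from the exact stationary promoter
    distribution unless ``initial_state`` is given; initial mRNA is
    ``initial_mrna`` for every cell.  Returns the dataset and the vector
    of terminal promoter-state fractions (C, B, A).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be positive")
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5354]))
    if initial_state is None:
        pi = stationary_state_distribution(rates)
        states0 = rng.choice(3, size=n_cells, p=pi).astype(np.int8)
    else:
        states0 = np.full(n_cells, _STATE_INDEX[initial_state], dtype=np.int8)
    seeds = _seed_array(seed, n_cells)
    out_states, out_counts = _population_final(
        rates.alpha, rates.beta, rates.lam, rates.nu, rates.K, rates.delta,
        float(t_end), states0, int(initial_mrna), seeds,
    )
    fractions = np.bincount(out_states, minlength=3) / n_cells
    prov = {
        "generator": "ssa_population",
        "seed": seed,
        "t_end": t_end,
        "rates": asdict(rates),
    }
    data = CountData.from_counts(out_counts, condition=condition, provenance=prov)
    return data, fractions


def sample_population_ssa(
    rates: BurstModelParams,
    n_cells: int,
    t_relax: float | None = None,
    seed: int = 0,
    condition: str = "ssa",
) -> tuple[CountData, np.ndarray]:
    """Stationary population snapshot from the mechanistic model.

    ``t_relax`` defaults to 20*max(1/delta, 1/(alpha+beta)); with the
    stationary promoter-state initialisation most of the relaxation burden
    is the mRNA equilibration (~1/delta).
    """
    if t_relax is None:
        t_relax = default_relaxation_time(rates)
    return simulate_population(
        rates, n_cells, t_end=t_relax, initial_state=None, seed=seed, condition=condition
    )


def sample_zinb(
    params: ZINBParams,
    n_cells: int,
    seed: int = 0,
    condition: str = "zinb",
) -> CountData:
    """I.i.d. draws from the ZINB steady state.

    With probability omega a cell is in the deep inactive state and emits
    zero; otherwise the count is negative binomial with shape r and mean
    burst contribution r*p/(1-p).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be positive")
    rng = np.random.default_rng(seed)
    inactive = rng.random(n_cells) < params.omega
    # numpy's negative_binomial(n, q) has pmf C(k+n-1, k) q^n (1-q)^k,
    # i.e. q = 1 - p in our convention
    counts = rng.negative_binomial(params.r, 1.0 - params.p, size=n_cells)
    counts[inactive] = 0
    prov = {
        "generator": "zinb",
        "seed": seed,
        "params": {"omega": params.omega, "r": params.r, "p": params.p},
    }
    return CountData.from_counts(counts, condition=condition, provenance=prov)


def inject_artifact_cells(
    data: CountData,
    fraction: float,
    count_range: tuple[int, int] = (300, 600),
    seed: int = 0,
) -> CountData:
    """Replace a random subset of cells with artifact high counts.

    Emulates hybridisation/imaging artefacts in which cells appear to hold
    several hundred mRNAs; the lower bound must exceed 150 so that the
    standard count filter removes every injected cell.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must lie in [0, 1)")
    lo, hi = count_range
    if lo <= 150:
        raise ValueError("count_range lower bound must exceed 150")
    if hi < lo:
        raise ValueError("count_range must be a non-empty interval")
    rng = np.random.default_rng(seed)
    n = data.n_cells
    mask = rng.random(n) < fraction
    counts = data.frame["count"].to_numpy().copy()
    counts[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))
    frame = data.frame.assign(count=counts)
    prov = dict(data.provenance)
    prov["artifact_cells"] = {
        "seed": seed,
        "fraction": fraction,
        "count_range": [lo, hi],
        "cell_ids": data.frame.loc[mask, "cell_id"].tolist(),
    }
    return CountData(frame=frame, provenance=prov)


def generate_scenario(
    spec: list[tuple[str, ZINBParams | BurstModelParams, int]],
    seed: int = 0,
) -> CountData:
    """Assemble a multi-condition dataset.

    ``spec`` is a list of (condition label, parameters, n_cells); ZINB
    parameter sets are sampled directly, mechanistic rate sets through the
    stationary Gillespie snapshot.  Per-condition seeds are derived from
    the global seed, so adding a condition does not change the others.
    """
    labels = [label for label, _, _ in spec]
    if len(set(labels)) != len(labels):
        raise ValueError("condition labels must be unique")
    parts = []
    for i, (label, params, n_cells) in enumerate(spec):
        child = int(np.random.SeedSequence([seed, i]).generate_state(1, dtype=np.uint32)[0])
        if isinstance(params, ZINBParams):
            part = sample_zinb(params, n_cells, seed=child, condition=label)
        elif isinstance(params, BurstModelParams):
            part, _ = sample_population_ssa(params, n_cells, seed=child, condition=label)
        else:
            raise TypeError(f"unsupported parameter type {type(params)!r}")
        part.frame["cell_id"] = [f"{label}_{j:06d}" for j in range(n_cells)]
        parts.append(part)
    out = CountData.concat(parts)
    out.provenance["generator"] = "scenario"
    out.provenance["seed"] = seed
    return out
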