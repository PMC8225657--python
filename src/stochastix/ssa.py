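"""Exact Gillespie stochastic simulation of a reaction system.

Direct-method SSA: at each iteration the time advances by
``tau = ln(1/r) / P`` with ``r ~ U(0,1)`` and ``P`` the summed propensity,
and one reaction fires with probability proportional to its propensity.
Each simulation starts with a burn (warm-up) phase in which only genes
flagged as burn-active may be transcribed; recorded burn rows carry
negative times and cells are never sampled from them.

Molecule counts, reaction propensities and per-interval firing counts are
recorded on a census grid (every ``census_interval`` time units); with a
census interval of 0 every single event is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .kinetics import ReactionSystem

__all__ = ["SSAConfig", "SimulationTrace", "ssa_step", "simulate", "run_simulations"]


@dataclass
class SSAConfig:
    total_time: float = 10.0
    burn_time: float = 2.0
    census_interval: float = 0.01
    num_simulations: int = 32
    seed: int | None = None
    max_event_records: int = 2_000_000  # cap when census_interval == 0

    def __post_init__(self) -> None:
        if self.total_time <= 0:
            raise ValueError("total_time must be positive")
        if self.census_interval < 0:
            raise ValueError("census_interval must be >= 0")
        if self.num_simulations < 1:
            raise ValueError("num_simulations must be >= 1")


@dataclass
class SimulationTrace:
    """Census-time record of one SSA run (burn rows have negative times)."""

    times: np.ndarray              # (n,)
    counts: np.ndarray             # (n, 3G) int64
    propensities: np.ndarray       # (n, 6G)
    firings: np.ndarray            # (n, 6G) int64
    sim_index: int = 0

    @property
    def main_rows(self) -> np.ndarray:
        return self.times >= 0


@njit(cache=False)
def _tx_propensities(
    s, G, xpr, ba, sy, tptr, reg_idx, k_arr, n_arr, eff_arr, reg_offset, tx_mask
):
    f = np.empty(G)
    for g in range(G):
        lo, hi = tptr[g], tptr[g + 1]
        if hi == lo:
            f[g] = xpr[g] * ba[g]
        else:
            numer_prod = 1.0
            denom = 1.0
            n_act = 0
            for e in range(lo, hi):
                nu = (s[reg_offset + reg_idx[e]] / k_arr[e]) ** n_arr[e]
                denom *= nu + 1.0
                if eff_arr[e] > 0:
                    numer_prod *= nu + sy[g]
                    n_act += 1
            numer = ba[g] - sy[g] ** n_act + numer_prod
            f[g] = xpr[g] * numer / denom
        if f[g] < 0.0:
            f[g] = 0.0
        f[g] *= tx_mask[g]
    return f


@njit(cache=False)
def _all_propensities(
    s, G, xpr, ba, sy, spl, tr, dx, dy, dz,
    tptr, reg_idx, k_arr, n_arr, eff_arr, reg_offset, tx_mask,
):
    props = np.empty(6 * G)
    f = _tx_propensities(
        s, G, xpr, ba, sy, tptr, reg_idx, k_arr, n_arr, eff_arr, reg_offset, tx_mask
    )
    for g in range(G):
        props[6 * g + 0] = f[g]
        props[6 * g + 1] = spl[g] * s[g]
        props[6 * g + 2] = tr[g] * s[G + g]
        props[6 * g + 3] = dx[g] * s[g]
        props[6 * g + 4] = dy[g] * s[G + g]
        props[6 * g + 5] = dz[g] * s[2 * G + g]
    return props


@njit(cache=False)
def _apply_reaction(s, j, G):
    g = j // 6
    r = j % 6
    if r == 0:
        s[g] += 1                       # transcription: +x
    elif r == 1:
        s[g] -= 1                       # splicing: -x +y
        s[G + g] += 1
    elif r == 2:
        s[2 * G + g] += 1               # translation: +z (y catalytic)
    elif r == 3:
        s[g] -= 1                       # pre-mRNA degradation
    elif r == 4:
        s[G + g] -= 1                   # mRNA degradation
    else:
        s[2 * G + g] -= 1               # protein degradation


@njit(cache=False)
def _ssa_core(
    s, G, xpr, ba, sy, spl, tr, dx, dy, dz,
    tptr, reg_idx, k_arr, n_arr, eff_arr, reg_offset, tx_mask,
    t0, t_end, census_interval, seed,
    rec_times, rec_counts, rec_props, rec_fir,
):
    """Direct-method SSA from t0 to t_end; fills the rec_* arrays.

    Returns the number of records written. With census_interval > 0 the
    record grid is t0 + i * census_interval; a census row carries the state
    after all events strictly before its census time and the firing counts
    since the previous census, so stoichiometry times firings reproduces the
    abundance deltas between rows exactly.
    """
    np.random.seed(seed)
    n_max = rec_times.shape[0]
    nR = 6 * G
    fir = np.zeros(nR, dtype=np.int64)
    props = _all_propensities(
        s, G, xpr, ba, sy, spl, tr, dx, dy, dz,
        tptr, reg_idx, k_arr, n_arr, eff_arr, reg_offset, tx_mask,
    )
    t = t0
    rec = 0
    if census_interval > 0.0:
        # initial census row at t0
        rec_times[rec] = t0
        rec_counts[rec] = s
        rec_props[rec] = props
        rec_fir[rec] = fir
        rec += 1
        next_census = t0 + census_interval
        while True:
            P = props.sum()
            if P <= 0.0:
                t_new = t_end + census_interval  # absorbing: flush the rest
            else:
                r1 = np.random.random()
                t_new = t + (1.0 / P) * np.log(1.0 / r1)
            while rec < n_max and next_census <= t_new and next_census <= t_end + 1e-12:
                rec_times[rec] = next_census
                rec_counts[rec] = s
                rec_props[rec] = props
                rec_fir[rec] = fir
                fir = np.zeros(nR, dtype=np.int64)
                rec += 1
                next_census += census_interval
            if P <= 0.0 or t_new > t_end or rec >= n_max:
                break
            # choose the firing reaction proportionally to its propensity
            target = np.random.random() * P
            acc = 0.0
            j = nR - 1
            for jj in range(nR):
                acc += props[jj]
                if acc >= target:
                    j = jj
                    break
            _apply_reaction(s, j, G)
            fir[j] += 1
            t = t_new
            props = _all_propensities(
                s, G, xpr, ba, sy, spl, tr, dx, dy, dz,
                tptr, reg_idx, k_arr, n_arr, eff_arr, reg_offset, tx_mask,
            )
    else:
        # census_interval == 0: record every event
        rec_times[rec] = t0
        rec_counts[rec] = s
        rec_props[rec] = props
        rec_fir[rec] = fir
        rec += 1
        while rec < n_max:
            P = props.sum()
            if P <= 0.0:
                break
            r1 = np.random.random()
            t_new = t + (1.0 / P) * np.log(1.0 / r1)
            if t_new > t_end:
                break
            target = np.random.random() * P
            acc = 0.0
            j = nR - 1
            for jj in range(nR):
                acc += props[jj]
                if acc >= target:
                    j = jj
                    break
            _apply_reaction(s, j, G)
            t = t_new
            props = _all_propensities(
                s, G, xpr, ba, sy, spl, tr, dx, dy, dz,
                tptr, reg_idx, k_arr, n_arr, eff_arr, reg_offset, tx_mask,
            )
            rec_times[rec] = t
            rec_counts[rec] = s
            rec_props[rec] = props
            rec_fir[rec, :] = 0
            rec_fir[rec, j] = 1
            rec += 1
    return rec


def ssa_step(
    propensities: np.ndarray, rng: np.random.Generator
) -> tuple[float, int]:
    """One direct-method SSA draw: (time increment tau, reaction index).

    tau = ln(1/r) / P with r ~ U(0,1); the reaction is chosen with
    probability proportional to its propensity.  With zero total propensity
    the state is absorbing: returns (inf, -1).
    """
    props = np.asarray(propensities, dtype=float)
    P = props.sum()
    if P <= 0:
        return float("inf"), -1
    r = rng.random()
    tau = np.log(1.0 / r) / P
    j = int(np.searchsorted(np.cumsum(props), rng.random() * P, side="left"))
    return float(tau), min(j, props.size - 1)


def _run_phase(
    system: ReactionSystem,
    s: np.ndarray,
    tx_mask: np.ndarray,
    t0: float,
    t_end: float,
    census_interval: float,
    seed: int,
    max_event_records: int,
):
    if census_interval > 0:
        n_max = int(np.floor((t_end - t0) / census_interval + 1e-9)) + 1
    else:
        n_max = max_event_records
    G = system.num_genes
    rec_times = np.zeros(n_max)
    rec_counts = np.zeros((n_max, 3 * G), dtype=np.int64)
    rec_props = np.zeros((n_max, 6 * G))
    rec_fir = np.zeros((n_max, 6 * G), dtype=np.int64)
    rec = _ssa_core(
        s, G, system.xpr, system.ba, system.sy, system.spl, system.tr,
        system.dx, system.dy, system.dz,
        system.tptr, system.reg_idx, system.k_arr, system.n_arr, system.eff_arr,
        system.reg_offset, tx_mask,
        t0, t_end, census_interval, seed,
        rec_times, rec_counts, rec_props, rec_fir,
    )
    # absorbing states may leave census rows unwritten: hold the final state
    # with zero propensities and zero firings
    if census_interval > 0 and rec < n_max:
        for i in range(rec, n_max):
            rec_times[i] = t0 + i * census_interval
            rec_counts[i] = s
        rec = n_max
    return rec_times[:rec], rec_counts[:rec], rec_props[:rec], rec_fir[:rec], s


def simulate(
    system: ReactionSystem,
    config: SSAConfig | None = None,
    sim_index: int = 0,
    seed: int | None = None,
) -> SimulationTrace:
    """Run one SSA simulation: burn phase from the zero state, then the main
    phase from the burn end state with all genes unmasked."""
    cfg = config or SSAConfig()
    if seed is None:
        seed = cfg.seed if cfg.seed is not None else 0
    ss = np.random.SeedSequence([int(seed), sim_index])
    burn_seed, main_seed = [int(x) for x in ss.generate_state(2) % (2 ** 31)]
    G = system.num_genes
    s = np.zeros(3 * G, dtype=np.int64)
    burn_mask = system.burn_genes.astype(np.float64)
    main_mask = np.ones(G, dtype=np.float64)

    parts = []
    if cfg.burn_time > 0:
        bt, bc, bp, bf, s = _run_phase(
            system, s, burn_mask, -cfg.burn_time, 0.0,
            cfg.census_interval, burn_seed, cfg.max_event_records,
        )
        keep = bt < 0  # the t=0 row is re-recorded by the main phase
        parts.append((bt[keep], bc[keep], bp[keep], bf[keep]))
    mt, mc, mp, mf, s = _run_phase(
        system, s, main_mask, 0.0, cfg.total_time,
        cfg.census_interval, main_seed, cfg.max_event_records,
    )
    parts.append((mt, mc, mp, mf))
    times = np.concatenate([p[0] for p in parts])
    counts = np.concatenate([p[1] for p in parts])
    props = np.concatenate([p[2] for p in parts])
    fir = np.concatenate([p[3] for p in parts])
    return SimulationTrace(times, counts, props, fir, sim_index=sim_index)


def run_simulations(
    system: ReactionSystem, config: SSAConfig | None = None
) -> list[SimulationTrace]:
    """Run ``config.num_simulations`` independent, reproducibly seeded runs."""
    cfg = config or SSAConfig()
    seed = cfg.seed if cfg.seed is not None else 0
    return [simulate(system, cfg, sim_index=i, seed=seed) for i in range(cfg.num_simulations)]
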