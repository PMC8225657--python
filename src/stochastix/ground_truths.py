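"""Per-cell ground truths: RNA velocity and the cell-specific regulatory network.

RNA velocity of a gene at a recorded state is the difference between its
transcription propensity and its mRNA decay propensity — positive when
expression is about to rise, negative when it is about to fall.

The cell-specific regulatory effect of an interaction R -> T at state S is
the drop in T's transcription propensity when the regulator's abundance is
zeroed, scaled by 1/xpr_T; it lies in [-1, 1], with -1 complete inhibition,
+1 maximal activation and 0 an inactive interaction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .kinetics import ReactionSystem

__all__ = [
    "compute_velocity_ground_truth",
    "compute_regulatory_effect",
    "compute_cell_specific_grn",
]


def compute_velocity_ground_truth(
    propensities: np.ndarray,
    system: ReactionSystem | None = None,
    layer: str = "mature",
) -> np.ndarray:
    """Ground-truth velocity matrix from recorded reaction propensities.

    ``propensities`` has shape (cells, 6G) in the engine's reaction order
    (six per gene). ``layer`` selects which mRNA molecule the velocity is
    about: ``"mature"`` uses transcription minus mature-mRNA degradation,
    ``"premrna"`` transcription minus pre-mRNA removal (splicing plus
    degradation).
    """
    p = np.atleast_2d(np.asarray(propensities, dtype=float))
    if p.shape[1] % 6 != 0:
        raise ValueError("propensity matrix must have 6 columns per gene")
    tx = p[:, 0::6]
    if layer == "mature":
        decay = p[:, 4::6]
    elif layer == "premrna":
        decay = p[:, 1::6] + p[:, 3::6]
    else:
        raise ValueError("layer must be 'mature' or 'premrna'")
    return tx - decay


def _gene_propensity_with_masked_regulator(
    nu: np.ndarray, act: np.ndarray, ba: float, sy: float, xpr: float,
    masked: int | None = None,
) -> np.ndarray:
    """Closed-form transcription propensity from per-cell Hill terms,
    optionally with one regulator's term forced to zero (unbound)."""
    nu = nu.copy()
    if masked is not None:
        nu[:, masked] = 0.0
    numer = ba - sy ** act.sum() + np.prod(nu[:, act] + sy, axis=1)
    denom = np.prod(nu + 1.0, axis=1)
    return np.clip(xpr * numer / denom, 0.0, None)


def compute_regulatory_effect(
    state: np.ndarray,
    regulator: str,
    target: str,
    system: ReactionSystem,
) -> float:
    """Regulatory effect of one interaction at one state (scalar form)."""
    df = compute_cell_specific_grn(np.atleast_2d(state), system)
    row = df[(df.regulator == regulator) & (df.target == target)]
    if row.empty:
        raise KeyError(f"interaction {regulator}->{target} not in the GRN")
    return float(row.regeffect.iloc[0])


def compute_cell_specific_grn(
    states: np.ndarray,
    system: ReactionSystem,
    activity_threshold: float = 1e-4,
) -> pd.DataFrame:
    """Regulatory effect of every static-GRN interaction in every cell.

    Returns a long-format frame (cell, regulator, target, regeffect, active)
    with one row per cell x interaction; ``active`` binarizes the ground
    truth at ``activity_threshold`` on \\|regeffect\\|.
    """
    states = np.atleast_2d(np.asarray(states, dtype=float))
    G = system.num_genes
    reg_block = states[:, system.reg_offset:system.reg_offset + G]
    n_cells = states.shape[0]
    frames = []
    for g in range(G):
        lo, hi = int(system.tptr[g]), int(system.tptr[g + 1])
        if hi == lo:
            continue
        regs = system.reg_idx[lo:hi]
        nu = (reg_block[:, regs] / system.k_arr[lo:hi]) ** system.n_arr[lo:hi]
        act = system.eff_arr[lo:hi] > 0
        ba, sy, xpr = system.ba[g], system.sy[g], system.xpr[g]
        f_full = _gene_propensity_with_masked_regulator(nu, act, ba, sy, xpr)
        tname = system.gene_names[g]
        for e in range(hi - lo):
            f_zero = _gene_propensity_with_masked_regulator(nu, act, ba, sy, xpr, masked=e)
            regeffect = (f_full - f_zero) / xpr
            frames.append(
                pd.DataFrame(
                    {
                        "cell": np.arange(n_cells),
                        "regulator": system.gene_names[int(regs[e])],
                        "target": tname,
                        "regeffect": regeffect,
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=["cell", "regulator", "target", "regeffect", "active"])
    out = pd.concat(frames, ignore_index=True)
    out["active"] = out.regeffect.abs() >= activity_threshold
    return out
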