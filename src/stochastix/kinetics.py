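"""Reaction kinetics: from a gene regulatory network to a reaction system.

Every gene G is tracked through three molecule species: pre-mRNA ``x_G``,
mature mRNA ``y_G`` and protein ``z_G``, coupled by six reactions
(transcription, splicing, translation and one degradation per species).
All reactions except transcription have linear (mass-action) propensities.

Transcription follows a thermodynamic model of gene regulation: the
promoter of G can be bound by any subset of its N regulators, each binding
configuration j has a Boltzmann weight w_j (a product of Hill terms
``nu_i = (z_i / k_i)^{n_i}``) and a relative activation ``alpha_j``; the
propensity is the pre-mRNA production rate ``xpr`` times the expected
promoter activity.  With alpha zero whenever a repressor is bound and one
otherwise, the 2^N-state sum collapses to a closed form, further extended
with a basal activity ``ba`` and a regulator synergism ``sy``:

    f(z_1..z_N) = xpr * (ba - sy^|A| + prod_{i in A}(nu_i + sy))
                        / prod_{i in R}(nu_i + 1)

where R is the set of all regulators and A its activating subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grn import GeneRegulatoryNetwork

__all__ = [
    "KineticsConfig",
    "GeneKinetics",
    "InteractionKinetics",
    "Kinetics",
    "Reaction",
    "ReactionSystem",
    "sample_kinetics",
    "hill_part",
    "transcription_propensity",
    "build_reaction_system",
]

REACTION_KINDS = (
    "transcription",
    "splicing",
    "translation",
    "degrade_premrna",
    "degrade_mrna",
    "degrade_protein",
)


@dataclass
class KineticsConfig:
    """Default kinetic constants (units: molecules and reciprocal simulation
    time). The pre-mRNA production rate is the base mRNA production rate
    amplified tenfold; degradation rates derive from half-lives as ln(2)/h."""

    base_mrna_production: float = 1.0
    transcription_amplification: float = 10.0
    premrna_halflife: float = 1.0
    mrna_halflife: float = 1.0
    protein_halflife: float = 2.0
    splicing_rate: float = 2.0
    translation_rate: float = 2.0
    hill_min: float = 2.0
    hill_max: float = 3.0
    synergism: float = 1.0
    # half-occupation is centred at 1/k_scale of the regulator's full
    # steady-state abundance so cascades activate well before saturation
    k_scale: float = 4.0
    # regulator abundance driving transcription: acting species is protein
    regulator_layer: str = "protein"  # or "mrna"
    # multiplicative jitter range on half-occupation constants
    k_jitter: tuple[float, float] = (0.75, 1.25)

    def validate(self) -> None:
        for name in (
            "base_mrna_production", "transcription_amplification",
            "premrna_halflife", "mrna_halflife", "protein_halflife",
            "splicing_rate", "translation_rate",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"kinetics config: {name} must be positive")
        if not 0 <= self.synergism <= 1:
            raise ValueError("synergism must lie in [0, 1]")
        if self.hill_min < 1 or self.hill_max < self.hill_min:
            raise ValueError("Hill coefficient range must satisfy 1 <= min <= max")
        if self.regulator_layer not in ("protein", "mrna"):
            raise ValueError("regulator_layer must be 'protein' or 'mrna'")


@dataclass(frozen=True)
class GeneKinetics:
    gene: str
    xpr: float                # pre-mRNA production rate
    splicing_rate: float
    translation_rate: float
    degradation_premrna: float
    degradation_mrna: float
    degradation_protein: float
    ba: float                 # basal expression in [0, 1]
    sy: float                 # synergism in [0, 1]


@dataclass(frozen=True)
class InteractionKinetics:
    regulator: str
    target: str
    effect: int
    strength: float
    k: float                  # regulator abundance at half-occupation
    n: float                  # Hill coefficient


@dataclass
class Kinetics:
    genes: dict[str, GeneKinetics]
    interactions: list[InteractionKinetics]
    config: KineticsConfig

    def gene_table(self) -> pd.DataFrame:
        return pd.DataFrame([vars(g) for g in self.genes.values()])

    def interaction_table(self) -> pd.DataFrame:
        return pd.DataFrame([vars(i) for i in self.interactions])


def sample_kinetics(
    grn: GeneRegulatoryNetwork,
    rng: np.random.Generator | int | None = None,
    config: KineticsConfig | None = None,
) -> Kinetics:
    """Draw per-gene and per-interaction kinetic constants.

    Gene-level rates come straight from the configuration (xpr is the base
    mRNA production rate amplified by ``transcription_amplification``);
    interaction-level Hill coefficients and half-occupation constants are
    sampled, which is what differentiates independently drawn kinetics of
    the same GRN (e.g. across batches).
    """
    rng = np.random.default_rng(rng)
    cfg = config or KineticsConfig()
    cfg.validate()
    ln2 = np.log(2.0)
    xpr = cfg.base_mrna_production * cfg.transcription_amplification
    dx = ln2 / cfg.premrna_halflife
    dy = ln2 / cfg.mrna_halflife
    dz = ln2 / cfg.protein_halflife
    genes = {
        g.name: GeneKinetics(
            gene=g.name,
            xpr=xpr,
            splicing_rate=cfg.splicing_rate,
            translation_rate=cfg.translation_rate,
            degradation_premrna=dx,
            degradation_mrna=dy,
            degradation_protein=dz,
            ba=g.basal,
            sy=cfg.synergism,
        )
        for g in grn.genes
    }
    # expected regulator abundance at full activation, used to centre k
    x_ss = xpr / (cfg.splicing_rate + dx)
    y_ss = cfg.splicing_rate * x_ss / dy
    z_ss = cfg.translation_rate * y_ss / dz
    reg_ss = z_ss if cfg.regulator_layer == "protein" else y_ss
    interactions = []
    for i in grn.interactions:
        n = float(rng.uniform(cfg.hill_min, cfg.hill_max))
        jitter = float(rng.uniform(*cfg.k_jitter))
        k = reg_ss / (cfg.k_scale * i.strength) * jitter
        interactions.append(
            InteractionKinetics(i.regulator, i.target, i.effect, i.strength, k, n)
        )
    return Kinetics(genes, interactions, cfg)


def hill_part(y: float, k: float, n: float) -> float:
    """Hill term nu = (y / k)^n of one regulator's occupancy.

    At ``y == k`` the term is 1, i.e. half-occupation: nu/(1+nu) = 1/2.
    """
    if np.any(np.asarray(y) < 0):
        raise ValueError("regulator abundance must be non-negative")
    if k <= 0:
        raise ValueError("half-occupation constant must be positive")
    return (y / k) ** n


def transcription_propensity(
    gene_kin: GeneKinetics,
    regulator_abundances: np.ndarray,
    interaction_kins: list[InteractionKinetics],
) -> float:
    """Closed-form transcription propensity of one gene at one state.

    ``regulator_abundances`` is aligned with ``interaction_kins``. Reduces to
    the pure thermodynamic form at ba = sy = 1, and to ``xpr * ba`` when all
    regulators are absent.
    """
    y = np.asarray(regulator_abundances, dtype=float)
    if y.shape != (len(interaction_kins),):
        raise ValueError("one abundance per regulator required")
    nu = np.array([hill_part(y[i], ik.k, ik.n) for i, ik in enumerate(interaction_kins)])
    act = np.array([ik.effect > 0 for ik in interaction_kins], dtype=bool)
    ba, sy = gene_kin.ba, gene_kin.sy
    numer = ba - sy ** act.sum() + np.prod(nu[act] + sy)
    denom = np.prod(nu + 1.0)
    f = gene_kin.xpr * numer / denom
    if f < 0:
        warnings.warn(
            f"negative transcription propensity for {gene_kin.gene} clamped to 0 "
            f"(ba={ba}, sy={sy})"
        )
        f = 0.0
    return float(f)


# ----------------------------------------------------------------------
# reaction system
# ----------------------------------------------------------------------

@dataclass
class Reaction:
    kind: str
    gene: str
    state_change: dict[str, int]
    propensity: "callable"


class ReactionSystem:
    """Full reaction system over species (x_G, y_G, z_G per gene).

    Species are laid out as three blocks of G: pre-mRNA ``x`` at
    ``[0, G)``, mature mRNA ``y`` at ``[G, 2G)``, protein ``z`` at
    ``[2G, 3G)``.  Reactions are ordered six per gene (transcription,
    splicing, translation, then the three degradations), so reaction
    ``6 g + r`` belongs to gene ``g``.

    For the stochastic engine, kinetics are packed into flat arrays with a
    CSR-style layout of interactions grouped by target gene.
    """

    def __init__(self, grn: GeneRegulatoryNetwork, kinetics: Kinetics):
        self.grn = grn
        self.kinetics = kinetics
        names = grn.gene_names
        self.gene_names = names
        G = len(names)
        self.num_genes = G
        self.species_names = (
            [f"x_{n}" for n in names] + [f"y_{n}" for n in names] + [f"z_{n}" for n in names]
        )
        idx = {n: i for i, n in enumerate(names)}
        self.gene_index = idx

        missing = set(names) - set(kinetics.genes)
        if missing:
            raise KeyError(f"kinetics missing for genes: {sorted(missing)}")
        gk = [kinetics.genes[n] for n in names]
        self.xpr = np.array([g.xpr for g in gk])
        self.ba = np.array([g.ba for g in gk])
        self.sy = np.array([g.sy for g in gk])
        self.spl = np.array([g.splicing_rate for g in gk])
        self.tr = np.array([g.translation_rate for g in gk])
        self.dx = np.array([g.degradation_premrna for g in gk])
        self.dy = np.array([g.degradation_mrna for g in gk])
        self.dz = np.array([g.degradation_protein for g in gk])

        # interactions grouped by target gene (CSR layout)
        by_target: dict[int, list[InteractionKinetics]] = {}
        for ik in kinetics.interactions:
            by_target.setdefault(idx[ik.target], []).append(ik)
        self.tptr = np.zeros(G + 1, dtype=np.int64)
        reg_idx, k_arr, n_arr, eff_arr = [], [], [], []
        self._iks_by_gene: list[list[InteractionKinetics]] = []
        for g in range(G):
            iks = by_target.get(g, [])
            self._iks_by_gene.append(iks)
            self.tptr[g + 1] = self.tptr[g] + len(iks)
            for ik in iks:
                reg_idx.append(idx[ik.regulator])
                k_arr.append(ik.k)
                n_arr.append(ik.n)
                eff_arr.append(ik.effect)
        self.reg_idx = np.array(reg_idx, dtype=np.int64)
        self.k_arr = np.array(k_arr, dtype=float)
        self.n_arr = np.array(n_arr, dtype=float)
        self.eff_arr = np.array(eff_arr, dtype=np.int64)
        # regulator abundance layer: protein block by default
        layer = kinetics.config.regulator_layer
        self.reg_offset = 2 * G if layer == "protein" else G
        # genes whose transcription is active during the burn phase
        self.burn_genes = np.array([g.burn for g in grn.genes], dtype=bool)
        self.reactions = self._build_reactions()

    # ------------------------------------------------------------------
    def _build_reactions(self) -> list[Reaction]:
        reactions = []
        G = self.num_genes
        for g, name in enumerate(self.gene_names):
            def tx_prop(state, g=g):
                return float(self.transcription_propensities(np.asarray(state, float))[g])

            reactions.append(Reaction("transcription", name, {f"x_{name}": +1}, tx_prop))
            reactions.append(
                Reaction(
                    "splicing", name, {f"x_{name}": -1, f"y_{name}": +1},
                    lambda s, g=g: float(self.spl[g] * s[g]),
                )
            )
            reactions.append(
                Reaction(
                    "translation", name, {f"z_{name}": +1},
                    lambda s, g=g: float(self.tr[g] * s[G + g]),
                )
            )
            reactions.append(
                Reaction(
                    "degrade_premrna", name, {f"x_{name}": -1},
                    lambda s, g=g: float(self.dx[g] * s[g]),
                )
            )
            reactions.append(
                Reaction(
                    "degrade_mrna", name, {f"y_{name}": -1},
                    lambda s, g=g: float(self.dy[g] * s[G + g]),
                )
            )
            reactions.append(
                Reaction(
                    "degrade_protein", name, {f"z_{name}": -1},
                    lambda s, g=g: float(self.dz[g] * s[2 * G + g]),
                )
            )
        return reactions

    # ------------------------------------------------------------------
    @property
    def num_species(self) -> int:
        return 3 * self.num_genes

    @property
    def num_reactions(self) -> int:
        return 6 * self.num_genes

    def state_change_matrix(self) -> np.ndarray:
        """Dense (reactions x species) stoichiometry matrix."""
        S = np.zeros((self.num_reactions, self.num_species), dtype=np.int64)
        sp_idx = {n: i for i, n in enumerate(self.species_names)}
        for r, rx in enumerate(self.reactions):
            for sp, delta in rx.state_change.items():
                S[r, sp_idx[sp]] = delta
        return S

    def transcription_propensities(
        self, state: np.ndarray, tx_mask: np.ndarray | None = None
    ) -> np.ndarray:
        """Vectorized transcription propensity for all genes.

        ``state`` has shape (..., 3G); returns shape (..., G). ``tx_mask``
        (boolean per gene) forces masked-off genes to zero propensity, which
        implements both the burn phase and per-branch module gating.
        """
        state = np.asarray(state, dtype=float)
        G = self.num_genes
        reg = state[..., self.reg_offset:self.reg_offset + G]
        f = np.empty(state.shape[:-1] + (G,), dtype=float)
        for g in range(G):
            lo, hi = self.tptr[g], self.tptr[g + 1]
            if hi == lo:
                f[..., g] = self.xpr[g] * self.ba[g]
                continue
            nu = (reg[..., self.reg_idx[lo:hi]] / self.k_arr[lo:hi]) ** self.n_arr[lo:hi]
            act = self.eff_arr[lo:hi] > 0
            sy = self.sy[g]
            numer = self.ba[g] - sy ** act.sum() + np.prod(nu[..., act] + sy, axis=-1)
            denom = np.prod(nu + 1.0, axis=-1)
            f[..., g] = self.xpr[g] * numer / denom
        np.clip(f, 0.0, None, out=f)
        if tx_mask is not None:
            f = f * tx_mask
        return f

    def propensities(
        self, state: np.ndarray, tx_mask: np.ndarray | None = None
    ) -> np.ndarray:
        """All 6G reaction propensities at a state (or a stack of states)."""
        state = np.asarray(state, dtype=float)
        G = self.num_genes
        x = state[..., :G]
        y = state[..., G:2 * G]
        z = state[..., 2 * G:3 * G]
        out = np.empty(state.shape[:-1] + (6 * G,), dtype=float)
        out[..., 0::6] = self.transcription_propensities(state, tx_mask)
        out[..., 1::6] = self.spl * x
        out[..., 2::6] = self.tr * y
        out[..., 3::6] = self.dx * x
        out[..., 4::6] = self.dy * y
        out[..., 5::6] = self.dz * z
        return out

    def mean_field_rhs(self, state: np.ndarray, tx_mask: np.ndarray | None = None) -> np.ndarray:
        """Deterministic (mean-field) rate of change of every species."""
        G = self.num_genes
        x, y, z = state[:G], state[G:2 * G], state[2 * G:]
        f = self.transcription_propensities(state, tx_mask)
        dxdt = f - (self.spl + self.dx) * x
        dydt = self.spl * x - self.dy * y
        dzdt = self.tr * y - self.dz * z
        return np.concatenate([dxdt, dydt, dzdt])


def build_reaction_system(grn: GeneRegulatoryNetwork, kinetics: Kinetics) -> ReactionSystem:
    """Assemble the reaction system (six reactions per gene) for a GRN."""
    return ReactionSystem(grn, kinetics)
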