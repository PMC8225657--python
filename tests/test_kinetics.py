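"""Kinetics sampling, the thermodynamic transcription propensity and its
brute-force promoter-state oracle, and reaction-system construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stochastix as sx
from stochastix.kinetics import (
    GeneKinetics,
    InteractionKinetics,
    KineticsConfig,
    build_reaction_system,
    hill_part,
    sample_kinetics,
    transcription_propensity,
)
from .conftest import make_regulated_pair


def brute_force_propensity(xpr, nus, activator):
    """Independent oracle: enumerate all 2^N promoter binding states.

    State j binds regulator i iff bit i of j is set; its Boltzmann weight is
    the product of the bound regulators' Hill terms, and its activation is 0
    if any bound regulator is a repressor, else 1. The propensity is xpr
    times the expected activation.
    """
    N = len(nus)
    num = 0.0
    den = 0.0
    for j in range(2 ** N):
        w = 1.0
        alpha = 1.0
        for i in range(N):
            if (j >> i) & 1:
                w *= nus[i]
                if not activator[i]:
                    alpha = 0.0
        num += alpha * w
        den += w
    return xpr * num / den


def closed_form(xpr, nus, activator, ba=1.0, sy=1.0):
    nus = np.asarray(nus, float)
    act = np.asarray(activator, bool)
    numer = ba - sy ** act.sum() + np.prod(nus[act] + sy)
    return xpr * numer / np.prod(nus + 1.0)


class TestPropensityOracle:
    def test_closed_form_equals_promoter_state_sum(self):
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(1000):
            N = int(rng.integers(1, 11))
            nus = rng.lognormal(0.0, 1.5, size=N)
            activator = rng.random(N) < 0.5
            bf = brute_force_propensity(10.0, nus, activator)
            cf = closed_form(10.0, nus, activator)
            rel = abs(bf - cf) / max(abs(bf), 1e-300)
            worst = max(worst, rel)
        assert worst < 1e-12

    def test_extended_form_reduces_to_thermodynamic_at_neutral_ba_sy(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            N = int(rng.integers(1, 8))
            nus = rng.lognormal(0.0, 1.0, size=N)
            activator = rng.random(N) < 0.5
            assert closed_form(5.0, nus, activator, ba=1.0, sy=1.0) == pytest.approx(
                brute_force_propensity(5.0, nus, activator), rel=1e-12
            )

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        nus=st.lists(st.floats(0.0, 50.0), min_size=1, max_size=6),
        data=st.data(),
    )
    def test_monotone_in_each_regulator(self, nus, data):
        """Raising an activator's occupancy never lowers the propensity;
        raising a repressor's never raises it."""
        activator = [data.draw(st.booleans()) for _ in nus]
        base = closed_form(1.0, nus, activator, ba=0.4, sy=0.8)
        for i in range(len(nus)):
            bumped = list(nus)
            bumped[i] += 1.0
            f = closed_form(1.0, bumped, activator, ba=0.4, sy=0.8)
            if activator[i]:
                assert f >= base - 1e-12
            else:
                assert f <= base + 1e-12


class TestHillPart:
    def test_half_occupation(self):
        assert hill_part(10.0, 10.0, 3.0) == pytest.approx(1.0)

    def test_zero_abundance(self):
        assert hill_part(0.0, 5.0, 2.0) == 0.0

    def test_power(self):
        assert hill_part(20.0, 10.0, 2.0) == pytest.approx(4.0)

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError):
            hill_part(-1.0, 5.0, 2.0)


class TestTranscriptionPropensity:
    def _gk(self, ba, sy=1.0, xpr=10.0):
        return GeneKinetics("B", xpr, 2.0, 2.0, 0.7, 0.7, 0.35, ba, sy)

    def test_no_regulators_gives_basal_expression(self):
        assert transcription_propensity(self._gk(ba=1.0), np.array([]), []) == 10.0
        assert transcription_propensity(self._gk(ba=0.25), np.array([]), []) == pytest.approx(2.5)

    def test_single_activator_at_half_occupation(self):
        ik = InteractionKinetics("A", "B", +1, 1.0, k=10.0, n=2.0)
        f = transcription_propensity(self._gk(ba=0.0), np.array([10.0]), [ik])
        assert f == pytest.approx(10.0 / 2)

    def test_single_repressor_example(self):
        # nu = 3 with ba = 1: f = xpr * (1 - 1 + 1) / (3 + 1) = xpr / 4
        ik = InteractionKinetics("A", "B", -1, 1.0, k=10.0, n=1.0)
        f = transcription_propensity(self._gk(ba=1.0), np.array([30.0]), [ik])
        assert f == pytest.approx(10.0 / 4)

    def test_all_regulators_absent_gives_xpr_times_ba(self):
        iks = [
            InteractionKinetics("A", "B", +1, 1.0, 10.0, 2.0),
            InteractionKinetics("C", "B", -1, 1.0, 5.0, 1.5),
        ]
        f = transcription_propensity(self._gk(ba=0.7), np.zeros(2), iks)
        assert f == pytest.approx(10.0 * 0.7)


class TestSampleKinetics:
    def test_transcription_rate_is_amplified_base_rate(self, small_grn):
        kin = sample_kinetics(small_grn, rng=0)
        cfg = kin.config
        for gk in kin.genes.values():
            assert gk.xpr == cfg.base_mrna_production * cfg.transcription_amplification

    def test_half_life_maps_to_degradation_rate(self, small_grn):
        cfg = KineticsConfig(mrna_halflife=3.5)
        kin = sample_kinetics(small_grn, rng=0, config=cfg)
        for gk in kin.genes.values():
            assert gk.degradation_mrna == pytest.approx(np.log(2) / 3.5)

    def test_same_seed_same_tables(self, small_grn):
        a = sample_kinetics(small_grn, rng=5)
        b = sample_kinetics(small_grn, rng=5)
        assert a.gene_table().equals(b.gene_table())
        assert a.interaction_table().equals(b.interaction_table())

    def test_all_constants_positive_and_bounded(self, small_kinetics):
        gt = small_kinetics.gene_table()
        for col in ("xpr", "splicing_rate", "translation_rate",
                    "degradation_premrna", "degradation_mrna", "degradation_protein"):
            assert (gt[col] > 0).all()
        assert gt.ba.between(0, 1).all()
        it = small_kinetics.interaction_table()
        assert (it.k > 0).all()
        assert (it.n >= 1).all()

    def test_invalid_config_rejected(self, small_grn):
        with pytest.raises(ValueError, match="positive"):
            sample_kinetics(small_grn, config=KineticsConfig(mrna_halflife=-1.0))


class TestReactionSystem:
    def test_reaction_and_species_counts(self, small_system):
        G = small_system.num_genes
        assert len(small_system.reactions) == 6 * G
        assert len(small_system.species_names) == 3 * G

    def test_splicing_state_change_converts_pre_to_mature(self, small_system):
        name = small_system.gene_names[0]
        splicing = small_system.reactions[1]
        assert splicing.kind == "splicing"
        assert splicing.state_change == {f"x_{name}": -1, f"y_{name}": +1}

    def test_translation_propensity_zero_without_mrna(self, small_system):
        state = np.zeros(small_system.num_species)
        translation = small_system.reactions[2]
        assert translation.propensity(state) == 0.0

    def test_propensities_nonnegative_and_finite(self, small_system):
        rng = np.random.default_rng(1)
        state = rng.integers(0, 200, small_system.num_species).astype(float)
        props = small_system.propensities(state)
        assert np.isfinite(props).all()
        assert (props >= 0).all()

    def test_linear_propensities_match_closures(self, small_system):
        rng = np.random.default_rng(2)
        state = rng.integers(0, 50, small_system.num_species).astype(float)
        props = small_system.propensities(state)
        for r, rx in enumerate(small_system.reactions):
            assert props[r] == pytest.approx(rx.propensity(state))

    def test_missing_kinetics_entry_rejected(self, small_grn, small_kinetics):
        from stochastix.kinetics import Kinetics

        partial = Kinetics(
            {k: v for k, v in list(small_kinetics.genes.items())[:-1]},
            small_kinetics.interactions,
            small_kinetics.config,
        )
        with pytest.raises(KeyError, match="missing"):
            build_reaction_system(small_grn, partial)

    def test_vectorized_matches_scalar_transcription(self, regulated_pair):
        grn, kin, system = regulated_pair
        state = np.array([0, 0, 0, 0, 20.0, 0])  # z_A = 20
        f_vec = system.transcription_propensities(state)
        f_scalar = transcription_propensity(
            kin.genes["B"], np.array([20.0]), kin.interactions
        )
        assert f_vec[1] == pytest.approx(f_scalar)
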