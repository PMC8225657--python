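import numpy as np
import pytest

import stochastix as sx
from stochastix.backbone import Backbone, Module, ModuleInteraction, StateEdge
from stochastix.grn import Gene, GeneInteraction, GeneRegulatoryNetwork
from stochastix.kinetics import (
    GeneKinetics,
    InteractionKinetics,
    Kinetics,
    KineticsConfig,
    build_reaction_system,
)


@pytest.fixture(scope="session")
def linear_backbone():
    return sx.predefined_backbone("linear")


@pytest.fixture(scope="session")
def small_grn(linear_backbone):
    return sx.generate_grn(linear_backbone, num_tfs=10, num_targets=8, num_hks=4, rng=11)


@pytest.fixture(scope="session")
def small_kinetics(small_grn):
    return sx.sample_kinetics(small_grn, rng=12)


@pytest.fixture(scope="session")
def small_system(small_grn, small_kinetics):
    return build_reaction_system(small_grn, small_kinetics)


def _two_state_backbone():
    """Single burn module driving nothing: one trivial transition."""
    return Backbone(
        "toy",
        modules=[Module("M1", basal=1.0, burn=True)],
        module_interactions=[],
        state_network=[StateEdge("S0", "S1", modules_on=set())],
        start_state="S0",
    )


def make_regulated_pair(effect=1, ba=0.0, sy=1.0, k=10.0, n=2.0, xpr=10.0):
    """Two-gene system: constitutive TF A regulating target B with one
    interaction; kinetic constants chosen by hand for closed-form checks."""
    bb = _two_state_backbone()
    genes = [
        Gene("A", "tf", "M1", burn=True, basal=1.0),
        Gene("B", "target", None, burn=True, basal=ba),
    ]
    inter = [GeneInteraction("A", "B", effect, 1.0)]
    grn = GeneRegulatoryNetwork(genes, inter, bb)
    cfg = KineticsConfig(synergism=sy)
    gk = lambda name, b: GeneKinetics(name, xpr, 2.0, 2.0, 0.7, 0.7, 0.35, b, sy)
    kin = Kinetics(
        {"A": gk("A", 1.0), "B": gk("B", ba)},
        [InteractionKinetics("A", "B", effect, 1.0, k, n)],
        cfg,
    )
    return grn, kin, build_reaction_system(grn, kin)


@pytest.fixture
def regulated_pair():
    return make_regulated_pair()


def make_constitutive_system(xpr=100.0, spl=0.2, dx=0.3, dy=0.4, tr=0.5, dz=0.5, ba=1.0):
    """One constitutive gene (no regulators): a linear birth-death cascade
    with analytically known Poisson stationary marginals."""
    bb = _two_state_backbone()
    genes = [Gene("A", "tf", "M1", burn=True, basal=ba)]
    grn = GeneRegulatoryNetwork(genes, [], bb)
    kin = Kinetics(
        {"A": GeneKinetics("A", xpr, spl, tr, dx, dy, dz, ba, 1.0)},
        [],
        KineticsConfig(),
    )
    return grn, kin, build_reaction_system(grn, kin)
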