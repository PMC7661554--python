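import numpy as np
import pytest

from aadeg.synthetic import (BinSpec, CommunitySpec, PathwayPlan,
                             emulate_study_design, generate_community)


def small_spec(seed: int = 0, noise: bool = True) -> CommunitySpec:
    """Compact three-bin community for fast unit tests: one proteolytic
    bin with complete glycine, one bin missing a glycine gene, one inert
    background bin."""
    b1 = BinSpec(
        bin_id="binA", abundance=0.5, n_contigs=5,
        pathways={
            "glycine": PathwayPlan(expressed=True),
            "alanine": PathwayPlan(expressed=True),
            "serine": PathwayPlan(),
        },
        peptidases_by_type={"M": 5, "S": 4, "C": 2},
        secreted_peptidases=3,
        lipases=2, secreted_lipases=1,
        cazymes_gh=3, secreted_cazymes=1,
        adhesion={"PF01103": 2, "PF02494": 1},
        susc_polypeptide=1,
        electron_markers=("Hyd", "Rnf"),
        n_filler=10,
        ssu_best_identity=84.0, aai_best=55.0,
    )
    b2 = BinSpec(
        bin_id="binB", abundance=0.3, n_contigs=5,
        pathways={
            "glycine": PathwayPlan(missing=1),
            "alanine": PathwayPlan(expressed=True),
        },
        peptidases_by_type={"M": 3, "S": 3},
        secreted_peptidases=2,
        n_filler=10,
        ssu_best_identity=96.0,
    )
    b3 = BinSpec(
        bin_id="binC", abundance=0.2, n_contigs=5,
        peptidases_by_type={"M": 1},
        n_filler=10,
    )
    return CommunitySpec(bins=[b1, b2, b3], seed=seed, noise=noise)


@pytest.fixture(scope="session")
def small_community():
    return generate_community(small_spec(seed=3))


@pytest.fixture(scope="session")
def study_community():
    """The emulated enrichment-study community, one fixed seed."""
    return generate_community(emulate_study_design(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
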