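import numpy as np
import pandas as pd
import pytest

from urobiome.io import CountMatrix, PhyloTree, TaxonomyTable, parse_tree
from urobiome.profiling import collapse_taxonomy, rarefy, relative_abundance
from urobiome.qc import apply_qc
from urobiome.simulate import default_cohort_config, simulate_cohort


@pytest.fixture
def toy_counts() -> CountMatrix:
    frame = pd.DataFrame(
        {
            "ASV_A": [100, 50, 3, 0],
            "ASV_B": [10, 0, 40, 35],
            "ASV_C": [0, 5, 2, 1],
        },
        index=["GU1", "GU2", "GU3", "NC1"],
    )
    types = pd.Series(["GU", "GU", "GU", "NC"], index=frame.index)
    return CountMatrix(frame, types)


@pytest.fixture
def toy_tree() -> PhyloTree:
    return parse_tree("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def desk_pipeline():
    """Desk-scale simulation -> QC -> rarefied genus profile, cached per seed."""
    cache: dict[int, dict] = {}

    def run(seed: int) -> dict:
        if seed not in cache:
            config = default_cohort_config("desk", seed=seed)
            cm, tax, tree, meta, truth = simulate_cohort(config)
            filtered, report = apply_qc(cm)
            rarefied = rarefy(filtered, 4000, seed=0)
            profile = relative_abundance(
                collapse_taxonomy(rarefied, tax, "genus"), rank="genus"
            )
            cache[seed] = dict(
                counts=cm, taxonomy=tax, tree=tree, metadata=meta, truth=truth,
                filtered=filtered, report=report, rarefied=rarefied, profile=profile,
            )
        return cache[seed]

    return run


@pytest.fixture(scope="session")
def tiny_cohort():
    return simulate_cohort(default_cohort_config("tiny", seed=7))
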