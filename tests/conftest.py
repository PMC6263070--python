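import numpy as np
import pandas as pd
import pytest

from combosig.formats import ExpressionMatrix, SampleAnnotation
from combosig import synthdata as sd


@pytest.fixture
def toy_matrix():
    """3 genes x 4 samples, log2 scale."""
    frame = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0], [2.0, 2.0, 5.0, 1.0]],
        index=["Ga", "Gb", "Gc"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(frame, scale="log2")


@pytest.fixture
def two_arm_annotation():
    return SampleAnnotation(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3", "s4"],
                "arm": ["Veh", "Veh", "ED", "ED"],
                "batch": ["b1", "b2", "b1", "b2"],
                "replicate": [1, 2, 1, 2],
            }
        )
    )


@pytest.fixture
def small_experiment():
    """Small planted-effect experiment with its ground truth."""
    design = sd.default_design(replicates_per_arm=4)
    effects = sd.default_effect_model(n_genes=2000, seed=0)
    return sd.simulate_treatment_experiment(design, effects, seed=7)
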