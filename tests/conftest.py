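import numpy as np
import pytest

from methylclass import (
    LabelSet,
    MethylationMatrix,
    default_training_design,
    generate_cohort,
)


@pytest.fixture
def tiny_matrix():
    """3 probes x 4 samples, hand-set values."""
    return MethylationMatrix(
        probe_ids=["cgA", "cgB", "cgC"],
        sample_ids=["s1", "s2", "s3", "s4"],
        values=np.array(
            [
                [0.1, 0.2, 0.8, 0.9],
                [0.5, 0.5, 0.5, 0.5],
                [0.3, 0.7, 0.4, 0.6],
            ]
        ),
    )


@pytest.fixture
def tiny_labels():
    return LabelSet(assignments={"s1": "A", "s2": "A", "s3": "B", "s4": "B"})


@pytest.fixture(scope="session")
def small_cohort():
    """2 classes x 20 samples, 100 probes, 5 informative/class, wide margin."""
    from methylclass import SimulationDesign

    design = SimulationDesign(
        class_sizes={"X": 20, "Y": 20},
        n_probes=100,
        n_informative_per_class=5,
        effect_delta=0.4,
        seed=7,
    )
    return generate_cohort(design)


@pytest.fixture(scope="session")
def desk_cohort():
    """The seven-class imbalanced preset at a reduced probe count."""
    design = default_training_design(
        n_probes=300, n_informative_per_class=5, effect_delta=0.35, seed=11
    )
    return generate_cohort(design)
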