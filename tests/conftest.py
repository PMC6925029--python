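import numpy as np
import pytest

from ctcmorph import CohortSpec, FrameSceneSpec, generate_cohort_features, generate_frame
from ctcmorph.io import PipelineConfig


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_scene():
    """A small frame with a WBC lawn, single tumor cells and one 2-cell cluster."""
    spec = FrameSceneSpec(
        frame_shape=(320, 320),
        n_wbc=30,
        n_tumor=5,
        n_tumor_clusters=1,
        cluster_size=2,
        seed=11,
    )
    return generate_frame(spec)


@pytest.fixture(scope="session")
def small_cohort():
    """3-patient liquid/metastasis cohort with the default planted concordance."""
    return generate_cohort_features(CohortSpec(n_patients=3, seed=5))


def archetype_cohort(within_sd, seed, n_patients=10, n_features=82, cells=40):
    """Cohort with 4 planted archetypes shared across patients.

    Archetype means are constant across features at offsets with increasing
    gaps, so complete linkage yields a balanced 4-way split at the second
    branch level without distance ties.
    """
    offsets = [0.0, 2.0, 4.2, 6.6]
    archetypes = np.array([[o] * n_features for o in offsets])
    zero = [0.0] * n_features
    spec = CohortSpec(
        n_patients=n_patients,
        compartments=("liquid", "metastasis"),
        cells_per_compartment=cells,
        n_features=n_features,
        within_sd=within_sd,
        planted_cluster_archetypes=archetypes,
        compartment_shift={"liquid": zero, "metastasis": zero},
        seed=seed,
    )
    return generate_cohort_features(spec)
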