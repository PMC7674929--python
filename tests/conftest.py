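import numpy as np
import pytest

from preictal import ClusterSpec, RankedMontage, SyntheticSpec, generate_patient
from preictal.experiment import Patient


@pytest.fixture(scope="session")
def small_patient():
    """A fast synthetic patient for unit tests: 4 channels at a 256 Hz native
    rate, 4.8 h, one 2-seizure cluster — small enough to regenerate in
    seconds, long enough to contain interictal time."""
    spec = SyntheticSpec(
        n_channels=4,
        fs_native=256.0,
        duration_h=4.8,
        n_affected_channels=2,
        clusters=ClusterSpec(n_clusters=1, seizures_per_cluster=2, intra_gap_min=10.0),
        transition_onset_min=5.0,
        effect_size=2.0,
        seed=7,
    )
    recording, truth = generate_patient(spec)
    patient = Patient("unit01", recording, truth.events,
                      RankedMontage(tuple(truth.ranked_channels)))
    return patient, truth, spec


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
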