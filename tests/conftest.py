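import pytest

from bcgkit.io import AnnotationTrack
from bcgkit.preprocess import bandpass
from bcgkit.simulate import CardiacParams, ChannelLayout, simulate_paired


@pytest.fixture(scope="session")
def clean_pair():
    """One clean 60-s synthetic subject at 200 Hz."""
    return simulate_paired(CardiacParams(duration=60.0, seed=11))


@pytest.fixture(scope="session")
def clean_filtered(clean_pair):
    return bandpass(clean_pair.bcg)


@pytest.fixture(scope="session")
def clean_truth(clean_pair):
    return AnnotationTrack(clean_pair.true_r_times, label="R", source="simulated-truth")


@pytest.fixture(scope="session")
def noisy_pair():
    layout = ChannelLayout(
        weights=(0.3, 0.25, 0.25, 0.2),
        noise_sd=4.0,
        motion_artifact_rate=2.0,
        respiration_amplitude=5.0,
    )
    return simulate_paired(CardiacParams(duration=60.0, seed=12), layout=layout)


@pytest.fixture(scope="session")
def trained_model(clean_filtered, clean_truth):
    """Small model trained on the clean subject's own windows (fast)."""
    from bcgkit.peaks import StoppingCriteria, make_training_windows, train_peak_model

    windows = make_training_windows(clean_filtered, clean_truth)
    return train_peak_model(
        windows, StoppingCriteria(max_epochs=30), seed=5
    )
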