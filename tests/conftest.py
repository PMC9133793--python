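import pytest

from oddwave.containers import default_layout
from oddwave.design import DesignSpec, generate_design
from oddwave.preprocess import run_preprocessing
from oddwave.simulate import default_ground_truth, default_times, simulate_epochs


@pytest.fixture(scope="session")
def times50():
    """Coarse epoch grid (-200..550 ms at 50 Hz) used by most decoding tests."""
    return default_times(50.0)


@pytest.fixture(scope="session")
def layout32():
    return default_layout(32)


@pytest.fixture(scope="session")
def smoke_design():
    return generate_design(DesignSpec(n_trains=60, length_counts={4: 20, 5: 20, 6: 20}, seed=3))


def make_clean_epochs(design, layout, times, profile="control", seed=0, **truth_kwargs):
    """Simulate + preprocess one synthetic participant."""
    truth = default_ground_truth(layout, times, profile=profile, seed=seed, **truth_kwargs)
    epochs = simulate_epochs(design, truth, layout, seed=seed + 10_000)
    clean, _ = run_preprocessing(epochs)
    return clean, truth
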