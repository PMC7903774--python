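import pandas as pd
import pytest

from synconcord import SyntheticConfig, match_layers, simulate_multiomics
from synconcord.quantify import TRANSCRIPT_LAYERS


def make_profiles(config: SyntheticConfig) -> pd.DataFrame:
    """Simulate a dataset and return its matched-profile table."""
    dataset = simulate_multiomics(config)
    profiles, _ = match_layers(
        dataset.fold_changes["proteome"],
        [dataset.fold_changes[layer] for layer in TRANSCRIPT_LAYERS],
    )
    return profiles


@pytest.fixture(scope="session")
def default_profiles() -> pd.DataFrame:
    """One default-regime matched-profile table (5000 genes, seed 1)."""
    return make_profiles(SyntheticConfig(seed=1))


@pytest.fixture
def tiny_profiles() -> pd.DataFrame:
    """Hand-sized matched profiles for enumerable join/selection checks."""
    frame = pd.DataFrame(
        {
            "protein_log2fc": [3.0, 2.0, 1.0, -1.0, -2.0, -3.0],
            "syn_polysome": [2.5, 1.5, 0.5, -0.5, -1.5, -2.5],
        },
        index=pd.Index(["a", "b", "c", "d", "e", "f"], name="id"),
    )
    return frame
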