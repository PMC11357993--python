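import pytest

from engram import (
    AgonistChannel,
    BarcodeVocabulary,
    ReadModel,
    SimConfig,
    TapeSpec,
    default_tape_channels,
)


@pytest.fixture
def tape_spec() -> TapeSpec:
    return TapeSpec()


@pytest.fixture
def tape_channels() -> list[AgonistChannel]:
    return default_tape_channels()


@pytest.fixture
def small_config() -> SimConfig:
    """Desk-scale population: enough tapes for stable proportions, fast."""
    return SimConfig(n_cells=300, tapes_per_cell=20, seed=11)


@pytest.fixture
def read_model() -> ReadModel:
    return ReadModel(reads_per_sample=3000, per_base_error=0.001)


@pytest.fixture
def pentamer_vocab() -> BarcodeVocabulary:
    """Hand-picked 5-mers, all pairwise Hamming distances >= 3."""
    return BarcodeVocabulary(
        k=5,
        entries={
            "R1": "AAAAA",
            "R2": "CCCAA",
            "R3": "AACCC",
            "R4": "GGGGG",
            "R5": "TTTGG",
        },
    )
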