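import numpy as np
import pytest

from glycopore import classify
from glycopore import features as ft
from glycopore import synthetic_data as sd

FOUR_CLASSES = ("GT1c", "GT1b", "GT1a", "GT1aα")

# Feature-QC dwell cutoff of the identification workflow (one 8-sample
# spectral window at 50 kHz).
MIN_DWELL_MS = 0.16


@pytest.fixture(scope="session")
def presets():
    return sd.class_presets()


@pytest.fixture(scope="session")
def four_class_tables(presets):
    """QC'd per-class feature tables for a medium 4-class event population."""
    events = sd.simulate_labeled_events(
        [presets[n] for n in FOUR_CLASSES], 1_500, seed=20_260_928
    )
    table = ft.extract_feature_table(events)
    table = table[table["dwell_time"] >= MIN_DWELL_MS].reset_index(drop=True)
    return {
        name: table[table["label"] == name].reset_index(drop=True)
        for name in FOUR_CLASSES
    }


@pytest.fixture(scope="session")
def trained_setup(four_class_tables):
    """Assembled split + selected features + fitted preprocessor (shared)."""
    data, split = classify.assemble_dataset(four_class_tables, 1_500, seed=7)
    train = data.iloc[split.train]
    ranked = classify.rank_features_anova(train)
    selected = classify.select_top_k(ranked, 12)
    pp = classify.fit_preprocessor(train, selected)
    return {
        "data": data,
        "split": split,
        "train": train,
        "validation": data.iloc[split.validation],
        "test": data.iloc[split.test],
        "ranked": ranked,
        "selected": selected,
        "preprocessor": pp,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
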