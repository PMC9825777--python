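import numpy as np
import pytest

from difftf.models.cnn import CnnSpec, build_cnn, train_cnn
from difftf.models.metrics import evaluate
from difftf.pipeline import chromosome_splits, encode_bundle, task_labels
from difftf.synth import FixtureConfig, make_bundle

TRAIN_SEED = 7


@pytest.fixture(scope="session")
def bundle_small():
    """A light bundle for format and feature tests."""
    return make_bundle(FixtureConfig(seed=11, n_peaks=(30, 30, 30)))


@pytest.fixture(scope="session")
def bundle_default():
    """The default-scale bundle (300 peaks) used for recovery and training."""
    return make_bundle(FixtureConfig(seed=1))


@pytest.fixture(scope="session")
def bundle_dir(bundle_small, tmp_path_factory):
    """The small bundle written to disk in standard formats."""
    from difftf.synth import write_bundle

    out = tmp_path_factory.mktemp("bundle")
    paths = write_bundle(bundle_small, out)
    return out, paths


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def task_b(bundle_default):
    """Task-B labels and chromosome splits for the default bundle."""
    y, keep = task_labels(bundle_default.labels, "B")
    assert keep.all()
    splits = chromosome_splits(bundle_default.peaks)
    return {
        "y": y,
        "train": splits == "TRAIN",
        "val": splits == "VAL",
        "test": splits == "TEST",
    }


def train_cnn_variant(bundle, task_b, channels, in_channels,
                      warmup_inits=2, max_epochs=15):
    """Train one CNN encoding variant on task B; returns test metrics."""
    X = encode_bundle(bundle, "plus", channels=channels) \
        if channels != "plain" else encode_bundle(bundle, "plain")
    y = task_b["y"]
    tr, va, te = task_b["train"], task_b["val"], task_b["test"]
    model = build_cnn(CnnSpec.small(), in_channels, 600, 2)
    model, _ = train_cnn(
        model, (X[tr], y[tr]), (X[va], y[va]),
        seed=TRAIN_SEED, warmup_inits=warmup_inits, warmup_epochs=2,
        max_epochs=max_epochs, patience=5, batch_size=50,
    )
    scores = model.predict_proba(np.transpose(X[te], (0, 2, 1)))
    return evaluate(scores, y[te], "B")


@pytest.fixture(scope="session")
def cnn_results(bundle_default, task_b):
    """Test metrics of the four encoding variants, trained once and shared
    across the suite."""
    return {
        "plus": train_cnn_variant(bundle_default, task_b, "all", 7),
        "diff": train_cnn_variant(bundle_default, task_b, "diff", 5),
        "cellA": train_cnn_variant(bundle_default, task_b, "cellA", 5),
        "plain": train_cnn_variant(bundle_default, task_b, "plain", 4,
                                   warmup_inits=1, max_epochs=8),
    }
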