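import numpy as np
import pytest

from sshapelet import SparseDataset


def make_dataset(records, labels, feature_ids=None):
    """Build a SparseDataset from {(obj, feat): values} and {obj: label}."""
    if feature_ids is None:
        feature_ids = sorted({f for _, f in records})
    return SparseDataset(
        feature_ids=feature_ids,
        object_ids=list(labels),
        records={k: np.asarray(v, dtype=float) for k, v in records.items()},
        labels=dict(labels),
    )


@pytest.fixture
def two_class_dataset():
    """Six objects, two features, one empty record, two classes."""
    records = {
        ("o1", "lab_a"): [1.0, 2.0, 9.0, 8.0],
        ("o2", "lab_a"): [2.0, 1.0, 8.0, 9.0, 7.0],
        ("o3", "lab_a"): [5.0, 5.1, 4.9, 5.0],
        ("o4", "lab_a"): [4.0, 4.2, 4.1],
        ("o5", "lab_a"): [3.0, 3.3, 2.9, 3.1],
        ("o1", "lab_b"): [0.5, 0.7],
        ("o2", "lab_b"): [0.6, 0.4, 0.5],
        ("o3", "lab_b"): [0.2, 0.9, 0.1],
        ("o4", "lab_b"): [0.8, 0.3],
        ("o5", "lab_b"): [0.4, 0.6, 0.5, 0.4],
        # o6 is empty on both features
    }
    labels = {"o1": "case", "o2": "case", "o3": "control",
              "o4": "control", "o5": "control", "o6": "control"}
    return make_dataset(records, labels, feature_ids=["lab_a", "lab_b"])


def random_symbolic_column(rng, n_max=12, alpha_max=5, empty_rate=0.3,
                           require_empty=False):
    """A random (symbolic record or ∅, label) column with >= 1 non-empty."""
    while True:
        n = int(rng.integers(2, n_max + 1))
        alpha = int(rng.integers(2, alpha_max + 1))
        symbols = "abcde"[:alpha]
        column = []
        for _ in range(n):
            if rng.random() < empty_rate:
                column.append(("", str(rng.integers(0, 2))))
            else:
                length = int(rng.integers(1, 9))
                seq = "".join(rng.choice(list(symbols), size=length))
                column.append((seq, str(rng.integers(0, 2))))
        has_nonempty = any(t for t, _ in column)
        has_empty = any(not t for t, _ in column)
        if has_nonempty and (has_empty or not require_empty):
            s_len = int(rng.integers(1, 6))
            s = "".join(rng.choice(list(symbols), size=s_len))
            return s, column
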