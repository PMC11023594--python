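"""Clustering agreement and synthetic-data utility metrics.

The adjusted Rand index is implemented directly from the pair-counting
contingency form (Hubert-Arabie chance correction) rather than delegated,
since benchmark conclusions hang on it; tests cross-check it against
explicit all-pairs counting and an independent library implementation.

The utility harness measures how useful synthetic data is for learning: a
classifier is trained on synthetic rows and scored (area under the ROC
curve) on real rows, against a reference classifier trained on the real
rows themselves.  Classifiers come from scikit-learn; they are measuring
instruments here, not part of the method.
"""

from __future__ import annotations

import numpy as np
from scipy.special import comb

from .io_cli import Table

__all__ = [
    "adjusted_rand_index",
    "train_synthetic_test_real",
    "utility_benchmark",
]


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Hubert-Arabie adjusted Rand index between two partitions.

    1 means identical partitions, about 0 chance-level agreement; the
    index is invariant to relabelling either side.
    """
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.shape != b.shape:
        raise ValueError(f"label lengths differ: {a.shape} vs {b.shape}")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 items")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    contingency = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(contingency, (ai, bi), 1)

    sum_cells = comb(contingency, 2).sum()
    sum_rows = comb(contingency.sum(axis=1), 2).sum()
    sum_cols = comb(contingency.sum(axis=0), 2).sum()
    n_pairs = comb(n, 2)
    expected = sum_rows * sum_cols / n_pairs
    max_index = 0.5 * (sum_rows + sum_cols)
    if max_index == expected:  # both partitions trivial
        return 1.0 if sum_cells == expected else 0.0
    return float((sum_cells - expected) / (max_index - expected))


def _features_and_target(table: Table):
    """One-hot feature matrix over input columns plus the binary target."""
    from .mmmsynth import _design, _output_values

    y, kind = _output_values(table)
    if kind == "numeric":
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(
                "utility harness needs a binary output column; numeric "
                f"output has {len(classes)} distinct values"
            )
        y = (y == classes.max()).astype(int)
    return _design(table.inputs()), y.astype(int)


def _make_classifier(model_kind: str, seed: int):
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    if model_kind == "logreg":
        return make_pipeline(StandardScaler(),
                             LogisticRegression(max_iter=1000))
    if model_kind == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    raise ValueError(f"unknown model kind {model_kind!r}")


def train_synthetic_test_real(train: Table, test: Table,
                              model_kind: str = "logreg",
                              seed: int = 0) -> float:
    """AUC of a classifier fitted on ``train`` and scored on ``test``."""
    from sklearn.metrics import roc_auc_score

    x_train, y_train = _features_and_target(train)
    x_test, y_test = _features_and_target(test)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training output column has a single class")
    clf = _make_classifier(model_kind, seed)
    clf.fit(x_train, y_train)
    scores = clf.predict_proba(x_test)[:, 1]
    return float(roc_auc_score(y_test, scores))


def utility_benchmark(real_train: Table, real_test: Table, synth_source,
                      model_kind: str = "logreg", n_runs: int = 20,
                      seed: int = 0) -> dict:
    """Train-on-synthetic / test-on-real AUC, averaged over fresh draws.

    ``synth_source`` is either a fixed synthetic Table (reused each run)
    or a callable ``seed -> Table`` producing a fresh synthetic draw per
    run.  The report includes the real-trained reference AUC on the same
    test rows.
    """
    aucs = []
    for run in range(n_runs):
        synth = synth_source(seed + run) if callable(synth_source) else synth_source
        aucs.append(
            train_synthetic_test_real(synth, real_test, model_kind,
                                      seed=seed + run)
        )
    auc_real = train_synthetic_test_real(real_train, real_test, model_kind,
                                         seed=seed)
    aucs = np.asarray(aucs)
    return {
        "model": model_kind,
        "n_runs": n_runs,
        "auc_synthetic_mean": float(aucs.mean()),
        "auc_synthetic_sd": float(aucs.std(ddof=1)) if n_runs > 1 else 0.0,
        "auc_synthetic_runs": aucs.tolist(),
        "auc_real_reference": auc_real,
        "auc_gap": float(auc_real - aucs.mean()),
    }
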