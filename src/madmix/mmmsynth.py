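"""Cluster-wise synthetic tabular data generation.

The generator pre-clusters the real table on its input columns (the
declared output column is excluded from clustering), fits independent
per-column distributions within each cluster — observed category
frequencies for categorical columns, Gaussian mean/sd for numeric columns
— and a linear model of the output column on the (one-hot expanded)
inputs.  A synthetic cluster of the same size is then sampled column-wise
from the fitted distributions, its output column generated as the linear
prediction plus Gaussian residual noise (thresholded at 0.5 for a binary
output), and the synthetic clusters are pooled and shuffled into a table
of the same shape as the original.

Because each cluster is resampled independently with its own column
distributions, between-column association that is expressible as cluster
structure survives into the synthetic data even though columns are
independent within a cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clustering_engine import fit, fit_k, score_matrix
from .column_models import ColumnSchema
from .io_cli import RunConfig, Table

__all__ = [
    "ClusterGenerativeModel",
    "fit_cluster_models",
    "sample_synthetic",
    "mmmsynth_pipeline",
]


@dataclass
class ClusterGenerativeModel:
    """Fitted sampling distributions for one cluster."""

    size: int
    cat_probs: list  # per categorical input column: level probabilities
    num_mean: np.ndarray  # per numeric input column
    num_sd: np.ndarray
    out_weights: np.ndarray | None  # over the one-hot design, ref levels dropped
    out_intercept: float | None
    out_resid_sd: float | None
    out_class_probs: np.ndarray | None = None  # logistic binary mode only


def _design(table: Table) -> np.ndarray:
    """One-hot design matrix of the input columns; the first level of each
    categorical column is the dropped reference."""
    blocks = [table.num]
    for ci, spec in enumerate(table.cat_specs):
        k = len(spec.levels)
        onehot = np.eye(k)[table.cat[:, ci]][:, 1:]
        blocks.append(onehot)
    return np.concatenate(blocks, axis=1)


def _output_values(table: Table) -> tuple[np.ndarray, str]:
    """The output column as floats plus its kind ('numeric'|'binary')."""
    out = table.schema.output_column
    if out is None:
        raise ValueError("schema declares no output column")
    if out.kind == "numeric":
        idx = [c.name for c in table.num_specs].index(out.name)
        return table.num[:, idx].astype(float), "numeric"
    if len(out.levels) != 2:
        raise ValueError(
            f"categorical output column {out.name!r} must be binary, "
            f"has {len(out.levels)} levels"
        )
    idx = [c.name for c in table.cat_specs].index(out.name)
    return table.cat[:, idx].astype(float), "binary"


def merge_degenerate_clusters(table: Table, assignment: np.ndarray,
                              min_size: int = 2) -> np.ndarray:
    """Reassign rows of clusters smaller than ``min_size`` to their
    best-scoring surviving cluster."""
    a = np.asarray(assignment, dtype=np.int64)
    sizes = np.bincount(a - 1)
    good = np.nonzero(sizes >= min_size)[0]
    if len(good) == len(sizes):
        return a
    if len(good) == 0:
        return np.ones_like(a)
    scores = score_matrix(table, a)
    bad_rows = np.isin(a - 1, np.nonzero(sizes < min_size)[0])
    a = a.copy()
    a[bad_rows] = good[np.argmax(scores[np.ix_(bad_rows, good)], axis=1)] + 1
    # compact labels
    remap = {old + 1: new + 1 for new, old in enumerate(np.unique(a) - 1)}
    return np.array([remap[v] for v in a], dtype=np.int64)


def fit_cluster_models(table: Table, assignment: np.ndarray,
                       binary_mode: str = "threshold"
                       ) -> list[ClusterGenerativeModel]:
    """Maximum-likelihood per-cluster column fits plus the output model.

    ``assignment`` is 1-based, from clustering the input columns only.
    Clusters with fewer than two rows are merged into their nearest
    cluster by predictive score before fitting.
    """
    if binary_mode not in ("threshold", "logistic"):
        raise ValueError(f"unknown binary_mode {binary_mode!r}")
    inputs_all = table.inputs()
    assignment = merge_degenerate_clusters(inputs_all, assignment)
    y, out_kind = _output_values(table)
    x_all = _design(inputs_all)
    models = []
    for j in range(1, int(assignment.max()) + 1):
        members = assignment == j
        nj = int(members.sum())
        sub = inputs_all.take(np.nonzero(members)[0])
        cat_probs = []
        for ci, spec in enumerate(sub.cat_specs):
            cnt = np.bincount(sub.cat[:, ci], minlength=len(spec.levels))
            cat_probs.append(cnt / nj)
        num_mean = sub.num.mean(axis=0) if sub.num.size else np.zeros(0)
        num_sd = sub.num.std(axis=0) if sub.num.size else np.zeros(0)

        xj = np.column_stack([x_all[members], np.ones(nj)])
        yj = y[members]
        coef, *_ = np.linalg.lstsq(xj, yj, rcond=None)
        resid = yj - xj @ coef
        resid_sd = float(np.sqrt(np.mean(resid**2)))
        class_probs = None
        if out_kind == "binary" and binary_mode == "logistic":
            class_probs = _logistic_probs(x_all[members], yj)
        models.append(
            ClusterGenerativeModel(
                size=nj,
                cat_probs=cat_probs,
                num_mean=num_mean,
                num_sd=num_sd,
                out_weights=coef[:-1],
                out_intercept=float(coef[-1]),
                out_resid_sd=resid_sd,
                out_class_probs=class_probs,
            )
        )
    return models


def _logistic_probs(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-row success probabilities from a within-cluster logistic fit
    (constant when the cluster is single-class)."""
    from sklearn.linear_model import LogisticRegression

    classes = np.unique(y)
    if len(classes) == 1:
        return np.full(len(y), float(classes[0]))
    clf = LogisticRegression(max_iter=1000)
    clf.fit(x, y.astype(int))
    return clf.predict_proba(x)[:, 1]


def sample_synthetic(models: list[ClusterGenerativeModel],
                     schema: ColumnSchema, seed: int = 0,
                     binary_mode: str = "threshold") -> Table:
    """Sample one synthetic table from fitted cluster models.

    Each cluster contributes exactly its original number of rows; rows are
    shuffled after pooling.  Numeric sampling is unbounded Gaussian (no
    clipping to the observed range).
    """
    rng = np.random.default_rng(seed)
    out_spec = schema.output_column
    if out_spec is None:
        raise ValueError("schema declares no output column")
    in_schema = schema.input_schema()
    in_cat_specs = [c for c in in_schema if c.kind == "categorical"]
    n_total = sum(m.size for m in models)
    cat_parts, num_parts, y_parts = [], [], []
    for m in models:
        cat = np.empty((m.size, len(in_cat_specs)), dtype=np.int64)
        for ci, spec in enumerate(in_cat_specs):
            cat[:, ci] = rng.choice(len(spec.levels), size=m.size,
                                    p=m.cat_probs[ci])
        num = rng.normal(m.num_mean, m.num_sd, size=(m.size, len(m.num_mean)))
        inputs = Table(in_schema, cat, num)
        x = _design(inputs)
        linear = x @ m.out_weights + m.out_intercept
        if out_spec.kind == "numeric":
            y = linear + rng.normal(0.0, m.out_resid_sd, size=m.size)
        elif binary_mode == "logistic" and m.out_class_probs is not None:
            p = float(np.mean(m.out_class_probs))
            y = (rng.random(m.size) < p).astype(float)
        else:
            noisy = linear + rng.normal(0.0, m.out_resid_sd, size=m.size)
            y = (noisy >= 0.5).astype(float)
        cat_parts.append(cat)
        num_parts.append(num)
        y_parts.append(y)
    cat = np.concatenate(cat_parts)
    num = np.concatenate(num_parts)
    y = np.concatenate(y_parts)
    perm = rng.permutation(n_total)
    cat, num, y = cat[perm], num[perm], y[perm]

    # reassemble in full-schema column order
    full_cat_specs = [c for c in schema if c.kind == "categorical"]
    full_num_specs = [c for c in schema if c.kind == "numeric"]
    out_cat = np.empty((n_total, len(full_cat_specs)), dtype=np.int64)
    out_num = np.empty((n_total, len(full_num_specs)))
    ci = ni = 0
    for spec in schema:
        if spec.kind == "categorical":
            if spec.output:
                out_cat[:, ci] = np.clip(y, 0, 1).astype(np.int64)
            else:
                src = [c.name for c in in_cat_specs].index(spec.name)
                out_cat[:, ci] = cat[:, src]
            ci += 1
        else:
            if spec.output:
                out_num[:, ni] = y
            else:
                src = [c.name for c in in_schema if c.kind == "numeric"]
                out_num[:, ni] = num[:, src.index(spec.name)]
            ni += 1
    return Table(schema, out_cat, out_num)


def mmmsynth_pipeline(table: Table, config: RunConfig | None = None,
                      binary_mode: str = "threshold"):
    """End-to-end generation: cluster, fit, sample.

    Returns (synthetic Table, report dict).  Cluster-number selection
    follows ``config.selection`` ("hmbeta" | "ti" | "fixed" with
    ``config.fixed_k``).
    """
    config = config or RunConfig()
    inputs = table.inputs()
    if config.selection == "fixed":
        if not config.fixed_k:
            raise ValueError("selection='fixed' requires fixed_k")
        res = fit_k(inputs, config.fixed_k, mode=config.em_mode,
                    seed=config.seed, max_iters=config.max_iters,
                    hyper=config.hyper)
        assignment, k = res.assignment, res.k
        evidence_report = None
    else:
        sel = fit(inputs, k_max=config.k_max, selection=config.selection,
                  beta=config.beta, m=config.n_samples,
                  n_temperatures=config.n_temperatures, seed=config.seed,
                  mode=config.em_mode, hyper=config.hyper)
        assignment = sel.assignments[sel.best_k]
        k = sel.fits[sel.best_k].k
        evidence_report = [e.to_dict() for e in sel.evidences.values()]
    models = fit_cluster_models(table, assignment, binary_mode=binary_mode)
    synth = sample_synthetic(models, table.schema, seed=config.seed,
                             binary_mode=binary_mode)
    report = {
        "k": int(k),
        "cluster_sizes": [m.size for m in models],
        "binary_mode": binary_mode,
        "config": config.to_dict(),
        "columns": [
            {
                "name": spec.name,
                "kind": spec.kind,
                "output": spec.output,
            }
            for spec in table.schema
        ],
    }
    if evidence_report is not None:
        report["evidence"] = evidence_report
    return synth, report
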