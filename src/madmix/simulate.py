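"""Planted-cluster synthetic benchmark datasets.

These generators emulate heterogeneous clinical-style tables with known
row structure, used to benchmark clustering and cluster-number selection:

* categorical tables where cluster j draws each column from probabilities
  proportional to a shared base weight vector v0 plus a cluster-specific
  perturbation Delta * v_j — larger Delta means more distinct clusters;
* numeric tables where cluster means step by ``mean_gap`` (default 1.0)
  and standard deviations step by ``dsigma`` (optionally with all means
  equal, so only the variances separate the clusters);
* mixed tables of five numeric and five 4-valued categorical columns with
  the coupling dsigma = 5.0 - Delta, so one knob tunes the difficulty of
  both halves at once;
* a series of mixed tables with equal-sized clusters for K = 2..10.

The default shape is 5000 rows, 10 columns, five clusters in a 5:4:3:2:1
ratio.  Everything is driven by a single seed; identical specs give
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .column_models import ColumnSchema, ColumnSpec
from .io_cli import Table

__all__ = [
    "SynthSpec",
    "make_categorical",
    "make_numeric",
    "make_mixed",
    "make_k_series",
    "ratio_sizes",
]

_PROB_FLOOR = 0.05


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one planted-cluster dataset."""

    n_rows: int = 5000
    n_binary: int = 5
    n_multi: int = 5
    multi_k: int = 4
    n_numeric: int = 5
    delta: float = 2.5  # categorical separation
    dsigma: float | None = None  # numeric sd separation; mixed: 5 - delta
    mean_gap: float = 1.0
    base_sd: float = 1.0
    same_mean: bool = False
    ratio: tuple = (5, 4, 3, 2, 1)
    n_clusters: int | None = None  # equal sizes when set (overrides ratio)
    seed: int = 0

    def cluster_sizes(self) -> np.ndarray:
        if self.n_clusters is not None:
            return ratio_sizes(self.n_rows, (1,) * self.n_clusters)
        return ratio_sizes(self.n_rows, self.ratio)


def ratio_sizes(n_rows: int, ratio) -> np.ndarray:
    """Split n_rows into len(ratio) parts by the largest-remainder rule."""
    ratio = np.asarray(ratio, dtype=float)
    if (ratio <= 0).any():
        raise ValueError("ratio entries must be positive")
    exact = n_rows * ratio / ratio.sum()
    sizes = np.floor(exact).astype(np.int64)
    remainder = exact - sizes
    short = n_rows - sizes.sum()
    for idx in np.argsort(-remainder, kind="stable")[:short]:
        sizes[idx] += 1
    if (sizes == 0).any():
        raise ValueError("n_rows too small for the requested cluster ratio")
    return sizes


def _labels(spec: SynthSpec, rng: np.random.Generator):
    sizes = spec.cluster_sizes()
    labels = np.repeat(np.arange(1, len(sizes) + 1), sizes)
    perm = rng.permutation(spec.n_rows)
    return labels[perm]


def _cat_columns(spec: SynthSpec, labels, rng, n_cols: int, k: int):
    """Sample n_cols categorical columns with k levels each.

    Category probabilities for cluster j are proportional to a shared base
    weight vector v0 (uniform on [0.1, 0.3] per level) plus Delta times a
    cluster-specific preference vector v_j, here the indicator of one
    uniformly drawn preferred level.  Delta therefore tunes how strongly
    each cluster concentrates on its own characteristic level: at
    Delta=0.5 the preferred level carries roughly half the mass, at
    Delta=4.5 almost all of it.
    """
    n_clusters = int(labels.max())
    out = np.empty((spec.n_rows, n_cols), dtype=np.int64)
    probs = np.empty((n_cols, n_clusters, k))
    for col in range(n_cols):
        v0 = rng.uniform(0.1, 0.3, size=k)
        vj = np.eye(k)[rng.integers(0, k, size=n_clusters)]
        p = np.maximum(v0[None, :] + spec.delta * vj, _PROB_FLOOR)
        p /= p.sum(axis=1, keepdims=True)
        probs[col] = p
        for j in range(n_clusters):
            members = labels == j + 1
            out[members, col] = rng.choice(k, size=int(members.sum()), p=p[j])
    return out, probs


def _num_columns(spec: SynthSpec, labels, rng, n_cols: int, dsigma: float):
    """Sample n_cols Gaussian columns; cluster j has mean j*mean_gap (or a
    common mean) and sd base_sd + (j-1)*dsigma."""
    n_clusters = int(labels.max())
    out = np.empty((spec.n_rows, n_cols))
    means = np.zeros(n_clusters) if spec.same_mean else (
        spec.mean_gap * np.arange(1, n_clusters + 1))
    sds = spec.base_sd + dsigma * np.arange(n_clusters)
    for col in range(n_cols):
        for j in range(n_clusters):
            members = labels == j + 1
            out[members, col] = rng.normal(
                means[j], sds[j], size=int(members.sum()))
    return out, means, sds


def _schema(n_binary: int, n_multi: int, multi_k: int,
            n_numeric: int) -> ColumnSchema:
    cols: list[ColumnSpec] = []
    cols += [ColumnSpec(f"num{i}", "numeric") for i in range(n_numeric)]
    cols += [
        ColumnSpec(f"bin{i}", "categorical", levels=["0", "1"])
        for i in range(n_binary)
    ]
    cols += [
        ColumnSpec(f"cat{i}", "categorical",
                   levels=[str(v) for v in range(multi_k)])
        for i in range(n_multi)
    ]
    return ColumnSchema(cols)


def make_categorical(spec: SynthSpec | None = None):
    """Purely categorical benchmark table: binary plus multi-valued
    columns.  Returns (Table, 1-based true labels)."""
    spec = spec or SynthSpec(n_numeric=0)
    rng = np.random.default_rng(spec.seed)
    labels = _labels(spec, rng)
    bin_cols, _ = _cat_columns(spec, labels, rng, spec.n_binary, 2)
    multi_cols, _ = _cat_columns(spec, labels, rng, spec.n_multi, spec.multi_k)
    cat = np.concatenate([bin_cols, multi_cols], axis=1)
    schema = _schema(spec.n_binary, spec.n_multi, spec.multi_k, 0)
    table = Table(schema, cat, np.empty((spec.n_rows, 0)))
    return table, labels


def make_numeric(spec: SynthSpec | None = None):
    """Purely numeric benchmark table.  Returns (Table, true labels)."""
    spec = spec or SynthSpec(n_binary=0, n_multi=0, n_numeric=10, dsigma=0.5)
    rng = np.random.default_rng(spec.seed)
    dsigma = 0.5 if spec.dsigma is None else spec.dsigma
    labels = _labels(spec, rng)
    num, _, _ = _num_columns(spec, labels, rng, spec.n_numeric, dsigma)
    schema = _schema(0, 0, spec.multi_k, spec.n_numeric)
    table = Table(schema, np.empty((spec.n_rows, 0), np.int64), num)
    return table, labels


def make_mixed(spec: SynthSpec | None = None):
    """Mixed benchmark table: numeric block plus multi-valued categorical
    block sharing the same planted labels, with the difficulty coupling
    dsigma = 5.0 - delta unless dsigma is given explicitly."""
    spec = spec or SynthSpec(n_binary=0)
    dsigma = (5.0 - spec.delta) if spec.dsigma is None else spec.dsigma
    rng = np.random.default_rng(spec.seed)
    labels = _labels(spec, rng)
    num, _, _ = _num_columns(spec, labels, rng, spec.n_numeric, dsigma)
    bin_cols, _ = _cat_columns(spec, labels, rng, spec.n_binary, 2)
    multi_cols, _ = _cat_columns(spec, labels, rng, spec.n_multi, spec.multi_k)
    cat = np.concatenate([bin_cols, multi_cols], axis=1)
    schema = _schema(spec.n_binary, spec.n_multi, spec.multi_k, spec.n_numeric)
    table = Table(schema, cat, num)
    return table, labels


def make_supervised(spec: SynthSpec | None = None, *,
                    noise_sd: float = 0.5):
    """Planted-cluster table with a binary outcome column.

    Inputs are a mixed table as in :func:`make_mixed`.  Within each
    cluster the outcome is a noisy linear function of the inputs: a
    cluster-specific weight vector over the numeric columns and one-hot
    categorical levels, plus Gaussian noise of sd ``noise_sd``, thresholded
    at the cluster median so classes are roughly balanced within every
    cluster.  This emulates a clinical table whose response depends on the
    predictors differently in each latent subpopulation.

    Returns (Table including the output column, true cluster labels).
    """
    spec = spec or SynthSpec(n_rows=1000, n_binary=0, n_clusters=2, delta=3.0)
    table, labels = make_mixed(spec)
    rng = np.random.default_rng(spec.seed + 777)
    blocks = [table.num]
    for ci, cspec in enumerate(table.cat_specs):
        k = len(cspec.levels)
        blocks.append(np.eye(k)[table.cat[:, ci]][:, 1:])
    x = np.concatenate(blocks, axis=1)
    x = (x - x.mean(axis=0)) / np.maximum(x.std(axis=0), 1e-9)
    n_clusters = int(labels.max())
    score = np.empty(spec.n_rows)
    y = np.empty(spec.n_rows, dtype=np.int64)
    for j in range(1, n_clusters + 1):
        members = labels == j
        w = rng.normal(0.0, 1.0, size=x.shape[1])
        s = x[members] @ w + rng.normal(0.0, noise_sd, size=int(members.sum()))
        score[members] = s
        y[members] = (s > np.median(s)).astype(np.int64)
    out_schema = ColumnSchema(
        list(table.schema.columns)
        + [ColumnSpec("outcome", "categorical", levels=["0", "1"], output=True)]
    )
    cat = np.concatenate([table.cat, y[:, None]], axis=1)
    full = Table(out_schema, cat, table.num)
    return full, labels


def make_k_series(n_rows: int = 5000, k_range=range(2, 11), seed: int = 0,
                  delta: float = 4.5):
    """One mixed dataset per K with equal-sized clusters.

    Returns {K: (Table, labels)}.  Sizes differ by at most one row
    (largest-remainder split)."""
    base = SynthSpec(n_rows=n_rows, n_binary=0, delta=delta, seed=seed)
    out = {}
    for idx, k in enumerate(k_range):
        spec = replace(base, n_clusters=int(k), seed=seed + idx)
        out[int(k)] = make_mixed(spec)
    return out
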