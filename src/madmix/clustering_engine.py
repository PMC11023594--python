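"""Hard-assignment EM over collapsed conjugate column models.

The clustering objective is the joint collapsed likelihood of a partition:
the product over clusters, and independently over columns, of the
closed-form marginal likelihood of the rows assigned to that cluster.  No
distribution parameters are ever estimated; they are integrated out, so the
only unknown is the assignment vector.

The loop: score every row against every cluster with the row removed from
its own cluster (leave-one-out posterior predictive), reassign each row to
its best-scoring cluster, repeat until no reassignment.  ``batch`` mode
moves all rows simultaneously; ``sequential`` mode moves one row at a time
with immediate state update, which makes the objective provably
non-decreasing.  The number of clusters is grown incrementally: a fitted
K-clustering seeds K+1 by splitting off the worst-fitting rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .column_models import Hyperparameters
from .io_cli import Table

__all__ = [
    "ClusterState",
    "FitResult",
    "SelectionResult",
    "joint_log_likelihood",
    "score_row",
    "score_matrix",
    "fit_k",
    "warm_start_split",
    "fit_incremental",
    "fit",
]

_LOG_PI = math.log(math.pi)
_LOG_2PI = math.log(2.0 * math.pi)


class ClusterState:
    """Sufficient statistics of every (cluster, column) pair.

    Categorical counts live in one padded integer array; numeric columns
    keep per-cluster sums and sums of squares.  All scoring is vectorized
    across columns, and across rows where possible.  Labels are 0-based
    internally.
    """

    def __init__(self, table: Table, labels: np.ndarray, k: int,
                 hyper: Hyperparameters | None = None):
        hyper = hyper or Hyperparameters()
        self.table = table
        self.hyper = hyper
        self.k = int(k)
        labels = np.asarray(labels, dtype=np.int64)
        if labels.shape != (table.n_rows,):
            raise ValueError("labels length does not match table")
        if labels.min(initial=0) < 0 or (table.n_rows and labels.max() >= k):
            raise ValueError("labels out of range for k clusters")
        self.labels = labels.copy()

        self.n_cat = table.cat.shape[1]
        self.n_num = table.num.shape[1]
        levels = table.cat_levels
        self._kmax = max(levels, default=0)
        self._levels = np.asarray(levels, dtype=np.int64)
        self._c = hyper.pseudo_count
        self._c_tot = self._c * self._levels  # per-column total pseudo-count

        # numeric prior, per column (mu0/b0 empirical over the whole column)
        resolved = [hyper.resolve(table.num[:, j]) for j in range(self.n_num)]
        self._mu0 = np.array([r[0] for r in resolved])
        self._beta0 = hyper.beta0
        self._a0 = hyper.a0
        self._b0 = np.array([r[3] for r in resolved])

        self.sizes = np.zeros(k, dtype=np.int64)
        self.cat_counts = np.zeros((k, self.n_cat, self._kmax), dtype=np.int64)
        self.num_sum = np.zeros((k, self.n_num))
        self.num_sumsq = np.zeros((k, self.n_num))
        self._arange_cat = np.arange(self.n_cat)
        for j in range(k):
            members = np.nonzero(self.labels == j)[0]
            self.sizes[j] = len(members)
            if self.n_cat:
                for l in range(self.n_cat):
                    cnt = np.bincount(table.cat[members, l],
                                      minlength=self._kmax)
                    self.cat_counts[j, l] = cnt
            if self.n_num and len(members):
                x = table.num[members]
                self.num_sum[j] = x.sum(axis=0)
                self.num_sumsq[j] = (x * x).sum(axis=0)

    # -- incremental updates --------------------------------------------

    def remove(self, i: int) -> int:
        """Detach row ``i`` from its cluster; returns the old label."""
        j = self.labels[i]
        self.sizes[j] -= 1
        if self.n_cat:
            self.cat_counts[j, self._arange_cat, self.table.cat[i]] -= 1
        if self.n_num:
            x = self.table.num[i]
            self.num_sum[j] -= x
            self.num_sumsq[j] -= x * x
        self.labels[i] = -1
        return int(j)

    def add(self, i: int, j: int) -> None:
        """Attach detached row ``i`` to cluster ``j``."""
        self.sizes[j] += 1
        if self.n_cat:
            self.cat_counts[j, self._arange_cat, self.table.cat[i]] += 1
        if self.n_num:
            x = self.table.num[i]
            self.num_sum[j] += x
            self.num_sumsq[j] += x * x
        self.labels[i] = j

    # -- scoring ----------------------------------------------------------

    def _num_posterior(self, j: int):
        """Posterior (mu_n, beta_n, a_n, b_n) arrays for cluster j's
        numeric columns."""
        n = self.sizes[j]
        beta_n = self._beta0 + n
        a_n = self._a0 + 0.5 * n
        if n == 0:
            return self._mu0, beta_n, a_n, self._b0
        s_sum = self.num_sum[j]
        mean = s_sum / n
        ss = np.maximum(self.num_sumsq[j] - s_sum * mean, 0.0)
        mu_n = (self._beta0 * self._mu0 + s_sum) / beta_n
        b_n = (self._b0 + 0.5 * ss
               + self._beta0 * n * (mean - self._mu0) ** 2 / (2.0 * beta_n))
        return mu_n, beta_n, a_n, b_n

    def predictive(self, i: int, j: int) -> float:
        """Log posterior predictive of row ``i`` under cluster ``j``
        (row must not currently be a member of ``j``)."""
        total = 0.0
        n = self.sizes[j]
        if self.n_cat:
            cnt = self.cat_counts[j, self._arange_cat, self.table.cat[i]]
            total += float(np.sum(np.log(cnt + self._c))
                           - np.sum(np.log(n + self._c_tot)))
        if self.n_num:
            mu_n, beta_n, a_n, b_n = self._num_posterior(j)
            lam = a_n * beta_n / (b_n * (beta_n + 1.0))
            x = self.table.num[i]
            const = (-0.5 * _LOG_PI + math.lgamma(a_n + 0.5)
                     - math.lgamma(a_n) - 0.5 * math.log(2.0 * a_n))
            total += float(
                self.n_num * const
                + 0.5 * np.sum(np.log(lam))
                - (a_n + 0.5)
                * np.sum(np.log1p(lam * (x - mu_n) ** 2 / (2.0 * a_n)))
            )
        return total

    def joint_log_likelihood(self) -> float:
        """Collapsed log-likelihood of the current partition: sum over
        clusters and columns of closed-form marginals."""
        total = 0.0
        if self.n_cat:
            c = self._c
            per_level = gammaln(self.cat_counts + c) - gammaln(c)
            # padded level slots hold zero counts and contribute exactly 0
            if self._kmax:
                mask = np.arange(self._kmax) < self._levels[:, None]
                per_level = np.where(mask[None, :, :], per_level, 0.0)
            total += float(per_level.sum())
            total += float(
                np.sum(gammaln(self._c_tot)[None, :]
                       - gammaln(self._c_tot[None, :] + self.sizes[:, None]))
            )
        if self.n_num:
            for j in range(self.k):
                n = self.sizes[j]
                if n == 0:
                    continue
                _, beta_n, a_n, b_n = self._num_posterior(j)
                total += float(np.sum(
                    math.lgamma(a_n) - math.lgamma(self._a0)
                    + self._a0 * np.log(self._b0) - a_n * np.log(b_n)
                    + 0.5 * (math.log(self._beta0) - math.log(beta_n))
                    - 0.5 * n * _LOG_2PI
                ))
        return total

    # -- vectorized full-table scoring ------------------------------------

    def score_matrix(self) -> np.ndarray:
        """Leave-one-out score matrix L[i, j]: log predictive of row i
        under cluster j, with i removed from its own cluster first."""
        n_rows, k = self.table.n_rows, self.k
        scores = np.zeros((n_rows, k))
        cat, num = self.table.cat, self.table.num
        for j in range(k):
            members = self.labels == j
            col = np.zeros(n_rows)
            n = self.sizes[j]
            if self.n_cat:
                cnt = self.cat_counts[j][self._arange_cat[:, None],
                                         cat.T]  # (Lc, N)
                col += np.sum(np.log(cnt + self._c), axis=0)
                col -= np.sum(np.log(n + self._c_tot))
                if n > 0 and members.any():
                    cnt_m = cnt[:, members] - 1
                    col[members] = (
                        np.sum(np.log(cnt_m + self._c), axis=0)
                        - np.sum(np.log(n - 1 + self._c_tot))
                    )
            if self.n_num:
                col += self._num_scores(num, j, members)
            scores[:, j] = col
        return scores

    def _num_scores(self, num: np.ndarray, j: int, members: np.ndarray):
        """Numeric part of the score of all rows under cluster j, with the
        member rows scored against the cluster minus themselves."""
        out = np.zeros(num.shape[0])
        mu_n, beta_n, a_n, b_n = self._num_posterior(j)
        out[:] = _student_t_rows(num, mu_n, beta_n, a_n, b_n)
        n = self.sizes[j]
        if n > 0 and members.any():
            x = num[members]  # (m, Ln)
            s_sum = self.num_sum[j] - x
            s_sq = self.num_sumsq[j] - x * x
            n1 = n - 1
            beta1 = self._beta0 + n1
            a1 = self._a0 + 0.5 * n1
            if n1 == 0:
                mu1 = np.broadcast_to(self._mu0, x.shape)
                b1 = np.broadcast_to(self._b0, x.shape)
            else:
                mean = s_sum / n1
                ss = np.maximum(s_sq - s_sum * mean, 0.0)
                mu1 = (self._beta0 * self._mu0 + s_sum) / beta1
                b1 = (self._b0 + 0.5 * ss
                      + self._beta0 * n1 * (mean - self._mu0) ** 2
                      / (2.0 * beta1))
            lam = a1 * beta1 / (b1 * (beta1 + 1.0))
            const = (-0.5 * _LOG_PI + math.lgamma(a1 + 0.5)
                     - math.lgamma(a1) - 0.5 * math.log(2.0 * a1))
            out[members] = (
                num.shape[1] * const
                + 0.5 * np.sum(np.log(lam), axis=1)
                - (a1 + 0.5)
                * np.sum(np.log1p(lam * (x - mu1) ** 2 / (2.0 * a1)), axis=1)
            )
        return out

    def compact(self) -> None:
        """Drop empty clusters and relabel contiguously."""
        keep = np.nonzero(self.sizes > 0)[0]
        if len(keep) == self.k:
            return
        remap = -np.ones(self.k, dtype=np.int64)
        remap[keep] = np.arange(len(keep))
        self.labels = remap[self.labels]
        self.sizes = self.sizes[keep]
        self.cat_counts = self.cat_counts[keep]
        self.num_sum = self.num_sum[keep]
        self.num_sumsq = self.num_sumsq[keep]
        self.k = len(keep)


def _student_t_rows(num, mu_n, beta_n, a_n, b_n):
    """Student-t predictive log-density of each row (summed over numeric
    columns) for fixed posterior parameter vectors."""
    lam = a_n * beta_n / (b_n * (beta_n + 1.0))
    const = (-0.5 * _LOG_PI + math.lgamma(a_n + 0.5) - math.lgamma(a_n)
             - 0.5 * math.log(2.0 * a_n))
    return (
        num.shape[1] * const
        + 0.5 * np.sum(np.log(lam))
        - (a_n + 0.5)
        * np.sum(np.log1p(lam * (num - mu_n) ** 2 / (2.0 * a_n)), axis=1)
    )


# -- public functional surface (1-based labels) ------------------------------

def _to_internal(assignment: np.ndarray) -> np.ndarray:
    a = np.asarray(assignment, dtype=np.int64)
    if a.min(initial=1) < 1:
        raise ValueError("cluster labels must be 1-based")
    return a - 1


def joint_log_likelihood(table: Table, assignment: np.ndarray,
                         hyper: Hyperparameters | None = None) -> float:
    """Collapsed log-likelihood of a partition (labels 1..K)."""
    a = _to_internal(assignment)
    k = int(a.max(initial=0)) + 1 if len(a) else 1
    return ClusterState(table, a, k, hyper).joint_log_likelihood()


def score_row(state: ClusterState, i: int) -> np.ndarray:
    """Leave-one-out log-score of row ``i`` against every cluster."""
    j = state.remove(i)
    scores = np.array([state.predictive(i, c) for c in range(state.k)])
    state.add(i, j)
    return scores


def score_matrix(table: Table, assignment: np.ndarray,
                 hyper: Hyperparameters | None = None) -> np.ndarray:
    a = _to_internal(assignment)
    k = int(a.max(initial=0)) + 1
    return ClusterState(table, a, k, hyper).score_matrix()


@dataclass
class FitResult:
    assignment: np.ndarray  # 1-based labels
    k: int
    log_likelihood: float
    iterations: int
    converged: bool
    trace: list = field(default_factory=list)

    @property
    def cluster_sizes(self) -> list[int]:
        return np.bincount(self.assignment - 1, minlength=self.k).tolist()


def _argmax_keep_current(scores: np.ndarray, current: np.ndarray) -> np.ndarray:
    """Row-wise argmax that keeps the current label on ties and otherwise
    takes the lowest winning index (deterministic)."""
    best = scores.max(axis=1)
    new = np.argmax(scores == best[:, None], axis=1)
    keep = scores[np.arange(len(current)), current] >= best
    new[keep] = current[keep]
    return new


def fit_k(table: Table, k: int, *, mode: str = "batch",
          init: np.ndarray | None = None, seed: int = 0,
          max_iters: int = 100,
          hyper: Hyperparameters | None = None) -> FitResult:
    """Cluster a table into (at most) ``k`` clusters.

    ``init`` may give a 1-based starting assignment (e.g. from
    :func:`warm_start_split`); otherwise K=1 starts trivially and K>1
    starts from a seeded random assignment.  Empty clusters arising during
    the run are dropped, so the fitted ``k`` may be smaller than requested.
    """
    n = table.n_rows
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n_rows, got k={k}, n={n}")
    if mode not in ("batch", "sequential"):
        raise ValueError(f"unknown mode {mode!r}")
    if init is not None:
        labels = _to_internal(init)
        if labels.max(initial=0) >= k:
            raise ValueError("init labels exceed k")
    elif k == 1:
        labels = np.zeros(n, dtype=np.int64)
    else:
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, k, size=n)
        # guarantee every cluster is non-empty
        labels[rng.permutation(n)[:k]] = np.arange(k)
    state = ClusterState(table, labels, k, hyper)
    state.compact()

    if state.k == 1 or n == 1:
        ll = state.joint_log_likelihood()
        return FitResult(state.labels + 1, state.k, ll, 1, True, [ll])

    trace: list[float] = []
    best_ll, best_labels, best_k = -np.inf, state.labels.copy(), state.k
    converged = False
    iterations = 0
    for iterations in range(1, max_iters + 1):
        if mode == "batch":
            scores = state.score_matrix()
            new = _argmax_keep_current(scores, state.labels)
            changed = int(np.sum(new != state.labels))
            if changed:
                state = ClusterState(table, new, state.k, hyper)
                state.compact()
        else:
            changed = 0
            for i in range(n):
                if state.sizes[state.labels[i]] == 1 and state.k > 1:
                    # moving the last row away deletes the cluster; allow it
                    pass
                old = state.remove(i)
                s = np.array([state.predictive(i, c) for c in range(state.k)])
                best = s.max()
                j = int(np.argmax(s == best))
                if s[old] >= best:
                    j = old
                state.add(i, j)
                if j != old:
                    changed += 1
                    if state.sizes[old] == 0:
                        state.compact()
        ll = state.joint_log_likelihood()
        trace.append(ll)
        if ll > best_ll:
            best_ll, best_labels, best_k = ll, state.labels.copy(), state.k
        if changed == 0:
            converged = True
            break
    return FitResult(best_labels + 1, best_k, best_ll, iterations, converged,
                     trace)


def warm_start_split(table: Table, result: FitResult,
                     hyper: Hyperparameters | None = None) -> np.ndarray:
    """Seed a (K+1)-cluster fit from a fitted K-clustering.

    The floor(N/(K+1)) rows with the lowest leave-one-out posterior
    predictive under their own cluster are relabelled as a new cluster.
    Ties are broken by row index (stable sort), so the split is
    deterministic.  Returns a 1-based assignment.
    """
    a = _to_internal(result.assignment)
    k = result.k
    state = ClusterState(table, a, k, hyper)
    scores = state.score_matrix()
    own = scores[np.arange(table.n_rows), a]
    n_move = table.n_rows // (k + 1)
    new = a.copy()
    if n_move > 0:
        worst = np.argsort(own, kind="stable")[:n_move]
        new[worst] = k
    return new + 1


@dataclass
class SelectionResult:
    best_k: int
    fits: dict  # k -> FitResult
    evidences: dict  # k -> EvidenceEstimate

    @property
    def assignments(self) -> dict:
        return {k: f.assignment for k, f in self.fits.items()}


def fit_incremental(table: Table, k_max: int, *, mode: str = "batch",
                    seed: int = 0, max_iters: int = 100,
                    hyper: Hyperparameters | None = None
                    ) -> dict[int, FitResult]:
    """The incremental-K ladder: fit K=1, then seed each K+1 fit by
    splitting off the worst-fitting rows of the fitted K-clustering."""
    fits: dict[int, FitResult] = {}
    fits[1] = fit_k(table, 1, mode=mode, seed=seed, max_iters=max_iters,
                    hyper=hyper)
    for k in range(2, k_max + 1):
        init = warm_start_split(table, fits[k - 1], hyper)
        fits[k] = fit_k(table, k, mode=mode, init=init, seed=seed,
                        max_iters=max_iters, hyper=hyper)
    return fits


def fit(table: Table, k_max: int, *, selection: str = "hmbeta",
        beta: float = 0.5, m: int = 200, n_temperatures: int = 11,
        seed: int = 0, mode: str = "batch",
        hyper: Hyperparameters | None = None) -> SelectionResult:
    """Fit K = 1..K_max with incremental warm starts and pick K by maximum
    estimated evidence (``ti`` | ``hmbeta`` | ``bic``)."""
    from . import evidence as ev  # deferred: evidence builds on this module

    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if selection not in ("ti", "hmbeta", "bic"):
        raise ValueError(f"unknown selection method {selection!r}")
    fits = fit_incremental(table, k_max, mode=mode, seed=seed, hyper=hyper)
    evidences: dict[int, object] = {}
    for k, res in fits.items():
        if selection == "bic":
            evidences[k] = ev.bic_log_ml(table, res.assignment, hyper=hyper)
        elif selection == "ti":
            evidences[k] = ev.ti_log_ml(
                table, res.k, m=m, n_temperatures=n_temperatures,
                seed=seed + k, init=res.assignment, hyper=hyper)
        else:
            evidences[k] = ev.hmbeta_log_ml(
                table, res.k, beta=beta, m=m, seed=seed + k,
                init=res.assignment, hyper=hyper)
    best_k = max(evidences, key=lambda k: evidences[k].log_ml)
    return SelectionResult(best_k, fits, evidences)
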