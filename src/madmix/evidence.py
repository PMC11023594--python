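"""Marginal-likelihood (model evidence) estimation over cluster assignments.

For K clusters the evidence is the sum, over every assignment vector A in
which no cluster is empty, of the collapsed likelihood P(D|A,K) times a
uniform prior over those assignments.  Distribution parameters are already
integrated out in closed form, so A is the only variable marginalized here.

Estimators:

* ``exact_log_ml`` — direct enumeration of all assignments (tiny N only);
* ``am_log_ml`` — arithmetic mean over prior draws (biased low);
* ``hm_log_ml`` — harmonic mean over posterior samples (biased high);
* ``hmbeta_log_ml`` — the tempered harmonic-mean family, interpolating
  between AM (beta=0) and HM (beta=1) via a chain at inverse temperature
  beta; beta=0.5 splits the two biases and is the recommended default;
* ``ti_log_ml`` — thermodynamic integration of the expected log-likelihood
  along an inverse-temperature path from prior to posterior;
* ``bic_log_ml`` — the Bayesian information criterion on a -BIC/2 scale,
  as a cheap baseline.

Sampling is single-site Metropolis over row labels: propose relabelling a
uniformly chosen row to a uniformly chosen other cluster, reject proposals
that would empty a cluster (the prior excludes those assignments), and
accept with probability min(1, exp(beta * delta-log-likelihood)).  At
beta=0 the target is the uniform prior itself, which is sampled exactly
(i.i.d. draws) instead of by a random walk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import simpson
from scipy.special import gammaln, logsumexp

from .column_models import Hyperparameters
from .clustering_engine import ClusterState
from .io_cli import Table

__all__ = [
    "EvidenceEstimate",
    "count_surjective_assignments",
    "exact_log_ml",
    "am_log_ml",
    "hm_log_ml",
    "hmbeta_log_ml",
    "ti_log_ml",
    "bic_log_ml",
]

DEFAULT_MAX_ENUMERATIONS = 2_000_000


@dataclass
class EvidenceEstimate:
    """A log marginal likelihood with its provenance."""

    log_ml: float
    method: str  # exact | AM | HM | HMbeta | TI | BIC
    k: int
    beta: float | None = None
    m: int | None = None
    mc_error: float | None = None
    seed: int | None = None
    n_assignments: int | None = None
    settings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "k": self.k,
            "method": self.method,
            "log_ml": self.log_ml,
        }
        for key in ("beta", "m", "mc_error", "seed", "n_assignments"):
            v = getattr(self, key)
            if v is not None:
                d[key] = v
        if self.settings:
            d["settings"] = self.settings
        return d


def count_surjective_assignments(n: int, k: int) -> int:
    """Number of length-n label vectors over 1..k with no empty cluster
    (inclusion-exclusion)."""
    total = 0
    for j in range(k + 1):
        total += (-1) ** j * math.comb(k, j) * (k - j) ** n
    return total


def _uniform_surjective(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """An exact uniform draw over surjective label vectors, by rejection."""
    while True:
        labels = rng.integers(0, k, size=n)
        if len(np.unique(labels)) == k:
            return labels


def _joint_ll(table: Table, labels: np.ndarray, k: int,
              hyper: Hyperparameters | None) -> float:
    return ClusterState(table, labels, k, hyper).joint_log_likelihood()


# -- exact enumeration --------------------------------------------------------

def exact_log_ml(table: Table, k: int, *,
                 max_enumerations: int = DEFAULT_MAX_ENUMERATIONS,
                 hyper: Hyperparameters | None = None) -> EvidenceEstimate:
    """Evidence by summing the collapsed likelihood over every assignment.

    Only feasible for tiny tables; the enumeration size K^N is capped by
    ``max_enumerations``.  K=2 uses a vectorized subset-statistics path,
    other K a depth-first chain-rule enumeration.
    """
    n = table.n_rows
    if k < 1 or k > n:
        raise ValueError(f"need 1 <= k <= {n}, got k={k}")
    if k ** n > max_enumerations:
        raise ValueError(
            f"enumeration of {k}^{n} assignments exceeds the cap of "
            f"{max_enumerations}"
        )
    if k == 1:
        ll = _joint_ll(table, np.zeros(n, dtype=np.int64), 1, hyper)
        return EvidenceEstimate(ll, "exact", 1, n_assignments=1)
    if k == 2:
        log_ml, count = _exact_k2(table, hyper)
    else:
        log_ml, count = _exact_dfs(table, k, hyper)
    return EvidenceEstimate(log_ml, "exact", k, n_assignments=count)


def _exact_k2(table: Table, hyper: Hyperparameters | None):
    """All 2^N - 2 two-cluster assignments at once.

    Every assignment is a subset mask (cluster 1) and its complement
    (cluster 2).  Per-subset sufficient statistics for every mask are built
    by doubling: appending row i maps mask m -> m + 2^i.  The collapsed
    marginal of a subset is then evaluated vectorized over all masks.
    """
    hyper = hyper or Hyperparameters()
    n = table.n_rows
    m_total = 1 << n
    sizes = np.zeros(1, dtype=np.int32)
    for _ in range(n):
        sizes = np.concatenate([sizes, sizes + 1])

    log_f = np.zeros(m_total)

    c = hyper.pseudo_count
    count_table = gammaln(c + np.arange(n + 1)) - gammaln(c)
    for l in range(table.cat.shape[1]):
        k_l = table.cat_levels[l]
        x = table.cat[:, l]
        cnts = np.zeros((1, k_l), dtype=np.int32)
        for i in range(n):
            row = np.zeros(k_l, dtype=np.int32)
            row[x[i]] = 1
            cnts = np.concatenate([cnts, cnts + row])
        c_tot = c * k_l
        size_table = gammaln(c_tot) - gammaln(c_tot + np.arange(n + 1))
        log_f += count_table[cnts].sum(axis=1) + size_table[sizes]

    if table.num.shape[1]:
        a0, beta0 = hyper.a0, hyper.beta0
        a_table = np.array(
            [math.lgamma(a0 + 0.5 * i) - math.lgamma(a0) for i in range(n + 1)]
        )
        nn = sizes.astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            for l in range(table.num.shape[1]):
                mu0, _, _, b0 = hyper.resolve(table.num[:, l])
                x = table.num[:, l]
                s1 = np.zeros(1)
                s2 = np.zeros(1)
                for i in range(n):
                    s1 = np.concatenate([s1, s1 + x[i]])
                    s2 = np.concatenate([s2, s2 + x[i] * x[i]])
                mean = np.where(nn > 0, s1 / np.maximum(nn, 1), 0.0)
                ss = np.maximum(s2 - s1 * mean, 0.0)
                beta_n = beta0 + nn
                a_n = a0 + 0.5 * nn
                b_n = (b0 + 0.5 * ss
                       + beta0 * nn * (mean - mu0) ** 2 / (2.0 * beta_n))
                marg = (a_table[sizes]
                        + a0 * math.log(b0) - a_n * np.log(b_n)
                        + 0.5 * (math.log(beta0) - np.log(beta_n))
                        - 0.5 * nn * math.log(2.0 * math.pi))
                log_f += np.where(nn > 0, marg, 0.0)

    total = log_f + log_f[::-1]  # complement of mask m is (2^N - 1) - m
    count = m_total - 2
    log_prior = -math.log(count)
    log_ml = float(logsumexp(total[1:-1]) + log_prior)
    return log_ml, count


def _exact_dfs(table: Table, k: int, hyper: Hyperparameters | None):
    """Depth-first enumeration for general K, scoring by the chain rule:
    the collapsed likelihood of a full assignment is the sum of sequential
    posterior predictives as rows are added."""
    n = table.n_rows
    state = ClusterState(table, np.zeros(n, dtype=np.int64), k, hyper)
    for i in range(n):
        state.remove(i)
    terms: list[float] = []
    count = 0

    def recurse(i: int, acc: float) -> None:
        nonlocal count
        if i == n:
            if (state.sizes > 0).all():
                terms.append(acc)
            count += 1
            return
        for j in range(k):
            delta = state.predictive(i, j)
            state.add(i, j)
            recurse(i + 1, acc + delta)
            state.remove(i)

    recurse(0, 0.0)
    n_surjective = len(terms)
    log_ml = float(logsumexp(np.asarray(terms)) - math.log(n_surjective))
    return log_ml, n_surjective


# -- samplers -----------------------------------------------------------------

def sample_tempered_log_likelihoods(
    table: Table, k: int, beta: float, m: int, seed: int, *,
    burn_in: int | None = None, thin: int | None = None,
    init: np.ndarray | None = None,
    hyper: Hyperparameters | None = None,
) -> np.ndarray:
    """M values of log P(D|A,K) with A sampled from a distribution
    proportional to P(D|A,K)^beta over surjective assignments.

    beta=0 draws i.i.d. from the uniform prior; beta>0 runs single-site
    Metropolis with ``burn_in`` initial proposals (default 10N) and
    ``thin`` proposals between retained samples (default N).
    """
    n = table.n_rows
    rng = np.random.default_rng(seed)
    if k == 1:
        ll = _joint_ll(table, np.zeros(n, dtype=np.int64), 1, hyper)
        return np.full(m, ll)
    if beta == 0.0:
        out = np.empty(m)
        for s in range(m):
            labels = _uniform_surjective(rng, n, k)
            out[s] = _joint_ll(table, labels, k, hyper)
        return out

    burn_in = 10 * n if burn_in is None else burn_in
    thin = max(n, 1) if thin is None else max(thin, 1)
    if init is not None:
        labels = np.asarray(init, dtype=np.int64) - 1
        if labels.max() >= k or len(np.unique(labels)) < k:
            labels = _uniform_surjective(rng, n, k)
    else:
        labels = _uniform_surjective(rng, n, k)
    state = ClusterState(table, labels, k, hyper)
    ll = state.joint_log_likelihood()

    total_steps = burn_in + m * thin
    rows = rng.integers(0, n, size=total_steps)
    offsets = rng.integers(1, k, size=total_steps)
    accept_u = rng.random(size=total_steps)

    out = np.empty(m)
    s_idx = 0
    for t in range(total_steps):
        i = rows[t]
        old = state.labels[i]
        new = (old + offsets[t]) % k
        if state.sizes[old] > 1:  # move may not empty a cluster
            old_j = state.remove(i)
            s_old = state.predictive(i, old_j)
            s_new = state.predictive(i, new)
            delta = s_new - s_old
            if accept_u[t] < math.exp(min(0.0, beta * delta)):
                state.add(i, new)
                ll += delta
            else:
                state.add(i, old_j)
        if t >= burn_in and (t - burn_in + 1) % thin == 0:
            out[s_idx] = ll
            s_idx += 1
    return out


def _log_mean_exp(y: np.ndarray) -> float:
    return float(logsumexp(y) - math.log(len(y)))


def _batch_se(values: np.ndarray, estimator, n_batches: int = 10) -> float:
    """Batch-means standard error of a statistic of a (possibly
    autocorrelated) sample stream."""
    m = len(values)
    n_batches = min(n_batches, m)
    if n_batches < 2:
        return float("nan")
    batches = np.array_split(values, n_batches)
    ests = np.array([estimator(b) for b in batches])
    return float(np.std(ests, ddof=1) / math.sqrt(n_batches))


# -- Monte Carlo estimators ---------------------------------------------------

def am_log_ml(table: Table, k: int, *, m: int = 200, seed: int = 0,
              hyper: Hyperparameters | None = None) -> EvidenceEstimate:
    """Arithmetic-mean estimate: average likelihood over prior draws."""
    lls = sample_tempered_log_likelihoods(table, k, 0.0, m, seed, hyper=hyper)
    log_ml = _log_mean_exp(lls)
    se = _batch_se(lls, _log_mean_exp)
    return EvidenceEstimate(log_ml, "AM", k, m=m, mc_error=se, seed=seed)


def hm_log_ml(table: Table, k: int, *, m: int = 200, seed: int = 0,
              burn_in: int | None = None, thin: int | None = None,
              init: np.ndarray | None = None,
              hyper: Hyperparameters | None = None) -> EvidenceEstimate:
    """Harmonic-mean estimate over posterior samples."""
    lls = sample_tempered_log_likelihoods(
        table, k, 1.0, m, seed, burn_in=burn_in, thin=thin, init=init,
        hyper=hyper)
    log_ml = -_log_mean_exp(-lls)
    se = _batch_se(lls, lambda b: -_log_mean_exp(-b))
    return EvidenceEstimate(log_ml, "HM", k, m=m, mc_error=se, seed=seed)


def hmbeta_log_ml(table: Table, k: int, *, beta: float = 0.5, m: int = 200,
                  seed: int = 0, burn_in: int | None = None,
                  thin: int | None = None, init: np.ndarray | None = None,
                  variant: str = "ratio",
                  hyper: Hyperparameters | None = None) -> EvidenceEstimate:
    """Tempered harmonic-mean evidence estimate.

    The default ``ratio`` variant uses a single chain at inverse
    temperature ``beta`` (target proportional to P(D|A,K)^beta) and forms

        log ML = log< P^(1-beta) > - log< P^(-beta) >

    over that one stream.  Both averages then share every sample, and the
    estimator reduces exactly to the arithmetic mean at beta=0 (the chain
    is the prior) and to the harmonic mean at beta=1 (the chain is the
    posterior).

    ``variant="two_chain"`` instead estimates the second factor from a
    separate posterior chain:

        log ML = -log< P^(-beta) >_tempered - log< P^(beta-1) >_posterior

    which splits the prior-to-posterior bridge into two half-bridges at the
    cost of a second chain; its endpoint reductions are both the harmonic
    mean.  See the methods note for the trade-off.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must be in [0, 1], got {beta}")
    if variant not in ("ratio", "two_chain"):
        raise ValueError(f"unknown variant {variant!r}")
    if variant == "ratio":
        lls = sample_tempered_log_likelihoods(
            table, k, beta, m, seed, burn_in=burn_in, thin=thin, init=init,
            hyper=hyper)

        def est(b):
            return _log_mean_exp((1.0 - beta) * b) - _log_mean_exp(-beta * b)

        log_ml = est(lls)
        se = _batch_se(lls, est)
        return EvidenceEstimate(log_ml, "HMbeta", k, beta=beta, m=m,
                                mc_error=se, seed=seed,
                                settings={"variant": "ratio"})
    lls_t = sample_tempered_log_likelihoods(
        table, k, beta, m, seed, burn_in=burn_in, thin=thin, init=init,
        hyper=hyper)
    lls_p = sample_tempered_log_likelihoods(
        table, k, 1.0, m, seed + 1_000_003, burn_in=burn_in, thin=thin,
        init=init, hyper=hyper)
    term1 = -_log_mean_exp(-beta * lls_t)
    term2 = -_log_mean_exp((beta - 1.0) * lls_p)
    se1 = _batch_se(lls_t, lambda b: -_log_mean_exp(-beta * b))
    se2 = _batch_se(lls_p, lambda b: -_log_mean_exp((beta - 1.0) * b))
    se = math.hypot(se1, se2)
    return EvidenceEstimate(term1 + term2, "HMbeta", k, beta=beta, m=m,
                            mc_error=se, seed=seed,
                            settings={"variant": "two_chain"})


def ti_log_ml(table: Table, k: int, *, m: int = 200, n_temperatures: int = 11,
              seed: int = 0, burn_in: int | None = None,
              thin: int | None = None, init: np.ndarray | None = None,
              hyper: Hyperparameters | None = None) -> EvidenceEstimate:
    """Thermodynamic integration along an inverse-temperature grid.

    log ML is the integral over beta in [0, 1] of the tempered expectation
    of log P(D|A,K); the grid is uniform with an odd number of points so
    Simpson's rule applies.  The anchor is the normalized prior at beta=0.
    """
    if n_temperatures < 3 or n_temperatures % 2 == 0:
        raise ValueError("n_temperatures must be odd and >= 3")
    grid = np.linspace(0.0, 1.0, n_temperatures)
    e_beta = np.empty(n_temperatures)
    se_beta = np.empty(n_temperatures)
    for g, b in enumerate(grid):
        lls = sample_tempered_log_likelihoods(
            table, k, float(b), m, seed + g, burn_in=burn_in, thin=thin,
            init=init, hyper=hyper)
        e_beta[g] = lls.mean()
        se_beta[g] = _batch_se(lls, np.mean)
    log_ml = float(simpson(e_beta, x=grid))
    h = grid[1] - grid[0]
    w = np.full(n_temperatures, 2.0)
    w[1::2] = 4.0
    w[0] = w[-1] = 1.0
    w *= h / 3.0
    se = float(np.sqrt(np.nansum((w * se_beta) ** 2)))
    return EvidenceEstimate(
        log_ml, "TI", k, m=m, mc_error=se, seed=seed,
        settings={"beta_grid": grid.tolist(), "e_beta": e_beta.tolist()})


def bic_log_ml(table: Table, assignment: np.ndarray, *,
               hyper: Hyperparameters | None = None) -> EvidenceEstimate:
    """BIC baseline on the -BIC/2 scale (comparable to a log evidence).

    The fit term is the maximized plug-in log-likelihood of the hard
    partition (per-cluster MLE category frequencies and Gaussian
    parameters, plus mixture weights); the penalty counts (k_l - 1)
    categorical parameters and 2 Gaussian parameters per column per
    cluster, plus K-1 weights.
    """
    labels = np.asarray(assignment, dtype=np.int64) - 1
    n = table.n_rows
    k = int(labels.max()) + 1
    ll = 0.0
    n_params = k - 1
    for j in range(k):
        members = labels == j
        nj = int(members.sum())
        if nj == 0:
            continue
        ll += nj * math.log(nj / n)
        for l in range(table.cat.shape[1]):
            cnt = np.bincount(table.cat[members, l],
                              minlength=table.cat_levels[l])
            nz = cnt[cnt > 0]
            ll += float(np.sum(nz * np.log(nz / nj)))
        for l in range(table.num.shape[1]):
            x = table.num[members, l]
            var = max(float(np.var(x)), 1e-12)
            ll += -0.5 * nj * (math.log(2.0 * math.pi * var) + 1.0)
    n_params += k * sum(k_l - 1 for k_l in table.cat_levels)
    n_params += k * 2 * table.num.shape[1]
    log_ml = ll - 0.5 * n_params * math.log(n)
    return EvidenceEstimate(log_ml, "BIC", k,
                            settings={"n_parameters": n_params,
                                      "max_log_likelihood": ll})
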