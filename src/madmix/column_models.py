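"""Collapsed conjugate models for single table columns.

Each model holds the sufficient statistics of one column restricted to the
rows of one cluster, together with the hyperparameters of its conjugate
prior.  Because the priors are conjugate, the posterior predictive for a new
value and the marginal likelihood of all absorbed values are available in
closed form, and rows can be added and removed incrementally.  This is the
machinery that lets the clustering loop work with parameters integrated out
rather than estimated.

Two column kinds are supported:

* categorical values with a Dirichlet prior over category probabilities,
  whose marginal is the Dirichlet-multinomial;
* real values with a normal-gamma prior over (mean, precision), whose
  predictive is a Student-t and whose marginal has a closed gamma-function
  form.

All likelihood arithmetic is in log space.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "CategoricalModel",
    "GaussianModel",
    "ColumnSpec",
    "ColumnSchema",
    "Hyperparameters",
]

_LOG_PI = math.log(math.pi)
_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class Hyperparameters:
    """Prior settings shared across the package.

    ``pseudo_count`` is the symmetric Dirichlet weight per category.  The
    normal-gamma prior on a numeric column has location ``mu0``, precision
    scale ``beta0`` and Gamma(shape ``a0``, rate ``b0``) on the precision.
    ``mu0`` and ``b0`` default to ``None`` meaning "set empirically from the
    whole column" (its sample mean and variance), so the prior is on the
    scale of the data regardless of units.
    """

    pseudo_count: float = 1.0
    mu0: float | None = None
    beta0: float = 1.0
    a0: float = 1.0
    b0: float | None = None

    def resolve(self, column: np.ndarray) -> tuple[float, float, float, float]:
        """Concrete (mu0, beta0, a0, b0) for one numeric column."""
        mu0 = float(np.mean(column)) if self.mu0 is None else self.mu0
        if self.b0 is None:
            v = float(np.var(column))
            b0 = v if v > 1e-12 else 1.0
        else:
            b0 = self.b0
        return mu0, self.beta0, self.a0, b0

    def to_dict(self) -> dict:
        return {
            "pseudo_count": self.pseudo_count,
            "mu0": self.mu0,
            "beta0": self.beta0,
            "a0": self.a0,
            "b0": self.b0,
        }


class CategoricalModel:
    """Dirichlet-categorical model of one column within one cluster.

    Categories are indexed ``0..k-1``.  With pseudo-counts ``c_i`` and
    observed counts ``N_i`` the posterior predictive for category ``x`` is
    ``(N_x + c_x) / (N + C)`` where ``C`` is the total pseudo-count; the
    marginal likelihood of all absorbed rows is the Dirichlet-multinomial.
    """

    __slots__ = ("k", "pseudo", "counts", "n", "_c_total")

    def __init__(self, k: int, pseudo_counts: float | np.ndarray = 1.0):
        if k < 2:
            raise ValueError(f"need at least 2 categories, got k={k}")
        self.k = int(k)
        pseudo = np.broadcast_to(np.asarray(pseudo_counts, dtype=float), (k,)).copy()
        if np.any(pseudo <= 0):
            raise ValueError("pseudo-counts must be strictly positive")
        self.pseudo = pseudo
        self.counts = np.zeros(k, dtype=np.int64)
        self.n = 0
        self._c_total = float(pseudo.sum())

    def _check(self, x: int) -> int:
        x = int(x)
        if not 0 <= x < self.k:
            raise ValueError(f"category index {x} out of range [0, {self.k})")
        return x

    def add_row(self, x: int) -> None:
        x = self._check(x)
        self.counts[x] += 1
        self.n += 1

    def remove_row(self, x: int) -> None:
        x = self._check(x)
        if self.counts[x] == 0:
            raise ValueError(f"cannot remove category {x}: not present")
        self.counts[x] -= 1
        self.n -= 1

    def log_predictive(self, x: int) -> float:
        x = self._check(x)
        return math.log(self.counts[x] + self.pseudo[x]) - math.log(
            self.n + self._c_total
        )

    def log_marginal(self) -> float:
        """Dirichlet-multinomial evidence of the absorbed counts."""
        c = self.pseudo
        return float(
            gammaln(self._c_total)
            - gammaln(self._c_total + self.n)
            + np.sum(gammaln(c + self.counts) - gammaln(c))
        )

    def copy(self) -> "CategoricalModel":
        new = CategoricalModel(self.k, self.pseudo)
        new.counts = self.counts.copy()
        new.n = self.n
        return new


class GaussianModel:
    """Normal-gamma model of one numeric column within one cluster.

    The prior on (mean mu, precision lam) is
    ``N(mu | mu0, (beta0 lam)^-1) Gamma(lam | a0, b0)``.  Sufficient
    statistics are the count ``n``, running mean ``mean`` and sum of squared
    deviations ``s`` maintained by Welford updates, so rows can be removed
    as well as added.
    """

    __slots__ = ("mu0", "beta0", "a0", "b0", "n", "mean", "s")

    def __init__(self, mu0: float = 0.0, beta0: float = 1.0, a0: float = 1.0,
                 b0: float = 1.0):
        if beta0 <= 0 or a0 <= 0 or b0 <= 0:
            raise ValueError("beta0, a0, b0 must be strictly positive")
        self.mu0 = float(mu0)
        self.beta0 = float(beta0)
        self.a0 = float(a0)
        self.b0 = float(b0)
        self.n = 0
        self.mean = 0.0
        self.s = 0.0

    @staticmethod
    def _check_value(x: float) -> float:
        x = float(x)
        if not math.isfinite(x):
            raise ValueError(f"non-finite value {x!r} in numeric column")
        return x

    def add_row(self, x: float) -> None:
        x = self._check_value(x)
        self.n += 1
        delta = x - self.mean
        self.mean += delta / self.n
        self.s += delta * (x - self.mean)

    def remove_row(self, x: float) -> None:
        x = self._check_value(x)
        if self.n == 0:
            raise ValueError("cannot remove from an empty model")
        if self.n == 1:
            self.n, self.mean, self.s = 0, 0.0, 0.0
            return
        n_new = self.n - 1
        mean_new = (self.n * self.mean - x) / n_new
        self.s = max(self.s - (x - mean_new) * (x - self.mean), 0.0)
        self.mean = mean_new
        self.n = n_new

    def posterior(self) -> tuple[float, float, float, float]:
        """Posterior hyperparameters (mu_n, beta_n, a_n, b_n)."""
        n = self.n
        if n == 0:
            return self.mu0, self.beta0, self.a0, self.b0
        beta_n = self.beta0 + n
        mu_n = (self.beta0 * self.mu0 + n * self.mean) / beta_n
        a_n = self.a0 + 0.5 * n
        b_n = (
            self.b0
            + 0.5 * self.s
            + self.beta0 * n * (self.mean - self.mu0) ** 2 / (2.0 * beta_n)
        )
        return mu_n, beta_n, a_n, b_n

    def log_predictive(self, x: float) -> float:
        """Student-t posterior predictive log-density at ``x``."""
        x = self._check_value(x)
        mu_n, beta_n, a_n, b_n = self.posterior()
        lam = a_n * beta_n / (b_n * (beta_n + 1.0))
        return (
            -0.5 * _LOG_PI
            + math.lgamma(a_n + 0.5)
            - math.lgamma(a_n)
            + 0.5 * (math.log(lam) - math.log(2.0 * a_n))
            - (a_n + 0.5) * math.log1p(lam * (x - mu_n) ** 2 / (2.0 * a_n))
        )

    def log_marginal(self) -> float:
        """Closed-form evidence of the absorbed rows."""
        if self.n == 0:
            return 0.0
        _, beta_n, a_n, b_n = self.posterior()
        return (
            math.lgamma(a_n)
            - math.lgamma(self.a0)
            + self.a0 * math.log(self.b0)
            - a_n * math.log(b_n)
            + 0.5 * (math.log(self.beta0) - math.log(beta_n))
            - 0.5 * self.n * _LOG_2PI
        )

    def copy(self) -> "GaussianModel":
        new = GaussianModel(self.mu0, self.beta0, self.a0, self.b0)
        new.n, new.mean, new.s = self.n, self.mean, self.s
        return new


@dataclass
class ColumnSpec:
    """Declaration of a single column: name, kind, levels, output flag."""

    name: str
    kind: str  # "categorical" | "numeric"
    levels: list[str] | None = None
    output: bool = False

    def __post_init__(self):
        if self.kind not in ("categorical", "numeric"):
            raise ValueError(f"column {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "categorical":
            if not self.levels or len(self.levels) < 2:
                raise ValueError(
                    f"categorical column {self.name!r} needs >= 2 levels"
                )
            self.levels = [str(v) for v in self.levels]
        elif self.levels is not None:
            raise ValueError(f"numeric column {self.name!r} cannot have levels")


@dataclass
class ColumnSchema:
    """Typed description of a table: ordered column declarations.

    At most one column may be flagged as the output (response) column; the
    clustering itself never uses it, only the synthetic-data generator does.
    """

    columns: list[ColumnSpec] = field(default_factory=list)

    def __post_init__(self):
        names = [c.name for c in self.columns]
        if len(set(names)) != len(names):
            raise ValueError("duplicate column names in schema")
        n_out = sum(c.output for c in self.columns)
        if n_out > 1:
            raise ValueError(f"at most one output column allowed, got {n_out}")

    def __iter__(self):
        return iter(self.columns)

    def __len__(self):
        return len(self.columns)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.columns]

    @property
    def output_column(self) -> ColumnSpec | None:
        for c in self.columns:
            if c.output:
                return c
        return None

    def input_schema(self) -> "ColumnSchema":
        """Schema with the output column dropped."""
        return ColumnSchema([c for c in self.columns if not c.output])

    def __getitem__(self, name: str) -> ColumnSpec:
        for c in self.columns:
            if c.name == name:
                return c
        raise KeyError(name)

    def to_dict(self) -> dict:
        cols = []
        for c in self.columns:
            d: dict = {"name": c.name, "kind": c.kind}
            if c.levels is not None:
                d["levels"] = list(c.levels)
            if c.output:
                d["output"] = True
            cols.append(d)
        return {"columns": cols}

    @classmethod
    def from_dict(cls, d: dict) -> "ColumnSchema":
        cols = [
            ColumnSpec(
                name=c["name"],
                kind=c["kind"],
                levels=c.get("levels"),
                output=bool(c.get("output", False)),
            )
            for c in d["columns"]
        ]
        return cls(cols)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "ColumnSchema":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))
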