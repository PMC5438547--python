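"""Shared statistical result containers and regression helpers.

Every model-fitting operation in the pipeline returns a
:class:`RegressionResult`: a per-term coefficient table (beta, s.e.m., t,
two-sided p) plus the observation count and a model label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


class DegenerateDesignError(ValueError):
    """Raised when a regression design is rank deficient or single-class."""


@dataclass(frozen=True)
class TermResult:
    name: str
    beta: float
    sem: float
    t: float
    p: float

    def one_sided_p(self, alternative: str = "greater") -> float:
        """One-sided p for this term's t statistic (symmetry of the t law)."""
        if alternative not in ("greater", "less"):
            raise ValueError(f"unknown alternative {alternative!r}")
        half = self.p / 2.0
        positive = self.beta > 0
        if (alternative == "greater") == positive:
            return half
        return 1.0 - half


@dataclass(frozen=True)
class RegressionResult:
    terms: tuple[TermResult, ...]
    n_observations: int
    model_label: str
    extra: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> TermResult:
        for term in self.terms:
            if term.name == name:
                return term
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(t.name, t.beta, t.sem, t.t, t.p) for t in self.terms],
            columns=["term", "beta", "sem", "t", "p"],
        )

    def to_dict(self) -> dict:
        return {
            "model": self.model_label,
            "n_observations": self.n_observations,
            "terms": {
                t.name: {"beta": t.beta, "sem": t.sem, "t": t.t, "p": t.p}
                for t in self.terms
            },
            **({"extra": self.extra} if self.extra else {}),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def ols_fit(
    y: np.ndarray,
    X: pd.DataFrame,
    model_label: str,
    report_terms: list[str] | None = None,
    add_intercept: bool = True,
) -> RegressionResult:
    """Ordinary least squares with named columns, two-sided t-test p-values.

    Parameters
    ----------
    y
        Response vector.
    X
        Design matrix; column names become term names.
    report_terms
        Subset of term names to include in the result (default: all
        non-intercept, non-dummy terms are still all returned; pass a list
        to restrict, e.g. to drop hundreds of group dummies).
    """
    X = X.copy()
    if add_intercept:
        X.insert(0, "Intercept", 1.0)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise DegenerateDesignError(
            f"rank-deficient design for {model_label!r}: rank {rank} < "
            f"{X.shape[1]} columns {list(X.columns)}"
        )
    fit = sm.OLS(np.asarray(y, dtype=float), X).fit()
    names = list(X.columns)
    keep = report_terms if report_terms is not None else names
    terms = tuple(
        TermResult(
            name=name,
            beta=float(fit.params[name]),
            sem=float(fit.bse[name]),
            t=float(fit.tvalues[name]),
            p=float(fit.pvalues[name]),
        )
        for name in names
        if name in keep
    )
    return RegressionResult(terms=terms, n_observations=int(fit.nobs), model_label=model_label)


def welch_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Welch two-sample t-test of mean(x) - mean(y), two-sided.

    Returns (mean difference, t, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t, p = sps.ttest_ind(x, y, equal_var=False)
    return float(np.mean(x) - np.mean(y)), float(t), float(p)
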