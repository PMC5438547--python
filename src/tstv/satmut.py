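"""Re-analysis of saturation-mutagenesis enhancer data.

In a saturation-mutagenesis reporter experiment every position of an
enhancer is mutated to each of the three alternative bases and the
resulting activity fold change is measured in replicate.  Replicate fold
changes are averaged on the ratio scale first; the response analysed is
the absolute log2 of that average.  Linear models then ask whether
transversions shift activity more than transitions, adjusting (in the
pooled model) for between-element activity differences and for the
mutation's location within its element; the test of the transversion
coefficient is one-sided (beta_TV > 0).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import classify_substitution
from .stats import DegenerateDesignError, RegressionResult, ols_fit

REQUIRED_COLUMNS = ["element_id", "position", "ref", "alt"]


class SatMutDataError(ValueError):
    """Raised for malformed saturation-mutagenesis tables."""


def load_satmut(path) -> pd.DataFrame:
    """Load a saturation-mutagenesis TSV.

    Expected columns: element_id, position (0-based offset within the
    element), ref, alt, and one or more replicate fold-change columns
    named ``rep1``, ``rep2``, ...  Fold changes must be positive; ``alt``
    must differ from ``ref``.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SatMutDataError(f"missing columns: {missing}")
    rep_cols = [c for c in df.columns if c.startswith("rep")]
    if not rep_cols:
        raise SatMutDataError("no replicate columns (rep1, rep2, ...)")
    if (df["ref"].str.upper() == df["alt"].str.upper()).any():
        raise SatMutDataError("records with alt == ref")
    if (df[rep_cols] <= 0).to_numpy().any():
        raise SatMutDataError("nonpositive replicate fold changes")
    n_alts = df.groupby(["element_id", "position"]).size()
    if (n_alts > 3).any():
        bad = n_alts[n_alts > 3].index[0]
        raise SatMutDataError(f"more than 3 alt records at {bad}")
    df = annotate(df)
    return df


def save_satmut(records: pd.DataFrame, path) -> None:
    rep_cols = [c for c in records.columns if c.startswith("rep")]
    records[REQUIRED_COLUMNS + rep_cols].to_csv(path, sep="\t", index=False)


def annotate(records: pd.DataFrame) -> pd.DataFrame:
    """Attach the Ts/Tv class of every record."""
    out = records.copy()
    out["klass"] = [
        classify_substitution(r, a).value
        for r, a in zip(out["ref"], out["alt"])
    ]
    return out


def summarize_effects(records: pd.DataFrame) -> pd.DataFrame:
    """Average replicate fold changes, then take |log2| of the mean.

    Averaging happens on the ratio scale before the log transform, so
    replicates (2.0, 2.0) give |log2 2| = 1 and a neutral mutation
    (all replicates 1.0) gives 0.
    """
    rep_cols = [c for c in records.columns if c.startswith("rep")]
    if not rep_cols:
        raise SatMutDataError("no replicate columns to summarize")
    out = records.copy()
    mean_fc = out[rep_cols].mean(axis=1)
    if (mean_fc <= 0).any():
        raise SatMutDataError("nonpositive mean fold change")
    out["mean_abs_log2fc"] = np.abs(np.log2(mean_fc))
    return out


def _center_distance(records: pd.DataFrame) -> np.ndarray:
    """|position - element centre| / element length, per record."""
    pos = records["position"].to_numpy(dtype=float)
    out = np.empty(len(records))
    for elem, sub in records.groupby("element_id"):
        idx = records["element_id"] == elem
        p = pos[idx.to_numpy()]
        length = p.max() - p.min() + 1
        center = (p.max() + p.min()) / 2.0
        out[idx.to_numpy()] = np.abs(p - center) / length
    return out


def satmut_ts_tv_test(
    records: pd.DataFrame, scope: str = "pooled"
) -> RegressionResult | dict:
    """Test whether transversions shift activity more than transitions.

    ``scope="pooled"`` fits one OLS of ``mean_abs_log2fc`` on a Tv
    indicator plus the element (categorical) and the scaled distance of
    the mutation from its element's centre; ``scope="per_element"`` fits
    the Tv indicator alone within each element and returns a dict of
    results keyed by element.  The reported ``p`` per term is two-sided;
    the one-sided p for beta_TV > 0 is available via
    ``result["is_tv"].one_sided_p()``.
    """
    if scope not in ("pooled", "per_element"):
        raise ValueError(f"unknown scope {scope!r}")
    if "mean_abs_log2fc" not in records.columns:
        records = summarize_effects(records)
    if "klass" not in records.columns:
        records = annotate(records)

    def _fit(df: pd.DataFrame, label: str, with_covariates: bool) -> RegressionResult:
        classes = set(df["klass"].unique())
        if classes != {"Ts", "Tv"}:
            raise DegenerateDesignError(
                f"{label}: both classes required, found {sorted(classes)}"
            )
        X = pd.DataFrame({"is_tv": (df["klass"] == "Tv").astype(float).to_numpy()})
        if with_covariates:
            X["center_distance"] = _center_distance(df)
            dummies = pd.get_dummies(
                df["element_id"].astype(str), prefix="element",
                drop_first=True, dtype=float,
            )
            X = pd.concat([X, dummies.reset_index(drop=True)], axis=1)
        return ols_fit(
            df["mean_abs_log2fc"].to_numpy(dtype=float),
            X,
            model_label=label,
            report_terms=["is_tv", "center_distance"],
        )

    if scope == "pooled":
        return _fit(records, "satmut_pooled", with_covariates=True)
    return {
        str(elem): _fit(sub.reset_index(drop=True), f"satmut_{elem}", with_covariates=False)
        for elem, sub in records.groupby("element_id")
    }
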