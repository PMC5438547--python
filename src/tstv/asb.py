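"""Allele-specific binding (ASB) transversion-enrichment analysis.

Heterozygous SNPs inside ChIP-seq peaks are tested for allele-specific
binding; the question here is whether the significant (ASB) subset is
enriched for transversions relative to all SNPs tested.  The transversion
fraction in each set is treated as a binomial proportion and the two
fractions are compared with a pooled-variance two-proportion Z-test
(two-tailed).  When variants are pooled across transcription factors or
cell lines, redundant variants are collapsed to unique (chrom, pos, ref,
alt) keys, and the null sample size can be taken as the mean number of
SNPs tested per group — the convention used when the overlap of tested
SNPs between groups is unknown.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import classify_substitution

SNP_COLUMNS = ["chrom", "pos", "ref", "alt", "group", "is_asb"]


class DegenerateTestError(ValueError):
    """Raised when the pooled proportion has zero variance."""


@dataclass(frozen=True)
class EnrichmentResult:
    """Two-proportion Z-test of the Tv fraction in ASB vs tested variants."""

    p1: float  # Tv fraction among ASB variants
    p0: float  # Tv fraction among all tested variants
    n1: float
    n0: float
    z: float
    p_two_tailed: float
    se: float

    def to_dict(self) -> dict:
        return {
            "tv_fraction_asb": self.p1,
            "tv_fraction_tested": self.p0,
            "n_asb": self.n1,
            "n_tested_null": self.n0,
            "z": self.z,
            "p_two_tailed": self.p_two_tailed,
            "se": self.se,
        }


def annotate_klass(records: pd.DataFrame) -> pd.DataFrame:
    """Add/validate the Ts/Tv class column from the ref/alt bases."""
    out = records.copy()
    key = out["ref"].str.upper() + out["alt"].str.upper()
    klass = key.map(
        {r + a: classify_substitution(r, a).value
         for r in "ACGT" for a in "ACGT" if r != a}
    )
    if klass.isna().any():
        bad = out.loc[klass.isna(), ["ref", "alt"]].drop_duplicates()
        raise ValueError(f"invalid substitutions in table: {bad.to_dict('records')}")
    out["klass"] = klass
    return out


def read_snp_table(path) -> pd.DataFrame:
    """Read a tested-SNP table (TSV: chrom, pos, ref, alt, group, is_asb)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in SNP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"SNP table missing columns: {missing}")
    df["is_asb"] = df["is_asb"].astype(bool)
    return annotate_klass(df)


def collapse_redundant(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse to unique (chrom, pos, ref, alt) variants.

    A variant flagged ASB in any group remains ASB after collapsing.
    Output is deterministically sorted by the variant key.
    """
    if records.empty:
        return records.copy()
    df = records if "klass" in records.columns else annotate_klass(records)
    grouped = (
        df.groupby(["chrom", "pos", "ref", "alt"], as_index=False)
        .agg(klass=("klass", "first"), is_asb=("is_asb", "any"))
        .sort_values(["chrom", "pos", "ref", "alt"], kind="mergesort")
        .reset_index(drop=True)
    )
    return grouped


def tv_fraction(records: pd.DataFrame) -> float:
    """Fraction of transversions among the records."""
    if len(records) == 0:
        raise ValueError("empty record table")
    df = records if "klass" in records.columns else annotate_klass(records)
    return float((df["klass"] == "Tv").mean())


def two_tailed_z_test(
    p1: float, n1: float, p0: float, n0: float
) -> EnrichmentResult:
    """Pooled-variance two-proportion Z-test, two-tailed.

    With pooled proportion p = (p1*n1 + p0*n0) / (n1 + n0), the statistic is
    z = (p1 - p0) / sqrt(p(1-p)(1/n1 + 1/n0)) and the p-value 2*Phi(-|z|).
    """
    if n1 < 1 or n0 < 1:
        raise ValueError(f"sample sizes must be >= 1, got n1={n1}, n0={n0}")
    for name, p in (("p1", p1), ("p0", p0)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    pooled = (p1 * n1 + p0 * n0) / (n1 + n0)
    if pooled <= 0.0 or pooled >= 1.0:
        raise DegenerateTestError(
            f"pooled proportion {pooled} has zero variance; test undefined"
        )
    se = float(np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n0)))
    z = float((p1 - p0) / se)
    p_two = float(2.0 * sps.norm.sf(abs(z)))
    return EnrichmentResult(
        p1=float(p1), p0=float(p0), n1=float(n1), n0=float(n0),
        z=z, p_two_tailed=min(p_two, 1.0), se=se,
    )


def one_sample_z_test(p1: float, n1: float, p0: float) -> EnrichmentResult:
    """One-sample variant: tests p1 against a fixed null proportion p0."""
    if n1 < 1:
        raise ValueError(f"n1 must be >= 1, got {n1}")
    if p0 <= 0.0 or p0 >= 1.0:
        raise DegenerateTestError(f"null proportion {p0} has zero variance")
    se = float(np.sqrt(p0 * (1.0 - p0) / n1))
    z = float((p1 - p0) / se)
    p_two = float(2.0 * sps.norm.sf(abs(z)))
    return EnrichmentResult(
        p1=float(p1), p0=float(p0), n1=float(n1), n0=np.inf,
        z=z, p_two_tailed=min(p_two, 1.0), se=se,
    )


def asb_enrichment(
    dataset: pd.DataFrame, pooling: str = "across_groups_mean_n"
) -> EnrichmentResult:
    """Tv enrichment of ASB variants relative to all variants tested.

    ``p1`` is the Tv fraction among collapsed ASB variants (n1 = their
    count); ``p0`` the Tv fraction among all tested variants.  With
    ``pooling="across_groups_mean_n"`` the null sample size is the mean
    number of SNPs tested per group (appropriate when the overlap of
    tested SNPs between groups is unknown); ``pooling="union"`` uses the
    collapsed tested count.  ASB variants are a subset of tested variants
    and are not removed from the null set.
    """
    if pooling not in ("across_groups_mean_n", "union"):
        raise ValueError(f"unknown pooling {pooling!r}")
    df = dataset if "klass" in dataset.columns else annotate_klass(dataset)
    if not df["is_asb"].any():
        raise ValueError("dataset contains no ASB records")
    if df["is_asb"].all():
        raise ValueError("dataset contains no non-ASB tested records")
    collapsed = collapse_redundant(df)
    asb = collapsed[collapsed["is_asb"]]
    p1 = tv_fraction(asb)
    n1 = len(asb)
    p0 = tv_fraction(collapsed)
    if pooling == "across_groups_mean_n":
        n0 = float(df.groupby("group").size().mean())
    else:
        n0 = float(len(collapsed))
    return two_tailed_z_test(p1=p1, n1=n1, p0=p0, n0=n0)
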