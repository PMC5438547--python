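"""Population-scale reporter-assay (POP-STARR) haplotype Ts/Tv analysis.

Haplotypes assayed for regulatory activity are grouped by amplicon so that
each haplotype is only compared with others sharing exactly the same
genomic coordinates.  Within each group one haplotype is designated the
reference; every other haplotype is summarised as a contrast: the absolute
change in log2 activity relative to the reference, together with the
number of transition and transversion differences between the two
haplotypes (optionally re-counted inside the middle third of the
element's DNase hypersensitive site, where TF binding concentrates).

Three linear models relate activity changes to substitution content,
always with the amplicon as a categorical covariate:

- presence:  |dlog2 effect| ~ has_ts + has_tv + amplicon
- count:     |dlog2 effect| ~ n_ts + n_tv + amplicon
- count_mid: |dlog2 effect| ~ n_ts_mid + n_tv_mid + amplicon

Coordinates follow the VCF/BED conventions: variant positions are
1-based; intervals are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import classify_substitution
from .stats import DegenerateDesignError, RegressionResult, ols_fit

MODELS = ("presence", "count", "count_mid")
_MODEL_TERMS = {
    "presence": ("has_ts", "has_tv"),
    "count": ("n_ts", "n_tv"),
    "count_mid": ("n_ts_mid", "n_tv_mid"),
}


class AlignmentError(ValueError):
    """Raised when haplotypes of one amplicon disagree on their site set."""


@dataclass(frozen=True)
class Interval:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"empty interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains_position(self, pos_1based: int) -> bool:
        return self.start <= pos_1based - 1 < self.end


def middle_third(interval: Interval) -> Interval:
    """The central third of an interval: [start + L//3, start + 2L//3)."""
    L = len(interval)
    return Interval(
        chrom=interval.chrom,
        start=interval.start + L // 3,
        end=interval.start + (2 * L) // 3,
    )


@dataclass(frozen=True)
class Haplotype:
    """One assayed haplotype: alleles at segregating sites plus its
    measured activity (effect size, a positive ratio) and p-value."""

    haplotype_id: str
    amplicon_id: str
    alleles: dict  # 1-based genomic position -> base
    effect_size: float
    effect_p: float

    def __post_init__(self) -> None:
        if not self.effect_size > 0:
            raise ValueError(
                f"{self.haplotype_id}: effect_size must be > 0, "
                f"got {self.effect_size}"
            )


@dataclass
class AmpliconGroup:
    """Haplotypes sharing one amplicon's exact coordinates."""

    amplicon_id: str
    interval: Interval
    dhs_interval: Interval
    haplotypes: list
    reference_id: str | None = None

    @property
    def reference(self) -> Haplotype:
        if self.reference_id is None:
            raise ValueError(f"{self.amplicon_id}: no reference designated")
        for hap in self.haplotypes:
            if hap.haplotype_id == self.reference_id:
                return hap
        raise KeyError(self.reference_id)

    def min_effect_p(self) -> float:
        ps = [h.effect_p for h in self.haplotypes]
        if any(p is None or (isinstance(p, float) and np.isnan(p)) for p in ps):
            raise ValueError(f"{self.amplicon_id}: missing effect p-values")
        return min(ps)


@dataclass(frozen=True)
class HaplotypeContrast:
    """One haplotype against its amplicon's reference haplotype."""

    haplotype_id: str
    amplicon_id: str
    delta_mag: float
    n_ts: int
    n_tv: int
    n_ts_mid: int
    n_tv_mid: int

    @property
    def has_ts(self) -> bool:
        return self.n_ts > 0

    @property
    def has_tv(self) -> bool:
        return self.n_tv > 0


def group_by_amplicon(
    haplotypes: list,
    amplicons: pd.DataFrame,
    dhs: pd.DataFrame | None = None,
) -> list:
    """Group haplotypes by amplicon, attaching amplicon and DHS intervals.

    ``amplicons`` needs columns amplicon_id, chrom, start, end; ``dhs``
    (same columns) supplies each amplicon's DHS interval and defaults to
    the amplicon interval itself.  Groups preserve input haplotype order;
    single-haplotype groups are retained (they yield no contrasts).
    """
    amp_idx = {
        str(r.amplicon_id): Interval(str(r.chrom), int(r.start), int(r.end))
        for r in amplicons.itertuples()
    }
    dhs_idx = (
        {
            str(r.amplicon_id): Interval(str(r.chrom), int(r.start), int(r.end))
            for r in dhs.itertuples()
        }
        if dhs is not None
        else {}
    )
    by_amp: dict[str, list] = {}
    order: list[str] = []
    for hap in haplotypes:
        if hap.amplicon_id not in amp_idx:
            raise KeyError(
                f"haplotype {hap.haplotype_id} references unknown amplicon "
                f"{hap.amplicon_id!r}"
            )
        if hap.amplicon_id not in by_amp:
            by_amp[hap.amplicon_id] = []
            order.append(hap.amplicon_id)
        by_amp[hap.amplicon_id].append(hap)
    return [
        AmpliconGroup(
            amplicon_id=amp,
            interval=amp_idx[amp],
            dhs_interval=dhs_idx.get(amp, amp_idx[amp]),
            haplotypes=by_amp[amp],
        )
        for amp in order
    ]


def choose_reference(
    group: AmpliconGroup,
    seed: int | np.random.Generator | None = None,
    explicit: str | None = None,
) -> AmpliconGroup:
    """Designate the group's reference haplotype.

    By default one member is drawn uniformly at random (reproducible for a
    fixed seed); ``explicit`` designates a specific haplotype instead.
    """
    if not group.haplotypes:
        raise ValueError(f"{group.amplicon_id}: empty group")
    if explicit is not None:
        if explicit not in {h.haplotype_id for h in group.haplotypes}:
            raise KeyError(explicit)
        ref_id = explicit
    else:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        ref_id = group.haplotypes[int(rng.integers(len(group.haplotypes)))].haplotype_id
    return AmpliconGroup(
        amplicon_id=group.amplicon_id,
        interval=group.interval,
        dhs_interval=group.dhs_interval,
        haplotypes=group.haplotypes,
        reference_id=ref_id,
    )


def build_contrasts(group: AmpliconGroup) -> list:
    """Contrast every non-reference haplotype with the group reference.

    At each segregating site where the two haplotypes carry different
    bases, the base pair is classified as a transition or transversion;
    counts are accumulated overall and restricted to the DHS middle third.
    ``delta_mag`` is |log2(effect) - log2(effect of reference)|.
    """
    ref = group.reference
    site_keys = set(ref.alleles)
    mid = middle_third(group.dhs_interval)
    contrasts = []
    for hap in group.haplotypes:
        if hap.haplotype_id == ref.haplotype_id:
            continue
        if set(hap.alleles) != site_keys:
            raise AlignmentError(
                f"{group.amplicon_id}: haplotype {hap.haplotype_id} has a "
                "different segregating-site set than the reference"
            )
        n_ts = n_tv = n_ts_mid = n_tv_mid = 0
        for pos in site_keys:
            a, b = ref.alleles[pos], hap.alleles[pos]
            if a == b:
                continue
            is_ts = classify_substitution(a, b).value == "Ts"
            in_mid = mid.contains_position(pos)
            if is_ts:
                n_ts += 1
                n_ts_mid += in_mid
            else:
                n_tv += 1
                n_tv_mid += in_mid
        delta = abs(float(np.log2(hap.effect_size) - np.log2(ref.effect_size)))
        contrasts.append(
            HaplotypeContrast(
                haplotype_id=hap.haplotype_id,
                amplicon_id=group.amplicon_id,
                delta_mag=delta,
                n_ts=n_ts,
                n_tv=n_tv,
                n_ts_mid=int(n_ts_mid),
                n_tv_mid=int(n_tv_mid),
            )
        )
    return contrasts


def filter_groups(groups: list, alpha: float = 0.05) -> list:
    """Keep only amplicon groups containing at least one haplotype whose
    effect-size p-value is below ``alpha`` (the reference included)."""
    return [g for g in groups if g.min_effect_p() < alpha]


def contrasts_frame(contrasts: list) -> pd.DataFrame:
    """Tabulate contrasts for regression and export."""
    return pd.DataFrame(
        [
            {
                "haplotype_id": c.haplotype_id,
                "amplicon_id": c.amplicon_id,
                "delta_mag": c.delta_mag,
                "n_ts": c.n_ts,
                "n_tv": c.n_tv,
                "has_ts": int(c.has_ts),
                "has_tv": int(c.has_tv),
                "n_ts_mid": c.n_ts_mid,
                "n_tv_mid": c.n_tv_mid,
            }
            for c in contrasts
        ]
    )


def fit_model(
    contrasts,
    model: str = "count",
    mid_mode: str = "recount",
) -> RegressionResult:
    """OLS of contrast magnitude on substitution content with amplicon
    as a categorical covariate.

    ``model`` selects the predictors (see module docstring).  For
    ``count_mid``, ``mid_mode="recount"`` keeps every contrast and counts
    only middle-third sites, while ``mid_mode="subset"`` additionally drops
    contrasts with no middle-third difference.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    df = contrasts if isinstance(contrasts, pd.DataFrame) else contrasts_frame(contrasts)
    if df.empty:
        raise DegenerateDesignError("no contrasts to fit")
    if model == "count_mid" and mid_mode == "subset":
        df = df[(df["n_ts_mid"] + df["n_tv_mid"]) > 0]
        if df.empty:
            raise DegenerateDesignError("no contrasts with middle-third variants")
    terms = list(_MODEL_TERMS[model])
    if df["amplicon_id"].nunique() < 2:
        raise DegenerateDesignError(
            "at least 2 amplicons required for the amplicon covariate"
        )
    dummies = pd.get_dummies(
        df["amplicon_id"].astype(str), prefix="amplicon", drop_first=True, dtype=float
    )
    X = pd.concat(
        [df[terms].astype(float).reset_index(drop=True), dummies.reset_index(drop=True)],
        axis=1,
    )
    return ols_fit(
        df["delta_mag"].to_numpy(dtype=float),
        X,
        model_label=f"haplo_{model}",
        report_terms=terms,
    )


def run_haplo_regression(
    haplotypes: list,
    amplicons: pd.DataFrame,
    dhs: pd.DataFrame | None = None,
    seed: int | None = 0,
    alpha: float = 0.05,
    models: tuple = MODELS,
    reference_ids: dict | None = None,
) -> dict:
    """End-to-end haplotype analysis: group, choose references, filter,
    contrast, and fit the requested models.

    ``reference_ids`` (amplicon_id -> haplotype_id) overrides the random
    reference choice where provided.  Returns ``{"contrasts": DataFrame,
    "results": {model: RegressionResult}}``.
    """
    groups = group_by_amplicon(haplotypes, amplicons, dhs)
    rng = np.random.default_rng(seed)
    chosen = []
    for g in groups:
        explicit = (reference_ids or {}).get(g.amplicon_id)
        chosen.append(choose_reference(g, seed=rng, explicit=explicit))
    kept = filter_groups(chosen, alpha=alpha)
    contrasts: list = []
    for g in kept:
        contrasts.extend(build_contrasts(g))
    frame = contrasts_frame(contrasts)
    results = {m: fit_model(frame, model=m) for m in models}
    return {"contrasts": frame, "results": results, "n_groups_kept": len(kept)}


def haplotypes_from_sequences(
    sequences: dict,
    effects: pd.DataFrame,
    amplicons: pd.DataFrame,
) -> list:
    """Build haplotypes from equal-length per-amplicon sequences.

    ``sequences`` maps haplotype_id -> sequence; ``effects`` needs columns
    haplotype_id, amplicon_id, effect_size, effect_p.  Segregating sites
    are the columns at which the amplicon's haplotypes disagree; genomic
    positions are 1-based offsets from the amplicon start.
    """
    amp_start = {
        str(r.amplicon_id): int(r.start) for r in amplicons.itertuples()
    }
    haps: list = []
    for amp_id, sub in effects.groupby("amplicon_id", sort=False):
        ids = [str(h) for h in sub["haplotype_id"]]
        seqs = []
        for hid in ids:
            if hid not in sequences:
                raise KeyError(f"no sequence for haplotype {hid!r}")
            seqs.append(sequences[hid].upper())
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise AlignmentError(
                f"{amp_id}: haplotype sequences have unequal lengths {sorted(lengths)}"
            )
        mat = np.array([list(s) for s in seqs])
        segregating = np.flatnonzero((mat != mat[0]).any(axis=0))
        start = amp_start[str(amp_id)]
        for row, hid in enumerate(ids):
            rec = sub.iloc[row]
            haps.append(
                Haplotype(
                    haplotype_id=hid,
                    amplicon_id=str(amp_id),
                    alleles={
                        int(start + col + 1): mat[row, col] for col in segregating
                    },
                    effect_size=float(rec["effect_size"]),
                    effect_p=float(rec["effect_p"]),
                )
            )
    return haps


def read_haplotype_effects(path) -> pd.DataFrame:
    """Read the haplotype effects TSV (haplotype_id, amplicon_id,
    effect_size, effect_p)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["haplotype_id", "amplicon_id", "effect_size", "effect_p"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"effects table missing columns: {missing}")
    if (df["effect_size"] <= 0).any():
        raise ValueError("effect_size must be positive")
    return df


def read_bed(path) -> pd.DataFrame:
    """Read a 4-column BED (chrom, start, end, name) into an amplicon
    interval table (0-based half-open)."""
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["chrom", "start", "end", "amplicon_id"],
        header=None, dtype={"chrom": str, "amplicon_id": str},
    )
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df
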