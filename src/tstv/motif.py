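"""PFM -> PSSM machinery and exhaustive single-nucleotide mutation scoring
across a motif library.

A position frequency matrix (PFM) holds observed base counts per motif
position.  With a pseudocount of 0.1 added to every element, counts become
frequencies f(b,i) = (count + 0.1) / (column total + 0.4), and the
position-specific scoring matrix (PSSM) holds log-odds scores
log2(f(b,i) / background(b)) in bits.  Per-position information content is
IC(i) = 2 + sum_b f(b,i) log2 f(b,i), bounded by [0, 2] bits.  The score of
a sequence is the sum of its per-position scores, so a single-base change
moves the total by exactly the within-column score difference — which is
what the exhaustive mutation scan tabulates for every unordered base pair
at every position.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from .core import BASES, classify_substitution, encode
from .stats import welch_t_test

#: unordered base pairs in enumeration order; A-G and C-T are transitions
BASE_PAIRS = tuple(combinations(range(4), 2))


class MotifParseError(ValueError):
    """Raised for malformed JASPAR flat files."""


@dataclass(frozen=True)
class PFM:
    """A position frequency matrix: per-position base counts."""

    motif_id: str
    matrix: np.ndarray  # (length, 4) nonnegative counts, columns A,C,G,T
    name: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise MotifParseError(
                f"{self.motif_id}: matrix shape {m.shape}, expected (L>=1, 4)"
            )
        if (m < 0).any():
            raise MotifParseError(f"{self.motif_id}: negative counts")
        object.__setattr__(self, "matrix", m)

    def __len__(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class PSSM:
    """Log-odds scoring matrix with per-position information content."""

    motif_id: str
    scores: np.ndarray  # (length, 4) log2 odds, bits
    ic: np.ndarray  # (length,) bits in [0, 2]
    consensus: str

    def __len__(self) -> int:
        return self.scores.shape[0]


def parse_jaspar(path) -> list[PFM]:
    """Parse a JASPAR flat file (">ID NAME" headers, bracketed A/C/G/T rows).

    Counts are preserved exactly; parsing is delegated to ``Bio.motifs``.
    """
    try:
        with open(path) as handle:
            records = bio_motifs.parse(handle, "jaspar")
    except Exception as exc:  # noqa: BLE001 - re-raise with context
        raise MotifParseError(f"cannot parse JASPAR file {path}: {exc}") from exc
    pfms = []
    for rec in records:
        counts = np.column_stack([np.asarray(rec.counts[b], dtype=float) for b in BASES])
        pfms.append(
            PFM(motif_id=rec.matrix_id or rec.name, matrix=counts, name=rec.name or "")
        )
    return pfms


def write_jaspar(pfms: list[PFM], path) -> None:
    """Write PFMs in JASPAR flat-file format (round-trips through the parser)."""
    with open(path, "w") as handle:
        for pfm in pfms:
            handle.write(f">{pfm.motif_id} {pfm.name or pfm.motif_id}\n")
            for b_idx, base in enumerate(BASES):
                row = " ".join(
                    f"{v:g}" for v in pfm.matrix[:, b_idx]
                )
                handle.write(f"{base}  [ {row} ]\n")


def pfm_to_pssm(
    pfm: PFM,
    pseudocount: float = 0.1,
    background: np.ndarray | None = None,
) -> PSSM:
    """Convert a PFM to a log2-odds PSSM with pseudocount smoothing.

    ``pseudocount`` (default 0.1) is added to every matrix element before
    normalising each column to frequencies.  ``background`` defaults to the
    uniform distribution.  Consensus ties resolve to the first base in
    A < C < G < T order.
    """
    if pseudocount < 0:
        raise ValueError(f"pseudocount must be >= 0, got {pseudocount}")
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    if background.shape != (4,) or (background <= 0).any() or not np.isclose(
        background.sum(), 1.0
    ):
        raise ValueError("background must be 4 positive entries summing to 1")
    counts = pfm.matrix + pseudocount
    col_totals = counts.sum(axis=1, keepdims=True)
    if (col_totals == 0).any():
        raise ValueError(f"{pfm.motif_id}: zero column total after pseudocount")
    freqs = counts / col_totals
    scores = np.log2(freqs / background)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    ic = np.clip(ic, 0.0, 2.0)  # guard float round-off at the boundaries
    consensus = "".join(BASES[i] for i in scores.argmax(axis=1))
    return PSSM(motif_id=pfm.motif_id, scores=scores, ic=ic, consensus=consensus)


def score_sequence(pssm: PSSM, seq: str) -> float:
    """PSSM score of a sequence: the sum of per-position log-odds (bits)."""
    codes = encode(seq)
    if len(codes) != len(pssm):
        raise ValueError(
            f"sequence length {len(codes)} != motif length {len(pssm)}"
        )
    return float(pssm.scores[np.arange(len(codes)), codes].sum())


def normalized_position(i: int, length: int) -> float:
    """Fold a motif position to distance-from-edge scaled to [0, 1].

    0 at either motif edge, 1 at the centre; defined as 1 for
    single-position motifs.
    """
    if length == 1:
        return 1.0
    return 2.0 * min(i, length - 1 - i) / (length - 1)


def enumerate_mutation_scores(pssm: PSSM) -> pd.DataFrame:
    """Exhaustive single-nucleotide mutation scan of one motif.

    Emits one record per position per unordered base pair (6 per position,
    2 transitions and 4 transversions) with the absolute within-column
    score change ``delta = |score(b1, i) - score(b2, i)|`` in bits.

    Columns: motif_id, position, norm_position, ic, b1, b2, klass, delta.
    """
    L = len(pssm)
    rows = []
    for i in range(L):
        col = pssm.scores[i]
        npos = normalized_position(i, L)
        ic = float(pssm.ic[i])
        for v1, v2 in BASE_PAIRS:
            b1, b2 = BASES[v1], BASES[v2]
            rows.append(
                {
                    "motif_id": pssm.motif_id,
                    "position": i,
                    "norm_position": npos,
                    "ic": ic,
                    "b1": b1,
                    "b2": b2,
                    "klass": classify_substitution(b1, b2).value,
                    "delta": float(abs(col[v1] - col[v2])),
                }
            )
    return pd.DataFrame(rows)


def scan_motif_library(
    pfms: list[PFM], pseudocount: float = 0.1
) -> pd.DataFrame:
    """Mutation-score records for every motif of a library, concatenated."""
    frames = [enumerate_mutation_scores(pfm_to_pssm(p, pseudocount)) for p in pfms]
    if not frames:
        return pd.DataFrame(
            columns=[
                "motif_id", "position", "norm_position", "ic",
                "b1", "b2", "klass", "delta",
            ]
        )
    return pd.concat(frames, ignore_index=True)


def stratified_ts_tv_test(
    records: pd.DataFrame,
    stratify_by: str = "norm_position",
    n_bins: int = 11,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-bin Welch t-tests of Tv vs Ts mutation-score magnitudes.

    Records are partitioned into ``n_bins`` equal-width bins over [0, 1]
    (``norm_position``) or [0, 2] (``ic``); within each bin the Tv deltas
    are compared with the Ts deltas by a two-sided Welch two-sample t-test.
    Bins with fewer than 2 records in either class are flagged untestable.
    The Bonferroni-adjusted threshold ``alpha / n_bins`` is reported in
    every row; p-values themselves are unadjusted.
    """
    if records.empty:
        raise ValueError("empty record table")
    if stratify_by not in ("norm_position", "ic"):
        raise ValueError(f"unknown stratification {stratify_by!r}")
    if n_bins < 1:
        raise ValueError(f"n_bins must be >= 1, got {n_bins}")
    upper = 1.0 if stratify_by == "norm_position" else 2.0
    edges = np.linspace(0.0, upper, n_bins + 1)
    values = records[stratify_by].to_numpy(dtype=float)
    # right-closed last bin so the upper boundary is kept
    bin_idx = np.clip(np.digitize(values, edges[1:-1], right=False), 0, n_bins - 1)

    rows = []
    for b in range(n_bins):
        sub = records.iloc[np.flatnonzero(bin_idx == b)]
        ts = sub.loc[sub["klass"] == "Ts", "delta"].to_numpy()
        tv = sub.loc[sub["klass"] == "Tv", "delta"].to_numpy()
        row = {
            "bin": b,
            "bin_low": float(edges[b]),
            "bin_high": float(edges[b + 1]),
            "n_ts": len(ts),
            "n_tv": len(tv),
            "testable": len(ts) >= 2 and len(tv) >= 2,
            "mean_diff": np.nan,
            "t": np.nan,
            "p": np.nan,
            "bonferroni_alpha": alpha / n_bins,
        }
        if row["testable"]:
            diff, t, p = welch_t_test(tv, ts)
            row.update(mean_diff=diff, t=t, p=p)
        rows.append(row)
    return pd.DataFrame(rows)
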