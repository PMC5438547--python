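"""Pentamer-lookup DNA shape prediction and the random-sequence Ts/Tv
shape-effect experiment.

The shape model assigns each position of a sequence four structural
parameters predicted from the 5-mer centred on it: minor groove width
(MGW, angstroms) and propeller twist (ProT, degrees) are per base pair;
roll and helical twist (HelT, degrees) are per base-pair step and are
taken as the mean of the values contributed by the two pentamers flanking
the step.  Entries whose pentamer window does not fit (the first and last
two positions) are undefined (NaN) and excluded from all sums.

The experiment draws random sequences, substitutes the middle base to all
three alternatives, and quantifies each substitution's structural impact
as the summed absolute profile difference between the two sequences of a
pair.  Because the pentamer model is local, a central substitution can
only perturb positions within +/-2 bp (and steps within -3..+2) of the
mutation, which permits an exact windowed shortcut.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import BASES, SubstitutionClass, classify_substitution, encode
from .stats import DegenerateDesignError, RegressionResult, TermResult

PARAMS = ("mgw", "prot", "roll", "helt")
_PENT_WEIGHTS = np.array([256, 64, 16, 4, 1], dtype=np.int64)
# contribution of the window's centre base (index 5 of an 11-mer) to the
# pentamer code centred at window index k+2, k = 0..6
_CENTER_WEIGHTS = np.array([0, 1, 4, 16, 64, 256, 0], dtype=np.int64)

#: the 6 unordered base pairs of a quartet, by base index (A=0,C=1,G=2,T=3)
QUARTET_PAIRS = tuple(combinations(range(4), 2))
_TS_PAIRS = {(0, 2), (1, 3)}  # A-G and C-T


class ShapeTableError(ValueError):
    """Raised for malformed pentamer shape tables."""


def _all_pentamers() -> list[str]:
    return ["".join(p) for p in product(BASES, repeat=5)]


def _pent_code(pentamer: str) -> int:
    return int(encode(pentamer) @ _PENT_WEIGHTS)


@dataclass(frozen=True)
class ShapeTable:
    """Pentamer -> (MGW, ProT, Roll, HelT) lookup over all 1024 5-mers.

    Values are stored as flat arrays indexed by the base-4 encoding of the
    pentamer (A=0, C=1, G=2, T=3, most significant base first).
    """

    mgw: np.ndarray
    prot: np.ndarray
    roll: np.ndarray
    helt: np.ndarray

    def __post_init__(self) -> None:
        for name in PARAMS:
            arr = getattr(self, name)
            if arr.shape != (1024,):
                raise ShapeTableError(
                    f"{name} array has shape {arr.shape}, expected (1024,)"
                )
            if not np.all(np.isfinite(arr)):
                raise ShapeTableError(f"{name} contains non-finite values")

    def values(self, pentamer: str) -> dict[str, float]:
        code = _pent_code(pentamer)
        return {name: float(getattr(self, name)[code]) for name in PARAMS}

    @classmethod
    def constant(cls, value: float = 0.0) -> "ShapeTable":
        """A table mapping every pentamer to the same value (test utility)."""
        arr = np.full(1024, float(value))
        return cls(mgw=arr.copy(), prot=arr.copy(), roll=arr.copy(), helt=arr.copy())

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ShapeTable":
        cols = {c.lower(): c for c in frame.columns}
        required = ["pentamer", *PARAMS]
        missing = [c for c in required if c not in cols]
        if missing:
            raise ShapeTableError(f"missing columns: {missing}")
        pents = frame[cols["pentamer"]].astype(str).str.upper()
        if pents.duplicated().any():
            dups = sorted(pents[pents.duplicated()].unique())
            raise ShapeTableError(f"duplicate pentamers: {dups[:5]} ...")
        if len(pents) != 1024:
            raise ShapeTableError(
                f"incomplete table: {len(pents)} rows, expected 1024"
            )
        arrays = {}
        codes = np.array([_pent_code(p) for p in pents])
        for name in PARAMS:
            col = pd.to_numeric(frame[cols[name]], errors="coerce")
            if col.isna().any():
                raise ShapeTableError(f"non-numeric values in column {name!r}")
            arr = np.empty(1024)
            arr[codes] = col.to_numpy(dtype=float)
            arrays[name] = arr
        return cls(**arrays)

    def to_frame(self) -> pd.DataFrame:
        pents = _all_pentamers()  # lexicographic == code order
        return pd.DataFrame(
            {"pentamer": pents, **{n: getattr(self, n) for n in PARAMS}}
        )


def load_shape_table(path) -> ShapeTable:
    """Load and validate a pentamer shape table from TSV.

    Expected columns (case-insensitive): pentamer, MGW, ProT, Roll, HelT.
    """
    frame = pd.read_csv(path, sep="\t", comment="#")
    return ShapeTable.from_frame(frame)


def save_shape_table(table: ShapeTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ShapeProfile:
    """Per-position (mgw, prot) and per-step (roll, helt) shape vectors.

    ``mgw``/``prot`` have one entry per base pair (NaN at the first and
    last two positions); ``roll``/``helt`` have one entry per step
    (length - 1 entries, NaN at the first two and last two steps).
    """

    mgw: np.ndarray
    prot: np.ndarray
    roll: np.ndarray
    helt: np.ndarray
    length: int


def shape_profile(seq: str, table: ShapeTable) -> ShapeProfile:
    """Predict the four shape parameters across a sequence.

    The base-pair parameters at position ``i`` (0-based, 2 <= i <= L-3)
    come from the pentamer centred at ``i``; the step parameters at step
    ``j`` (between bases j and j+1, 2 <= j <= L-4) are the mean of the
    values from the pentamers centred at ``j`` and ``j+1``.
    """
    codes = encode(seq)
    L = len(codes)
    if L < 5:
        raise ValueError(f"sequence length {L} < 5: no pentamer window fits")
    windows = np.lib.stride_tricks.sliding_window_view(codes.astype(np.int64), 5)
    pcodes = windows @ _PENT_WEIGHTS  # centre positions 2 .. L-3

    mgw = np.full(L, np.nan)
    prot = np.full(L, np.nan)
    mgw[2 : L - 2] = table.mgw[pcodes]
    prot[2 : L - 2] = table.prot[pcodes]

    roll = np.full(L - 1, np.nan)
    helt = np.full(L - 1, np.nan)
    if L >= 6:
        rp = table.roll[pcodes]
        hp = table.helt[pcodes]
        roll[2 : L - 3] = 0.5 * (rp[:-1] + rp[1:])
        helt[2 : L - 3] = 0.5 * (hp[:-1] + hp[1:])
    return ShapeProfile(mgw=mgw, prot=prot, roll=roll, helt=helt, length=L)


@dataclass(frozen=True)
class ShapeEffect:
    """Summed |profile difference| between two sequences differing by one
    substitution, per shape parameter."""

    d_mgw: float
    d_prot: float
    d_roll: float
    d_helt: float
    klass: SubstitutionClass
    quartet_id: int = -1


class PairingError(ValueError):
    """Raised when two sequences do not differ at exactly one position."""


def mutation_shape_effect(seq_a: str, seq_b: str, table: ShapeTable) -> ShapeEffect:
    """Shape impact of the single substitution separating two sequences.

    Sums |profile_a - profile_b| over all defined positions/steps for each
    parameter; symmetric in its sequence arguments.
    """
    if len(seq_a) != len(seq_b):
        raise PairingError(
            f"sequence lengths differ: {len(seq_a)} vs {len(seq_b)}"
        )
    a = encode(seq_a)
    b = encode(seq_b)
    diff = np.flatnonzero(a != b)
    if len(diff) != 1:
        raise PairingError(
            f"sequences differ at {len(diff)} positions, expected exactly 1"
        )
    pos = int(diff[0])
    klass = classify_substitution(seq_a[pos], seq_b[pos])
    pa = shape_profile(seq_a, table)
    pb = shape_profile(seq_b, table)
    deltas = {
        f"d_{name}": float(np.nansum(np.abs(getattr(pa, name) - getattr(pb, name))))
        for name in PARAMS
    }
    return ShapeEffect(**deltas, klass=klass)


def _quartet_effects_windowed(
    seq_codes: np.ndarray, center: int, table: ShapeTable
) -> np.ndarray:
    """Deltas for the 6 variant pairs of many quartets at once.

    ``seq_codes`` is (n, L); the 11-bp window around ``center`` captures
    every pentamer the central substitution can touch, so summing defined
    |differences| inside the window equals the full-profile sum.
    Returns an array of shape (n, 6 pairs, 4 parameters).
    """
    n = seq_codes.shape[0]
    window = seq_codes[:, center - 5 : center + 6].astype(np.int64)
    sw = np.lib.stride_tricks.sliding_window_view(window, 5, axis=1)
    base_codes = sw @ _PENT_WEIGHTS  # (n, 7) pentamer codes, centre base included
    base_codes = base_codes - window[:, 5][:, None] * _CENTER_WEIGHTS

    per_variant = np.empty((4, n, 7, 4))
    for v in range(4):
        pc = base_codes + v * _CENTER_WEIGHTS
        per_variant[v, :, :, 0] = table.mgw[pc]
        per_variant[v, :, :, 1] = table.prot[pc]
        per_variant[v, :, :, 2] = table.roll[pc]
        per_variant[v, :, :, 3] = table.helt[pc]

    out = np.empty((n, 6, 4))
    for k, (v1, v2) in enumerate(QUARTET_PAIRS):
        d = np.abs(per_variant[v1] - per_variant[v2])  # (n, 7, 4)
        # base-pair parameters: sum the 7 affected positions directly
        out[:, k, 0] = d[:, :, 0].sum(axis=1)
        out[:, k, 1] = d[:, :, 1].sum(axis=1)
        # step parameters: steps are means of adjacent pentamer values
        for p in (2, 3):
            pv1 = per_variant[v1][:, :, p]
            pv2 = per_variant[v2][:, :, p]
            s1 = 0.5 * (pv1[:, :-1] + pv1[:, 1:])
            s2 = 0.5 * (pv2[:, :-1] + pv2[:, 1:])
            out[:, k, p] = np.abs(s1 - s2).sum(axis=1)
    return out


def run_shape_experiment(
    n_sequences: int,
    length: int = 503,
    seed: int = 0,
    table: ShapeTable | None = None,
) -> pd.DataFrame:
    """Random-sequence central-substitution shape experiment.

    Draws ``n_sequences`` random sequences of odd ``length``, replaces the
    middle base with all alternatives (a 4-variant quartet per sequence),
    and emits one record per unordered variant pair that differs by the
    single central substitution: 6 pairs per quartet, of which 2 are
    transitions and 4 transversions.

    Returns a DataFrame with columns ``quartet_id``, ``base1``, ``base2``,
    ``klass`` ("Ts"/"Tv"), and ``d_mgw``, ``d_prot``, ``d_roll``,
    ``d_helt``.
    """
    if table is None:
        raise ValueError("a ShapeTable is required")
    if length % 2 == 0:
        raise ValueError(f"length must be odd so the middle base is unique, got {length}")
    if n_sequences < 1:
        raise ValueError(f"n_sequences must be >= 1, got {n_sequences}")
    if length < 11:
        raise ValueError(f"length must be >= 11, got {length}")
    rng = np.random.default_rng(seed)
    seqs = rng.integers(0, 4, size=(n_sequences, length), dtype=np.int8)
    center = length // 2
    deltas = _quartet_effects_windowed(seqs, center, table)

    n_pairs = 6 * n_sequences
    quartet_id = np.repeat(np.arange(n_sequences), 6)
    b1 = np.tile([BASES[v1] for v1, _ in QUARTET_PAIRS], n_sequences)
    b2 = np.tile([BASES[v2] for _, v2 in QUARTET_PAIRS], n_sequences)
    klass = np.tile(
        [
            SubstitutionClass.TS.value if pair in _TS_PAIRS else SubstitutionClass.TV.value
            for pair in QUARTET_PAIRS
        ],
        n_sequences,
    )
    flat = deltas.reshape(n_pairs, 4)
    return pd.DataFrame(
        {
            "quartet_id": quartet_id,
            "base1": b1,
            "base2": b2,
            "klass": klass,
            "d_mgw": flat[:, 0],
            "d_prot": flat[:, 1],
            "d_roll": flat[:, 2],
            "d_helt": flat[:, 3],
        }
    )


def compare_shape_effects(effects: pd.DataFrame) -> dict:
    """Ts-vs-Tv comparison of shape effects with quartet fixed effects.

    For each parameter the class effect (Tv minus Ts) is estimated by a
    linear model with the originating sequence absorbed as a fixed effect:
    response and class indicator are demeaned within quartet and the slope
    fitted by least squares, which is algebraically identical to including
    one dummy per quartet.  Degrees of freedom account for the absorbed
    quartet means.

    Returns ``{"summary": DataFrame, "regressions": {param: RegressionResult}}``
    where the summary holds mean |delta| per class and the Tv/Ts ratio.
    """
    if effects.empty:
        raise ValueError("empty effects table")
    classes = set(effects["klass"].unique())
    if classes != {"Ts", "Tv"}:
        raise DegenerateDesignError(
            f"both substitution classes required, found {sorted(classes)}"
        )
    x = (effects["klass"] == "Tv").to_numpy(dtype=float)
    groups = effects["quartet_id"]
    n_groups = groups.nunique()
    n = len(effects)
    dof = n - n_groups - 1
    if dof < 1:
        raise DegenerateDesignError("not enough observations for quartet fixed effects")
    xt = x - pd.Series(x).groupby(groups.to_numpy()).transform("mean").to_numpy()
    sxx = float(xt @ xt)
    if sxx == 0.0:
        raise DegenerateDesignError("class indicator constant within every quartet")

    rows = []
    regressions = {}
    for name in PARAMS:
        y = effects[f"d_{name}"].to_numpy(dtype=float)
        yt = y - pd.Series(y).groupby(groups.to_numpy()).transform("mean").to_numpy()
        beta = float(xt @ yt) / sxx
        resid = yt - beta * xt
        sigma2 = float(resid @ resid) / dof
        sem = float(np.sqrt(sigma2 / sxx))
        t = beta / sem if sem > 0 else np.inf
        p = float(2.0 * sps.t.sf(abs(t), dof))
        regressions[name] = RegressionResult(
            terms=(TermResult(name="tv", beta=beta, sem=sem, t=t, p=p),),
            n_observations=n,
            model_label=f"shape_{name}_quartet_fe",
        )
        mean_ts = float(effects.loc[effects["klass"] == "Ts", f"d_{name}"].mean())
        mean_tv = float(effects.loc[effects["klass"] == "Tv", f"d_{name}"].mean())
        median_ts = float(effects.loc[effects["klass"] == "Ts", f"d_{name}"].median())
        median_tv = float(effects.loc[effects["klass"] == "Tv", f"d_{name}"].median())
        rows.append(
            {
                "parameter": name,
                "mean_ts": mean_ts,
                "mean_tv": mean_tv,
                "median_ts": median_ts,
                "median_tv": median_tv,
                "ratio_tv_ts": mean_tv / mean_ts if mean_ts > 0 else np.nan,
                "larger_class": "Tv" if mean_tv >= mean_ts else "Ts",
                "fold_larger": (
                    max(mean_tv, mean_ts) / min(mean_tv, mean_ts)
                    if min(mean_tv, mean_ts) > 0
                    else np.nan
                ),
                "beta_tv": beta,
                "sem": sem,
                "p": p,
            }
        )
    return {"summary": pd.DataFrame(rows), "regressions": regressions}
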