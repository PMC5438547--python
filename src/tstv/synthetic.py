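"""Synthetic-data generators for every input the pipeline consumes.

Each generator is a pure function of its parameters and seed (re-runs are
byte-identical) and plants a known Ts/Tv effect structure so that every
analysis arm can be exercised and calibrated without external downloads:

- a pentamer shape table with values in physically plausible ranges;
- motif libraries with Dirichlet-multinomial count columns;
- allele-specific-binding SNP tables with chosen Tv fractions in the
  tested and ASB sets;
- reporter-assay haplotype datasets whose log2 activities are additive in
  alt-allele content (separate planted coefficients for transitions and
  transversions, amplicon-level magnitude offsets, half-normal noise);
- saturation-mutagenesis tables whose mutation-effect magnitudes scale by
  a Tv multiplier, optionally concentrated toward the element centre.

Planted defaults follow the coefficient scale reported for population
reporter assays (Ts 0.06, Tv 0.12 per additional substitution on the
|dlog2 activity| scale) and ASB Tv fractions near 39.3% vs 34.2%, so that
recovery tests read as "recover coefficients of realistic magnitude".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BASES, decode, random_sequence
from .haplo import Haplotype
from .motif import PFM
from .satmut import annotate as _annotate_satmut
from .shape import PARAMS, ShapeTable

# physically plausible parameter ranges for the synthetic pentamer table
SHAPE_RANGES = {
    "mgw": (2.8, 6.2),  # angstroms
    "prot": (-18.0, 0.0),  # degrees
    "roll": (-8.0, 10.0),  # degrees
    "helt": (30.0, 40.0),  # degrees
}

_TS_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TV_PARTNERS = {
    "A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G"),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Scales and planted parameters for the full simulation study."""

    seed: int = 0
    scenario: str = "planted"  # or "null"
    # shape arm
    n_sequences: int = 100_000
    sequence_length: int = 503
    # motif arm
    n_motifs: int = 200
    motif_length_range: tuple = (6, 14)
    motif_concentration: float = 0.5
    # ASB arm
    n_tested: int = 50_000
    n_asb: int = 5_000
    tested_tv_fraction: float = 0.3416
    asb_tv_fraction: float = 0.3933
    n_groups: int = 6
    # haplotype arm
    n_amplicons: int = 100
    haplotypes_per_amplicon: int = 8
    amplicon_length: int = 450
    dhs_length: int = 300
    mean_segregating_sites: float = 3.0
    beta_ts: float = 0.06
    beta_tv: float = 0.12
    noise_sd: float = 0.8
    amplicon_sd: float = 0.3
    sig_fraction: float = 0.3
    ts_bias: float | None = None
    # saturation-mutagenesis arm
    n_elements: int = 3
    element_length: int = 200
    tv_multiplier: float = 1.5
    center_weighting: float = 0.0
    replicates: int = 3

    def __post_init__(self) -> None:
        if self.scenario not in ("null", "planted"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name in ("tested_tv_fraction", "asb_tv_fraction", "sig_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @property
    def effective_beta_ts(self) -> float:
        return 0.0 if self.scenario == "null" else self.beta_ts

    @property
    def effective_beta_tv(self) -> float:
        return 0.0 if self.scenario == "null" else self.beta_tv


def gen_shape_table(seed: int = 0) -> ShapeTable:
    """Random pentamer shape table with values in plausible ranges."""
    rng = np.random.default_rng(seed)
    arrays = {}
    for name in PARAMS:
        low, high = SHAPE_RANGES[name]
        arrays[name] = rng.uniform(low, high, size=1024)
    return ShapeTable(**arrays)


def gen_shape_effects(
    n_quartets: int, tv_multiplier: float = 1.0, seed: int = 0
) -> pd.DataFrame:
    """Synthetic shape-effect records with quartet structure.

    Per quartet a baseline magnitude is drawn and the 6 pair records (2 Ts,
    4 Tv) receive half-normal deltas scaled by the baseline, with Tv deltas
    further scaled by ``tv_multiplier`` (1.0 = null).  Used to calibrate
    the class-effect regression independently of any shape table.
    """
    rng = np.random.default_rng(seed)
    baselines = np.exp(rng.normal(0.0, 0.3, size=n_quartets))
    klass = np.tile(["Tv", "Ts", "Tv", "Tv", "Ts", "Tv"], n_quartets)
    scale = np.repeat(baselines, 6) * np.where(klass == "Tv", tv_multiplier, 1.0)
    raw = np.abs(rng.normal(0.0, 1.0, size=(6 * n_quartets, 4))) * scale[:, None]
    return pd.DataFrame(
        {
            "quartet_id": np.repeat(np.arange(n_quartets), 6),
            "klass": klass,
            "d_mgw": raw[:, 0],
            "d_prot": raw[:, 1],
            "d_roll": raw[:, 2],
            "d_helt": raw[:, 3],
        }
    )


def gen_motif_library(
    n_motifs: int,
    length_range: tuple = (6, 14),
    concentration: float = 0.5,
    seed: int = 0,
    n_sites: int = 100,
) -> list:
    """Random PFMs with Dirichlet-multinomial count columns.

    Low ``concentration`` gives sharply peaked (high-information) columns;
    high concentration gives near-uniform (low-information) columns.
    """
    if concentration <= 0:
        raise ValueError(f"concentration must be > 0, got {concentration}")
    rng = np.random.default_rng(seed)
    low, high = length_range
    pfms = []
    for m in range(n_motifs):
        L = int(rng.integers(low, high + 1))
        probs = rng.dirichlet(np.full(4, concentration), size=L)
        counts = np.vstack([rng.multinomial(n_sites, p) for p in probs]).astype(float)
        pfms.append(PFM(motif_id=f"M{m:04d}", matrix=counts, name=f"synthTF{m}"))
    return pfms


def _draw_alt(ref: str, is_tv: bool, rng: np.random.Generator) -> str:
    if is_tv:
        return _TV_PARTNERS[ref][int(rng.integers(2))]
    return _TS_PARTNER[ref]


def gen_asb_dataset(
    n_tested: int = 50_000,
    tested_tv_fraction: float = 0.3416,
    n_asb: int = 5_000,
    asb_tv_fraction: float = 0.3933,
    n_groups: int = 6,
    seed: int = 0,
    duplicate_rate: float = 0.0,
) -> pd.DataFrame:
    """Tested-SNP table with planted Tv fractions in the tested and ASB sets.

    The ASB subset is drawn from the tested pool with its own Tv frequency;
    groups (TFs or cell lines) are assigned round-robin; cross-group
    duplicate rows are injected at ``duplicate_rate`` to exercise
    redundant-variant collapsing.
    """
    if n_asb > n_tested:
        raise ValueError("n_asb must be <= n_tested")
    rng = np.random.default_rng(seed)
    is_tv = rng.random(n_tested) < tested_tv_fraction
    refs = np.array(list(BASES))[rng.integers(0, 4, size=n_tested)]
    alts = np.array(
        [_draw_alt(r, tv, rng) for r, tv in zip(refs, is_tv)]
    )
    # choose the ASB subset with its own class frequency
    tv_pool = list(np.flatnonzero(is_tv))
    ts_pool = list(np.flatnonzero(~is_tv))
    rng.shuffle(tv_pool)
    rng.shuffle(ts_pool)
    asb_idx = []
    for _ in range(n_asb):
        want_tv = rng.random() < asb_tv_fraction
        pool = tv_pool if (want_tv and tv_pool) or not ts_pool else ts_pool
        asb_idx.append(pool.pop())
    is_asb = np.zeros(n_tested, dtype=bool)
    is_asb[asb_idx] = True

    df = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(1, n_tested + 1) * 10,
            "ref": refs,
            "alt": alts,
            "group": [f"group{i % n_groups}" for i in range(n_tested)],
            "is_asb": is_asb,
        }
    )
    df["klass"] = np.where(is_tv, "Tv", "Ts")
    if duplicate_rate > 0 and n_groups > 1:
        dup_mask = rng.random(n_tested) < duplicate_rate
        dups = df[dup_mask].copy()
        shift = rng.integers(1, n_groups, size=len(dups))
        dups["group"] = [
            f"group{(i + s) % n_groups}"
            for i, s in zip(np.flatnonzero(dup_mask) % n_groups, shift)
        ]
        df = pd.concat([df, dups], ignore_index=True)
    return df


def gen_haplotype_dataset(config: SimulationConfig) -> dict:
    """Reporter-assay haplotype dataset with planted Ts/Tv coefficients.

    Per amplicon, the first haplotype carries the reference allele at
    every segregating site; the others carry alternative alleles
    independently with probability 1/2.  On the log2 activity scale each
    non-reference haplotype differs from the first by a signed magnitude

        m = c_amplicon + beta_ts * n_ts + beta_tv * n_tv + |eps|

    with ``eps ~ N(0, noise_sd)`` and ``c_amplicon`` a nonnegative
    amplicon offset, so that with the first haplotype as reference the
    contrast magnitude is exactly the planted linear model (half-normal
    noise, amplicon intercepts absorbed by the categorical covariate).
    A random analysis reference instead emulates the blinded convention of
    population reporter studies, at the cost of the planted structure.

    Returns a dict with haplotypes, sequences, effects, amplicons, dhs,
    variants, and the map of true reference ids per amplicon.
    """
    rng = np.random.default_rng(config.seed)
    beta_ts = config.effective_beta_ts
    beta_tv = config.effective_beta_tv
    haplotypes: list = []
    sequences: dict = {}
    effects_rows = []
    amp_rows = []
    dhs_rows = []
    var_rows = []
    reference_ids = {}
    for a in range(config.n_amplicons):
        amp_id = f"amp{a:03d}"
        start = 1000 + a * (config.amplicon_length + 550)
        end = start + config.amplicon_length
        dhs_start = start + (config.amplicon_length - config.dhs_length) // 2
        amp_rows.append(("chr3", start, end, amp_id))
        dhs_rows.append(("chr3", dhs_start, dhs_start + config.dhs_length, amp_id))

        ref_seq = random_sequence(config.amplicon_length, rng)
        n_sites = max(1, int(rng.poisson(config.mean_segregating_sites)))
        cols = np.sort(rng.choice(config.amplicon_length, size=n_sites, replace=False))
        site_ref = [ref_seq[c] for c in cols]
        site_alt = []
        for rb in site_ref:
            if config.ts_bias is not None:
                is_tv = rng.random() >= config.ts_bias
            else:
                is_tv = rng.random() < (2.0 / 3.0)  # uniform alt base
            site_alt.append(_draw_alt(rb, is_tv, rng))
        site_is_tv = [
            alt not in (_TS_PARTNER[rb],) for rb, alt in zip(site_ref, site_alt)
        ]
        for c, rb, ab in zip(cols, site_ref, site_alt):
            var_rows.append(("chr3", int(start + c + 1), rb, ab))

        amp_offset = abs(rng.normal(0.0, config.amplicon_sd))
        ref_effect = 2.0 ** rng.normal(0.0, 0.5)
        ref_id = f"{amp_id}_h0"
        reference_ids[amp_id] = ref_id
        for h in range(config.haplotypes_per_amplicon):
            hap_id = f"{amp_id}_h{h}"
            if h == 0:
                carries = np.zeros(n_sites, dtype=bool)
            else:
                carries = rng.random(n_sites) < 0.5
            alleles = {
                int(start + c + 1): (site_alt[s] if carries[s] else site_ref[s])
                for s, c in enumerate(cols)
            }
            n_tv = int(sum(1 for s in range(n_sites) if carries[s] and site_is_tv[s]))
            n_ts = int(carries.sum()) - n_tv
            if h == 0:
                effect = ref_effect
            else:
                m = (
                    amp_offset
                    + beta_ts * n_ts
                    + beta_tv * n_tv
                    + abs(rng.normal(0.0, config.noise_sd))
                )
                sign = 1.0 if rng.random() < 0.5 else -1.0
                effect = ref_effect * 2.0 ** (sign * m)
            if rng.random() < config.sig_fraction:
                effect_p = rng.uniform(0.0, 0.05)
            else:
                effect_p = rng.uniform(0.05, 1.0)
            seq = list(ref_seq)
            for s, c in enumerate(cols):
                seq[c] = site_alt[s] if carries[s] else site_ref[s]
            sequences[hap_id] = "".join(seq)
            haplotypes.append(
                Haplotype(
                    haplotype_id=hap_id,
                    amplicon_id=amp_id,
                    alleles=alleles,
                    effect_size=float(effect),
                    effect_p=float(effect_p),
                )
            )
            effects_rows.append((hap_id, amp_id, float(effect), float(effect_p)))
    return {
        "haplotypes": haplotypes,
        "sequences": sequences,
        "effects": pd.DataFrame(
            effects_rows,
            columns=["haplotype_id", "amplicon_id", "effect_size", "effect_p"],
        ),
        "amplicons": pd.DataFrame(
            amp_rows, columns=["chrom", "start", "end", "amplicon_id"]
        ),
        "dhs": pd.DataFrame(dhs_rows, columns=["chrom", "start", "end", "amplicon_id"]),
        "variants": pd.DataFrame(var_rows, columns=["chrom", "pos", "ref", "alt"]),
        "reference_ids": reference_ids,
    }


def gen_satmut_dataset(
    n_elements: int = 3,
    element_length: int = 200,
    tv_multiplier: float = 1.5,
    center_weighting: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
    base_scale: float = 0.3,
    rep_noise_sd: float = 0.1,
) -> pd.DataFrame:
    """Complete saturation-mutagenesis design with planted Tv scaling.

    Every position receives all 3 alternative bases (1 Ts + 2 Tv).  Each
    mutation's true |log2 fold change| is half-normal with scale
    ``base_scale``, multiplied by ``tv_multiplier`` for transversions and
    by ``1 + center_weighting * proximity`` toward the element centre
    (proximity 1 at the centre, 0 at the edges).  Replicate fold changes
    add lognormal measurement noise.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    center = (element_length - 1) / 2.0
    for e in range(n_elements):
        elem = f"enh{e + 1}"
        ref_bases = decode(rng.integers(0, 4, size=element_length))
        for pos in range(element_length):
            ref = ref_bases[pos]
            proximity = 1.0 - abs(pos - center) / (element_length / 2.0)
            pos_scale = base_scale * (1.0 + center_weighting * proximity)
            for alt in BASES:
                if alt == ref:
                    continue
                is_tv = alt != _TS_PARTNER[ref]
                scale = pos_scale * (tv_multiplier if is_tv else 1.0)
                mag = abs(rng.normal(0.0, scale))
                sign = 1.0 if rng.random() < 0.5 else -1.0
                log2fc = sign * mag
                reps = 2.0 ** (log2fc + rng.normal(0.0, rep_noise_sd, size=replicates))
                rows.append((elem, pos, ref, alt, *reps))
    df = pd.DataFrame(
        rows,
        columns=["element_id", "position", "ref", "alt"]
        + [f"rep{i + 1}" for i in range(replicates)],
    )
    return _annotate_satmut(df)
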