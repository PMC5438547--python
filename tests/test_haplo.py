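"""Haplotype grouping, contrasts, and the Ts/Tv regressions."""

import numpy as np
import pandas as pd
import pytest

from tstv.haplo import (
    AlignmentError,
    Haplotype,
    Interval,
    build_contrasts,
    choose_reference,
    filter_groups,
    fit_model,
    group_by_amplicon,
    haplotypes_from_sequences,
    middle_third,
    run_haplo_regression,
)
from tstv.stats import DegenerateDesignError
from tstv.synthetic import SimulationConfig, gen_haplotype_dataset


def hap(hid, amp, alleles, effect=1.0, p=0.5):
    return Haplotype(hid, amp, alleles, effect, p)


AMPS = pd.DataFrame(
    {
        "amplicon_id": ["a1", "a2"],
        "chrom": ["chr3", "chr3"],
        "start": [0, 1000],
        "end": [300, 1300],
    }
)


def test_grouping_conserves_haplotypes():
    haps = [
        hap("h1", "a1", {10: "A"}),
        hap("h2", "a1", {10: "G"}),
        hap("h3", "a2", {1100: "C"}),
    ]
    groups = group_by_amplicon(haps, AMPS)
    assert len(groups) == 2
    assert sorted(len(g.haplotypes) for g in groups) == [1, 2]
    assert sum(len(g.haplotypes) for g in groups) == 3
    assert group_by_amplicon([], AMPS) == []
    with pytest.raises(KeyError):
        group_by_amplicon([hap("h", "zzz", {1: "A"})], AMPS)


def test_choose_reference_contract():
    haps = [hap(f"h{i}", "a1", {10: "A"}) for i in range(4)]
    group = group_by_amplicon(haps, AMPS)[0]
    assert (
        choose_reference(group, seed=3).reference_id
        == choose_reference(group, seed=3).reference_id
    )
    single = group_by_amplicon([hap("only", "a1", {10: "A"})], AMPS)[0]
    assert choose_reference(single, seed=0).reference_id == "only"
    assert choose_reference(group, explicit="h2").reference_id == "h2"
    counts = {}
    for s in range(10000):
        rid = choose_reference(group, seed=s).reference_id
        counts[rid] = counts.get(rid, 0) + 1
    for frac in (v / 10000 for v in counts.values()):
        assert abs(frac - 0.25) < 0.02


def test_contrasts_against_site_by_site_oracle():
    """Hand-built 5-site group: 2 Ts + 1 Tv difference vs the reference."""
    sites_ref = {11: "A", 12: "C", 13: "G", 14: "T", 15: "A"}
    sites_alt = {11: "G", 12: "T", 13: "G", 14: "A", 15: "A"}  # A>G Ts, C>T Ts, T>A Tv
    haps = [
        hap("ref", "a1", sites_ref, effect=1.0),
        hap("alt", "a1", sites_alt, effect=2.0),
    ]
    group = choose_reference(group_by_amplicon(haps, AMPS)[0], explicit="ref")
    (contrast,) = build_contrasts(group)
    assert contrast.n_ts == 2 and contrast.n_tv == 1
    assert contrast.delta_mag == pytest.approx(1.0)  # |log2 2 - log2 1|
    assert contrast.has_ts and contrast.has_tv
    assert contrast.n_ts + contrast.n_tv == sum(
        sites_ref[k] != sites_alt[k] for k in sites_ref
    )
    # symmetry: swap reference
    swapped = choose_reference(group, explicit="alt")
    (back,) = build_contrasts(swapped)
    assert (back.n_ts, back.n_tv, back.delta_mag) == (
        contrast.n_ts, contrast.n_tv, pytest.approx(contrast.delta_mag),
    )


def test_contrasts_middle_third_counts():
    # amplicon a1 spans [0, 300); the middle third of its DHS is [100, 200),
    # so of the differences A>T (pos 50, Tv), C>T (pos 150, Ts) and
    # G>A (pos 250, Ts), only the pos-150 transition is mid-DHS
    haps = [
        hap("ref", "a1", {50: "A", 150: "C", 250: "G"}, effect=1.0),
        hap("alt", "a1", {50: "T", 150: "T", 250: "A"}, effect=1.0),
    ]
    group = choose_reference(group_by_amplicon(haps, AMPS)[0], explicit="ref")
    (c,) = build_contrasts(group)
    assert (c.n_ts, c.n_tv) == (2, 1)
    assert (c.n_ts_mid, c.n_tv_mid) == (1, 0)


def test_contrast_alignment_error():
    haps = [hap("ref", "a1", {10: "A"}), hap("alt", "a1", {11: "C"})]
    group = choose_reference(group_by_amplicon(haps, AMPS)[0], explicit="ref")
    with pytest.raises(AlignmentError):
        build_contrasts(group)


def test_middle_third_examples_and_nesting():
    assert middle_third(Interval("c", 0, 300)) == Interval("c", 100, 200)
    assert middle_third(Interval("c", 0, 10)) == Interval("c", 3, 6)
    outer = Interval("c", 17, 1040)
    mid = middle_third(outer)
    assert outer.start <= mid.start < mid.end <= outer.end
    assert abs(len(mid) - len(outer) / 3) <= 1
    inner = middle_third(mid)
    assert mid.start <= inner.start < inner.end <= mid.end
    with pytest.raises(ValueError):
        Interval("c", 5, 5)


def test_filter_groups_matches_independent_oracle(rng):
    groups = []
    expected = []
    for g in range(50):
        ps = rng.uniform(0, 1, size=4)
        haps = [
            hap(f"g{g}h{i}", "a1", {10: "A"}, p=float(ps[i])) for i in range(4)
        ]
        grp = group_by_amplicon(haps, AMPS)[0]
        groups.append(grp)
        expected.append(ps.min() < 0.05)
    kept = filter_groups(groups, alpha=0.05)
    assert len(kept) == sum(expected)
    explicit = [
        [hap("a", "a1", {1: "A"}, p=0.2), hap("b", "a1", {1: "A"}, p=0.8)],
        [hap("c", "a1", {1: "A"}, p=0.01), hap("d", "a1", {1: "A"}, p=0.9)],
    ]
    gs = [group_by_amplicon(h, AMPS)[0] for h in explicit]
    assert filter_groups(gs) == [gs[1]]


def test_fit_model_exact_recovery_without_noise():
    """Noiseless planted coefficients are recovered exactly by OLS."""
    rows = []
    rng = np.random.default_rng(5)
    for a in range(6):
        for h in range(6):
            n_ts = int(rng.integers(0, 4))
            n_tv = int(rng.integers(0, 4))
            rows.append(
                {
                    "haplotype_id": f"a{a}h{h}",
                    "amplicon_id": f"a{a}",
                    "delta_mag": 0.06 * n_ts + 0.12 * n_tv + 0.01 * a,
                    "n_ts": n_ts, "n_tv": n_tv,
                    "has_ts": int(n_ts > 0), "has_tv": int(n_tv > 0),
                    "n_ts_mid": 0, "n_tv_mid": 0,
                }
            )
    df = pd.DataFrame(rows)
    res = fit_model(df, model="count")
    assert res["n_ts"].beta == pytest.approx(0.06, abs=1e-10)
    assert res["n_tv"].beta == pytest.approx(0.12, abs=1e-10)


def test_fit_model_matches_lstsq_oracle():
    """OLS coefficients equal an independent QR/lstsq solution."""
    cfg = SimulationConfig(seed=4, n_amplicons=10, haplotypes_per_amplicon=6)
    data = gen_haplotype_dataset(cfg)
    res = run_haplo_regression(
        data["haplotypes"], data["amplicons"], data["dhs"],
        seed=0, reference_ids=data["reference_ids"], models=("count",),
    )
    df = res["contrasts"]
    dummies = pd.get_dummies(df["amplicon_id"], drop_first=True, dtype=float)
    X = np.column_stack(
        [np.ones(len(df)), df[["n_ts", "n_tv"]].to_numpy(float), dummies.to_numpy()]
    )
    beta, *_ = np.linalg.lstsq(X, df["delta_mag"].to_numpy(float), rcond=None)
    got = res["results"]["count"]
    assert got["n_ts"].beta == pytest.approx(beta[1], abs=1e-8)
    assert got["n_tv"].beta == pytest.approx(beta[2], abs=1e-8)


def test_fit_model_degenerate_designs():
    df = pd.DataFrame(
        {
            "haplotype_id": ["h1", "h2"],
            "amplicon_id": ["a1", "a1"],
            "delta_mag": [0.1, 0.2],
            "n_ts": [1, 2], "n_tv": [0, 1],
            "has_ts": [1, 1], "has_tv": [0, 1],
            "n_ts_mid": [0, 0], "n_tv_mid": [0, 0],
        }
    )
    with pytest.raises(DegenerateDesignError):
        fit_model(df, model="count")  # single amplicon
    with pytest.raises(ValueError):
        fit_model(df, model="bogus")


def test_haplotypes_from_sequences_columnwise():
    amps = pd.DataFrame(
        {"amplicon_id": ["a1"], "chrom": ["chr3"], "start": [100], "end": [110]}
    )
    effects = pd.DataFrame(
        {
            "haplotype_id": ["h1", "h2"],
            "amplicon_id": ["a1", "a1"],
            "effect_size": [1.0, 2.0],
            "effect_p": [0.01, 0.5],
        }
    )
    seqs = {"h1": "ACGTACGTAC", "h2": "ACGAACGTAT"}
    haps = haplotypes_from_sequences(seqs, effects, amps)
    # segregating columns 3 (T/A) and 9 (C/T); positions 104 and 110
    assert haps[0].alleles == {104: "T", 110: "C"}
    assert haps[1].alleles == {104: "A", 110: "T"}
    bad = {"h1": "ACGT", "h2": "ACG"}
    with pytest.raises(AlignmentError):
        haplotypes_from_sequences(bad, effects, amps)


def test_end_to_end_regression_uses_filter_and_reports_all_models():
    cfg = SimulationConfig(seed=11, n_amplicons=30, haplotypes_per_amplicon=6)
    data = gen_haplotype_dataset(cfg)
    res = run_haplo_regression(
        data["haplotypes"], data["amplicons"], data["dhs"],
        seed=2, reference_ids=data["reference_ids"],
    )
    assert set(res["results"]) == {"presence", "count", "count_mid"}
    assert res["n_groups_kept"] <= 30
    df = res["contrasts"]
    assert (df["n_ts_mid"] <= df["n_ts"]).all()
    assert (df["n_tv_mid"] <= df["n_tv"]).all()
    assert (df["delta_mag"] >= 0).all()
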