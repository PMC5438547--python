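"""Pentamer shape prediction and the mutation-quartet experiment."""

import numpy as np
import pandas as pd
import pytest

from tstv.core import decode, random_sequence
from tstv.shape import (
    PairingError,
    ShapeTable,
    ShapeTableError,
    compare_shape_effects,
    load_shape_table,
    mutation_shape_effect,
    run_shape_experiment,
    save_shape_table,
    shape_profile,
)
from tstv.stats import DegenerateDesignError
from tstv.synthetic import gen_shape_effects, gen_shape_table


def naive_profile(seq, table):
    """Independent sliding-window re-implementation (the oracle)."""
    L = len(seq)
    mgw = np.full(L, np.nan)
    prot = np.full(L, np.nan)
    roll = np.full(L - 1, np.nan)
    helt = np.full(L - 1, np.nan)
    pent_vals = {}
    for i in range(2, L - 2):
        pent_vals[i] = table.values(seq[i - 2 : i + 3])
        mgw[i] = pent_vals[i]["mgw"]
        prot[i] = pent_vals[i]["prot"]
    for j in range(2, L - 3):
        roll[j] = 0.5 * (pent_vals[j]["roll"] + pent_vals[j + 1]["roll"])
        helt[j] = 0.5 * (pent_vals[j]["helt"] + pent_vals[j + 1]["helt"])
    return mgw, prot, roll, helt


def test_profile_matches_naive_oracle(shape_table, rng):
    seq = random_sequence(40, seed=5)
    prof = shape_profile(seq, shape_table)
    mgw, prot, roll, helt = naive_profile(seq, shape_table)
    np.testing.assert_allclose(prof.mgw, mgw, equal_nan=True)
    np.testing.assert_allclose(prof.prot, prot, equal_nan=True)
    np.testing.assert_allclose(prof.roll, roll, equal_nan=True)
    np.testing.assert_allclose(prof.helt, helt, equal_nan=True)


def test_profile_support_and_constant_table():
    table = ShapeTable.constant(4.2)
    prof = shape_profile("ACGTA", table)
    assert np.isnan(prof.mgw[[0, 1, 3, 4]]).all()
    assert prof.mgw[2] == 4.2
    # length-5 sequence has no defined step entries (needs two pentamers)
    assert np.isnan(prof.roll).all()
    longer = shape_profile("ACGTACGT", table)
    defined = ~np.isnan(longer.roll)
    assert defined.sum() == 3 and np.all(longer.roll[defined] == 4.2)


def test_profile_rejects_short_or_bad_sequences(shape_table):
    with pytest.raises(ValueError):
        shape_profile("ACGT", shape_table)
    with pytest.raises(Exception):
        shape_profile("ACGTN", shape_table)


def test_mutation_effect_constant_table_is_zero():
    table = ShapeTable.constant(3.0)
    eff = mutation_shape_effect("ACGTACGTACGTA", "ACGTACATACGTA", table)
    assert eff.d_mgw == eff.d_prot == eff.d_roll == eff.d_helt == 0.0
    assert eff.klass.value == "Ts"  # G->A


def test_mutation_effect_symmetry_and_pairing_errors(shape_table):
    a, b = "ACGTACGTACGTA", "ACGTACATACGTA"
    e1 = mutation_shape_effect(a, b, shape_table)
    e2 = mutation_shape_effect(b, a, shape_table)
    assert (e1.d_mgw, e1.d_prot, e1.d_roll, e1.d_helt) == (
        e2.d_mgw, e2.d_prot, e2.d_roll, e2.d_helt,
    )
    with pytest.raises(PairingError):
        mutation_shape_effect(a, a, shape_table)
    with pytest.raises(PairingError):
        mutation_shape_effect(a, "TCGTACATACGTA", shape_table)  # 2 differences


def test_locality_of_central_mutation(shape_table):
    """A mutation at c perturbs positions c-2..c+2 and steps c-3..c+2 only."""
    seq = random_sequence(31, seed=9)
    c = 15
    mutant = seq[:c] + ("A" if seq[c] != "A" else "C") + seq[c + 1 :]
    pa = shape_profile(seq, shape_table)
    pb = shape_profile(mutant, shape_table)
    d_mgw = np.nan_to_num(np.abs(pa.mgw - pb.mgw))
    d_roll = np.nan_to_num(np.abs(pa.roll - pb.roll))
    assert d_mgw[: c - 2].sum() == 0 and d_mgw[c + 3 :].sum() == 0
    assert d_roll[: c - 3].sum() == 0 and d_roll[c + 3 :].sum() == 0


def test_experiment_pair_counts_and_determinism(shape_table):
    eff = run_shape_experiment(10, 21, seed=4, table=shape_table)
    assert len(eff) == 60
    assert (eff["klass"] == "Ts").sum() == 20
    assert (eff["klass"] == "Tv").sum() == 40
    per_quartet = eff.groupby("quartet_id")["klass"].value_counts().unstack()
    assert (per_quartet["Ts"] == 2).all() and (per_quartet["Tv"] == 4).all()
    again = run_shape_experiment(10, 21, seed=4, table=shape_table)
    pd.testing.assert_frame_equal(eff, again)
    with pytest.raises(ValueError):
        run_shape_experiment(10, 20, seed=4, table=shape_table)


def test_experiment_windowed_matches_full_profile_bruteforce(shape_table):
    """Windowed quartet deltas equal full-profile sums (pentamer locality)."""
    n, L = 25, 503
    eff = run_shape_experiment(n, L, seed=12, table=shape_table)
    rng = np.random.default_rng(12)
    seqs = rng.integers(0, 4, size=(n, L), dtype=np.int8)
    c = L // 2
    k = 0
    for q in range(n):
        variants = []
        for v in range(4):
            codes = seqs[q].copy()
            codes[c] = v
            variants.append(decode(codes))
        for i in range(4):
            for j in range(i + 1, 4):
                oracle = mutation_shape_effect(variants[i], variants[j], shape_table)
                row = eff.iloc[k]
                assert row["klass"] == oracle.klass.value
                for p in ("d_mgw", "d_prot", "d_roll", "d_helt"):
                    assert row[p] == pytest.approx(getattr(oracle, p), abs=1e-9)
                k += 1


def test_compare_effects_demeaning_equals_dummy_regression(shape_table):
    """Fixed-effect absorption equals explicit quartet-dummy OLS."""
    import statsmodels.formula.api as smf

    eff = run_shape_experiment(50, 21, seed=3, table=shape_table)
    res = compare_shape_effects(eff)
    for param in ("mgw", "roll"):
        fit = smf.ols(
            f"d_{param} ~ C(quartet_id) + I(klass == 'Tv')", data=eff
        ).fit()
        term = [t for t in fit.params.index if "klass" in t][0]
        mine = res["regressions"][param]["tv"]
        assert mine.beta == pytest.approx(float(fit.params[term]), rel=1e-9)
        assert mine.sem == pytest.approx(float(fit.bse[term]), rel=1e-9)
        assert mine.p == pytest.approx(float(fit.pvalues[term]), rel=1e-6)


def test_compare_effects_null_and_planted_recovery():
    null = gen_shape_effects(1500, tv_multiplier=1.0, seed=21)
    res0 = compare_shape_effects(null)
    assert (res0["summary"]["p"] > 0.01).all()  # no spurious strong signal
    planted = gen_shape_effects(1500, tv_multiplier=2.0, seed=22)
    res2 = compare_shape_effects(planted)
    assert res2["summary"]["ratio_tv_ts"].between(1.8, 2.2).all()
    assert (res2["summary"]["p"] < 1e-6).all()


def test_compare_effects_rejects_single_class():
    eff = gen_shape_effects(10, seed=0)
    with pytest.raises(DegenerateDesignError):
        compare_shape_effects(eff[eff["klass"] == "Tv"])


def test_shape_table_roundtrip_and_validation(tmp_path):
    table = gen_shape_table(seed=5)
    path = tmp_path / "table.tsv"
    save_shape_table(table, path)
    loaded = load_shape_table(path)
    for p in ("mgw", "prot", "roll", "helt"):
        np.testing.assert_allclose(getattr(loaded, p), getattr(table, p))
    frame = table.to_frame()
    with pytest.raises(ShapeTableError, match="incomplete"):
        ShapeTable.from_frame(frame.iloc[:1023])
    dup = frame.copy()
    dup.iloc[1, 0] = dup.iloc[0, 0]
    with pytest.raises(ShapeTableError, match="duplicate"):
        ShapeTable.from_frame(dup)
    bad = frame.copy()
    bad["mgw"] = bad["mgw"].astype(object)
    bad.loc[0, "mgw"] = "x"
    with pytest.raises(ShapeTableError, match="non-numeric"):
        ShapeTable.from_frame(bad)
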