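"""Quotient normalization, filters, differential tests, replication."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from lipidomix import (
    LipidSimConfig,
    desaturation_elongation_indices,
    differential_test,
    filter_by_detection,
    generate_lipid_experiments,
    missingness_bias_test,
    quotient_normalize,
    replication_filter,
    saturation_class_sums,
    verified_species_frame,
)
from lipidomix.lipid_stats import DifferentialResult, welch_t

from conftest import make_table


def _random_table(rng, n=6, p=10, missing=0.0):
    values = {
        f"FA {2 * (k + 6)}:{k % 3}": rng.lognormal(1.0, 0.5, n)
        for k in range(p)
    }
    table = make_table(values, groups=["GF"] * (n // 2) + ["SPF"] * (n - n // 2))
    if missing:
        mask = rng.random(table.values.shape) < missing
        table.values[:] = table.values.where(~mask)
    return table


# ---------------------------------------------------------------------------
# Quotient normalization


def test_pqn_recovers_known_dilution():
    """A sample at exactly twice the reference profile gets factor 2."""
    base = {"FA 16:0": [4.0, 4.0, 4.0, 8.0],
            "FA 18:0": [2.0, 2.0, 2.0, 4.0],
            "FA 20:4 n-6": [1.0, 1.0, 1.0, 2.0]}
    table = make_table(base, groups=["GF", "GF", "SPF", "SPF"])
    norm = quotient_normalize(table, scope="global")
    np.testing.assert_allclose(norm.values.iloc[3], norm.values.iloc[0])
    assert norm.attrs["pqn_factors"]["all"][3] == pytest.approx(2.0)


def test_pqn_identity_on_identical_samples():
    table = make_table({"FA 16:0": [3.0] * 4, "FA 18:0": [1.0] * 4},
                       groups=["GF", "GF", "SPF", "SPF"])
    norm = quotient_normalize(table, scope="global")
    pd.testing.assert_frame_equal(norm.values, table.values)


def test_pqn_unit_median_quotient_and_idempotence(rng):
    table = _random_table(rng, n=6, p=10)
    norm = quotient_normalize(table, scope="global")
    ref = norm.values.median(axis=0)
    quotients = (norm.values / ref).median(axis=1)
    np.testing.assert_allclose(quotients, 1.0, atol=1e-9)
    twice = quotient_normalize(norm, scope="global")
    np.testing.assert_allclose(twice.values, norm.values, rtol=1e-9)


def test_pqn_preserves_missing_mask_and_class_blocks(rng):
    table = _random_table(rng, n=6, p=10, missing=0.15)
    norm = quotient_normalize(table, scope="class")
    pd.testing.assert_frame_equal(norm.mask, table.mask)
    assert set(norm.attrs["pqn_factors"]) == {
        sp.lipid_class for sp in table.species}


def test_pqn_requires_three_samples_and_nonempty_block():
    small = make_table({"FA 16:0": [1.0, 2.0]}, groups=["GF", "SPF"])
    with pytest.raises(ValueError, match="3 samples"):
        quotient_normalize(small)
    empty = make_table({"FA 16:0": [np.nan] * 4},
                       groups=["GF", "GF", "SPF", "SPF"])
    empty.values[:] = np.nan
    with pytest.raises(ValueError, match="all reference species missing"):
        quotient_normalize(empty, scope="global")


# ---------------------------------------------------------------------------
# Detection filter and missingness


def test_detection_filter_boundary_inclusive():
    """Kept at exactly 50% per group; dropped when one group falls below."""
    table = make_table(
        {
            "FA 16:0": [1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1],
            "FA 18:0": [1, 1, 1, np.nan, np.nan, np.nan,
                        1, 1, 1, np.nan, np.nan, np.nan],
            "FA 20:4 n-6": [1, 1, np.nan, np.nan, np.nan, np.nan,
                            1, 1, 1, 1, 1, 1],
        },
        groups=["GF"] * 6 + ["SPF"] * 6,
    )
    filtered, excluded = filter_by_detection(table, 0.5)
    assert list(filtered.values.columns) == ["FA 16:0", "FA 18:0"]
    assert list(excluded.index) == ["FA 20:4 n-6"]
    assert excluded.loc["FA 20:4 n-6"].min() == pytest.approx(2 / 6)
    with pytest.raises(ValueError):
        filter_by_detection(table, 1.5)


def test_missingness_fisher_exact_values():
    no_missing = make_table({"FA 16:0": [1.0] * 12},
                            groups=["GF"] * 6 + ["SPF"] * 6)
    assert missingness_bias_test(no_missing, "FA 16:0")[1] == 1.0

    fully_biased = make_table(
        {"FA 16:0": [1.0] * 6 + [np.nan] * 6},
        groups=["GF"] * 6 + ["SPF"] * 6)
    _, p = missingness_bias_test(fully_biased, "FA 16:0")
    assert p == pytest.approx(1 / 462, rel=1e-12)

    balanced = make_table(
        {"FA 16:0": [1, 1, 1, np.nan, np.nan, np.nan] * 2},
        groups=["GF"] * 6 + ["SPF"] * 6)
    assert missingness_bias_test(balanced, "FA 16:0")[1] == 1.0
    with pytest.raises(KeyError):
        missingness_bias_test(balanced, "PC 34:1")


# ---------------------------------------------------------------------------
# Saturation sums


def test_saturation_sums_by_category():
    table = make_table(
        {"FA 16:0": [2.0], "FA 16:1 n-7": [1.0], "FA 20:4 n-6": [3.0]},
        groups=["GF"])
    summary = saturation_class_sums(table)
    row = summary.sums.loc["S1", "FA"]
    assert (row["SA"], row["MU"], row["PU"]) == (2.0, 1.0, 3.0)
    assert summary.n_imputed == 0
    total = summary.totals().loc["S1", "FA"]
    assert total == pytest.approx(6.0)


def test_saturation_sums_invariant_under_column_permutation(rng):
    table = _random_table(rng, n=4, p=8, missing=0.1)
    cols = list(table.values.columns)
    shuffled = make_table(
        {c: table.values[c].tolist() for c in cols[::-1]},
        groups=list(table.sample_meta["group"]))
    a = saturation_class_sums(table).sums
    b = saturation_class_sums(shuffled).sums
    pd.testing.assert_frame_equal(a.sort_index(axis=1), b.sort_index(axis=1))


# ---------------------------------------------------------------------------
# Welch t and BH


def test_welch_identical_groups_gives_p_one():
    t, _, p, _ = welch_t(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
    assert (t, p) == (0.0, 1.0)


def test_welch_hand_computed_example():
    """[1,2,3,4] vs [3,4,5,6]: |t| = 2.191, Welch df = 6, p = 0.0710.

    Hand computation: mean difference 2, per-group variance 5/3, so
    t = 2 / sqrt(2 * 5/12) = 2.1909, the Welch-Satterthwaite df reduces to
    6 exactly for equal groups, and 2 * P(T_6 > 2.1909) = 0.07099.
    """
    t, df, p, _ = welch_t(np.array([1.0, 2, 3, 4]), np.array([3.0, 4, 5, 6]))
    assert abs(t) == pytest.approx(2.1909, abs=1e-4)
    assert df == pytest.approx(6.0, abs=1e-9)
    assert p == pytest.approx(0.07099, abs=1e-4)


def test_welch_degenerate_variance_cases():
    t, _, p, flag = welch_t(np.array([2.0, 2.0]), np.array([2.0, 2.0]))
    assert (t, p, flag) == (0.0, 1.0, False)
    t, _, p, flag = welch_t(np.array([2.0, 2.0]), np.array([3.0, 3.0]))
    assert p == 0.0 and flag


def test_bh_step_up_example_and_monotonicity():
    _, adj, _, _ = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")
    np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])


@given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=30))
@settings(max_examples=60, deadline=None)
def test_bh_adjustment_is_monotone(pvals):
    _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    order = np.argsort(pvals)
    assert np.all(np.diff(np.asarray(adj)[order]) >= -1e-12)


def test_differential_test_effect_convention_and_skips(small_table):
    analysis = differential_test(small_table)
    by_label = {r.species.label: r for r in analysis}
    # SPF concentrations double GF ones -> log2 FC of +1 (higher in SPF)
    assert by_label["FA 16:0"].log2_fc == pytest.approx(1.0, abs=0.15)
    assert by_label["FA 16:1 n-7"].log2_fc > 0
    for r in analysis:
        assert r.fdr_adjusted_p >= r.p_value
        assert 0 < r.p_value <= 1


def test_differential_test_skips_sparse_species():
    table = make_table(
        {"FA 16:0": [1, 2, 3, 4, 5, 6],
         "FA 18:0": [1, np.nan, np.nan, 4, 5, 6]},
        groups=["GF"] * 3 + ["SPF"] * 3)
    analysis = differential_test(table)
    assert len(analysis) == 1
    assert analysis.skipped == [("FA 18:0", "insufficient data (1 vs 3)")]


def test_differential_test_treats_zero_as_missing():
    table = make_table(
        {"FA 16:0": [0.0, 2, 3, 4, 5, 6]},
        groups=["GF"] * 3 + ["SPF"] * 3)
    analysis = differential_test(table)
    assert analysis.results[0].n_per_group == (2, 3)


# ---------------------------------------------------------------------------
# Replication filter


def _result(label, matrix, log2_fc, fdr, experiment):
    from lipidomix import parse_lipid_name

    return DifferentialResult(
        species=parse_lipid_name(label), log2_fc=log2_fc, t_statistic=0.0,
        df=10.0, p_value=min(fdr, 1.0), fdr_adjusted_p=fdr,
        experiment=experiment, matrix=matrix)


def test_replication_filter_semantics():
    exp1 = [
        _result("FA 16:1 n-7", "liver", 1.39, 0.02, "exp1"),
        _result("PC 34:1", "liver", 0.9, 0.03, "exp1"),
        _result("PI 40:6", "liver", -0.92, 0.01, "exp1"),
        _result("CE 20:4", "liver", -0.65, 0.01, "exp1"),
    ]
    exp2 = [
        _result("FA 16:1 n-7", "liver", 0.31, 0.03, "exp2"),   # passes
        _result("PC 34:1", "liver", -0.4, 0.02, "exp2"),       # sign flip
        _result("PI 40:6", "liver", -0.88, 0.30, "exp2"),      # not significant
    ]
    out = replication_filter(exp1, exp2, q=0.05)
    assert out.labels() == ["FA 16:1 n-7"]
    assert out.unmatched == ["CE 20:4 [liver]"]
    assert out.verified[0].direction == 1


def test_replication_output_is_subset_of_each_significant_set():
    cfg = LipidSimConfig(effects={"FA 16:1 n-7": 1.5, "FA 22:6 n-3": -1.0},
                         seed=2)
    t1, t2 = generate_lipid_experiments(cfg)
    a1, a2 = differential_test(t1), differential_test(t2)
    verified = set(replication_filter(a1, a2).labels())
    sig1 = {r.species.label for r in a1 if r.fdr_adjusted_p < 0.05}
    sig2 = {r.species.label for r in a2 if r.fdr_adjusted_p < 0.05}
    assert verified <= sig1 and verified <= sig2


def test_replication_on_bundled_verified_panel():
    """Re-running the direction-consistency rule on the printed two-cohort
    panel reproduces the published verified counts (16 liver, 15 plasma)."""
    frame = verified_species_frame()
    counts = {}
    for matrix in ("liver", "plasma"):
        sub = frame[frame["matrix"] == matrix]
        exp1 = [_result(r.species, matrix, r.log2_fc_exp1, r.p_exp1, "exp1")
                for r in sub.itertuples()]
        exp2 = [_result(r.species, matrix, r.log2_fc_exp2,
                        max(r.p_exp2, 1e-6), "exp2")
                for r in sub.itertuples()]
        counts[matrix] = len(replication_filter(exp1, exp2, q=0.05))
    assert counts == {"liver": 16, "plasma": 15}


# ---------------------------------------------------------------------------
# Indices


def test_desaturation_index_value_and_flags():
    table = make_table(
        {"FA 16:1 n-7": [1.0, np.nan], "FA 16:0": [4.0, 5.0],
         "FA 20:3 n-6": [1.0, 1.0], "FA 18:3 n-6": [0.5, 0.5]},
        groups=["GF", "SPF"])
    ratios = desaturation_elongation_indices(table)
    assert ratios.values.loc["S1", "desaturation_16"] == pytest.approx(0.25)
    assert np.isnan(ratios.values.loc["S2", "desaturation_16"])
    assert not ratios.defined.loc["S2", "desaturation_16"]
    assert ratios.values.loc["S1", "elongation_20_3"] == pytest.approx(2.0)


def test_ratio_invariant_under_global_rescaling():
    base = {"FA 16:1 n-7": [1.0, 2.0], "FA 16:0": [4.0, 8.0],
            "FA 20:3 n-6": [1.0, 1.0], "FA 18:3 n-6": [0.5, 0.25]}
    t1 = make_table(base, groups=["GF", "SPF"])
    t2 = make_table({k: [3 * x for x in v] for k, v in base.items()},
                    groups=["GF", "SPF"])
    pd.testing.assert_frame_equal(
        desaturation_elongation_indices(t1).values,
        desaturation_elongation_indices(t2).values)


def test_indices_reject_unknown_species(small_table):
    with pytest.raises(KeyError, match="unknown species"):
        desaturation_elongation_indices(
            small_table, {"bad": ("FA 16:1 n-7", "FA 18:0")})
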