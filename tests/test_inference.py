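import dataclasses
import warnings

import numpy as np
import pytest

from covnet import (
    MorphometryTable,
    PipelineConfig,
    SyntheticSpec,
    fdr_correct,
    generate_cohort,
    observed_auc_difference,
    permutation_test,
    regional_ttests,
    residualize_pair,
)
from covnet.atlas import synthetic_atlas
from covnet.simulate import GROUP_A, GROUP_B

GLOBALS = (
    "normalized_path_length",
    "global_efficiency",
    "normalized_clustering",
    "local_efficiency",
    "small_worldness",
)


def _relabel(table, prefix):
    return dataclasses.replace(
        table, subjects=tuple(prefix + s for s in table.subjects)
    )


# --------------------------------------------------- observed differences


def test_identical_groups_give_exactly_zero_differences(residualized_pair, fast_config):
    ra, _ = residualized_pair
    clone = _relabel(ra, "x")
    obs = observed_auc_difference(ra, clone, fast_config, seed=3)
    assert np.all(obs["observed_diff"].to_numpy() == 0.0)


def test_swapping_groups_negates_every_difference(residualized_pair, fast_config):
    ra, rb = residualized_pair
    ab = observed_auc_difference(ra, rb, fast_config, seed=3)
    ba = observed_auc_difference(rb, ra, fast_config, seed=3)
    assert np.array_equal(
        ab["observed_diff"].to_numpy(), -ba["observed_diff"].to_numpy()
    )


def test_differences_shrink_with_sample_size_under_the_null(fast_config):
    sizes = {}
    for n in (30, 300):
        spec = SyntheticSpec(
            seed=21, n_group_a=n, n_group_b=n,
            within_loading_a=0.5, within_loading_b=0.5,
        )
        cohort = generate_cohort(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ra, rb = residualize_pair(
                cohort.table(GROUP_A, "BL"),
                cohort.table(GROUP_B, "BL"),
                cohort.covariates["BL"],
            )
        obs = observed_auc_difference(ra, rb, fast_config, seed=4)
        sizes[n] = np.abs(obs["observed_diff"].to_numpy()).sum()
    assert sizes[300] < sizes[30]


# -------------------------------------------------------- permutation test


def test_permutation_test_is_seed_deterministic(residualized_pair, fast_config):
    ra, rb = residualized_pair
    a = permutation_test(ra, rb, n_perm=100, seed=5, config=fast_config)
    b = permutation_test(ra, rb, n_perm=100, seed=5, config=fast_config)
    for name in GLOBALS:
        assert np.array_equal(
            a.result(name).null_diffs, b.result(name).null_diffs
        )
        assert a.result(name).p == b.result(name).p
    c = permutation_test(ra, rb, n_perm=100, seed=6, config=fast_config)
    assert any(
        not np.array_equal(a.result(n).null_diffs, c.result(n).null_diffs)
        for n in GLOBALS
    )


def test_label_swap_preserves_p_and_negates_observed(residualized_pair, fast_config):
    ra, rb = residualized_pair
    ab = permutation_test(ra, rb, n_perm=100, seed=5, config=fast_config)
    ba = permutation_test(rb, ra, n_perm=100, seed=5, config=fast_config)
    for name in GLOBALS:
        assert ba.result(name).observed_diff == -ab.result(name).observed_diff
        assert ba.result(name).p == ab.result(name).p
        assert np.array_equal(
            ba.result(name).null_diffs, -ab.result(name).null_diffs
        )


def test_duplicated_cohort_gives_p_one(residualized_pair, fast_config):
    ra, _ = residualized_pair
    clone = _relabel(ra, "x")
    ptr = permutation_test(ra, clone, n_perm=100, seed=2, config=fast_config)
    for name in GLOBALS:
        assert ptr.result(name).observed_diff == 0.0
        assert ptr.result(name).p == 1.0


def test_strong_effect_hits_the_add_one_p_floor(fast_config):
    spec = SyntheticSpec(
        seed=30, within_loading_a=0.9, within_loading_b=0.0, n_modules=2
    )
    cohort = generate_cohort(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ra, rb = residualize_pair(
            cohort.table(GROUP_A, "BL"),
            cohort.table(GROUP_B, "BL"),
            cohort.covariates["BL"],
        )
    ptr = permutation_test(ra, rb, n_perm=100, seed=8, config=fast_config)
    r = ptr.result("local_efficiency")
    assert r.p == pytest.approx(1.0 / 101.0)
    assert np.all(np.abs(r.null_diffs) < abs(r.observed_diff))


def test_permutation_test_input_validation(residualized_pair, fast_config):
    ra, rb = residualized_pair
    with pytest.raises(ValueError, match="n_perm"):
        permutation_test(ra, rb, n_perm=50, config=fast_config)
    with pytest.raises(ValueError, match="duplicate subject"):
        permutation_test(ra, ra, n_perm=100, config=fast_config)


def test_nodal_results_present_with_expected_family_sizes(residualized_pair):
    ra, rb = residualized_pair
    cfg = PipelineConfig(n_null=1, swaps_per_edge=3, include_nodal=True)
    ptr = permutation_test(ra, rb, n_perm=100, seed=1, config=cfg)
    frame = ptr.to_frame()
    assert len(frame) == 5 + 3 * 68
    for name in ("degree", "nodal_efficiency", "betweenness"):
        assert (frame["metric"] == name).sum() == 68
    assert ptr.result("degree", "lh.entorhinal").n_perm == 100


# ------------------------------------------------------------------- FDR


def test_bh_is_fixed_point_on_equal_pvalues():
    p = np.full(7, 0.03)
    assert np.allclose(fdr_correct(p), p)


def test_bh_hand_executed_step_up():
    q = fdr_correct([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])


def test_bh_single_p_and_empty_family():
    assert fdr_correct([0.2])[0] == pytest.approx(0.2)
    with pytest.raises(ValueError, match="empty"):
        fdr_correct([])


# ---------------------------------------------------------------- t-tests


def _pair_of_tables(shift=0.0, n_regions=6, seed=0):
    rng = np.random.default_rng(seed)
    atlas = synthetic_atlas(n_regions)
    a = rng.normal(2.5, 0.1, (20, n_regions))
    b = rng.normal(2.5, 0.1, (22, n_regions))
    b[:, 0] += shift
    ta = MorphometryTable(
        values=a, subjects=tuple(f"a{i}" for i in range(20)), atlas=atlas
    )
    tb = MorphometryTable(
        values=b, subjects=tuple(f"b{i}" for i in range(22)), atlas=atlas
    )
    return ta, tb


def test_identical_groups_have_t_zero_p_one():
    ta, _ = _pair_of_tables()
    tb = dataclasses.replace(
        ta, subjects=tuple("x" + s for s in ta.subjects)
    )
    frame = regional_ttests(ta, tb)
    assert np.allclose(frame["t"], 0.0)
    assert np.allclose(frame["p"], 1.0)
    assert (frame["df"] == 38).all()


def test_ten_sd_shift_is_detected_after_fdr():
    ta, tb = _pair_of_tables(shift=1.0)  # 10 pooled SDs
    frame = regional_ttests(ta, tb)
    assert frame.loc[0, "q"] < 1e-3
    assert frame.loc[0, "significant"]
    assert (frame["df"] == 40).all()


def test_t_statistic_matches_pooled_variance_formula():
    x = np.array([4.0, 5.0, 6.0, 7.0])
    y = np.array([5.0, 6.0, 9.0])
    atlas = synthetic_atlas(3)
    ta = MorphometryTable(
        values=np.tile(x[:, None], (1, 3)) + np.arange(3) * 0.0 + np.random.default_rng(1).normal(0, 1e-6, (4, 3)),
        subjects=("a1", "a2", "a3", "a4"),
        atlas=atlas,
    )
    # hand computation on region 0 with the exact x/y values
    ta = dataclasses.replace(ta, values=np.column_stack([x, x + 1, x * 2]))
    tb = MorphometryTable(
        values=np.column_stack([y, y + 1, y * 2]),
        subjects=("b1", "b2", "b3"),
        atlas=atlas,
    )
    frame = regional_ttests(ta, tb)
    sp2 = (3 * x.var(ddof=1) + 2 * y.var(ddof=1)) / 5
    expected = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / 4 + 1 / 3))
    assert frame.loc[0, "t"] == pytest.approx(expected, abs=1e-12)


def test_zero_pooled_variance_region_is_named():
    atlas = synthetic_atlas(2)
    const = np.full(4, 2.0)
    varying = np.array([1.0, 2.0, 3.0, 4.0])
    ta = MorphometryTable(
        values=np.column_stack([const, varying]),
        subjects=("a1", "a2", "a3", "a4"),
        atlas=atlas,
    )
    tb = MorphometryTable(
        values=np.column_stack([const, varying + 1]),
        subjects=("b1", "b2", "b3", "b4"),
        atlas=atlas,
    )
    with pytest.raises(ValueError, match=atlas.region_ids[0]):
        regional_ttests(ta, tb)
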