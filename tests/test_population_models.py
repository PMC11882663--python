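import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bsemfit.population_models import (
    BLOCK_PATTERN,
    CfaModelSpec,
    MisspecificationPlan,
    as_analysis_model,
    build_generation_model,
    count_free_parameters,
    default_merge_map,
    implied_covariance,
    misspecify,
    study_misspecification_plans,
)

ALL_GENERATION_SPECS = [
    build_generation_model("A", 0.85),
    build_generation_model("A", 0.35),
    build_generation_model("B", cross_loading_value=0.5),
    build_generation_model("B", cross_loading_value=0.2),
    build_generation_model("C1", 0.85),
    build_generation_model("C2", 0.85),
    build_generation_model("C3", 0.35),
    build_generation_model("D1", cross_loading_value=0.5),
    build_generation_model("D2", cross_loading_value=0.5),
    build_generation_model("D3", cross_loading_value=0.5),
]


class TestBuildGenerationModel:
    def test_model_a_loading_pattern(self):
        spec = build_generation_model("A", 0.85)
        assert spec.loadings.shape == (15, 3)
        for f in range(3):
            block = spec.loadings[5 * f:5 * (f + 1), f]
            np.testing.assert_allclose(block, BLOCK_PATTERN)
        assert np.count_nonzero(spec.loadings) == 15
        off = spec.factor_corr[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 0.85)

    def test_model_b_cross_loading_placement(self):
        spec = build_generation_model("B", cross_loading_value=0.5)
        # items 5, 9, 15 (1-based) load on the next factor cyclically
        assert spec.loadings[4, 1] == 0.5
        assert spec.loadings[8, 2] == 0.5
        assert spec.loadings[14, 0] == 0.5
        assert np.count_nonzero(spec.loadings) == 18
        np.testing.assert_allclose(spec.factor_corr[0, 1], 0.5)

    def test_model_d2_shape(self):
        spec = build_generation_model("D2", 0.85, 0.5)
        assert (spec.n_factors, spec.n_items) == (6, 30)
        assert len(spec.cross_loading_positions) == 6
        # one cross-loading per factor, each landing on a different factor
        assert sorted(f for _, f in spec.cross_loading_positions) == list(range(6))

    def test_ten_item_factors_repeat_block(self):
        spec = build_generation_model("C1", 0.85)
        np.testing.assert_allclose(spec.loadings[:10, 0], BLOCK_PATTERN * 2)

    def test_residual_variances_complement_loadings(self):
        spec = build_generation_model("B", cross_loading_value=0.5)
        # non-cross item: 1 - 0.7^2
        assert spec.residual_variances[0] == pytest.approx(0.51)
        # cross item 5: 1 - 0.8^2 - 0.5^2
        assert spec.residual_variances[4] == pytest.approx(0.11)

    @pytest.mark.parametrize("family,corr,cld,err", [
        ("Z", 0.5, None, "unknown model family"),
        ("A", 1.5, None, "factor_corr_value"),
        ("A", None, None, "required"),
        ("B", 0.5, -0.1, "nonnegative"),
    ])
    def test_invalid_arguments(self, family, corr, cld, err):
        with pytest.raises(ValueError, match=err):
            build_generation_model(family, corr, cld)


class TestImpliedCovariance:
    def test_model_a_is_correlation_matrix(self, model_a85):
        sigma = implied_covariance(model_a85)
        np.testing.assert_allclose(np.diag(sigma), 1.0, atol=1e-12)
        np.testing.assert_allclose(sigma, sigma.T, atol=1e-14)

    def test_same_factor_covariance(self, model_a85):
        sigma = implied_covariance(model_a85)
        assert sigma[0, 1] == pytest.approx(0.7 * 0.7)

    def test_between_factor_covariance(self, model_a85):
        sigma = implied_covariance(model_a85)
        assert sigma[0, 5] == pytest.approx(0.7 * 0.7 * 0.85)

    @pytest.mark.parametrize("spec", ALL_GENERATION_SPECS, ids=lambda s: s.name)
    def test_positive_definite_across_study_grid(self, spec):
        sigma = implied_covariance(spec)
        assert np.linalg.eigvalsh(sigma).min() > 0


class TestMisspecify:
    def test_one_factor_collapse(self, model_a85):
        plan = MisspecificationPlan("dimensionality", target_factors=1,
                                    merge_map=default_merge_map(3, 1))
        am = misspecify(model_a85, plan)
        assert am.n_factors == 1
        assert am.free_mask.all()

    def test_two_factor_merge_items(self, model_a85):
        plan = MisspecificationPlan("dimensionality", target_factors=2,
                                    merge_map={0: 0, 1: 1, 2: 1})
        am = misspecify(model_a85, plan)
        assert am.free_mask[:5, 0].all() and not am.free_mask[:5, 1].any()
        assert am.free_mask[5:, 1].all() and not am.free_mask[5:, 0].any()

    def test_drop_all_cross_loadings(self, model_b05):
        plan = MisspecificationPlan("cross_loading", retained_cross_loadings=0)
        am = misspecify(model_b05, plan)
        assert int(am.free_mask.sum()) == 15          # independent-cluster pattern
        assert am.cross_loading_positions == []

    def test_retained_count_bounds(self, model_b05):
        plan = MisspecificationPlan("cross_loading", retained_cross_loadings=4)
        with pytest.raises(ValueError, match="retained count"):
            misspecify(model_b05, plan)

    def test_merge_map_must_cover_factors(self, model_a85):
        plan = MisspecificationPlan("dimensionality", target_factors=2,
                                    merge_map={0: 0, 1: 1})
        with pytest.raises(ValueError, match="missing"):
            misspecify(model_a85, plan)

    def test_item_assignment_split(self):
        spec = build_generation_model("C1", 0.85)
        plan = study_misspecification_plans("C1")["moderate"]
        am = misspecify(spec, plan)
        assert am.n_factors == 2
        assert am.free_mask[:15, 0].all() and am.free_mask[15:, 1].all()

    def test_unknown_kind(self):
        with pytest.raises(ValueError, match="unknown misspecification"):
            MisspecificationPlan("typo")


def test_count_free_parameters_a1(model_a85):
    # 15 loadings + 3 correlations + 15 residual variances
    assert count_free_parameters(as_analysis_model(model_a85)) == 33


def test_yaml_round_trip(model_b05, tmp_path):
    path = tmp_path / "model.yaml"
    model_b05.to_yaml(path)
    back = CfaModelSpec.from_yaml(path)
    np.testing.assert_array_equal(back.loadings, model_b05.loadings)
    np.testing.assert_array_equal(back.free_mask, model_b05.free_mask)
    np.testing.assert_array_equal(back.residual_variances, model_b05.residual_variances)
    assert back.cross_loading_positions == model_b05.cross_loading_positions


@settings(deadline=None, max_examples=25)
@given(corr=st.floats(0.05, 0.95), cld=st.floats(0.0, 0.55))
def test_generation_models_always_positive_definite(corr, cld):
    """Any admissible correlation/cross-loading combination yields a
    proper covariance model."""
    for family in ("A", "B", "D2"):
        spec = build_generation_model(family, corr, cld if family != "A" else None)
        sigma = implied_covariance(spec)
        assert np.linalg.eigvalsh(sigma).min() > 0
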