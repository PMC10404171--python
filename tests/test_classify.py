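"""Prediction-rule semantics: branches, boundaries, built-in models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from protreact import (
    DPRA_MEAN,
    PROTREACT_COMBINED,
    PROTREACT_CYS,
    PROTREACT_MEAN,
    DepletionProfile,
    DepletionRuleClassifier,
    HazardLabel,
    PredictionModelConfig,
    predict,
    predict_all,
)
from protreact.exceptions import ConfigurationError

pct = st.floats(0, 100, allow_nan=False)


def profile(cys=None, mean=None):
    return DepletionProfile(cys_pct=cys, lys_pct=None, mean_pct=mean)


class TestPredict:
    def test_dncb_is_sensitizer(self, by_index):
        p = predict(by_index[1].protreact, PROTREACT_CYS)
        assert p.predicted is HazardLabel.SENSITIZER
        assert p.triggering_rule == "cys"

    def test_formaldehyde_is_false_negative(self, by_index):
        # ProtReact Cys 13.7 just misses the 13.935 cut-off (human category 2)
        r = by_index[11]
        assert r.name == "Formaldehyde"
        p = predict(r.protreact, PROTREACT_CYS)
        assert p.predicted is HazardLabel.NON_SENSITIZER
        assert r.hazard is HazardLabel.SENSITIZER

    def test_phenol_is_dpra_false_positive(self, by_index):
        # DPRA mean 7.7 > 6.38 although phenol is a human non-sensitizer
        r = by_index[104]
        assert r.name == "Phenol"
        p = predict(r.dpra, DPRA_MEAN)
        assert p.predicted is HazardLabel.SENSITIZER
        assert r.hazard is HazardLabel.NON_SENSITIZER

    @pytest.mark.parametrize(
        "comparison,expected",
        [("inclusive", HazardLabel.SENSITIZER), ("strict", HazardLabel.NON_SENSITIZER)],
    )
    def test_boundary_semantics_at_exact_threshold(self, comparison, expected):
        config = PredictionModelConfig(
            "boundary", "cys_only", cys_threshold=13.935, comparison=comparison
        )
        assert predict(profile(cys=13.935), config).predicted is expected

    def test_negative_printed_value_compares_as_is(self, by_index):
        # Chlorpromazine's signed DPRA mean (-9.8) is below any positive cut-off
        assert predict(by_index[31].dpra, DPRA_MEAN).predicted is HazardLabel.NON_SENSITIZER

    def test_missing_required_value_is_config_error(self):
        with pytest.raises(ConfigurationError):
            predict(profile(cys=50.0, mean=None), PROTREACT_MEAN)

    def test_builtin_comparisons_follow_table(self):
        assert PROTREACT_CYS.comparison == "inclusive"
        assert PROTREACT_MEAN.comparison == "inclusive"
        assert DPRA_MEAN.comparison == "strict"


class TestConfigValidation:
    def test_unknown_branch(self):
        with pytest.raises(ConfigurationError):
            PredictionModelConfig("x", "both", cys_threshold=10)

    def test_threshold_out_of_range(self):
        with pytest.raises(ConfigurationError):
            PredictionModelConfig("x", "cys_only", cys_threshold=120)

    def test_branch_requires_its_threshold(self):
        with pytest.raises(ConfigurationError):
            PredictionModelConfig("x", "combined_or", cys_threshold=10, mean_threshold=None)


class TestPredictAll:
    def test_protreact_cys_predicts_54_sensitizers(self, records):
        preds = predict_all(records, "protreact", PROTREACT_CYS)
        assert sum(p.predicted is HazardLabel.SENSITIZER for p in preds) == 54  # 49 TP + 5 FP

    def test_dpra_mean_predicts_61_sensitizers(self, records):
        preds = predict_all(records, "dpra", DPRA_MEAN)
        assert sum(p.predicted is HazardLabel.SENSITIZER for p in preds) == 61  # 52 TP + 9 FP

    def test_empty_input_empty_output(self):
        assert predict_all([], "protreact", PROTREACT_CYS) == []

    def test_order_preserving(self, records):
        preds = predict_all(records, "dpra", DPRA_MEAN)
        assert [p.index for p in preds] == [r.index for r in records]

    def test_combined_or_is_elementwise_or(self, records):
        cys = predict_all(records, "protreact", PROTREACT_CYS)
        mean = predict_all(records, "protreact", PROTREACT_MEAN)
        both = predict_all(records, "protreact", PROTREACT_COMBINED)
        for pc, pm, pb in zip(cys, mean, both):
            expected = (
                pc.predicted is HazardLabel.SENSITIZER
                or pm.predicted is HazardLabel.SENSITIZER
            )
            assert (pb.predicted is HazardLabel.SENSITIZER) == expected


@settings(deadline=None, max_examples=150)
@given(cys=pct, mean=pct, bump=st.floats(0, 50, allow_nan=False),
       branch=st.sampled_from(["cys_only", "mean_only", "combined_or"]),
       comparison=st.sampled_from(["inclusive", "strict"]),
       t_cys=pct, t_mean=pct)
def test_property_monotone_in_depletion(cys, mean, bump, branch, comparison, t_cys, t_mean):
    """Raising any depletion value never flips sensitizer -> non-sensitizer."""
    config = PredictionModelConfig(
        "m", branch, cys_threshold=t_cys, mean_threshold=t_mean, comparison=comparison
    )
    before = predict(profile(cys=cys, mean=mean), config).predicted
    after = predict(
        profile(cys=min(cys + bump, 100.0), mean=min(mean + bump, 100.0)), config
    ).predicted
    if before is HazardLabel.SENSITIZER:
        assert after is HazardLabel.SENSITIZER


class TestSklearnEstimator:
    def test_fit_predict_dataframe(self, records):
        import pandas as pd

        X = pd.DataFrame(
            {
                "cys": [r.protreact.cys_pct for r in records],
                "mean": [r.protreact.mean_pct for r in records],
            }
        )
        est = DepletionRuleClassifier(branch="cys_only", cys_threshold=13.935).fit(X)
        preds = est.predict(X)
        assert (preds == "sensitizer").sum() == 54

    def test_array_input_and_boundary(self):
        est = DepletionRuleClassifier(
            branch="mean_only", cys_threshold=None, mean_threshold=6.38, comparison="strict"
        ).fit(np.array([[0.0, 6.38]]))
        assert est.predict(np.array([[0.0, 6.38]]))[0] == "non_sensitizer"
        assert est.predict(np.array([[0.0, 6.381]]))[0] == "sensitizer"

    def test_clone_preserves_params(self):
        est = DepletionRuleClassifier(branch="combined_or", cys_threshold=10, mean_threshold=5)
        assert clone(est).get_params()["mean_threshold"] == 5

    def test_predict_before_fit_raises(self):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            DepletionRuleClassifier().predict([[1.0, 1.0]])
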