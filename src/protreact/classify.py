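"""Hazard prediction rules applied to depletion profiles.

A prediction model is a small rule over one chemical's depletion profile:

* ``cys_only``     — sensitizer iff Cys depletion passes its threshold,
* ``mean_only``    — sensitizer iff the Cys/Lys mean passes its threshold,
* ``combined_or``  — sensitizer iff either rule fires.

Comparisons are either inclusive (``>=``) or strict (``>``); the ProtReact
models use inclusive comparisons (Cys >= 13.935%, mean >= 9.563%) while the
reference DPRA models use strict ones (mean > 6.38%, or Cys > 13.89% when
co-elution with the lysine peptide forces the cysteine-only rule — the
co-elution event itself is an HPLC phenomenon decided by the caller, not
modeled here).  Values are compared as given; externally published depletion
tables may contain signed values, which any positive threshold naturally
classifies as non-sensitizer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .dataset import ChemicalRecord, HazardLabel
from .depletion import DepletionProfile
from .exceptions import ConfigurationError

__all__ = [
    "PredictionModelConfig",
    "Prediction",
    "predict",
    "predict_all",
    "DepletionRuleClassifier",
    "PROTREACT_CYS",
    "PROTREACT_MEAN",
    "PROTREACT_COMBINED",
    "DPRA_MEAN",
    "DPRA_CYS",
    "BUILTIN_MODELS",
]

BRANCHES = ("cys_only", "mean_only", "combined_or")
COMPARISONS = ("inclusive", "strict")


@dataclass(frozen=True)
class PredictionModelConfig:
    """One classification rule: branch, threshold(s), comparison strictness."""

    name: str
    branch: str
    cys_threshold: float | None = None
    mean_threshold: float | None = None
    comparison: str = "inclusive"

    def __post_init__(self) -> None:
        if self.branch not in BRANCHES:
            raise ConfigurationError(f"branch must be one of {BRANCHES}, got {self.branch!r}")
        if self.comparison not in COMPARISONS:
            raise ConfigurationError(
                f"comparison must be one of {COMPARISONS}, got {self.comparison!r}"
            )
        needs_cys = self.branch in ("cys_only", "combined_or")
        needs_mean = self.branch in ("mean_only", "combined_or")
        for needed, value, label in (
            (needs_cys, self.cys_threshold, "cys_threshold"),
            (needs_mean, self.mean_threshold, "mean_threshold"),
        ):
            if needed:
                if value is None:
                    raise ConfigurationError(f"{self.name}: branch {self.branch} needs {label}")
                if not (0.0 <= float(value) <= 100.0):
                    raise ConfigurationError(f"{self.name}: {label}={value} outside [0, 100]")

    def _passes(self, value: float, threshold: float) -> bool:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise ConfigurationError(
                f"{self.name}: depletion value required by branch {self.branch} is missing"
            )
        return value >= threshold if self.comparison == "inclusive" else value > threshold

    def with_thresholds(self, cys=None, mean=None) -> "PredictionModelConfig":
        """A copy with replaced threshold(s) (e.g. a freshly derived cut-off)."""
        out = self
        if cys is not None:
            out = replace(out, cys_threshold=float(cys))
        if mean is not None:
            out = replace(out, mean_threshold=float(mean))
        return out


# Built-in models: the published prediction rules for both assays.
PROTREACT_CYS = PredictionModelConfig("protreact_cys", "cys_only", cys_threshold=13.935)
PROTREACT_MEAN = PredictionModelConfig("protreact_mean", "mean_only", mean_threshold=9.563)
PROTREACT_COMBINED = PredictionModelConfig(
    "protreact_combined", "combined_or", cys_threshold=13.935, mean_threshold=9.563
)
DPRA_MEAN = PredictionModelConfig(
    "dpra_mean", "mean_only", mean_threshold=6.38, comparison="strict"
)
DPRA_CYS = PredictionModelConfig("dpra_cys", "cys_only", cys_threshold=13.89, comparison="strict")

BUILTIN_MODELS = {
    m.name: m for m in (PROTREACT_CYS, PROTREACT_MEAN, PROTREACT_COMBINED, DPRA_MEAN, DPRA_CYS)
}


@dataclass(frozen=True)
class Prediction:
    """Outcome of one rule application to one chemical."""

    index: int
    predicted: HazardLabel
    triggering_rule: str | None     # "cys", "mean" or None when no rule fired
    inputs_used: dict


def predict(
    profile: DepletionProfile, config: PredictionModelConfig, index: int = 0
) -> Prediction:
    """Apply one prediction model to one depletion profile."""
    fired = None
    inputs: dict = {}
    if config.branch in ("cys_only", "combined_or"):
        inputs["cys_pct"] = profile.cys_pct
        if config._passes(profile.cys_pct, config.cys_threshold):
            fired = "cys"
    if config.branch in ("mean_only", "combined_or") and fired is None:
        inputs["mean_pct"] = profile.mean_pct
        if config._passes(profile.mean_pct, config.mean_threshold):
            fired = "mean"
    elif config.branch == "combined_or":
        inputs["mean_pct"] = profile.mean_pct
    label = HazardLabel.SENSITIZER if fired else HazardLabel.NON_SENSITIZER
    return Prediction(index=index, predicted=label, triggering_rule=fired, inputs_used=inputs)


def predict_all(
    records: Sequence[ChemicalRecord], assay: str, config: PredictionModelConfig
) -> list[Prediction]:
    """Apply one model to every record's profile for the given assay."""
    return [predict(r.profile(assay), config, index=r.index) for r in records]


class DepletionRuleClassifier(ClassifierMixin, BaseEstimator):
    """Fixed-threshold rule model over (Cys%, mean%) depletion features.

    ``X`` has two columns, Cys depletion and mean Cys/Lys depletion (a
    DataFrame with ``cys``/``mean``-named columns, or any 2-column array); a
    single column is accepted for the single-branch rules.  ``fit`` only
    validates and records the input layout — the thresholds are parameters,
    not learned — so the estimator composes with sklearn model selection
    (e.g. grid search over thresholds).

    Parameters mirror :class:`PredictionModelConfig`.
    """

    def __init__(
        self,
        branch: str = "cys_only",
        cys_threshold: float | None = 13.935,
        mean_threshold: float | None = None,
        comparison: str = "inclusive",
    ):
        self.branch = branch
        self.cys_threshold = cys_threshold
        self.mean_threshold = mean_threshold
        self.comparison = comparison

    def _config(self) -> PredictionModelConfig:
        return PredictionModelConfig(
            name="estimator",
            branch=self.branch,
            cys_threshold=self.cys_threshold,
            mean_threshold=self.mean_threshold,
            comparison=self.comparison,
        )

    def _columns(self, X) -> tuple[np.ndarray, np.ndarray]:
        if isinstance(X, pd.DataFrame):
            cols = {c.lower(): c for c in X.columns}
            cys_col = next((cols[c] for c in cols if "cys" in c), None)
            mean_col = next((cols[c] for c in cols if "mean" in c), None)
            cys = X[cys_col].to_numpy(float) if cys_col else np.full(len(X), np.nan)
            mean = X[mean_col].to_numpy(float) if mean_col else np.full(len(X), np.nan)
            return cys, mean
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.shape[1] == 1:
            only = arr[:, 0]
            if self.branch == "mean_only":
                return np.full(len(only), np.nan), only
            return only, np.full(len(only), np.nan)
        return arr[:, 0], arr[:, 1]

    def fit(self, X, y=None):
        self._config()  # validates parameters
        cys, _ = self._columns(X)
        self.classes_ = np.array(
            [HazardLabel.NON_SENSITIZER.value, HazardLabel.SENSITIZER.value]
        )
        self.n_features_in_ = 1 if np.asarray(X).ndim == 1 else np.asarray(X).shape[1]
        self.is_fitted_ = True
        return self

    def predict(self, X):
        check_is_fitted(self, "is_fitted_")
        config = self._config()
        cys, mean = self._columns(X)
        out = np.empty(len(cys), dtype=object)
        for i in range(len(cys)):
            profile = DepletionProfile(cys_pct=cys[i], lys_pct=None, mean_pct=mean[i])
            out[i] = predict(profile, config, index=i).predicted.value
        return out


def predictions_to_frame(
    records: Sequence[ChemicalRecord], assay: str, predictions: Iterable[Prediction]
) -> pd.DataFrame:
    """Tabulate predictions next to identity and truth, for CSV export."""
    by_index = {r.index: r for r in records}
    rows = []
    for p in predictions:
        r = by_index[p.index]
        rows.append(
            {
                "index": r.index,
                "name": r.name,
                "assay": assay,
                "predicted": p.predicted.value,
                "truth": r.hazard.value,
                "triggering_rule": p.triggering_rule or "",
            }
        )
    return pd.DataFrame(rows)
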