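"""Confusion matrices and hazard-prediction performance metrics.

Metrics follow the standard definitions: accuracy = (TP+TN)/n, sensitivity =
TP/(TP+FN), specificity = TN/(TN+FP), balanced accuracy = (sensitivity +
specificity)/2.  Reported percentages round half-up to whole percents
(74.53 -> 75, 73.58 -> 74, 77.36 -> 77); banker's rounding would shift the
exact .5 cases that occur with small-integer confusion counts.  A metric
whose denominator is empty (single-class truth) is reported as None, never
silently as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

from .classify import Prediction, PredictionModelConfig, predict_all
from .dataset import ChemicalRecord, HazardLabel

__all__ = ["ConfusionSummary", "confusion", "evaluate_model", "round_half_up", "table3_grid"]


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round with ties away from the floor (0.5 -> 1), not banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionSummary:
    """Binary confusion counts with derived proportions.

    Proportions are ``None`` when undefined (absent truth class).
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_correct(self) -> int:
        return self.tp + self.tn

    @property
    def accuracy(self) -> float | None:
        return self.n_correct / self.n if self.n else None

    @property
    def sensitivity(self) -> float | None:
        pos = self.tp + self.fn
        return self.tp / pos if pos else None

    @property
    def specificity(self) -> float | None:
        neg = self.tn + self.fp
        return self.tn / neg if neg else None

    @property
    def balanced_accuracy(self) -> float | None:
        if self.sensitivity is None or self.specificity is None:
            return None
        return (self.sensitivity + self.specificity) / 2.0

    @property
    def rounded_pct(self) -> dict[str, int | None]:
        """The four metrics as half-up-rounded integer percents."""
        out: dict[str, int | None] = {}
        for key in ("accuracy", "balanced_accuracy", "sensitivity", "specificity"):
            v = getattr(self, key)
            out[key] = None if v is None else int(round_half_up(v * 100.0))
        return out


def confusion(
    predictions: Sequence[Prediction | HazardLabel], truths: Sequence[HazardLabel]
) -> ConfusionSummary:
    """Tally a confusion matrix from predictions against truth labels."""
    if len(predictions) != len(truths):
        raise ValueError(f"length mismatch: {len(predictions)} predictions vs {len(truths)} truths")
    tp = fp = fn = tn = 0
    for p, t in zip(predictions, truths):
        label = p.predicted if isinstance(p, Prediction) else p
        pos = label is HazardLabel.SENSITIZER or label == "sensitizer"
        truth_pos = t is HazardLabel.SENSITIZER or t == "sensitizer"
        if pos and truth_pos:
            tp += 1
        elif pos:
            fp += 1
        elif truth_pos:
            fn += 1
        else:
            tn += 1
    return ConfusionSummary(tp=tp, fp=fp, fn=fn, tn=tn)


def evaluate_model(
    records: Sequence[ChemicalRecord], assay: str, config: PredictionModelConfig
) -> ConfusionSummary:
    """predict_all + human-category binarization + confusion, in one step."""
    predictions = predict_all(records, assay, config)
    truths = [r.hazard for r in records]
    return confusion(predictions, truths)


def table3_grid(records: Sequence[ChemicalRecord]) -> dict[str, dict[str, int | None]]:
    """The four-model performance grid (rounded integer percents).

    Columns: ProtReact Cys-only and mean-only rules, DPRA Cys-only and
    mean-only rules, each evaluated on its own assay's depletion columns.
    """
    from .classify import DPRA_CYS, DPRA_MEAN, PROTREACT_CYS, PROTREACT_MEAN

    grid = {}
    for assay, config in (
        ("protreact", PROTREACT_CYS),
        ("protreact", PROTREACT_MEAN),
        ("dpra", DPRA_CYS),
        ("dpra", DPRA_MEAN),
    ):
        grid[config.name] = evaluate_model(records, assay, config).rounded_pct
    return grid
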