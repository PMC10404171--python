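"""Two-model concordance: shared and unique misclassifications, per-domain hits.

Compares the hazard calls of two (assay, rule) pairs against human truth on
the same chemicals: how many each classifies correctly, how many both do,
and which false positives/negatives are shared versus model-specific.  With
mechanistic-domain annotations attached, correct classifications are also
tallied per protein-binding domain (Michael acceptor, Schiff base, SN2, SNAr,
acyl transfer, or no structural alert).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .classify import Prediction, PredictionModelConfig, predict_all
from .dataset import ChemicalRecord, DomainAnnotation, HazardLabel

__all__ = ["ModelSpec", "ConcordanceReport", "compare_models", "domain_tally"]

ModelSpec = tuple[str, PredictionModelConfig]  # (assay, rule config)


@dataclass(frozen=True)
class ConcordanceReport:
    """Concordance of two models against truth on one chemical set.

    The fp/fn fields are sets of chemical indices; ``names`` maps index ->
    chemical name for readable rosters.  Invariants: ``fp_common = fp_a &
    fp_b``, ``fn_common = fn_a & fn_b``, ``correct_a = n - |fp_a| - |fn_a|``.
    """

    n: int
    model_a: str
    model_b: str
    correct_a: int
    correct_b: int
    correct_both: int
    fp_a: frozenset[int]
    fp_b: frozenset[int]
    fn_a: frozenset[int]
    fn_b: frozenset[int]
    names: Mapping[int, str]
    domain_breakdown: Mapping[str, tuple[int, int, int]] | None = None

    @property
    def fp_common(self) -> frozenset[int]:
        return self.fp_a & self.fp_b

    @property
    def fn_common(self) -> frozenset[int]:
        return self.fn_a & self.fn_b

    def roster(self, indices: frozenset[int]) -> list[str]:
        """Chemical names for an index set, sorted by dataset index."""
        return [self.names[i] for i in sorted(indices)]

    def to_dict(self) -> dict:
        """JSON-serializable summary (schema version 1)."""
        out = {
            "schema_version": 1,
            "n": self.n,
            "models": {"a": self.model_a, "b": self.model_b},
            "correct": {"a": self.correct_a, "b": self.correct_b, "both": self.correct_both},
            "false_positives": {
                "a": self.roster(self.fp_a),
                "b": self.roster(self.fp_b),
                "common": self.roster(self.fp_common),
            },
            "false_negatives": {
                "a": self.roster(self.fn_a),
                "b": self.roster(self.fn_b),
                "common": self.roster(self.fn_common),
            },
        }
        if self.domain_breakdown is not None:
            out["domain_breakdown"] = {
                d: {"correct_a": a, "correct_b": b, "total": t}
                for d, (a, b, t) in sorted(self.domain_breakdown.items())
            }
        return out


def _misclassified(
    records: Sequence[ChemicalRecord], predictions: Sequence[Prediction]
) -> tuple[frozenset[int], frozenset[int]]:
    fp, fn = set(), set()
    for r, p in zip(records, predictions):
        truth_pos = r.hazard is HazardLabel.SENSITIZER
        pred_pos = p.predicted is HazardLabel.SENSITIZER
        if pred_pos and not truth_pos:
            fp.add(r.index)
        elif truth_pos and not pred_pos:
            fn.add(r.index)
    return frozenset(fp), frozenset(fn)


def compare_models(
    records: Sequence[ChemicalRecord],
    model_a: ModelSpec,
    model_b: ModelSpec,
    domains: Mapping[int, DomainAnnotation] | None = None,
) -> ConcordanceReport:
    """Full two-model concordance report; domains are optional."""
    assay_a, config_a = model_a
    assay_b, config_b = model_b
    pred_a = predict_all(records, assay_a, config_a)
    pred_b = predict_all(records, assay_b, config_b)
    fp_a, fn_a = _misclassified(records, pred_a)
    fp_b, fn_b = _misclassified(records, pred_b)
    n = len(records)
    wrong_a = fp_a | fn_a
    wrong_b = fp_b | fn_b
    breakdown = None
    if domains is not None:
        breakdown = domain_tally(records, pred_a, pred_b, domains)
    return ConcordanceReport(
        n=n,
        model_a=f"{assay_a}:{config_a.name}",
        model_b=f"{assay_b}:{config_b.name}",
        correct_a=n - len(wrong_a),
        correct_b=n - len(wrong_b),
        correct_both=n - len(wrong_a | wrong_b),
        fp_a=fp_a,
        fp_b=fp_b,
        fn_a=fn_a,
        fn_b=fn_b,
        names={r.index: r.name for r in records},
        domain_breakdown=breakdown,
    )


def domain_tally(
    records: Sequence[ChemicalRecord],
    predictions_a: Sequence[Prediction],
    predictions_b: Sequence[Prediction],
    domains: Mapping[int, DomainAnnotation] | None = None,
) -> dict[str, tuple[int, int, int]]:
    """Per-domain (correct_a, correct_b, total) counts.

    Every record needs a domain annotation, either attached to the record or
    supplied via ``domains``; missing annotations raise ``ValueError`` naming
    the offending indices.
    """
    tokens: dict[int, str] = {}
    missing = []
    for r in records:
        ann = (domains or {}).get(r.index) or r.domain
        if ann is None:
            missing.append(r.index)
        else:
            tokens[r.index] = ann.token
    if missing:
        raise ValueError(f"records without domain annotation: {missing}")
    tally: dict[str, list[int]] = {}
    for r, pa, pb in zip(records, predictions_a, predictions_b):
        counts = tally.setdefault(tokens[r.index], [0, 0, 0])
        counts[2] += 1
        if pa.predicted is r.hazard:
            counts[0] += 1
        if pb.predicted is r.hazard:
            counts[1] += 1
    return {d: (a, b, t) for d, (a, b, t) in tally.items()}
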