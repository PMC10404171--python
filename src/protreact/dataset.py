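"""The 106-chemical study dataset: typed records, loading, binarization.

Each record carries a chemical's identity (name, CAS), its human sensitizing
potency category (1 = most potent ... 5 = very weak, 6 = true non-sensitizer)
and the percent peptide depletion measured by the two assays: the
spectrophotometric ProtReact readout and the reference HPLC-based DPRA.
Categories 1-4 count as human sensitizers; 5 and 6 as non-sensitizers
(category-5 chemicals sensitize so rarely in the general population that they
are grouped with the true non-sensitizers).

The bundled table is the published dataset transcribed at the printed one
decimal; printed values are carried verbatim, including one negative DPRA
entry (Chlorpromazine) that was evidently never clamped at source and one row
(Dibenzyl ether) whose printed ProtReact mean is not the mean of its printed
Cys/Lys values (flagged ``mean_inconsistent``, not corrected).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import pandas as pd

from .depletion import DepletionProfile
from .exceptions import DatasetError

__all__ = [
    "HazardLabel",
    "ChemicalRecord",
    "DomainAnnotation",
    "binarize_human_category",
    "load_dataset",
    "save_dataset",
    "load_table",
    "load_domains",
    "normalize_domain",
    "bundled_dataset_path",
    "bundled_domains_path",
]

CAS_PATTERN = re.compile(r"^\d{2,7}-\d{2}-\d$")

_COLUMNS = [
    "index", "name", "cas", "human_category", "domain", "prohapten_flag",
    "pr_cys", "pr_lys", "pr_mean", "dpra_cys", "dpra_lys", "dpra_mean",
]
_NUMERIC = ["pr_cys", "pr_lys", "pr_mean", "dpra_cys", "dpra_lys", "dpra_mean"]

#: canonical mechanistic-domain tokens
DOMAIN_TOKENS = (
    "michael_acceptor", "schiff_base", "sn2", "snar", "acyl_transfer", "none",
)

_TOKEN_MAP = {
    "michael acceptor": "michael_acceptor",
    "michael_acceptor": "michael_acceptor",
    "schiff base": "schiff_base",
    "schiff_base": "schiff_base",
    "sn2": "sn2",
    "sn2-reaction": "sn2",
    "snar": "snar",
    "acyl transfer": "acyl_transfer",
    "acyl_transfer": "acyl_transfer",
    "none": "none",
}


class HazardLabel(str, enum.Enum):
    """Binary skin-sensitization hazard call."""

    SENSITIZER = "sensitizer"
    NON_SENSITIZER = "non_sensitizer"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def binarize_human_category(category: int) -> HazardLabel:
    """Map a human potency category (1-6) to the binary hazard label.

    Categories 1-4 are sensitizers; categories 5 and 6 are non-sensitizers.
    """
    if category not in (1, 2, 3, 4, 5, 6):
        raise ValueError(f"human potency category must be in 1..6, got {category!r}")
    return HazardLabel.SENSITIZER if category <= 4 else HazardLabel.NON_SENSITIZER


@dataclass(frozen=True)
class DomainAnnotation:
    """Mechanistic-domain annotation for one chemical.

    ``raw`` keeps the source label (possibly slashed, e.g. "Michael
    acceptor/none"); ``token`` is the normalized primary token and
    ``ambiguous`` marks slashed/compound assignments.
    """

    raw: str
    token: str
    ambiguous: bool
    prohapten_flag: str | None = None


def normalize_domain(raw: str) -> tuple[str, bool]:
    """Normalize a free-text domain label to (primary token, ambiguous flag).

    A slashed label maps to its non-"none" constituent ("Michael
    acceptor/none" -> michael_acceptor, "None/SN2" -> sn2), matching how
    compound assignments are grouped in aggregate domain counts; "none/none"
    degenerates to none.  Unknown labels raise ``DatasetError``.
    """
    text = raw.strip().lower()
    if not text:
        raise DatasetError("empty mechanistic-domain label")
    # drop trailing qualifiers such as "(and/or possibly other mechanism)"
    # before splitting, since they may themselves contain slashes
    text = re.sub(r"\s*\(.*\)$", "", text).strip()
    parts = [p.strip() for p in text.split("/")]
    ambiguous = len(parts) > 1
    candidates = [p for p in parts if p != "none"] or ["none"]
    key = candidates[0]
    if key not in _TOKEN_MAP:
        raise DatasetError(f"unknown mechanistic domain label: {raw!r}")
    return _TOKEN_MAP[key], ambiguous


@dataclass(frozen=True)
class ChemicalRecord:
    """One row of the study dataset."""

    index: int
    name: str
    cas: str
    human_category: int
    protreact: DepletionProfile
    dpra: DepletionProfile
    domain: DomainAnnotation | None = None
    mean_inconsistent: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.human_category not in (1, 2, 3, 4, 5, 6):
            raise DatasetError(
                f"record {self.index}: human_category {self.human_category!r} not in 1..6"
            )
        if not CAS_PATTERN.match(self.cas):
            raise DatasetError(f"record {self.index}: malformed CAS number {self.cas!r}")

    @property
    def hazard(self) -> HazardLabel:
        return binarize_human_category(self.human_category)

    def profile(self, assay: str) -> DepletionProfile:
        """The depletion profile for ``assay`` ('protreact' or 'dpra')."""
        if assay == "protreact":
            return self.protreact
        if assay == "dpra":
            return self.dpra
        raise ValueError(f"unknown assay {assay!r}; expected 'protreact' or 'dpra'")


def bundled_dataset_path():
    """Path-like handle to the packaged chemicals table."""
    return resources.files("protreact.data") / "chemicals.csv"


def bundled_domains_path():
    """Path-like handle to the packaged mechanistic-domain annotation file.

    The file is a synthetic reconstruction: domains of the misclassified
    chemicals and the per-domain totals follow the published analysis, the
    remaining (always correctly classified) chemicals carry plausible
    placeholder assignments.  See the file header/docs for details.
    """
    return resources.files("protreact.data") / "domains_s1_synthetic.csv"


def _mean_consistency(row) -> frozenset[str]:
    flags = []
    for assay, pre in (("protreact", "pr"), ("dpra", "dpra")):
        expected = (row[f"{pre}_cys"] + row[f"{pre}_lys"]) / 2.0
        if abs(expected - row[f"{pre}_mean"]) > 0.1 + 1e-9:
            flags.append(assay)
    return frozenset(flags)


def load_table(path=None) -> pd.DataFrame:
    """Load the chemicals table as a validated DataFrame.

    ``path=None`` loads the bundled dataset.  Schema:
    ``index,name,cas,human_category,domain,prohapten_flag,pr_cys,pr_lys,
    pr_mean,dpra_cys,dpra_lys,dpra_mean``.
    """
    if path is None:
        path = bundled_dataset_path()
    try:
        df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    except pd.errors.EmptyDataError as exc:
        raise DatasetError(f"empty or unreadable chemicals table: {path}") from exc
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"chemicals table is missing columns: {missing}")
    if df.empty:
        raise DatasetError("chemicals table contains no rows")
    for col in _NUMERIC:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.loc[coerced.isna() & df[col].notna(), "index"]
        if len(bad):
            raise DatasetError(
                f"non-numeric depletion in column {col!r} at row index {bad.iloc[0]}"
            )
        df[col] = coerced
    if df["index"].duplicated().any():
        dup = df.loc[df["index"].duplicated(), "index"].iloc[0]
        raise DatasetError(f"duplicate chemical index: {dup}")
    return df


def load_dataset(path=None, domains_path=None) -> list[ChemicalRecord]:
    """Load chemical records, optionally joined with domain annotations.

    The bundled table is used when ``path`` is None.  Domain annotations are
    attached from ``domains_path`` when given, else from any non-empty
    ``domain`` column in the table itself; records without annotation carry
    ``domain=None``.
    """
    df = load_table(path)
    annotations: dict[int, DomainAnnotation] = {}
    if domains_path is not None:
        annotations = load_domains(domains_path)
    records: list[ChemicalRecord] = []
    for row in df.to_dict("records"):
        idx = int(row["index"])
        domain = annotations.get(idx)
        if domain is None and isinstance(row.get("domain"), str) and row["domain"].strip():
            token, ambiguous = normalize_domain(row["domain"])
            flag = row.get("prohapten_flag")
            domain = DomainAnnotation(
                raw=row["domain"],
                token=token,
                ambiguous=ambiguous,
                prohapten_flag=flag if isinstance(flag, str) and flag else None,
            )
        records.append(
            ChemicalRecord(
                index=idx,
                name=str(row["name"]),
                cas=str(row["cas"]),
                human_category=int(row["human_category"]),
                protreact=DepletionProfile(
                    cys_pct=row["pr_cys"], lys_pct=row["pr_lys"], mean_pct=row["pr_mean"]
                ),
                dpra=DepletionProfile(
                    cys_pct=row["dpra_cys"], lys_pct=row["dpra_lys"], mean_pct=row["dpra_mean"]
                ),
                domain=domain,
                mean_inconsistent=_mean_consistency(row),
            )
        )
    return records


def save_dataset(records: Iterable[ChemicalRecord], path) -> None:
    """Serialize records back to the CSV schema (lossless round trip)."""
    rows = []
    for r in records:
        rows.append(
            {
                "index": r.index,
                "name": r.name,
                "cas": r.cas,
                "human_category": r.human_category,
                "domain": r.domain.raw if r.domain else "",
                "prohapten_flag": (r.domain.prohapten_flag or "") if r.domain else "",
                "pr_cys": r.protreact.cys_pct,
                "pr_lys": r.protreact.lys_pct,
                "pr_mean": r.protreact.mean_pct,
                "dpra_cys": r.dpra.cys_pct,
                "dpra_lys": r.dpra.lys_pct,
                "dpra_mean": r.dpra.mean_pct,
            }
        )
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


def load_domains(path=None) -> dict[int, DomainAnnotation]:
    """Load mechanistic-domain annotations keyed by chemical index.

    ``path=None`` loads the bundled synthetic reconstruction (see
    :func:`bundled_domains_path`).  Schema: ``index,domain,prohapten_flag``.
    """
    if path is None:
        path = bundled_domains_path()
    df = pd.read_csv(path, keep_default_na=False)
    for col in ("index", "domain"):
        if col not in df.columns:
            raise DatasetError(f"domain annotation file is missing column {col!r}")
    out: dict[int, DomainAnnotation] = {}
    for row in df.to_dict("records"):
        token, ambiguous = normalize_domain(str(row["domain"]))
        flag = str(row.get("prohapten_flag", "")).strip()
        out[int(row["index"])] = DomainAnnotation(
            raw=str(row["domain"]),
            token=token,
            ambiguous=ambiguous,
            prohapten_flag=flag or None,
        )
    return out
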