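"""Percent peptide depletion from raw plate-reader signals.

The reactivity readout of a competitive peptide-binding assay is an absorbance
(Ellman's reagent, 405 nm, thiol/cysteine) or fluorescence (FSE, Ex 485/Em 528,
amine/lysine) signal: the more peptide the test chemical consumed, the less
probe binds and the lower the signal.  Three reference controls anchor the
scale:

* ``A`` — peptide + solvent + probe: the maximum attainable signal,
* ``B`` — peptide + solvent, no probe: the blank,
* ``C`` — peptide + chemical, no probe: the chemical's own optical
  interference (one per test substance; also applicable to the positive and
  negative control substances).

Percent depletion for a well reading ``S`` with interference control ``C`` is

    depletion% = [1 - (S - C) / (A - B)] * 100

computed identically for the negative control, positive control and each test
chemical.  Values are kept signed for audit and clamped to [0, 100] for
reporting and classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import fmean
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import InsufficientReplicationError, InvalidRunError

__all__ = [
    "DepletionProfile",
    "PlateRun",
    "RunResult",
    "AggregateDepletion",
    "percent_depletion",
    "clamp_depletion",
    "run_depletion",
    "aggregate_runs",
    "read_plate_csv",
    "write_plate_csv",
]

PEPTIDES = ("cysteine", "lysine")
SIGNAL_KINDS = ("absorbance_405nm", "fluorescence_485_528")

#: default QC acceptance bands for the run controls (percent depletion).
#: The negative control (lactic acid) must stay essentially unreactive and the
#: positive control (DNFB) clearly reactive; no numeric band is standardized
#: for this assay, so both are configurable.
DEFAULT_NC_MAX_PCT = 10.0
DEFAULT_PC_MIN_PCT = 50.0


def clamp_depletion(raw: float) -> float:
    """Clamp a signed percent depletion to the reportable range [0, 100].

    Negative depletion (signal above the reference maximum, e.g. colored
    chemicals) reports as 0%; values past complete depletion report as 100%.
    """
    raw = float(raw)
    if not math.isfinite(raw):
        raise ValueError(f"depletion value must be finite, got {raw!r}")
    return max(0.0, min(100.0, raw))


def percent_depletion(reading: float, a: float, b: float, c: float) -> float:
    """Signed percent depletion of a mean well signal against controls A/B/C.

    Parameters
    ----------
    reading : mean raw signal of the wells being evaluated (NC, PC or TC).
    a, b : mean signals of reference controls A (maximum) and B (blank).
    c : mean signal of the substance's interference control C.

    Returns the unclamped value ``[1 - (reading - c)/(a - b)] * 100``.
    ``a > b`` is required: a run without positive dynamic range is invalid.
    """
    for name, v in (("reading", reading), ("a", a), ("b", b), ("c", c)):
        if not math.isfinite(float(v)):
            raise ValueError(f"signal {name!r} must be finite, got {v!r}")
    if a <= b:
        raise InvalidRunError(
            f"reference controls give non-positive dynamic range (A={a}, B={b})"
        )
    return (1.0 - (reading - c) / (a - b)) * 100.0


@dataclass(frozen=True)
class DepletionProfile:
    """Cys/Lys/mean percent depletion for one chemical under one assay.

    ``cys_pct``/``lys_pct``/``mean_pct`` are the reportable (normally clamped)
    values; ``raw_cys_pct``/``raw_lys_pct`` retain the signed percents for
    audit.  Externally published tables are stored exactly as printed, which
    may include signed values that were never clamped at source.
    """

    cys_pct: float
    lys_pct: float | None = None
    mean_pct: float | None = None
    raw_cys_pct: float | None = None
    raw_lys_pct: float | None = None

    @classmethod
    def from_raw(cls, raw_cys: float, raw_lys: float | None = None) -> "DepletionProfile":
        """Build a profile from signed percents, clamping and averaging.

        The mean is the unweighted arithmetic mean of the *clamped* Cys and
        Lys depletions, the convention used for reporting assay output.
        """
        cys = clamp_depletion(raw_cys)
        if raw_lys is None:
            return cls(cys_pct=cys, raw_cys_pct=float(raw_cys))
        lys = clamp_depletion(raw_lys)
        return cls(
            cys_pct=cys,
            lys_pct=lys,
            mean_pct=(cys + lys) / 2.0,
            raw_cys_pct=float(raw_cys),
            raw_lys_pct=float(raw_lys),
        )


@dataclass
class PlateRun:
    """Raw signals of one independent run for one peptide readout.

    ``ref_c`` maps substance id -> interference-control wells; every substance
    in ``tc`` must have a matching entry.  ``nc_ref_c``/``pc_ref_c`` are the
    interference controls for the negative/positive control substances; when
    absent the blank ``ref_b`` stands in (no interference assumed).
    """

    peptide: str
    ref_a: Sequence[float]
    ref_b: Sequence[float]
    ref_c: Mapping[str, Sequence[float]]
    nc: Sequence[float] = field(default_factory=list)
    pc: Sequence[float] = field(default_factory=list)
    tc: Mapping[str, Sequence[float]] = field(default_factory=dict)
    nc_ref_c: Sequence[float] | None = None
    pc_ref_c: Sequence[float] | None = None
    signal_kind: str | None = None
    run_id: str = "run"

    def __post_init__(self) -> None:
        if self.peptide not in PEPTIDES:
            raise ValueError(f"peptide must be one of {PEPTIDES}, got {self.peptide!r}")
        if self.signal_kind is None:
            self.signal_kind = (
                "absorbance_405nm" if self.peptide == "cysteine" else "fluorescence_485_528"
            )
        if self.signal_kind not in SIGNAL_KINDS:
            raise ValueError(f"signal_kind must be one of {SIGNAL_KINDS}")
        if not self.ref_a or not self.ref_b:
            raise ValueError("reference controls A and B must be non-empty")
        for sid in self.tc:
            if sid not in self.ref_c:
                raise KeyError(f"substance {sid!r} has no matching reference control C")
        for role, values in self._all_signals():
            for v in values:
                if not math.isfinite(float(v)) or float(v) < 0:
                    raise ValueError(f"{role} contains a non-finite or negative signal: {v!r}")

    def _all_signals(self):
        yield "ref_a", self.ref_a
        yield "ref_b", self.ref_b
        for sid, vals in self.ref_c.items():
            yield f"ref_c[{sid}]", vals
        yield "nc", self.nc
        yield "pc", self.pc
        for sid, vals in self.tc.items():
            yield f"tc[{sid}]", vals
        if self.nc_ref_c is not None:
            yield "nc_ref_c", self.nc_ref_c
        if self.pc_ref_c is not None:
            yield "pc_ref_c", self.pc_ref_c


@dataclass(frozen=True)
class RunResult:
    """Per-run depletion values plus control QC for one :class:`PlateRun`."""

    run_id: str
    peptide: str
    raw: dict[str, float]          # substance id -> signed percent depletion
    clamped: dict[str, float]      # substance id -> clamped percent depletion
    nc_depletion: float | None
    pc_depletion: float | None
    valid: bool
    qc_flags: tuple[str, ...]


def run_depletion(
    run: PlateRun,
    nc_max_pct: float = DEFAULT_NC_MAX_PCT,
    pc_min_pct: float = DEFAULT_PC_MIN_PCT,
) -> RunResult:
    """Compute percent depletion for every substance of one run.

    Replicate wells are averaged within the run for every role, then the
    depletion equation is applied per substance with its own interference
    control C.  The negative/positive control depletions are computed the same
    way and checked against the configured QC band; failing either check marks
    the run invalid (values are still returned for inspection).
    """
    a = fmean(run.ref_a)
    b = fmean(run.ref_b)
    raw: dict[str, float] = {}
    for sid, wells in run.tc.items():
        c = fmean(run.ref_c[sid])
        raw[sid] = percent_depletion(fmean(wells), a, b, c)
    clamped = {sid: clamp_depletion(v) for sid, v in raw.items()}

    flags: list[str] = []
    nc_dep = pc_dep = None
    if run.nc:
        c_nc = fmean(run.nc_ref_c) if run.nc_ref_c else b
        nc_dep = percent_depletion(fmean(run.nc), a, b, c_nc)
        if clamp_depletion(nc_dep) > nc_max_pct:
            flags.append(f"nc_depletion {nc_dep:.2f}% exceeds {nc_max_pct}%")
    if run.pc:
        c_pc = fmean(run.pc_ref_c) if run.pc_ref_c else b
        pc_dep = percent_depletion(fmean(run.pc), a, b, c_pc)
        if pc_dep < pc_min_pct:
            flags.append(f"pc_depletion {pc_dep:.2f}% below {pc_min_pct}%")
    return RunResult(
        run_id=run.run_id,
        peptide=run.peptide,
        raw=raw,
        clamped=clamped,
        nc_depletion=nc_dep,
        pc_depletion=pc_dep,
        valid=not flags,
        qc_flags=tuple(flags),
    )


@dataclass(frozen=True)
class AggregateDepletion:
    """Cross-run mean depletion for one substance: signed and clamped."""

    raw_pct: float
    pct: float
    n_runs: int


def aggregate_runs(per_run_values: Iterable[float], n_min: int = 3) -> AggregateDepletion:
    """Average signed per-run depletions, then clamp once.

    Clamping is applied to the cross-run mean, not per run, so transient
    negative values average out before truncation; the signed mean is kept
    for audit.  At least ``n_min`` independent runs are required (assay
    results are reported as the mean of >= 3 experiments).
    """
    values = [float(v) for v in per_run_values]
    if len(values) < n_min:
        raise InsufficientReplicationError(
            f"need at least {n_min} independent runs, got {len(values)}"
        )
    raw = fmean(values)
    return AggregateDepletion(raw_pct=raw, pct=clamp_depletion(raw), n_runs=len(values))


# ---------------------------------------------------------------------------
# plate CSV interchange:  run_id,peptide,role,substance_id,replicate,signal

_ROLES = ("A", "B", "C", "NC", "PC", "TC")


def read_plate_csv(path) -> list[PlateRun]:
    """Read plate runs from the long-format CSV schema.

    Columns: ``run_id,peptide,role,substance_id,replicate,signal`` with role in
    A/B/C/NC/PC/TC; C and TC rows carry a substance_id (the special ids ``NC``
    and ``PC`` attach a C row to the run controls).  Returns one
    :class:`PlateRun` per (run_id, peptide), ordered as first seen.
    """
    df = pd.read_csv(path, dtype={"substance_id": str}, keep_default_na=False)
    required = {"run_id", "peptide", "role", "substance_id", "replicate", "signal"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate CSV is missing columns: {sorted(missing)}")
    bad = set(df["role"]) - set(_ROLES)
    if bad:
        raise ValueError(f"unknown plate roles: {sorted(bad)}")
    runs: list[PlateRun] = []
    for (run_id, peptide), grp in df.groupby(["run_id", "peptide"], sort=False):
        ref_c: dict[str, list[float]] = {}
        tc: dict[str, list[float]] = {}
        simple: dict[str, list[float]] = {r: [] for r in ("A", "B", "NC", "PC")}
        nc_c: list[float] = []
        pc_c: list[float] = []
        for row in grp.itertuples(index=False):
            sig = float(row.signal)
            if row.role == "C":
                if row.substance_id == "NC":
                    nc_c.append(sig)
                elif row.substance_id == "PC":
                    pc_c.append(sig)
                else:
                    ref_c.setdefault(row.substance_id, []).append(sig)
            elif row.role == "TC":
                tc.setdefault(row.substance_id, []).append(sig)
            else:
                simple[row.role].append(sig)
        runs.append(
            PlateRun(
                peptide=str(peptide),
                ref_a=simple["A"],
                ref_b=simple["B"],
                ref_c=ref_c,
                nc=simple["NC"],
                pc=simple["PC"],
                tc=tc,
                nc_ref_c=nc_c or None,
                pc_ref_c=pc_c or None,
                run_id=str(run_id),
            )
        )
    return runs


def write_plate_csv(runs: Iterable[PlateRun], path) -> None:
    """Write plate runs in the long-format CSV schema (inverse of reader)."""
    rows = []

    def emit(run, role, sid, values):
        for i, v in enumerate(values, start=1):
            rows.append((run.run_id, run.peptide, role, sid, i, float(v)))

    for run in runs:
        emit(run, "A", "", run.ref_a)
        emit(run, "B", "", run.ref_b)
        for sid, vals in run.ref_c.items():
            emit(run, "C", sid, vals)
        if run.nc_ref_c:
            emit(run, "C", "NC", run.nc_ref_c)
        if run.pc_ref_c:
            emit(run, "C", "PC", run.pc_ref_c)
        emit(run, "NC", "", run.nc)
        emit(run, "PC", "", run.pc)
        for sid, vals in run.tc.items():
            emit(run, "TC", sid, vals)
    pd.DataFrame(
        rows, columns=["run_id", "peptide", "role", "substance_id", "replicate", "signal"]
    ).to_csv(path, index=False)
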