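"""Synthetic data generators for end-to-end testing without laboratory data.

Two generators:

* :func:`simulate_plate` inverts the depletion equation.  Given a true
  depletion ``d`` and control magnitudes, the expected test-chemical well
  signal is ``C + (1 - d/100) * (A - B)``; Gaussian noise is added on the
  signal scale (the instrument measures absorbance/fluorescence, so
  depletion-scale noise follows by propagation through the equation).  With
  zero noise the depletion pipeline recovers the target exactly.

* :func:`simulate_population` draws labeled class-conditional depletion
  scores from two normal distributions clamped to [0, 100] (truncation by
  clamping mirrors how out-of-range depletions are reported, and leaves every
  exceedance probability over thresholds inside (0, 100) unchanged — so the
  Youden-optimal threshold of the clamped pair equals the density
  intersection of the unclamped normals whenever it falls in (0, 100); see
  :func:`analytic_youden_threshold`).

Defaults describe a well-separated reactive class (Normal(60, 15)) against a
weakly reactive background (Normal(5, 5)), 200 chemicals per class, and an
Ellman's-like absorbance scale (A ~ 2.0 OD, blank ~ 0.2 OD).  Same seed,
same output — byte-identical when written to CSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import HazardLabel
from .depletion import PlateRun

__all__ = [
    "PlateSimConfig",
    "PopulationSimConfig",
    "simulate_plate",
    "simulate_population",
    "analytic_youden_threshold",
]


@dataclass(frozen=True)
class PlateSimConfig:
    """Signal model for synthetic plate runs.

    ``a_signal``/``b_signal`` are the maximum and blank control magnitudes;
    each substance gets an interference control drawn uniformly from
    ``c_signal_range``.  ``noise_sd`` is the per-well Gaussian standard
    deviation on the signal scale.  Two wells per chemical per run and three
    independent runs mirror the bench protocol.
    """

    peptide: str = "cysteine"
    a_signal: float = 2.0
    b_signal: float = 0.2
    c_signal_range: tuple[float, float] = (0.2, 0.4)
    noise_sd: float = 0.0
    n_replicates: int = 2
    n_runs: int = 3
    seed: int = 0
    nc_depletion: float = 0.5    # lactic-acid-like negative control
    pc_depletion: float = 90.0   # DNFB-like positive control

    def __post_init__(self) -> None:
        if self.a_signal <= self.b_signal:
            raise ValueError("a_signal must exceed b_signal")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1 or self.n_runs < 1:
            raise ValueError("n_replicates and n_runs must be >= 1")


def simulate_plate(targets: dict[str, float], config: PlateSimConfig) -> list[PlateRun]:
    """Generate plate runs whose noise-free depletion equals ``targets``.

    ``targets`` maps substance id -> true percent depletion in [0, 100].
    Returns ``config.n_runs`` independent :class:`PlateRun` objects; all well
    signals (controls included) carry i.i.d. Gaussian noise of
    ``config.noise_sd``, clipped at zero (signals are non-negative).
    """
    for sid, d in targets.items():
        if not (0.0 <= float(d) <= 100.0) or not math.isfinite(float(d)):
            raise ValueError(f"target depletion for {sid!r} must be in [0, 100], got {d!r}")
    rng = np.random.default_rng(config.seed)
    a, b = config.a_signal, config.b_signal
    span = a - b

    def wells(true_value: float) -> list[float]:
        noise = rng.normal(0.0, config.noise_sd, size=config.n_replicates)
        return list(np.clip(true_value + noise, 0.0, None))

    def tc_signal(c_true: float, depletion: float) -> float:
        return c_true + (1.0 - depletion / 100.0) * span

    runs = []
    for run_index in range(config.n_runs):
        c_true = {
            sid: rng.uniform(*config.c_signal_range) for sid in sorted(targets)
        }
        c_nc = rng.uniform(*config.c_signal_range)
        c_pc = rng.uniform(*config.c_signal_range)
        runs.append(
            PlateRun(
                peptide=config.peptide,
                ref_a=wells(a),
                ref_b=wells(b),
                ref_c={sid: wells(c) for sid, c in c_true.items()},
                nc=wells(tc_signal(c_nc, config.nc_depletion)),
                pc=wells(tc_signal(c_pc, config.pc_depletion)),
                tc={sid: wells(tc_signal(c_true[sid], targets[sid])) for sid in sorted(targets)},
                nc_ref_c=wells(c_nc),
                pc_ref_c=wells(c_pc),
                run_id=f"run{run_index + 1}",
            )
        )
    return runs


@dataclass(frozen=True)
class PopulationSimConfig:
    """Class-conditional depletion-score population.

    Normal(mean, sd) per class, clamped to [0, 100].  Defaults: 200
    sensitizers ~ N(60, 15) against 200 non-sensitizers ~ N(5, 5).
    """

    n_sensitizers: int = 200
    n_nonsensitizers: int = 200
    sensitizer_mean: float = 60.0
    sensitizer_sd: float = 15.0
    nonsensitizer_mean: float = 5.0
    nonsensitizer_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sensitizers < 1 or self.n_nonsensitizers < 1:
            raise ValueError("class counts must be >= 1")
        if self.sensitizer_sd < 0 or self.nonsensitizer_sd < 0:
            raise ValueError("standard deviations must be >= 0")


def simulate_population(config: PopulationSimConfig) -> pd.DataFrame:
    """Labeled depletion scores: columns ``score`` (percent) and ``label``."""
    rng = np.random.default_rng(config.seed)
    pos = rng.normal(config.sensitizer_mean, config.sensitizer_sd, config.n_sensitizers)
    neg = rng.normal(
        config.nonsensitizer_mean, config.nonsensitizer_sd, config.n_nonsensitizers
    )
    scores = np.clip(np.concatenate([pos, neg]), 0.0, 100.0)
    labels = [HazardLabel.SENSITIZER.value] * config.n_sensitizers + [
        HazardLabel.NON_SENSITIZER.value
    ] * config.n_nonsensitizers
    return pd.DataFrame({"score": scores, "label": labels})


def analytic_youden_threshold(config: PopulationSimConfig) -> float:
    """Population-optimal Youden threshold for the two normal classes.

    J(t) = P(S >= t | sensitizer) - P(S >= t | non-sensitizer) is maximized
    where the class densities intersect; for unequal variances the quadratic
    has two roots and the one between the class means is the relevant
    crossing.  Valid for the clamped scores whenever it lies in (0, 100).
    """
    m0, s0 = config.nonsensitizer_mean, config.nonsensitizer_sd
    m1, s1 = config.sensitizer_mean, config.sensitizer_sd
    if s0 == s1:
        return (m0 + m1) / 2.0
    # f0(t) = f1(t)  <=>  a t^2 + b t + c = 0 on the log scale
    a = 1.0 / s0**2 - 1.0 / s1**2
    b = 2.0 * (m1 / s1**2 - m0 / s0**2)
    c = m0**2 / s0**2 - m1**2 / s1**2 + 2.0 * math.log(s0 / s1)
    disc = b * b - 4.0 * a * c
    if disc < 0:
        raise ValueError("class densities do not intersect")
    roots = [(-b + sgn * math.sqrt(disc)) / (2.0 * a) for sgn in (1.0, -1.0)]
    lo, hi = sorted((m0, m1))
    inside = [r for r in roots if lo <= r <= hi]
    return inside[0] if inside else min(roots, key=lambda r: abs(r - (m0 + m1) / 2.0))
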