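"""Immune-monitoring assay arithmetic.

Small, exactly specified computations used across the trial's monitoring
assays: fold changes of iNKT/NK/T cell abundances with best-response
selection and cohort mean +/- SEM summaries, responder counting at a
1.5-fold threshold, tetramer positivity thresholds (control mean + 2 SD),
background subtraction for tetramer and intracellular-cytokine readouts,
ligand-dependent ELISPOT spot counts, and comparative-CT (delta-delta-CT)
relative expression for qPCR.

SEM and SD conventions default to the population form (n in the
denominator): this is the convention that reproduces the published cohort
summaries to two decimals.  The sample convention (n-1) is available via
``ddof=1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np

from .timepoints import Timepoint

ANALYTES = ("iNKT", "NK", "T", "tetramer_CD8", "blast", "other")
UNITS = ("cells_per_uL", "percent_of_parent")


@dataclass
class MeasurementSeries:
    """One analyte's time course for one patient and compartment."""

    patient_id: str
    compartment: str
    analyte: str
    unit: str
    values: Dict[Timepoint, float]

    def __post_init__(self) -> None:
        self.values = {Timepoint.parse(tp): float(v)
                       for tp, v in self.values.items()}
        for tp, v in self.values.items():
            if v < 0:
                raise ValueError(f"negative measurement {v} at {tp.label}")

    @property
    def pre(self) -> float:
        if Timepoint.PRE not in self.values:
            raise ValueError("series lacks a pre-treatment value")
        return self.values[Timepoint.PRE]

    def post_timepoints(self) -> List[Timepoint]:
        return sorted((tp for tp in self.values if tp is not Timepoint.PRE),
                      key=lambda tp: tp.days)


def fold_change(pre: float, post: float) -> float:
    """post/pre ratio; undefined (error) when the baseline is zero."""
    if pre <= 0:
        raise ValueError("fold change undefined for a zero or negative baseline")
    return post / pre


def best_response_fold(series: MeasurementSeries) -> Tuple[Timepoint, float]:
    """Post timepoint with the maximal fold over baseline (earliest on ties)."""
    posts = series.post_timepoints()
    if not posts:
        raise ValueError("series has no post-treatment values")
    pre = series.pre
    best_tp, best_fold = None, -math.inf
    for tp in posts:  # ordered by day, so ties keep the earliest
        f = fold_change(pre, series.values[tp])
        if f > best_fold:
            best_tp, best_fold = tp, f
    return best_tp, best_fold


@dataclass
class FoldSummary:
    """Cohort summary of per-patient fold changes."""

    folds: List[float]
    mean: float
    sem: float
    n: int


def summarize_folds(folds: Sequence[float], ddof: int = 0) -> FoldSummary:
    """Arithmetic mean and SEM of fold values.

    ``ddof=0`` (default) uses the population SD in the SEM; ``ddof=1``
    gives the sample convention.
    """
    folds = [float(f) for f in folds]
    if not folds:
        raise ValueError("cannot summarize an empty fold list")
    if any(f <= 0 for f in folds):
        raise ValueError("fold values must be positive")
    arr = np.asarray(folds)
    n = arr.size
    if n == 1:
        sem = 0.0
    else:
        sem = float(arr.std(ddof=ddof) / math.sqrt(n))
    return FoldSummary(folds=folds, mean=float(arr.mean()), sem=sem, n=n)


def count_responders(folds: Sequence[float], threshold: float = 1.5) -> int:
    """Number of fold values at or above the responder threshold."""
    return sum(1 for f in folds if f >= threshold)


def tetramer_threshold(control_values: Optional[Sequence[float]] = None, *,
                       mean: Optional[float] = None,
                       two_sd: Optional[float] = None,
                       ddof: int = 0) -> float:
    """Positivity threshold for tetramer staining: control mean + 2 SD.

    Accepts either the raw control frequencies (>= 2 values; SD uses the
    population convention by default) or precomputed aggregates
    ``mean`` and ``two_sd``.
    """
    if control_values is not None:
        vals = np.asarray([float(v) for v in control_values])
        if vals.size < 2:
            raise ValueError("need at least two control values")
        return float(vals.mean() + 2.0 * vals.std(ddof=ddof))
    if mean is None or two_sd is None:
        raise ValueError("provide control_values or both mean and two_sd")
    return float(mean + two_sd)


class SubtractedFrequency(NamedTuple):
    value: float
    clipped: bool


def background_subtract(stimulated: float, control: float) -> SubtractedFrequency:
    """Stimulated-minus-control frequency, clipped at zero with an audit flag."""
    if stimulated < 0 or control < 0:
        raise ValueError("frequencies must be non-negative")
    delta = stimulated - control
    if delta < 0:
        return SubtractedFrequency(0.0, True)
    return SubtractedFrequency(delta, False)


def elispot_delta(sfc_ligand: float, sfc_vehicle: float) -> SubtractedFrequency:
    """Ligand-dependent spot-forming cells: ligand minus vehicle wells."""
    if sfc_ligand < 0 or sfc_vehicle < 0:
        raise ValueError("spot counts must be non-negative")
    delta = sfc_ligand - sfc_vehicle
    if delta < 0:
        return SubtractedFrequency(0.0, True)
    return SubtractedFrequency(float(delta), False)


def ddct_relative_expression(ct_target: float, ct_ref: float,
                             ct_target_cal: float, ct_ref_cal: float) -> float:
    """Comparative-CT relative quantity, 2**-ddCT.

    ddCT = (ct_target - ct_ref) - (ct_target_cal - ct_ref_cal), with the
    reference gene (e.g. GAPDH) correcting input amount and the calibrator
    sample defining the unit.
    """
    for v in (ct_target, ct_ref, ct_target_cal, ct_ref_cal):
        if not math.isfinite(v):
            raise ValueError("CT values must be finite")
    ddct = (ct_target - ct_ref) - (ct_target_cal - ct_ref_cal)
    return 2.0 ** (-ddct)
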