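"""Longitudinal clonotype dynamics: trajectories, expansion testing,
kinetic and longevity classification, and marrow/blood clone sharing.

The central statistic is an exact two-sided binomial test of a clone's
post-treatment count against its pre-treatment frequency.  Two-sidedness
follows the minimum-likelihood convention (sum the probabilities of every
outcome no more likely than the observed one), with a 1e-7 relative
tolerance when comparing tied point probabilities, as in R's binom.test.
Two null conventions are supported:

``baseline_null``
    the pre-treatment frequency k1/n1 is taken as the known null
    proportion.  This mirrors a "change from baseline" framing but
    ignores the sampling noise in the baseline itself, which makes the
    test anti-conservative at typical repertoire depths.
``pooled_null`` (default)
    the null proportion is pooled, (k1+k2)/(n1+n2), the usual two-sample
    comparison; calibration under the null is much better, which is why
    it is the default classification mode.

P-values are Benjamini-Hochberg adjusted over all tested (clone,
timepoint) pairs of a patient-compartment before classification.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .repertoire import Clonotype, RepertoireSample
from .timepoints import Timepoint

logger = logging.getLogger(__name__)

KINETIC_CLASSES = ("Inc", "Dec", "New_transient", "New_stable",
                   "Unchanged", "Undetected")
LONGEVITY_CLASSES = ("transient", "medium_lived", "long_lived")

_TIE_RTOL = 1e-7


class UntestableBaselineError(ValueError):
    """Raised when a clone undetected at baseline is sent to the test."""


# ---------------------------------------------------------------------------
# Exact two-sided binomial test

def _search_first_leq(lo: int, hi: int, threshold: float, n: int, p0: float) -> int:
    """Smallest j in [lo, hi] with pmf(j) <= threshold; pmf non-increasing there."""
    if binom.pmf(hi, n, p0) > threshold:
        return hi + 1
    while lo < hi:
        mid = (lo + hi) // 2
        if binom.pmf(mid, n, p0) <= threshold:
            hi = mid
        else:
            lo = mid + 1
    return lo


def _search_last_leq(lo: int, hi: int, threshold: float, n: int, p0: float) -> int:
    """Largest j in [lo, hi] with pmf(j) <= threshold; pmf non-decreasing there."""
    if binom.pmf(lo, n, p0) > threshold:
        return lo - 1
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if binom.pmf(mid, n, p0) <= threshold:
            lo = mid
        else:
            hi = mid - 1
    return lo


def two_sided_binomial_p(k: int, n: int, p0: float) -> float:
    """Exact two-sided p-value for k successes in n trials at null p0.

    Minimum-likelihood summation: p = sum of Binomial(n, p0) probabilities
    over all outcomes whose point probability is <= pmf(k) * (1 + 1e-7).
    Runs in O(log n) pmf evaluations using the unimodality of the pmf.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must be within [0, 1]")
    if p0 == 0.0:
        return 1.0 if k == 0 else 0.0
    if p0 == 1.0:
        return 1.0 if k == n else 0.0
    mode = int(math.floor((n + 1) * p0))
    mode = min(mode, n)
    if k == mode:
        return 1.0
    threshold = binom.pmf(k, n, p0) * (1.0 + _TIE_RTOL)
    if k < mode:
        left = binom.cdf(k, n, p0)
        j = _search_first_leq(mode, n, threshold, n, p0)
        right = binom.sf(j - 1, n, p0) if j <= n else 0.0
    else:
        right = binom.sf(k - 1, n, p0)
        j = _search_last_leq(0, mode, threshold, n, p0)
        left = binom.cdf(j, n, p0) if j >= 0 else 0.0
    return float(min(1.0, left + right))


def binomial_expansion_test(k1: int, n1: int, k2: int, n2: int,
                            test_mode: str = "baseline_null") -> float:
    """Two-sided test of a clone's change from baseline.

    Parameters
    ----------
    k1, n1:
        baseline clone count and sample depth; ``k1`` must be >= 1 (clones
        undetected at baseline are routed to "new"-clone classification,
        not tested).
    k2, n2:
        post-treatment clone count and sample depth.
    test_mode:
        ``baseline_null`` tests k2 against p0 = k1/n1; ``pooled_null``
        tests k2 against p0 = (k1+k2)/(n1+n2).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample depths must be positive")
    if k1 == 0:
        raise UntestableBaselineError(
            "clone undetected at baseline: expansion from zero is untestable; "
            "classify as a new clone instead")
    if test_mode == "baseline_null":
        p0 = k1 / n1
    elif test_mode == "pooled_null":
        p0 = (k1 + k2) / (n1 + n2)
    else:
        raise ValueError(f"unknown test_mode {test_mode!r}")
    return two_sided_binomial_p(k2, n2, p0)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Trajectories

@dataclass
class ClonotypeTrajectory:
    """One clone's counts and frequencies across ordered timepoints."""

    clonotype: Clonotype
    compartment: str
    timepoints: List[Timepoint]
    counts: Dict[Timepoint, int]
    totals: Dict[Timepoint, int]
    p_values: Dict[Timepoint, float] = field(default_factory=dict)
    q_values: Dict[Timepoint, float] = field(default_factory=dict)
    kinetic_class: Optional[str] = None
    longevity_class: Optional[str] = None

    def frequency(self, tp: Timepoint) -> float:
        return self.counts[tp] / self.totals[tp]

    def detected(self, tp: Timepoint) -> bool:
        return self.counts[tp] >= 1

    @property
    def last_detected(self) -> Optional[Timepoint]:
        hits = [tp for tp in self.timepoints if self.counts[tp] >= 1]
        return max(hits, key=lambda tp: tp.days) if hits else None


def build_trajectories(samples: Sequence[RepertoireSample]) -> List[ClonotypeTrajectory]:
    """Assemble per-clone trajectories for one patient-compartment series.

    The clone universe is the union over timepoints; a clone absent from a
    sample is recorded with count zero at that sample's depth.  Requires
    at least two timepoints, a single compartment and platform, and no
    duplicate timepoints.
    """
    if len(samples) < 2:
        raise ValueError("need samples from at least two timepoints")
    compartments = {s.compartment for s in samples}
    platforms = {s.platform for s in samples}
    patients = {s.patient_id for s in samples}
    if len(compartments) != 1 or len(platforms) != 1 or len(patients) != 1:
        raise ValueError("samples must share patient, compartment, and platform")
    tps = [s.timepoint for s in samples]
    if len(set(tps)) != len(tps):
        raise ValueError(f"duplicate timepoints in series: {[t.label for t in tps]}")
    ordered = sorted(samples, key=lambda s: s.timepoint.days)
    timepoints = [s.timepoint for s in ordered]
    totals = {s.timepoint: s.total for s in ordered}
    universe: Set[Clonotype] = set()
    for s in ordered:
        universe |= s.clonotypes
    trajectories = []
    for clone in sorted(universe, key=lambda c: c.aa_cdr3b):
        counts = {s.timepoint: s.counts.get(clone, 0) for s in ordered}
        trajectories.append(ClonotypeTrajectory(
            clonotype=clone, compartment=ordered[0].compartment,
            timepoints=list(timepoints), counts=counts, totals=dict(totals)))
    return trajectories


def run_expansion_tests(trajectories: Sequence[ClonotypeTrajectory], *,
                      early="d14", late="d42",
                      test_mode: str = "pooled_null",
                      baseline="pre") -> None:
    """Test each baseline-detected clone at the early and late timepoints.

    Fills ``p_values`` and BH-adjusted ``q_values`` in place; the BH
    family is all tested (clone, timepoint) pairs in the collection.
    """
    early, late, baseline = (Timepoint.parse(early), Timepoint.parse(late),
                             Timepoint.parse(baseline))
    keys, pvals = [], []
    for traj in trajectories:
        if baseline not in traj.counts:
            raise ValueError("baseline timepoint missing from trajectory")
        k1, n1 = traj.counts[baseline], traj.totals[baseline]
        if k1 == 0:
            continue
        for tp in (early, late):
            if tp not in traj.counts:
                continue
            p = binomial_expansion_test(k1, n1, traj.counts[tp],
                                        traj.totals[tp], test_mode=test_mode)
            keys.append((traj, tp))
            pvals.append(p)
    if not pvals:
        return
    qvals = bh_adjust(pvals)
    for (traj, tp), p, q in zip(keys, pvals, qvals):
        traj.p_values[tp] = float(p)
        traj.q_values[tp] = float(q)


def classify_kinetics(traj: ClonotypeTrajectory, *, alpha: float = 0.05,
                      early="d14", late="d42", baseline="pre",
                      classification_mode: str = "significance") -> str:
    """Assign exactly one kinetic class to a trajectory.

    Classes partition the clone universe:

    * baseline-undetected clones appearing at the early timepoint only
      are ``New_transient``; those persisting to (or appearing at) the
      late timepoint are ``New_stable``; those seen at neither are
      ``Undetected`` (within the classification window);
    * baseline-detected clones are ``Inc``/``Dec`` when the expansion
      test is significant (BH q < alpha in ``significance`` mode, the
      default) with the direction taken from the frequency change at the
      most significant timepoint, else ``Unchanged``.  In
      ``frequency_only`` mode significance is ignored and the direction
      of the early (falling back to late) frequency change decides.
    """
    early, late, baseline = (Timepoint.parse(early), Timepoint.parse(late),
                             Timepoint.parse(baseline))
    for tp in (baseline, early, late):
        if tp not in traj.counts:
            raise ValueError(f"trajectory lacks required timepoint {tp.label}")
    k_pre = traj.counts[baseline]
    if k_pre == 0:
        det_early, det_late = traj.detected(early), traj.detected(late)
        if det_late:
            cls = "New_stable"
        elif det_early:
            cls = "New_transient"
        else:
            cls = "Undetected"
        traj.kinetic_class = cls
        return cls
    f_pre = traj.frequency(baseline)
    if classification_mode == "significance":
        sig = [tp for tp in (early, late)
               if traj.q_values.get(tp, 1.0) < alpha]
        if not sig:
            traj.kinetic_class = "Unchanged"
            return "Unchanged"
        best = min(sig, key=lambda tp: traj.q_values[tp])
        cls = "Inc" if traj.frequency(best) > f_pre else "Dec"
    elif classification_mode == "frequency_only":
        delta = traj.frequency(early) - f_pre
        if delta == 0.0:
            delta = traj.frequency(late) - f_pre
        if delta > 0:
            cls = "Inc"
        elif delta < 0:
            cls = "Dec"
        else:
            cls = "Unchanged"
    else:
        raise ValueError(f"unknown classification_mode {classification_mode!r}")
    traj.kinetic_class = cls
    return cls


def classify_longevity(traj: ClonotypeTrajectory) -> str:
    """Longevity from the last timepoint at which the clone was detected.

    Convention: last detection on or before day 14 -> transient; between
    day 28 and day 56 -> medium-lived; at 6 months or later -> long-lived.
    The trajectory must span through at least the 6-month visit for the
    distinction to be observable.
    """
    span = max(tp.days for tp in traj.timepoints)
    if span < Timepoint.M6.days:
        raise ValueError("trajectory must span through at least the 6-month "
                         "visit to classify longevity")
    last = traj.last_detected
    if last is None:
        raise ValueError("clone never detected; longevity undefined")
    if last.days <= Timepoint.D14.days:
        cls = "transient"
    elif last.days < Timepoint.M6.days:
        cls = "medium_lived"
    else:
        cls = "long_lived"
    traj.longevity_class = cls
    return cls


# ---------------------------------------------------------------------------
# Marrow / blood sharing

@dataclass
class SharedCloneReport:
    """Clone overlap between compartments plus marrow occupancy of shared clones."""

    patient_id: str
    shared_set: Set[Clonotype]
    bm_only: int
    pb_only: int
    shared: int
    cumulative_bm_frequency: Dict[str, float]  # timepoint label -> sum of freqs

    def venn_counts(self) -> Dict[str, int]:
        return {"bm_only": self.bm_only, "pb_only": self.pb_only,
                "shared": self.shared}


def shared_clones(bm: Sequence[RepertoireSample],
                  pb: Sequence[RepertoireSample]) -> SharedCloneReport:
    """Intersect marrow and blood clone sets (any timepoint) by aaCDR3b.

    Reports Venn counts and, per marrow timepoint, the cumulative
    frequency of shared clones among marrow T cells.
    """
    if not bm or not pb:
        raise ValueError("both compartments need at least one sample")
    patients = {s.patient_id for s in list(bm) + list(pb)}
    if len(patients) != 1:
        raise ValueError(f"patient mismatch across samples: {sorted(patients)}")
    bm_set: Set[Clonotype] = set().union(*(s.clonotypes for s in bm))
    pb_set: Set[Clonotype] = set().union(*(s.clonotypes for s in pb))
    shared = bm_set & pb_set
    cumulative = {}
    for s in sorted(bm, key=lambda s: s.timepoint.days):
        total = s.total
        freq = sum(s.counts.get(c, 0) for c in shared) / total if total else 0.0
        cumulative[s.timepoint.label] = freq
    return SharedCloneReport(
        patient_id=patients.pop(), shared_set=shared,
        bm_only=len(bm_set - pb_set), pb_only=len(pb_set - bm_set),
        shared=len(shared), cumulative_bm_frequency=cumulative)


# ---------------------------------------------------------------------------
# Clone-group expression

def clone_group_expression(groups: Mapping[str, Iterable[Clonotype]],
                           adata, cell_to_clone: Mapping[str, Clonotype],
                           genes: Sequence[str], *, layer: str = "lognorm",
                           timepoint_key: str = "timepoint") -> pd.DataFrame:
    """Mean normalized expression per (kinetic group, timepoint, gene).

    ``cell_to_clone`` maps barcodes (cells with an assigned TRB) to
    clones.  Combinations with no cells are absent from the result rather
    than reported as zero.  Genes missing from the matrix are listed in a
    warning and skipped.
    """
    import scipy.sparse as sp

    if layer not in adata.layers:
        raise ValueError(f"layer {layer!r} not found; run normalize_log1p first")
    present = [g for g in genes if g in adata.var_names]
    missing = [g for g in genes if g not in adata.var_names]
    if missing:
        logger.warning("genes not in matrix, skipped: %s", missing)
    if not present:
        raise ValueError("none of the requested genes are in the matrix")
    clone_to_group: Dict[Clonotype, str] = {}
    for group, clones in groups.items():
        for clone in clones:
            clone_to_group[clone] = group
    obs_groups = []
    for bc in adata.obs_names:
        clone = cell_to_clone.get(bc)
        obs_groups.append(clone_to_group.get(clone) if clone is not None else None)
    X = sp.csr_matrix(adata.layers[layer])
    col_idx = [adata.var_names.get_loc(g) for g in present]
    tps = adata.obs[timepoint_key].astype(str).to_numpy()
    rows = []
    group_arr = np.array([g if g is not None else "" for g in obs_groups])
    for group in groups:
        for tp in pd.unique(tps):
            mask = (group_arr == group) & (tps == tp)
            if not mask.any():
                continue
            sub = X[np.where(mask)[0]][:, col_idx]
            means = np.asarray(sub.mean(axis=0)).ravel()
            row = {"group": group, "timepoint": tp, "n_cells": int(mask.sum())}
            row.update(dict(zip(present, means)))
            rows.append(row)
    return pd.DataFrame(rows)


def trajectories_to_frame(trajectories: Sequence[ClonotypeTrajectory]) -> pd.DataFrame:
    """Long-format report: one row per clone with per-timepoint counts/freqs."""
    rows = []
    for t in trajectories:
        row = {"aa_cdr3b": t.clonotype.aa_cdr3b, "compartment": t.compartment,
               "kinetic_class": t.kinetic_class,
               "longevity_class": t.longevity_class}
        for tp in t.timepoints:
            row[f"count_{tp.label}"] = t.counts[tp]
            row[f"freq_{tp.label}"] = t.frequency(tp)
        for tp, q in sorted(t.q_values.items(), key=lambda kv: kv[0].days):
            row[f"q_{tp.label}"] = q
        rows.append(row)
    return pd.DataFrame(rows)
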