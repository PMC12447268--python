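"""Clinical response classification from bone-marrow blast time series.

Implements the trial's modified ELN response rules for AML:

* CR: best (minimum) post-treatment marrow blast fraction < 5%; reported
  as CRi when hematologic recovery (ANC and platelets) is incomplete;
* PR: > 50% blast decrease from baseline with the best value in 5-25%;
* PD: > 50% blast increase over baseline, requiring an absolute increase
  of at least 15 percentage points when baseline blasts are below 30%, or
  marrow blasts persistently above 70% over at least 3 months;
* SD: none of the above.

MLFS and measurable-residual-disease-negative CR are not emitted: marrow
cellularity and MRD assay inputs are outside this package's data model.
Hematologic recovery enters as boolean flags (standard ELN guidance: ANC
>= 1.0 x 10^9/L and platelets >= 100 x 10^9/L) rather than being computed
from blood counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

from .timepoints import Timepoint

RESPONSES = ("CR", "CRi", "PR", "SD", "PD")


@dataclass
class BlastSeries:
    """Per-patient marrow blast percentages (0-100) by timepoint."""

    patient_id: str
    values: Dict[Timepoint, float]

    def __post_init__(self) -> None:
        self.values = {Timepoint.parse(tp): float(v)
                       for tp, v in self.values.items()}
        for tp, v in self.values.items():
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"blast percentage {v} at {tp.label} "
                                 "outside [0, 100]")
        if Timepoint.PRE not in self.values:
            raise ValueError("blast series must include a pre-treatment value")

    @property
    def baseline(self) -> float:
        return self.values[Timepoint.PRE]

    def post(self) -> Dict[Timepoint, float]:
        return {tp: v for tp, v in sorted(self.values.items(),
                                          key=lambda kv: kv[0].days)
                if tp is not Timepoint.PRE}


@dataclass(frozen=True)
class RecoveryFlags:
    """Hematologic recovery status used to split CR from CRi."""

    anc_recovered: bool
    platelets_recovered: bool
    mrd_negative: Optional[bool] = None


def change_from_baseline(series: BlastSeries) -> Dict[Timepoint, float]:
    """Signed relative change (visit - baseline) / baseline per post visit."""
    baseline = series.baseline
    if baseline <= 0:
        raise ValueError("relative change undefined: baseline blast is zero")
    return {tp: (v - baseline) / baseline for tp, v in series.post().items()}


def _is_pd(series: BlastSeries) -> bool:
    baseline = series.baseline
    post = series.post()
    worst_tp = max(post, key=lambda tp: post[tp])
    worst = post[worst_tp]
    if baseline > 0:
        rel_inc = (worst - baseline) / baseline
        abs_inc = worst - baseline
        if rel_inc > 0.5 and (baseline >= 30.0 or abs_inc >= 15.0):
            return True
    # persistent high blast burden: >70% at >=2 post visits spanning >=90 days
    high = [tp for tp, v in post.items() if v > 70.0]
    if len(high) >= 2:
        span = max(tp.days for tp in high) - min(tp.days for tp in high)
        if span >= 90:
            return True
    return False


def classify_eln(series: BlastSeries, flags: Optional[RecoveryFlags] = None) -> str:
    """Best-response class for one patient; precedence CR/CRi > PR > PD > SD.

    The best (minimum) post-treatment blast value drives the remission
    rules and the worst (maximum) drives progression.  ``flags`` are
    required whenever the best value is below 5% (to separate CR from
    CRi); omitting them then is an error rather than a silent guess.
    """
    post = series.post()
    if not post:
        raise ValueError("need at least one post-treatment blast value")
    baseline = series.baseline
    best = min(post.values())
    if best < 5.0:
        if flags is None:
            raise ValueError("best blast < 5%: recovery flags required to "
                             "distinguish CR from CRi")
        if flags.anc_recovered and flags.platelets_recovered:
            return "CR"
        return "CRi"
    if baseline > 0:
        decrease = (baseline - best) / baseline
        if decrease > 0.5 and 5.0 <= best <= 25.0:
            return "PR"
    if _is_pd(series):
        return "PD"
    return "SD"
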