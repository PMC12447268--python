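"""Published immune-monitoring values from the aAVC-WT1 phase I trial.

These are the printed per-patient measurements of the first-in-human
aAVC-WT1 dose-escalation study in relapsed/refractory AML: iNKT and NK
cell abundances at baseline and best response (cells/uL in peripheral
blood; % of CD45-high cells in bone marrow), the published fold-change
values, marrow blast percentages, and the tetramer-assay control
aggregates.  They serve as desk-checkable inputs to the fold-change,
responder-count, summary, threshold, and response-classification
operations.

Transcription note: the cohort-1 PB iNKT fold for patient A002 appears in
print as "(428)" with a dropped decimal point; it is recorded here as
4.28, the value consistent with the printed cohort mean of 2.18 +/- 0.92.
Patient A010's bone-marrow panel was not done (leukopenia), so BM lists
hold eight patients against nine in blood.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

#: Cohort membership (dose level 1, 2, 3).
COHORTS: Dict[int, Tuple[str, ...]] = {
    1: ("A001", "A002", "A003"),
    2: ("A004", "A005", "A006"),
    3: ("A007", "A008", "A010"),
}

#: Published best-response/baseline fold changes per patient.
#: Keys: (analyte, compartment) -> ordered {patient: fold}.
PUBLISHED_FOLDS: Dict[Tuple[str, str], Dict[str, float]] = {
    ("iNKT", "PB"): {
        "A001": 1.83, "A002": 4.28, "A003": 0.42,
        "A004": 12.59, "A005": 0.89, "A006": 0.49,
        "A007": 3.11, "A008": 0.47, "A010": 0.25,
    },
    ("iNKT", "BM"): {
        "A001": 2.28, "A002": 5.71, "A003": 3.48,
        "A004": 4.71, "A005": 1.28, "A006": 0.73,
        "A007": 11.26, "A008": 4.38,
    },
    ("NK", "PB"): {
        "A001": 2.90, "A002": 5.28, "A003": 5.77,
        "A004": 2.38, "A005": 1.06, "A006": 5.42,
        "A007": 1.00, "A008": 0.32, "A010": 2.33,
    },
    ("NK", "BM"): {
        "A001": 0.68, "A002": 1.61, "A003": 2.68,
        "A004": 1.14, "A005": 1.49, "A006": 4.83,
        "A007": 1.44, "A008": 2.97,
    },
}

#: A few printed (pre, post) measurement pairs behind the fold values,
#: used to desk-check the fold computation itself.
MEASUREMENT_PAIRS: Dict[Tuple[str, str, str], Tuple[float, float]] = {
    ("A001", "iNKT", "PB"): (0.06, 0.11),   # cells/uL -> fold 1.83
    ("A002", "NK", "PB"): (5.63, 29.75),    # cells/uL -> fold 5.28
}

#: Marrow blast percentage (baseline, best post-treatment) for the three
#: patients who reached complete remission with incomplete recovery.
CRI_BLAST_PAIRS: Dict[str, Tuple[float, float]] = {
    "A004": (8.96, 1.62),
    "A008": (5.37, 2.56),
    "A010": (14.0, 4.0),
}

#: WT1/HLA-A24:02 tetramer background in control subjects
#: (HLA-A24+ healthy donors and HLA-A24- patients): mean and 2-SD of the
#: negative-control-subtracted tetramer+ CD8 frequency, in percent.
TETRAMER_CONTROL_MEAN: float = 0.081
TETRAMER_CONTROL_TWO_SD: float = 0.167


def folds_for(analyte: str, compartment: str) -> List[float]:
    """Published fold values for one analyte/compartment, patient order."""
    return list(PUBLISHED_FOLDS[(analyte, compartment)].values())


def cohort_folds(analyte: str, compartment: str, cohort: int) -> List[float]:
    """Published fold values restricted to one dose cohort."""
    table = PUBLISHED_FOLDS[(analyte, compartment)]
    return [table[p] for p in COHORTS[cohort] if p in table]
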