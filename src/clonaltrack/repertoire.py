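"""Clonotype data model and repertoire readers/writers.

Two sequencing platforms feed the clone-tracking analysis:

* single-cell V(D)J contig tables (10x ``filtered_contig_annotations.csv``
  dialect) for bone-marrow T cells, where a clone's count is the number of
  cells carrying it; and
* bulk TRB repertoire exports (immunoSEQ-style TSV) for peripheral blood,
  where the count is the number of templates.

Clone identity throughout the package is the amino-acid CDR3 of the TCR
beta chain (aaCDR3b) alone, which is the only key available when matching
bulk blood repertoires against single-cell marrow repertoires.  V/J gene
calls are carried as annotation and never enter equality or hashing.
"""

from __future__ import annotations

import csv
import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Collection, Dict, Iterable, List, NamedTuple, Optional, Sequence

import pandas as pd

from .timepoints import Timepoint

logger = logging.getLogger(__name__)

_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_RE = re.compile(rf"^[{_AA}]+$")


class RepertoireFormatError(ValueError):
    """Raised when an input table violates the expected dialect."""


@dataclass(frozen=True)
class Clonotype:
    """A T-cell clone identified by its TRB amino-acid CDR3.

    Equality and hashing use ``aa_cdr3b`` only; nucleotide sequence and
    V/J annotations are informative metadata.
    """

    aa_cdr3b: str
    nt_cdr3b: Optional[str] = field(default=None, compare=False)
    v_gene: Optional[str] = field(default=None, compare=False)
    j_gene: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        aa = self.aa_cdr3b.strip().upper()
        if not aa:
            raise ValueError("aa_cdr3b must be non-empty")
        if not _AA_RE.match(aa):
            raise ValueError(
                f"aa_cdr3b {self.aa_cdr3b!r} contains characters outside the "
                f"20 amino-acid alphabet")
        object.__setattr__(self, "aa_cdr3b", aa)


class CellChainRecord(NamedTuple):
    """One contig call for one chain in one cell barcode."""

    barcode: str
    chain: str  # "TRA", "TRB", or other
    cdr3_aa: str
    cdr3_nt: str
    productive: bool
    umis: int
    clonotype_id: Optional[str] = None


@dataclass
class RepertoireSample:
    """Clonotype counts for one (patient, compartment, timepoint) sample.

    ``counts`` maps clones to strictly positive integers (cells for
    single-cell data, templates for bulk data); undetected clones are
    absent, never zero.
    """

    patient_id: str
    compartment: str  # "PB" or "BM"
    timepoint: Timepoint
    counts: Dict[Clonotype, int]
    platform: str  # "single_cell" or "bulk"

    def __post_init__(self) -> None:
        if self.compartment not in ("PB", "BM"):
            raise ValueError(f"compartment must be PB or BM, got {self.compartment!r}")
        if self.platform not in ("single_cell", "bulk"):
            raise ValueError(f"platform must be single_cell or bulk, got {self.platform!r}")
        self.timepoint = Timepoint.parse(self.timepoint)
        for clone, k in self.counts.items():
            if k < 1:
                raise ValueError(
                    f"count for {clone.aa_cdr3b} is {k}; undetected clones must "
                    "be absent from the map, not zero")

    @property
    def total(self) -> int:
        """Sample depth: sum of all clone counts."""
        return sum(self.counts.values())

    def frequency(self, clone: Clonotype) -> float:
        total = self.total
        if total == 0:
            return 0.0
        return self.counts.get(clone, 0) / total

    def frequencies(self) -> Dict[Clonotype, float]:
        total = self.total
        return {c: k / total for c, k in self.counts.items()}

    @property
    def clonotypes(self) -> set:
        return set(self.counts)


def _parse_bool(value) -> bool:
    return str(value).strip().lower() == "true"


_SC_REQUIRED = ("barcode", "chain", "cdr3", "productive")
_KNOWN_CHAINS = {"TRA", "TRB"}


def read_cell_chain_records(path) -> List[CellChainRecord]:
    """Parse a 10x-style contig annotation CSV into chain records.

    Rows whose chain is neither TRA nor TRB (e.g. ``Multi``) are skipped
    with a warning.  Quoted fields and extra columns are tolerated.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in _SC_REQUIRED if c not in header]
        if missing:
            raise RepertoireFormatError(
                f"{path}: missing required columns {missing}; found {header}")
        records: List[CellChainRecord] = []
        for row in reader:
            chain = (row.get("chain") or "").strip()
            if chain not in _KNOWN_CHAINS:
                logger.warning("%s: skipping record with unknown chain %r "
                               "(barcode %s)", path.name, chain, row.get("barcode"))
                continue
            try:
                umis = int(row.get("umis") or 0)
            except ValueError:
                umis = 0
            records.append(CellChainRecord(
                barcode=(row.get("barcode") or "").strip(),
                chain=chain,
                cdr3_aa=(row.get("cdr3") or "").strip(),
                cdr3_nt=(row.get("cdr3_nt") or "").strip(),
                productive=_parse_bool(row.get("productive")),
                umis=umis,
                clonotype_id=(row.get("raw_clonotype_id") or None),
            ))
    return records


def read_sc_clonotypes(path, *, patient_id: str, compartment: str,
                       timepoint, cell_filter: Optional[Collection[str]] = None,
                       ) -> RepertoireSample:
    """Build a single-cell repertoire sample from a contig table.

    Policy: a cell contributes through its productive TRB chain only.
    Cells with no productive TRB (TRA-only cells, unproductive cells)
    contribute nothing.  When a barcode carries several productive TRB
    contigs the highest-UMI one defines the cell's clonotype, so each
    contributing barcode is counted exactly once and the sample total
    equals the number of contributing cells.

    Parameters
    ----------
    cell_filter:
        Optional set of barcodes to retain (e.g. barcodes of a CD8
        cluster from the expression analysis); ``None`` keeps all.
    """
    records = read_cell_chain_records(path)
    by_barcode: Dict[str, List[CellChainRecord]] = defaultdict(list)
    for rec in records:
        if cell_filter is not None and rec.barcode not in cell_filter:
            continue
        if rec.chain == "TRB" and rec.productive:
            by_barcode[rec.barcode].append(rec)

    counts: Dict[Clonotype, int] = defaultdict(int)
    for barcode, recs in by_barcode.items():
        # deterministic pick: UMI count first, then lexicographic CDR3
        best = max(recs, key=lambda r: (r.umis, r.cdr3_aa))
        try:
            clone = Clonotype(best.cdr3_aa, nt_cdr3b=best.cdr3_nt or None)
        except ValueError:
            logger.warning("skipping barcode %s: invalid CDR3 %r",
                           barcode, best.cdr3_aa)
            continue
        counts[clone] += 1
    return RepertoireSample(patient_id=patient_id, compartment=compartment,
                            timepoint=timepoint, counts=dict(counts),
                            platform="single_cell")


_BULK_REQUIRED = ("amino_acid", "templates", "frame_type")
_IN_FRAME = {"in", "in-frame", "inframe", "productive"}


def read_bulk_repertoire(path, *, patient_id: str, compartment: str = "PB",
                         timepoint=Timepoint.PRE) -> RepertoireSample:
    """Read an immunoSEQ-style TSV into a bulk repertoire sample.

    Only in-frame (productive) rearrangements are retained; rows sharing
    an amino-acid CDR3 are merged by summing templates, so the analysis
    operates at aaCDR3b resolution with nucleotide-level multiplicity
    collapsed.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _BULK_REQUIRED if c not in df.columns]
    if missing:
        raise RepertoireFormatError(
            f"{path}: missing required columns {missing}; found {list(df.columns)}")
    counts: Dict[Clonotype, int] = defaultdict(int)
    for _, row in df.iterrows():
        frame = str(row["frame_type"]).strip().lower()
        if frame not in _IN_FRAME:
            continue
        templates = int(float(row["templates"]))
        if templates < 0:
            raise RepertoireFormatError(
                f"{path}: negative template count {templates} for "
                f"{row['amino_acid']!r}")
        if templates == 0:
            continue
        aa = str(row["amino_acid"]).strip()
        if not aa or aa.lower() == "nan":
            continue
        try:
            clone = Clonotype(aa)
        except ValueError:
            logger.warning("%s: skipping row with invalid amino-acid CDR3 %r",
                           path.name, aa)
            continue
        counts[clone] += templates
    return RepertoireSample(patient_id=patient_id, compartment=compartment,
                            timepoint=timepoint, counts=dict(counts),
                            platform="bulk")


class TcrAssignmentStats(NamedTuple):
    frac_trb_only: float
    frac_tra_only: float
    frac_both: float


def tcr_assignment_stats(records: Iterable[CellChainRecord]) -> TcrAssignmentStats:
    """Fractions of TCR-bearing cells assigned TRB only / TRA only / both.

    Only barcodes with at least one productive TRA or TRB chain count as
    "cells with TCR".  Raises ``ValueError`` when no such barcode exists
    (the fractions would be 0/0).
    """
    chains_by_barcode: Dict[str, set] = defaultdict(set)
    for rec in records:
        if rec.productive and rec.chain in _KNOWN_CHAINS:
            chains_by_barcode[rec.barcode].add(rec.chain)
    n = len(chains_by_barcode)
    if n == 0:
        raise ValueError("no barcodes with a productive TCR chain; "
                         "assignment fractions are undefined")
    trb_only = sum(1 for ch in chains_by_barcode.values() if ch == {"TRB"})
    tra_only = sum(1 for ch in chains_by_barcode.values() if ch == {"TRA"})
    both = sum(1 for ch in chains_by_barcode.values() if ch == {"TRA", "TRB"})
    return TcrAssignmentStats(trb_only / n, tra_only / n, both / n)


_CLONE_TABLE_COLUMNS = ["patient", "compartment", "timepoint", "platform",
                        "aa_cdr3b", "count", "frequency"]


def write_clone_table(samples: Sequence[RepertoireSample], path) -> None:
    """Write samples as a long-format TSV round-trippable by ``read_clone_table``."""
    rows = []
    for sample in samples:
        total = sample.total
        for clone in sorted(sample.counts, key=lambda c: c.aa_cdr3b):
            k = sample.counts[clone]
            rows.append({
                "patient": sample.patient_id,
                "compartment": sample.compartment,
                "timepoint": sample.timepoint.label,
                "platform": sample.platform,
                "aa_cdr3b": clone.aa_cdr3b,
                "count": k,
                "frequency": k / total,
            })
    df = pd.DataFrame(rows, columns=_CLONE_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_clone_table(path) -> List[RepertoireSample]:
    """Inverse of :func:`write_clone_table` (counts preserved exactly)."""
    df = pd.read_csv(path, sep="\t", dtype={"patient": str})
    missing = [c for c in _CLONE_TABLE_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise RepertoireFormatError(f"{path}: missing columns {missing}")
    samples = []
    keys = ["patient", "compartment", "timepoint", "platform"]
    for (patient, compartment, timepoint, platform), grp in df.groupby(keys, sort=True):
        counts = {Clonotype(aa): int(k)
                  for aa, k in zip(grp["aa_cdr3b"], grp["count"])}
        samples.append(RepertoireSample(
            patient_id=str(patient), compartment=compartment,
            timepoint=timepoint, counts=counts, platform=platform))
    return samples
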