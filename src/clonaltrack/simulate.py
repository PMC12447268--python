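"""Synthetic longitudinal trial data with known ground truth.

Generates the paired data kinds the analysis consumes — longitudinal
marrow (single-cell) and blood (bulk) TRB repertoires with planted
expanded/contracted/new clones, cluster-structured single-cell expression
with planted phenotypes and quality defects, innate-cell assay series
with planted fold effects, and marrow blast trajectories realizing known
response classes — so every pipeline stage is testable without access to
patient sequencing data.

Repertoire model
----------------
Baseline clone frequencies are drawn from a symmetric Dirichlet over
``n_clones`` clones.  Post-treatment frequencies multiply planted clones
by their fold (expansion) or its inverse (contraction) and renormalize;
"new" clones are absent at baseline and appear at the day-14 visit at a
fixed frequency, transient ones vanishing afterwards and stable ones
persisting through day 42.  Each sample is an independent multinomial
draw at ``depth_per_sample``.  The default Dirichlet concentration (5) is
chosen so baseline clones are reliably detectable at the design depth of
10,000; real repertoires carry a long tail of rare clones whose sampling
noise produces apparent one-off "new" clones, a feature deliberately not
emulated here (see the methods note).

Expression model
----------------
Cells belong to planted phenotype clusters; counts are negative binomial
around gene base means, with each cluster's marker genes shifted up by a
multiplicative fold.  Recirculation markers (the negative
tissue-residency signature) are expressed by naive and effector clusters
but not by the resident-memory cluster, and exhaustion markers are
moderately elevated in the precursor-exhausted and resident-memory
clusters with a strongly exhausted cluster carrying the full shift.
Mitochondrial genes receive per-cluster mean fractions; planted
low-quality cells (high mitochondrial fraction or shallow libraries)
exercise the QC filters.

A single integer seed drives a hierarchical ``numpy`` seed sequence, so
the repertoire, expression, and clinical streams are independently
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .kinetics import MeasurementSeries
from .repertoire import Clonotype, RepertoireSample
from .response import BlastSeries, RecoveryFlags
from .signatures import default_signatures, all_signature_genes
from .timepoints import Timepoint

_AA = "ACDEFGHIKLMNPQRSTVWY"
_MITO_GENES = ("MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6",
               "MT-CO3", "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6",
               "MT-CYB")


@dataclass(frozen=True)
class ClusterSpec:
    """One planted cell cluster: phenotype, size, marker shift, mito level."""

    phenotype: str
    n_cells: int = 40
    marker_fold: float = 6.0
    mito_mean: float = 0.05


def default_cluster_spec() -> Tuple[ClusterSpec, ...]:
    """Seven annotatable phenotypes plus one terminally exhausted cluster
    (truth label ``unclassified``: it matches no marker rule)."""
    return (
        ClusterSpec("FGFBP2_TEFF"),
        ClusterSpec("IFN_TEFF"),
        ClusterSpec("TPEX"),
        ClusterSpec("preexhausted_TRM"),
        ClusterSpec("TREG"),
        ClusterSpec("TN"),
        ClusterSpec("TFH_like"),
        ClusterSpec("unclassified"),
    )


@dataclass
class SimulationParams:
    """Knobs of the generator; defaults are the package's study conditions."""

    seed: int = 0
    patient_id: str = "P001"
    timepoints: Tuple[str, ...] = ("pre", "d14", "d42", "m6", "m12")
    # repertoire
    n_clones: int = 200
    depth_per_sample: int = 10_000
    base_concentration: float = 5.0
    n_inc: int = 15
    inc_fold: float = 5.0
    n_dec: int = 15
    dec_fold: float = 5.0
    n_new_transient: int = 8
    n_new_stable: int = 8
    new_clone_freq: float = 2e-3
    new_start: str = "d14"
    min_planted_baseline_copies: int = 10
    shared_fraction: float = 0.7
    # expression
    cluster_spec: Tuple[ClusterSpec, ...] = field(default_factory=default_cluster_spec)
    n_filler_genes: int = 340
    base_gene_mean: float = 3.0
    nb_dispersion: float = 0.5
    n_high_mito_cells: int = 6
    high_mito_mean: float = 0.18
    n_shallow_cells: int = 6
    shallow_scale: float = 0.15
    # clinical
    assay_noise_sigma: float = 0.2

    def __post_init__(self) -> None:
        if self.inc_fold <= 0 or self.dec_fold <= 0:
            raise ValueError("planted folds must be positive")
        if self.n_inc + self.n_dec > self.n_clones:
            raise ValueError("planted Inc/Dec counts exceed n_clones")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must be in [0, 1]")
        if self.new_start not in self.timepoints:
            raise ValueError("new_start must be one of the timepoints")

    def streams(self) -> Dict[str, np.random.Generator]:
        """Named, independent generator streams derived from the one seed."""
        root = np.random.SeedSequence(self.seed)
        names = ("repertoire", "pb", "expression", "clinical")
        children = root.spawn(len(names))
        return {name: np.random.default_rng(child)
                for name, child in zip(names, children)}


@dataclass
class GroundTruth:
    """Planted truth tables, keyed the way the analysis reports are."""

    clones: pd.DataFrame        # aa_cdr3b, kinetic_class, longevity_class, shared
    cells: pd.DataFrame         # barcode, phenotype, cluster
    clinical: pd.DataFrame      # patient, response, analyte folds


def _unique_cdr3s(rng: np.random.Generator, n: int) -> List[str]:
    """Synthetic but format-realistic aaCDR3b strings: CASS + 6-10 residues."""
    seen, out = set(), []
    while len(out) < n:
        length = int(rng.integers(6, 11))
        suffix = "".join(rng.choice(list(_AA), size=length))
        cdr3 = "CASS" + suffix
        if cdr3 not in seen:
            seen.add(cdr3)
            out.append(cdr3)
    return out


def generate_repertoire(params: SimulationParams,
                        ) -> Tuple[Dict[Tuple[str, str], RepertoireSample], pd.DataFrame]:
    """Emit repertoire samples per (compartment, timepoint) plus clone truth.

    Marrow samples are ``single_cell`` platform, blood samples ``bulk``;
    planted dynamics (Inc/Dec/new) act in the marrow compartment, and a
    ``shared_fraction`` of marrow base clones also seeds the blood
    repertoire.
    """
    streams = params.streams()
    rng = streams["repertoire"]
    tps = [Timepoint.parse(tp) for tp in params.timepoints]
    n_new = params.n_new_transient + params.n_new_stable
    names = _unique_cdr3s(rng, params.n_clones + n_new)
    base_names = names[:params.n_clones]
    new_names = names[params.n_clones:]

    baseline = rng.dirichlet([params.base_concentration] * params.n_clones)
    min_freq = params.min_planted_baseline_copies / params.depth_per_sample
    eligible = np.where(baseline >= min_freq)[0]
    if len(eligible) < params.n_inc + params.n_dec:
        raise ValueError(
            f"only {len(eligible)} clones reach the minimum planted baseline "
            f"of {params.min_planted_baseline_copies} copies; lower the "
            "planted counts or raise base_concentration")
    # Planted truth must be self-consistent: only planted clones may change
    # in relative frequency.  Contractions are planted on the largest
    # eligible clones and expansions on the smallest, so the frequency mass
    # gained by expansions approximately equals the mass lost by
    # contractions ((fold-1) * m_inc ~ (1-1/fold) * m_dec) and the
    # renormalization leaves unplanted clones essentially unchanged.
    # Biologically this mirrors vaccine-responsive clones starting rare and
    # receding dominant clones being large.
    by_size = eligible[np.argsort(baseline[eligible])]
    inc_idx = set(by_size[:params.n_inc].tolist())
    dec_idx = set(by_size[::-1][:params.n_dec].tolist())

    start = Timepoint.parse(params.new_start)
    stable_end = Timepoint.D42 if Timepoint.D42 in tps else tps[-1]
    freq_rows = {}
    for tp in tps:
        freqs = baseline.copy()
        if tp is not Timepoint.PRE:
            for i in inc_idx:
                freqs[i] *= params.inc_fold
            for i in dec_idx:
                freqs[i] /= params.dec_fold
        new_freqs = np.zeros(n_new)
        for j in range(n_new):
            transient = j < params.n_new_transient
            if transient:
                present = tp is start
            else:
                present = start.days <= tp.days <= stable_end.days
            if present:
                new_freqs[j] = params.new_clone_freq
        full = np.concatenate([freqs, new_freqs])
        freq_rows[tp] = full / full.sum()

    # ground truth for the marrow compartment
    kinetic = []
    for i in range(params.n_clones):
        kinetic.append("Inc" if i in inc_idx else "Dec" if i in dec_idx
                       else "Unchanged")
    kinetic += (["New_transient"] * params.n_new_transient +
                ["New_stable"] * params.n_new_stable)
    longevity = (["long_lived"] * params.n_clones +
                 ["transient"] * params.n_new_transient +
                 ["medium_lived" if stable_end.days < Timepoint.M6.days
                  else "long_lived"] * params.n_new_stable)

    n_shared = int(round(params.shared_fraction * params.n_clones))
    shared_ids = set(rng.choice(params.n_clones, size=n_shared, replace=False).tolist())

    samples: Dict[Tuple[str, str], RepertoireSample] = {}
    all_names = base_names + new_names
    for tp in tps:
        counts = rng.multinomial(params.depth_per_sample, freq_rows[tp])
        cmap = {Clonotype(all_names[i]): int(c)
                for i, c in enumerate(counts) if c > 0}
        samples[("BM", tp.label)] = RepertoireSample(
            patient_id=params.patient_id, compartment="BM", timepoint=tp,
            counts=cmap, platform="single_cell")

    # blood: shared marrow clones plus blood-private clones, static over time
    pb_rng = streams["pb"]
    n_private = params.n_clones - n_shared
    private_names = _unique_cdr3s(pb_rng, n_private * 2)
    private_names = [nm for nm in private_names if nm not in set(all_names)][:n_private]
    pb_names = [base_names[i] for i in sorted(shared_ids)] + private_names
    pb_freqs = pb_rng.dirichlet([params.base_concentration] * len(pb_names))
    for tp in tps:
        counts = pb_rng.multinomial(params.depth_per_sample, pb_freqs)
        cmap = {Clonotype(pb_names[i]): int(c)
                for i, c in enumerate(counts) if c > 0}
        samples[("PB", tp.label)] = RepertoireSample(
            patient_id=params.patient_id, compartment="PB", timepoint=tp,
            counts=cmap, platform="bulk")

    truth = pd.DataFrame({
        "aa_cdr3b": all_names,
        "kinetic_class": kinetic,
        "longevity_class": longevity,
        "shared": [i in shared_ids for i in range(params.n_clones)] + [False] * n_new,
    })
    return samples, truth


# ---------------------------------------------------------------------------
# Expression

def _gene_panel(params: SimulationParams) -> Tuple[List[str], Dict[str, List[str]]]:
    signatures = default_signatures()
    sig_genes = all_signature_genes(signatures)
    fillers = [f"FILLER{i:04d}" for i in range(params.n_filler_genes)]
    genes = sig_genes + fillers + list(_MITO_GENES)
    return genes, {name: list(sig.genes) for name, sig in signatures.items()}


#: Which signatures each planted phenotype shifts, with a relative strength
#: (1.0 = the cluster's full marker fold, fractions soften the shift).
_PHENOTYPE_PROGRAM: Dict[str, Dict[str, float]] = {
    "FGFBP2_TEFF": {"cytotoxic": 1.0, "TRM_neg": 1.0},
    "IFN_TEFF": {"IFN_response": 1.0, "cytotoxic": 0.3, "TRM_neg": 1.0},
    "TPEX": {"TPEX": 1.0, "exhaustion": 0.5},
    "preexhausted_TRM": {"TRM_pos": 1.0, "exhaustion": 0.5},
    "TREG": {"Treg": 1.0},
    "TN": {"TN": 1.0, "TRM_neg": 1.0},
    "TFH_like": {"TFH": 1.0},
    "unclassified": {"exhaustion": 1.0},  # terminal exhaustion: no rule matches
}


def generate_expression(params: SimulationParams,
                        clone_assignment: Optional[Mapping[str, str]] = None,
                        ) -> Tuple[ad.AnnData, pd.DataFrame]:
    """Cluster-structured counts with planted phenotypes and QC defects.

    Returns a cells x genes AnnData (raw counts in ``.X``; obs columns
    patient, compartment, timepoint, cluster, and ``aa_cdr3b`` when
    ``clone_assignment`` maps barcodes to clones) plus a per-cell truth
    table (barcode, cluster, phenotype; planted low-quality cells carry
    phenotype ``low_quality``).
    """
    rng = params.streams()["expression"]
    genes, sig_map = _gene_panel(params)
    for spec in params.cluster_spec:
        if spec.phenotype not in _PHENOTYPE_PROGRAM:
            raise ValueError(f"unknown phenotype {spec.phenotype!r}")
    n_genes = len(genes)
    gene_idx = {g: i for i, g in enumerate(genes)}
    base_means = rng.gamma(shape=2.0, scale=params.base_gene_mean / 2.0,
                           size=n_genes)
    base_means = np.clip(base_means, 0.05, None)
    mito_cols = np.array([gene_idx[g] for g in _MITO_GENES])
    nonmito_total = base_means.sum() - base_means[mito_cols].sum()
    mito_weights = rng.dirichlet([5.0] * len(_MITO_GENES))

    r = 1.0 / params.nb_dispersion  # NB size parameter; var = m + disp * m^2
    rows, barcodes, clusters, phenos = [], [], [], []
    tps = list(params.timepoints)
    cell_no = 0

    def sample_cells(mean_vec: np.ndarray, n_cells: int) -> np.ndarray:
        p = r / (r + mean_vec)
        return rng.negative_binomial(r, p, size=(n_cells, len(mean_vec)))

    for ci, spec in enumerate(params.cluster_spec):
        means = base_means.copy()
        for sig_name, strength in _PHENOTYPE_PROGRAM[spec.phenotype].items():
            fold = spec.marker_fold ** strength
            for g in sig_map[sig_name]:
                means[gene_idx[g]] *= fold
        mito_total = spec.mito_mean / (1.0 - spec.mito_mean) * nonmito_total
        means[mito_cols] = mito_total * mito_weights
        rows.append(sample_cells(means, spec.n_cells))
        for _ in range(spec.n_cells):
            barcodes.append(f"BC{cell_no:05d}")
            clusters.append(f"C{ci + 1}")
            phenos.append(spec.phenotype)
            cell_no += 1

    # planted low-quality cells, appended to the first cluster's label so
    # they sit inside an otherwise healthy cluster
    defect_means = base_means.copy()
    mito_total = params.high_mito_mean / (1.0 - params.high_mito_mean) * nonmito_total
    defect_means[mito_cols] = mito_total * mito_weights
    if params.n_high_mito_cells:
        rows.append(sample_cells(defect_means, params.n_high_mito_cells))
        for _ in range(params.n_high_mito_cells):
            barcodes.append(f"BC{cell_no:05d}")
            clusters.append("C1")
            phenos.append("low_quality")
            cell_no += 1
    if params.n_shallow_cells:
        shallow = base_means * params.shallow_scale
        mito_total = 0.05 / 0.95 * nonmito_total * params.shallow_scale
        shallow[mito_cols] = mito_total * mito_weights
        rows.append(sample_cells(shallow, params.n_shallow_cells))
        for _ in range(params.n_shallow_cells):
            barcodes.append(f"BC{cell_no:05d}")
            clusters.append("C1")
            phenos.append("low_quality")
            cell_no += 1

    X = sp.csr_matrix(np.vstack(rows).astype(np.int64))
    n_cells = X.shape[0]
    timepoint_col = [tps[i % len(tps)] for i in range(n_cells)]
    obs = pd.DataFrame({
        "patient": params.patient_id,
        "compartment": "BM",
        "timepoint": timepoint_col,
        "cluster": clusters,
    }, index=pd.Index(barcodes, name="barcode"))
    if clone_assignment is not None:
        obs["aa_cdr3b"] = [clone_assignment.get(bc) for bc in barcodes]
    adata = ad.AnnData(X=X, obs=obs,
                       var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    truth = pd.DataFrame({"barcode": barcodes, "cluster": clusters,
                          "phenotype": phenos})
    return adata, truth


def generate_clone_linked_expression(params: SimulationParams,
                                     clone_truth: pd.DataFrame,
                                     cells_per_clone: int = 3,
                                     ) -> Tuple[ad.AnnData, Dict[str, Clonotype]]:
    """Expression for cells of planted Inc/Dec/new clones at pre and day 14.

    Inc-clone cells upregulate cytotoxic markers at day 14 while Dec-clone
    cells carry the exhaustion program throughout, emulating the
    reinvigoration contrast the clone-group expression summary reads out.
    Returns the AnnData plus the barcode -> clonotype map.
    """
    rng = params.streams()["expression"]
    genes, sig_map = _gene_panel(params)
    gene_idx = {g: i for i, g in enumerate(genes)}
    base_means = np.clip(rng.gamma(2.0, params.base_gene_mean / 2.0, len(genes)),
                         0.05, None)
    r = 1.0 / params.nb_dispersion

    groups = {
        "Inc": clone_truth.loc[clone_truth.kinetic_class == "Inc", "aa_cdr3b"],
        "Dec": clone_truth.loc[clone_truth.kinetic_class == "Dec", "aa_cdr3b"],
        "New_stable": clone_truth.loc[clone_truth.kinetic_class == "New_stable",
                                      "aa_cdr3b"],
    }
    rows, barcodes, tp_col, cell_to_clone = [], [], [], {}
    cell_no = 0
    for group, clones in groups.items():
        for aa in clones:
            for tp in ("pre", "d14"):
                if group == "New_stable" and tp == "pre":
                    continue  # new clones have no pre-treatment cells
                means = base_means.copy()
                if group == "Inc" and tp == "d14":
                    for g in sig_map["cytotoxic"]:
                        means[gene_idx[g]] *= 6.0
                if group == "Dec":
                    for g in sig_map["exhaustion"]:
                        means[gene_idx[g]] *= 6.0
                p = r / (r + means)
                rows.append(rng.negative_binomial(
                    r, p, size=(cells_per_clone, len(genes))))
                for _ in range(cells_per_clone):
                    bc = f"LBC{cell_no:05d}"
                    barcodes.append(bc)
                    tp_col.append(tp)
                    cell_to_clone[bc] = Clonotype(aa)
                    cell_no += 1
    X = sp.csr_matrix(np.vstack(rows).astype(np.int64))
    obs = pd.DataFrame({"patient": params.patient_id, "compartment": "BM",
                        "timepoint": tp_col, "cluster": "C1"},
                       index=pd.Index(barcodes, name="barcode"))
    adata = ad.AnnData(X=X, obs=obs,
                       var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    return adata, cell_to_clone


# ---------------------------------------------------------------------------
# Clinical

#: Planted patients: response class, marrow blast trajectory (percent),
#: and true iNKT / NK fold effects.
_DEFAULT_BLAST_SPEC = {
    "P001": ("CRi", {"pre": 9.0, "d14": 4.0, "d28": 1.6, "d42": 2.2, "d56": 2.8},
             3.0, 2.5),
    "P002": ("PR", {"pre": 39.0, "d14": 24.0, "d28": 15.0, "d42": 18.0},
             2.0, 1.8),
    "P003": ("SD", {"pre": 20.0, "d14": 18.0, "d28": 26.0, "d42": 32.0},
             1.1, 1.0),
    "P004": ("PD", {"pre": 20.0, "d14": 28.0, "d28": 36.0},
             0.8, 0.9),
}


def generate_clinical(params: SimulationParams,
                      blast_spec: Optional[dict] = None,
                      ) -> Tuple[Dict[str, BlastSeries], Dict[str, RecoveryFlags],
                                 List[MeasurementSeries], pd.DataFrame]:
    """Blast series realizing known response classes plus assay series.

    Blast trajectories are deterministic (their class is a closure
    property of the response rules); iNKT/NK series apply the planted
    fold at day 14 with multiplicative lognormal noise of width
    ``assay_noise_sigma`` (0 gives exact folds).
    """
    rng = params.streams()["clinical"]
    spec = blast_spec if blast_spec is not None else _DEFAULT_BLAST_SPEC
    blasts, flags, series, truth_rows = {}, {}, [], []
    for patient, (response, traj, inkt_fold, nk_fold) in spec.items():
        for v in traj.values():
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"blast value {v} outside [0, 100]")
        blasts[patient] = BlastSeries(patient_id=patient, values=dict(traj))
        flags[patient] = RecoveryFlags(anc_recovered=False,
                                       platelets_recovered=True)
        for analyte, fold, pre_value in (("iNKT", inkt_fold, 0.05),
                                         ("NK", nk_fold, 60.0)):
            noise = (float(np.exp(rng.normal(0.0, params.assay_noise_sigma)))
                     if params.assay_noise_sigma > 0 else 1.0)
            series.append(MeasurementSeries(
                patient_id=patient, compartment="PB", analyte=analyte,
                unit="cells_per_uL",
                values={"pre": pre_value, "d14": pre_value * fold * noise}))
        truth_rows.append({"patient": patient, "response": response,
                           "inkt_fold": inkt_fold, "nk_fold": nk_fold})
    return blasts, flags, series, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Dataset emission in the on-disk formats the readers consume

def _write_contig_csv(sample: RepertoireSample, path: Path,
                      rng: np.random.Generator) -> None:
    """Contig-table CSV for a single-cell sample: one productive TRB row per
    cell, plus a few TRA-only and unproductive decoy rows the reader must
    ignore."""
    nt = {"A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
          "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
          "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
          "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT"}
    lines = ["barcode,is_cell,chain,v_gene,j_gene,cdr3,cdr3_nt,productive,umis,raw_clonotype_id"]
    cell_no = 0
    prefix = f"{sample.compartment.lower()}-{sample.timepoint.label}"
    for ci, clone in enumerate(sorted(sample.counts, key=lambda c: c.aa_cdr3b)):
        cdr3_nt = "".join(nt[a] for a in clone.aa_cdr3b)
        for _ in range(sample.counts[clone]):
            bc = f"{prefix}-{cell_no:05d}"
            umis = int(rng.integers(2, 40))
            lines.append(f"{bc},True,TRB,TRBV19,TRBJ2-1,{clone.aa_cdr3b},"
                         f"{cdr3_nt},True,{umis},clonotype{ci + 1}")
            cell_no += 1
    for j in range(5):  # TRA-only cells: no productive TRB, must not count
        bc = f"{prefix}-tra-{j:03d}"
        lines.append(f"{bc},True,TRA,TRAV12,TRAJ33,CAVNARLMF,"
                     f"TGTGCTGTGAATGCAAGACTCATGTTT,True,{int(rng.integers(2, 20))},")
    for j in range(3):  # unproductive TRB rows, must not count
        bc = f"{prefix}-np-{j:03d}"
        lines.append(f"{bc},True,TRB,TRBV19,TRBJ2-1,CASSNPF,TGCGCTAGCTCTAATCCTTTT,"
                     f"False,{int(rng.integers(2, 20))},")
    path.write_text("\n".join(lines) + "\n")


def _write_bulk_tsv(sample: RepertoireSample, path: Path) -> None:
    lines = ["rearrangement\tamino_acid\ttemplates\tframe_type"]
    nt_stub = "TGTGCCAGCAGT"
    for clone in sorted(sample.counts, key=lambda c: c.aa_cdr3b):
        lines.append(f"{nt_stub}{clone.aa_cdr3b}\t{clone.aa_cdr3b}\t"
                     f"{sample.counts[clone]}\tIn")
    lines.append(f"{nt_stub}STOP\tCASSX*F\t7\tOut")  # out-of-frame decoy
    path.write_text("\n".join(lines) + "\n")


def write_dataset(outdir, params: SimulationParams) -> Dict[str, object]:
    """Generate everything and write it in reader-consumable formats.

    Layout under ``outdir``: ``repertoire/`` contig CSVs (marrow) and bulk
    TSVs (blood); ``expression/`` Matrix-Market triplet + features +
    barcodes + cell metadata; ``assays.tsv``, ``blast.tsv``, ``flags.tsv``;
    ``truth_*.tsv`` tables; ``manifest.json`` with all parameters.
    Returns the in-memory artifacts for callers that want them.
    """
    outdir = Path(outdir)
    (outdir / "repertoire").mkdir(parents=True, exist_ok=True)
    (outdir / "expression").mkdir(parents=True, exist_ok=True)
    io_rng = np.random.default_rng(np.random.SeedSequence(params.seed).spawn(5)[-1])

    samples, clone_truth = generate_repertoire(params)
    for (compartment, tp), sample in sorted(samples.items()):
        if sample.platform == "single_cell":
            _write_contig_csv(sample, outdir / "repertoire" /
                              f"{compartment.lower()}_{tp}_contigs.csv", io_rng)
        else:
            _write_bulk_tsv(sample, outdir / "repertoire" /
                            f"{compartment.lower()}_{tp}_bulk.tsv")

    adata, cell_truth = generate_expression(params)
    scipy.io.mmwrite(str(outdir / "expression" / "matrix.mtx"),
                     sp.csr_matrix(adata.X).T.tocoo(), field="integer")
    (outdir / "expression" / "features.tsv").write_text(
        "\n".join(adata.var_names) + "\n")
    (outdir / "expression" / "barcodes.tsv").write_text(
        "\n".join(adata.obs_names) + "\n")
    adata.obs.reset_index().rename(columns={"index": "barcode"}).to_csv(
        outdir / "expression" / "cell_meta.tsv", sep="\t", index=False)

    blasts, flags, series, clinical_truth = generate_clinical(params)
    assay_rows = []
    for s in series:
        for tp, v in sorted(s.values.items(), key=lambda kv: kv[0].days):
            assay_rows.append({"patient": s.patient_id, "compartment": s.compartment,
                               "analyte": s.analyte, "unit": s.unit,
                               "timepoint": tp.label, "value": v})
    pd.DataFrame(assay_rows).to_csv(outdir / "assays.tsv", sep="\t", index=False)
    blast_rows = [{"patient": b.patient_id, "timepoint": tp.label,
                   "blast_percent": v}
                  for b in blasts.values()
                  for tp, v in sorted(b.values.items(), key=lambda kv: kv[0].days)]
    pd.DataFrame(blast_rows).to_csv(outdir / "blast.tsv", sep="\t", index=False)
    flag_rows = [{"patient": p, "anc_recovered": f.anc_recovered,
                  "platelets_recovered": f.platelets_recovered}
                 for p, f in flags.items()]
    pd.DataFrame(flag_rows).to_csv(outdir / "flags.tsv", sep="\t", index=False)

    clone_truth.to_csv(outdir / "truth_clones.tsv", sep="\t", index=False)
    cell_truth.to_csv(outdir / "truth_cells.tsv", sep="\t", index=False)
    clinical_truth.to_csv(outdir / "truth_clinical.tsv", sep="\t", index=False)

    manifest = {"seed": params.seed, "params": _params_dict(params)}
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {"samples": samples, "clone_truth": clone_truth, "adata": adata,
            "cell_truth": cell_truth, "blasts": blasts, "flags": flags,
            "series": series, "clinical_truth": clinical_truth}


def _params_dict(params: SimulationParams) -> dict:
    d = asdict(params)
    d["cluster_spec"] = [asdict(c) if not isinstance(c, dict) else c
                         for c in d["cluster_spec"]]
    return d


def null_params(seed: int, **overrides) -> SimulationParams:
    """Parameters with no planted repertoire effects (null model)."""
    defaults = dict(seed=seed, n_inc=0, n_dec=0, n_new_transient=0,
                    n_new_stable=0)
    defaults.update(overrides)
    return SimulationParams(**defaults)
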