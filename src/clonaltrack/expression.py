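"""Single-cell expression QC, cluster profiling, and phenotype annotation.

The container is an :class:`anndata.AnnData` with cells as rows and genes
as columns, loaded from a Matrix-Market triplet plus feature/barcode files
(Cell Ranger layout: features x barcodes, transposed on load).  Upstream
graph clustering is out of scope; cluster labels arrive as a metadata
column and this module characterizes those clusters:

1. quality filtering on genes-per-cell and mitochondrial UMI fraction;
2. library-size normalization to 10,000 counts and log1p;
3. per-cluster mean expression pooled over all timepoints, per-timepoint
   cluster frequencies;
4. signature scoring and cross-labeling, either by correlation against
   reference cluster centroids or by ordered marker rules operating on
   z-scored signature levels.

"High"/"low" marker levels in the published cluster descriptions are
qualitative; they are operationalized here as z-scores of signature
scores across a patient's clusters (high >= +0.5, low <= -0.5).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from typing import Dict, Iterable, List, Optional, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .signatures import GeneSignature

logger = logging.getLogger(__name__)


class EmptyMatrixError(ValueError):
    """QC removed every cell (or gene) from the matrix."""


@dataclass(frozen=True)
class QCParams:
    """Cell- and gene-level quality thresholds.

    Defaults mirror standard droplet scRNA-seq practice: drop cells with
    fewer than 200 detected genes or more than 10% mitochondrial UMIs,
    then drop genes expressed in at most 0.1% of the remaining cells.
    """

    min_genes_per_cell: int = 200
    max_mito_fraction: float = 0.10
    min_gene_prevalence: float = 0.001
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must be within [0, 1]")
        if self.min_genes_per_cell < 0:
            raise ValueError("min_genes_per_cell must be >= 0")


def read_expression(matrix_path, features_path, barcodes_path,
                    cell_meta_path=None) -> ad.AnnData:
    """Load a Matrix-Market count triplet into cells x genes AnnData.

    The matrix file is features x barcodes (Cell Ranger convention) and is
    transposed on load.  ``cell_meta_path`` is an optional TSV with a
    ``barcode`` column plus per-cell metadata (patient, compartment,
    timepoint, cluster) merged into ``.obs``.
    """
    mat = scipy.io.mmread(str(matrix_path)).tocsr().astype(np.int64)
    features = pd.read_csv(features_path, sep="\t", header=None).iloc[:, 0].astype(str)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None).iloc[:, 0].astype(str)
    if mat.shape != (len(features), len(barcodes)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match features x barcodes "
            f"({len(features)}, {len(barcodes)})")
    if features.duplicated().any():
        raise ValueError("gene names are not unique")
    adata = ad.AnnData(X=mat.T.tocsr(),
                       obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
                       var=pd.DataFrame(index=pd.Index(features, name="gene")))
    if cell_meta_path is not None:
        meta = pd.read_csv(cell_meta_path, sep="\t", dtype=str)
        if "barcode" not in meta.columns:
            raise ValueError(f"{cell_meta_path}: cell metadata needs a 'barcode' column")
        meta = meta.set_index("barcode")
        adata.obs = adata.obs.join(meta, how="left")
    return adata


def _cell_qc_metrics(adata: ad.AnnData, mito_prefix: str):
    X = sp.csr_matrix(adata.X)
    n_genes = (X > 0).sum(axis=1).A1
    total = np.asarray(X.sum(axis=1)).ravel()
    mito_mask = adata.var_names.str.startswith(mito_prefix)
    if mito_mask.any():
        mito = np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
    else:
        mito = np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    return n_genes, mito_frac


def qc_filter(adata: ad.AnnData, params: QCParams = QCParams()) -> ad.AnnData:
    """Remove low-quality cells, then rarely expressed genes.

    Cell filtering (genes detected, mitochondrial fraction) and gene
    prevalence filtering are alternated until a fixed point, so the
    returned matrix satisfies all thresholds simultaneously and the
    operation is idempotent.  Cell and gene order is preserved.
    """
    out = adata
    while True:
        n_genes, mito_frac = _cell_qc_metrics(out, params.mito_prefix)
        keep_cells = (n_genes >= params.min_genes_per_cell) & \
                     (mito_frac <= params.max_mito_fraction)
        if keep_cells.sum() == 0:
            raise EmptyMatrixError(
                "QC removed all cells (min_genes_per_cell="
                f"{params.min_genes_per_cell}, max_mito_fraction="
                f"{params.max_mito_fraction})")
        out = out[keep_cells].copy() if not keep_cells.all() else out
        X = sp.csc_matrix(out.X)
        prevalence = (X > 0).sum(axis=0).A1
        keep_genes = prevalence > params.min_gene_prevalence * out.n_obs
        if keep_genes.sum() == 0:
            raise EmptyMatrixError("QC removed all genes")
        changed_genes = not keep_genes.all()
        if changed_genes:
            out = out[:, keep_genes].copy()
        if keep_cells.all() and not changed_genes:
            break
    n_genes, mito_frac = _cell_qc_metrics(out, params.mito_prefix)
    out.obs["n_genes"] = n_genes
    out.obs["mito_frac"] = mito_frac
    return out


def normalize_log1p(adata: ad.AnnData, target_sum: float = 1e4,
                    layer: str = "lognorm") -> ad.AnnData:
    """Scale each cell to ``target_sum`` counts and apply log1p.

    The result is stored in ``adata.layers[layer]``; raw counts in ``.X``
    are untouched.  All downstream scoring operates on this scale.
    """
    X = sp.csr_matrix(adata.X, dtype=np.float64)
    totals = np.asarray(X.sum(axis=1)).ravel()
    scale = np.divide(target_sum, totals, out=np.zeros_like(totals),
                      where=totals > 0)
    X = sp.diags(scale) @ X
    X.data = np.log1p(X.data)
    adata.layers[layer] = X.tocsr()
    return adata


@dataclass
class ClusterProfile:
    """Per-cluster summary: centroid expression, scores, label, kinetics."""

    cluster_id: str
    mean_expression: pd.Series  # gene -> mean normalized expression
    n_cells: int
    signature_scores: Dict[str, float] = field(default_factory=dict)
    phenotype_label: Optional[str] = None
    timepoint_frequency: Dict[str, float] = field(default_factory=dict)


def cluster_mean_expression(adata: ad.AnnData, *, layer: str = "lognorm",
                            cluster_key: str = "cluster",
                            timepoint_key: str = "timepoint",
                            ) -> List[ClusterProfile]:
    """Average normalized expression per cluster, pooling all timepoints.

    Also fills per-timepoint cluster frequencies (fractions of cells at
    each timepoint, summing to one over clusters).  Every cell must carry
    a cluster label; unlabeled barcodes are reported in the error.
    """
    if layer not in adata.layers:
        raise ValueError(f"layer {layer!r} not found; run normalize_log1p first")
    labels = adata.obs.get(cluster_key)
    if labels is None:
        raise ValueError(f"missing obs column {cluster_key!r}")
    unlabeled = adata.obs_names[labels.isna() | (labels.astype(str) == "")]
    if len(unlabeled):
        raise ValueError(f"unlabeled cells: {list(unlabeled[:20])}")
    X = sp.csr_matrix(adata.layers[layer])
    profiles = []
    labels = labels.astype(str)
    tps = adata.obs.get(timepoint_key)
    tp_counts = tps.value_counts() if tps is not None else None
    for cluster_id in sorted(labels.unique()):
        mask = (labels == cluster_id).to_numpy()
        mean = np.asarray(X[mask].mean(axis=0)).ravel()
        profile = ClusterProfile(
            cluster_id=cluster_id,
            mean_expression=pd.Series(mean, index=adata.var_names),
            n_cells=int(mask.sum()))
        if tps is not None:
            sub = tps[mask].value_counts()
            profile.timepoint_frequency = {
                str(tp): float(sub.get(tp, 0)) / float(tp_counts[tp])
                for tp in tp_counts.index}
        profiles.append(profile)
    return profiles


def signature_score(profile: ClusterProfile, signature: GeneSignature) -> float:
    """Mean of the cluster centroid over the signature genes present.

    Genes absent from the matrix are ignored; an empty intersection is an
    error because the score would be undefined.
    """
    present = [g for g in signature.genes if g in profile.mean_expression.index]
    if not present:
        raise ValueError(
            f"signature {signature.name!r}: none of its genes are in the matrix")
    if len(present) < len(signature.genes):
        logger.warning("signature %s: %d/%d genes absent from matrix",
                       signature.name, len(signature.genes) - len(present),
                       len(signature.genes))
    return float(profile.mean_expression[present].mean())


def score_signatures(profiles: Iterable[ClusterProfile],
                     signatures: Dict[str, GeneSignature]) -> None:
    """Fill ``signature_scores`` on each profile in place."""
    for profile in profiles:
        for name, sig in signatures.items():
            profile.signature_scores[name] = signature_score(profile, sig)


def correlate_with_reference(profiles: Sequence[ClusterProfile],
                             reference: Sequence[ClusterProfile],
                             genes: Optional[Sequence[str]] = None,
                             ) -> pd.DataFrame:
    """Pearson correlation of cluster centroids against reference centroids.

    Correlations are computed over ``genes`` (default: all genes shared by
    both centroid sets; at least two required).  A zero-variance vector
    yields NaN for its pairs, with a warning.
    """
    if genes is None:
        shared = [g for g in profiles[0].mean_expression.index
                  if g in set(reference[0].mean_expression.index)]
    else:
        shared = list(genes)
        for prof in list(profiles) + list(reference):
            missing = [g for g in shared if g not in prof.mean_expression.index]
            if missing:
                raise ValueError(f"genes absent from profile "
                                 f"{prof.cluster_id!r}: {missing}")
    if len(shared) < 2:
        raise ValueError("need at least two shared genes for correlation")
    result = pd.DataFrame(
        index=[p.cluster_id for p in profiles],
        columns=[r.cluster_id for r in reference], dtype=float)
    for p in profiles:
        x = p.mean_expression[shared].to_numpy(dtype=float)
        for r in reference:
            y = r.mean_expression[shared].to_numpy(dtype=float)
            if np.std(x) == 0.0 or np.std(y) == 0.0:
                warnings.warn(
                    f"zero-variance centroid in pair ({p.cluster_id}, "
                    f"{r.cluster_id}); correlation undefined", RuntimeWarning)
                result.loc[p.cluster_id, r.cluster_id] = np.nan
            else:
                result.loc[p.cluster_id, r.cluster_id] = float(
                    np.corrcoef(x, y)[0, 1])
    return result


# ---------------------------------------------------------------------------
# Phenotype rules

PHENOTYPES = ("FGFBP2_TEFF", "IFN_TEFF", "TPEX", "preexhausted_TRM",
              "TREG", "TN", "TFH_like", "unclassified")

HIGH = "high"
LOW = "low"
NOT_LOW = "not_low"  # at least intermediate

Z_HIGH = 0.5
Z_LOW = -0.5


@dataclass(frozen=True)
class PhenotypeRule:
    """Label plus required signature levels; first matching rule wins."""

    label: str
    requires: tuple  # of (signature_name, level) pairs


#: Ordered rules, most marker-specific first.  Exhaustion on the TRM and
#: TPEX rules is required to be at least intermediate (not low): precursor
#: exhaustion is defined by GZMK dominance with checkpoint expression
#: present, and a GZMK-high cluster with strong checkpoint expression is
#: still a TPEX rather than an unclassified cluster.
DEFAULT_RULES = (
    PhenotypeRule("TREG", (("Treg", HIGH),)),
    PhenotypeRule("TFH_like", (("TFH", HIGH),)),
    PhenotypeRule("TN", (("TN", HIGH),)),
    PhenotypeRule("preexhausted_TRM", (("TRM_pos", HIGH), ("TRM_neg", LOW),
                                       ("exhaustion", NOT_LOW))),
    PhenotypeRule("TPEX", (("TPEX", HIGH), ("exhaustion", NOT_LOW))),
    PhenotypeRule("FGFBP2_TEFF", (("cytotoxic", HIGH),)),
    PhenotypeRule("IFN_TEFF", (("IFN_response", HIGH),)),
)


def _zscores(profiles: Sequence[ClusterProfile]) -> pd.DataFrame:
    names = sorted({n for p in profiles for n in p.signature_scores})
    table = pd.DataFrame(
        {n: [p.signature_scores[n] for p in profiles] for n in names},
        index=[p.cluster_id for p in profiles])
    mean = table.mean(axis=0)
    std = table.std(axis=0, ddof=0)
    z = (table - mean).div(std.replace(0.0, np.nan), axis=1).fillna(0.0)
    return z


def _level_ok(z: float, level: str) -> bool:
    if level == HIGH:
        return z >= Z_HIGH
    if level == LOW:
        return z <= Z_LOW
    if level == NOT_LOW:
        return z > Z_LOW
    raise ValueError(f"unknown level {level!r}")


def assign_phenotypes(profiles: Sequence[ClusterProfile],
                      rules: Sequence[PhenotypeRule] = DEFAULT_RULES,
                      ) -> Dict[str, str]:
    """Label each cluster by the first matching rule; no match -> unclassified.

    Signature scores must already be filled (``score_signatures``); levels
    are z-scores of each signature across the given clusters, so at least
    two clusters are required for a meaningful assignment.
    """
    for p in profiles:
        if not p.signature_scores:
            raise ValueError(f"cluster {p.cluster_id}: signature scores missing")
    z = _zscores(profiles)
    labels: Dict[str, str] = {}
    for p in profiles:
        label = "unclassified"
        for rule in rules:
            if all(_level_ok(float(z.loc[p.cluster_id, sig]), level)
                   for sig, level in rule.requires):
                label = rule.label
                break
        p.phenotype_label = label
        labels[p.cluster_id] = label
    return labels


def profiles_to_frame(profiles: Sequence[ClusterProfile]) -> pd.DataFrame:
    """Tabular report: one row per cluster with scores, label, kinetics."""
    rows = []
    for p in profiles:
        row = {"cluster": p.cluster_id, "n_cells": p.n_cells,
               "phenotype": p.phenotype_label}
        row.update({f"score_{k}": v for k, v in sorted(p.signature_scores.items())})
        row.update({f"freq_{k}": v for k, v in sorted(p.timepoint_frequency.items())})
        rows.append(row)
    return pd.DataFrame(rows)
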