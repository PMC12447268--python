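"""Self-evaluation experiments: calibration, recovery, and determinism.

These routines measure the pipeline's operating characteristics on the
synthetic generator's ground truth — false-call rates under the null,
precision/recall of planted clone dynamics and cluster phenotypes, and
bit-level reproducibility of full runs.  They back both the test suite
and the reproduction script.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .dynamics import (build_trajectories, classify_kinetics,
                       run_expansion_tests, two_sided_binomial_p)
from .expression import (QCParams, assign_phenotypes, cluster_mean_expression,
                         normalize_log1p, qc_filter)
from .pipeline import PipelineConfig, run_pipeline
from .signatures import default_signatures
from .simulate import SimulationParams, generate_expression, generate_repertoire, null_params
from .expression import score_signatures


def enumeration_two_sided_p(k: int, n: int, p0: float) -> float:
    """Brute-force oracle: sum the full pmf over outcomes no more likely
    than the observed one."""
    pmf = binom.pmf(np.arange(n + 1), n, p0)
    return float(pmf[pmf <= pmf[k] * (1 + 1e-7)].sum())


def binomial_oracle_max_abs_diff(max_n: int = 50,
                                 p0_grid: Sequence[float] = (0.001, 0.01, 0.1,
                                                             0.25, 0.5, 0.9),
                                 ) -> float:
    """Largest |implementation - enumeration| over all k for n <= max_n."""
    worst = 0.0
    for n in range(1, max_n + 1):
        for p0 in p0_grid:
            pmf = binom.pmf(np.arange(n + 1), n, p0)
            for k in range(n + 1):
                oracle = float(pmf[pmf <= pmf[k] * (1 + 1e-7)].sum())
                ours = two_sided_binomial_p(k, n, p0)
                worst = max(worst, abs(ours - oracle))
    return worst


def _classify_bm(params: SimulationParams, alpha: float = 0.05,
                 test_mode: str = "pooled_null"):
    samples, truth = generate_repertoire(params)
    bm = [s for (compartment, _), s in samples.items() if compartment == "BM"]
    trajectories = build_trajectories(bm)
    run_expansion_tests(trajectories, test_mode=test_mode)
    calls = {t.clonotype.aa_cdr3b: classify_kinetics(t, alpha=alpha)
             for t in trajectories}
    return calls, dict(zip(truth.aa_cdr3b, truth.kinetic_class))


def null_incdec_fraction(seeds: Iterable[int], alpha: float = 0.05,
                         test_mode: str = "pooled_null", **param_overrides,
                         ) -> float:
    """Mean fraction of clones called Inc or Dec on null repertoires."""
    fractions = []
    for seed in seeds:
        calls, _ = _classify_bm(null_params(seed, **param_overrides),
                                alpha=alpha, test_mode=test_mode)
        bad = sum(1 for c in calls.values() if c in ("Inc", "Dec"))
        fractions.append(bad / len(calls))
    return float(np.mean(fractions))


def planted_recovery(seeds: Iterable[int], alpha: float = 0.05,
                     test_mode: str = "pooled_null", **param_overrides,
                     ) -> pd.DataFrame:
    """Pooled precision/recall of Inc, Dec, and New calls across seeds.

    "New" pools the transient and stable subtypes on both sides (a planted
    transient clone that sampling happens to carry into day 42 is still a
    correctly detected new clone).
    """
    tp: Dict[str, int] = {"Inc": 0, "Dec": 0, "New": 0}
    fp: Dict[str, int] = dict(tp)
    fn: Dict[str, int] = dict(tp)
    for seed in seeds:
        calls, truth = _classify_bm(SimulationParams(seed=seed, **param_overrides),
                                    alpha=alpha, test_mode=test_mode)
        for aa, called in calls.items():
            true_class = truth.get(aa, "Unchanged")
            for group in ("Inc", "Dec"):
                if called == group and true_class == group:
                    tp[group] += 1
                elif called == group:
                    fp[group] += 1
                elif true_class == group:
                    fn[group] += 1
            called_new = called.startswith("New")
            true_new = true_class.startswith("New")
            if called_new and true_new:
                tp["New"] += 1
            elif called_new:
                fp["New"] += 1
            elif true_new:
                fn["New"] += 1
    rows = []
    for group in ("Inc", "Dec", "New"):
        denom_p = tp[group] + fp[group]
        denom_r = tp[group] + fn[group]
        rows.append({"group": group,
                     "precision": tp[group] / denom_p if denom_p else np.nan,
                     "recall": tp[group] / denom_r if denom_r else np.nan,
                     "tp": tp[group], "fp": fp[group], "fn": fn[group]})
    return pd.DataFrame(rows).set_index("group")


def phenotype_recovery_accuracy(seed: int, qc: Optional[QCParams] = None,
                                **param_overrides) -> float:
    """Per-cell accuracy of rule-based phenotype labels vs planted truth.

    Cells removed by QC (including planted low-quality cells) are excluded
    from the denominator: the annotation operates on the filtered matrix.
    """
    params = SimulationParams(seed=seed, **param_overrides)
    adata, truth = generate_expression(params)
    adata = qc_filter(adata, qc or QCParams())
    normalize_log1p(adata)
    profiles = cluster_mean_expression(adata)
    score_signatures(profiles, default_signatures())
    labels = assign_phenotypes(profiles)
    truth = truth.set_index("barcode")
    kept = truth.loc[truth.index.intersection(adata.obs_names)]
    kept = kept[kept.phenotype != "low_quality"]
    clusters = adata.obs.loc[kept.index, "cluster"]
    hits = sum(labels[c] == pheno
               for c, pheno in zip(clusters, kept.phenotype))
    return hits / len(kept)


def pipeline_reruns_identical(workdir, seed: int,
                              simulate_overrides: Optional[dict] = None,
                              compare: Sequence[str] = (
                                  "trajectories.tsv", "cluster_profiles.tsv",
                                  "fold_summary.tsv", "fold_table.tsv",
                                  "response.tsv", "venn.json", "report.json"),
                              ) -> bool:
    """Run the full pipeline twice at one seed; True if outputs match bytewise."""
    workdir = Path(workdir)
    outputs = []
    for run in ("run1", "run2"):
        config = PipelineConfig(outdir=str(workdir / run), seed=seed,
                                simulate=dict(simulate_overrides or {}))
        run_pipeline(config)
        outputs.append(workdir / run)
    return all((outputs[0] / rel).read_bytes() == (outputs[1] / rel).read_bytes()
               for rel in compare)
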