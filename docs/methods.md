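# Methods

This note documents the models, conventions, and design choices behind
`clonaltrack`, in the spirit of a statistical methods appendix.  It
states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Clone identity and repertoire ingestion

A clonotype is the amino-acid CDR3 of the TCR β chain (aaCDR3b), upper
case, restricted to the 20 standard residues.  Identity deliberately
excludes V/J gene calls and the nucleotide sequence: the cross-platform
comparison at the heart of the analysis — bulk blood repertoires
(immunoSEQ-style TSV, template counts) against single-cell marrow
repertoires (10x-style contig CSV, cell counts) — is only possible at
amino-acid resolution.  V/J and nucleotide CDR3 are retained as
annotation; bulk rows sharing an aaCDR3b are merged by summing
templates.

Single-cell policy: a cell contributes through its productive TRB chain
only.  TRA-only cells and cells whose TRB contigs are all unproductive
contribute nothing; when a barcode carries several productive TRB
contigs, the highest-UMI contig (ties broken lexicographically) defines
the cell, so each contributing barcode counts exactly once and a
sample's total equals its contributing cells.  The TRB-only policy
follows the observed assignment pattern in 5' immune-profiling data,
where a large share of T cells receive only a TRB call;
`tcr_assignment_stats` quantifies that pattern (TRB-only / TRA-only /
both fractions over barcodes with at least one productive chain).

Undetected clones are absent from a sample's count map, never stored as
zeros; zeros enter only when trajectories are assembled and an absent
clone is recorded as k = 0 at that sample's depth.

## Expansion testing

For baseline count k₁ (of n₁) and post-treatment count k₂ (of n₂), the
test is an exact two-sided binomial test of k₂ against a null proportion
p₀, with two-sidedness by minimum-likelihood summation: all outcomes
whose point probability is at most pmf(k₂)·(1+10⁻⁷) contribute (the
relative tolerance guards against floating-point exclusion of exact
ties, as in R's `binom.test`).  The implementation exploits unimodality
of the pmf and runs in O(log n) pmf evaluations; the test suite checks
it against full-enumeration summation (≤ 10⁻¹² for all n ≤ 50) and
against `scipy.stats.binomtest` on randomized cases.

Two null conventions are implemented:

* `pooled_null` (default): p₀ = (k₁+k₂)/(n₁+n₂), the usual two-sample
  comparison.
* `baseline_null`: p₀ = k₁/n₁, the literal "change from the
  pre-treatment frequency" framing.

The default was chosen by a calibration experiment, not by convention:
`baseline_null` treats the *estimated* baseline frequency as an exact
null and therefore ignores baseline sampling noise; at the package's
design depth (10⁴) this inflates the variance of the effective test
statistic by ~√2 and, measured on null synthetic repertoires (no planted
effects, 200 clones, 50 seeds), calls ~5% of clones Inc/Dec at
BH q < 0.05 where `pooled_null` calls essentially none.  The same
inflation destroys precision on planted-effect repertoires.  Both modes
remain exposed (`test_mode` in the dynamics config); the acceptance
experiments (`clonaltrack.evaluation`) re-measure both properties on
every run.

Clones with k₁ = 0 are never tested (expansion from zero has no defined
fold): they are routed to new-clone classification, and the API refuses
them explicitly.  Multiple testing is controlled per
patient-compartment with Benjamini–Hochberg over all tested
(clone, timepoint) pairs, via `statsmodels`.

## Kinetic and longevity classification

Classification uses three anchored visits: baseline (`pre`), an early
post visit (default day 14) and a late one (default day 42).

* k_pre = 0, detected at early only → `New_transient`; detected at the
  late visit (with or without early) → `New_stable`; detected at
  neither → `Undetected` (within the classification window — the
  late-only case is treated as stable since the clone persists at the
  late visit).
* k_pre ≥ 1 → `Inc` or `Dec` when BH q < α (default 0.05) at early or
  late, with the direction read from the frequency change at the most
  significant visit; otherwise `Unchanged`.

A `frequency_only` mode classifies Inc/Dec by the sign of the frequency
change alone (early visit, falling back to late), matching analyses
that define the groups without a significance filter; the
significance-filtered mode is the default.

Longevity uses the last visit at which the clone was detected:
≤ day 14 transient, day 28–56 medium-lived, ≥ month 6 long-lived.  The
category names are standard; the day cut-offs are this package's stated
convention (no published cut-offs exist), and trajectories must span
the 6-month visit for the classes to be observable.

Compartment sharing intersects the union of marrow clones with the
union of blood clones (any visit) by aaCDR3b, reports Venn counts, and
accumulates the shared clones' frequency in each marrow sample — the
"how much of the marrow CD8 pool is blood-visible" statistic.

## Expression QC, profiling, and annotation

Counts are held in an `AnnData` (cells × genes).  QC removes cells with
fewer than 200 detected genes or more than 10% mitochondrial UMIs
(genes prefixed `MT-`), then genes expressed in ≤ 0.1% of cells.  The
two filters are alternated to a fixed point so the result satisfies
both simultaneously and the operation is idempotent (a single pass can
strand cells below the genes-detected threshold after gene removal).
An all-cells-removed outcome raises, never returns silently.

Normalization is counts-per-10,000 followed by log1p — the standard
transform of droplet scRNA-seq toolchains; all scoring operates on this
scale.  Cluster labels are inputs (graph clustering and embeddings are
out of scope).  A cluster profile is the mean normalized expression
over its cells pooled across visits, plus per-visit cluster frequencies
(a probability vector over clusters at each visit).

A signature score is the mean of the profile over the signature's genes
present in the matrix (absent genes warn; an empty intersection is an
error).  Signatures ship as editable YAML: cytotoxic (CX3CR1, PRF1,
GNLY, NKG7, GZMB, KLRD1, FGFBP2), IFN-response (IFIT2, IFIT3, OASL,
ISG15), proliferation (MKI67, TOP2A, STMN1, TYMS — a conventional set;
no specific list is prescribed by the source material), exhaustion
(PDCD1, HAVCR2, LAYN, TIGIT, LAG3, ENTPD1), T_PEX (GZMK), T_RM-positive
(CRTAM, RGS1, DUSP6, CD69, CXCR6, TNFRSF9), T_RM-negative/recirculation
(STK38, KLF2, RIPOR2), Treg (IL2RA, FOXP3), naive (CCR7, SELL, LEF1,
TCF7), T_FH (BCL6, CXCL13).

Phenotype assignment operationalizes qualitative "high/low" marker
descriptions as z-scores of each signature across a patient's clusters:
high ≥ +0.5, low ≤ −0.5.  Ordered rules, most specific first:
Treg-high → TREG; TFH-high → TFH_like; naive-high → TN; T_RM-positive
high AND recirculation low AND exhaustion not-low → preexhausted_TRM;
GZMK high AND exhaustion not-low → TPEX; cytotoxic high → FGFBP2_TEFF;
IFN high → IFN_TEFF; otherwise unclassified.  Two conventions to note:
(1) the exhaustion requirement on the T_RM and T_PEX rules is "at least
intermediate" (z > −0.5) rather than a two-sided intermediate band —
with a handful of clusters, the z-score of a genuinely moderate
exhaustion program routinely exceeds +0.5, and GZMK dominance already
separates T_PEX from terminal exhaustion; (2) assignment is relative to
the cluster set supplied, so at least two clusters are needed.
Cross-labeling against external reference centroids is provided as a
Pearson correlation matrix over shared genes (all shared genes by
default, a supplied gene list otherwise), with zero-variance vectors
yielding flagged NaNs.

## Assay arithmetic

Fold change is post/pre at each visit, with the best response being the
visit maximizing the fold (earliest on ties).  Cohort summaries report
mean ± SEM with the **population**-SD convention (n in the
denominator); this is the convention under which the published cohort
rows reproduce to two decimals, and the sample convention is available
via `ddof=1`.  Responders are folds ≥ 1.5 (the boundary is inclusive;
published 1.49 and 1.44 values are non-responders).  The tetramer
positivity threshold is control mean + 2 SD (population SD for
symmetry), accepting either raw control frequencies or published
aggregates.  Background subtraction (tetramer negative control,
non-stimulated cytokine wells) and ELISPOT vehicle subtraction clip at
zero and flag the clipping rather than reporting negative frequencies.
qPCR relative expression is 2^−ΔΔCT against a reference gene and
calibrator sample.

## Clinical response

Modified ELN rules on marrow blast percentages: best (minimum) post
visit < 5% → CR when both hematologic recovery flags (ANC, platelets)
are true, else CRi — the flags are required inputs at that point, not
guessed; > 50% decrease from baseline with the best visit in 5–25% →
PR; > 50% increase with (baseline ≥ 30% or an absolute increase ≥ 15
percentage points), or blasts > 70% at ≥ 2 post visits spanning ≥ 90
days → PD; otherwise SD.  Precedence is CR/CRi > PR > PD > SD (best
response).  MLFS and MRD-negative CR are not emitted: marrow
cellularity and MRD assays are outside the package's data model.
Hematologic recovery enters as booleans because no counts-based
definition is computed here; the standard cut-offs (ANC ≥ 1.0×10⁹/L,
platelets ≥ 100×10⁹/L) are the intended semantics.  Change from
baseline is (visit − baseline)/baseline, undefined (error) at zero
baseline.

## Synthetic data

The generator emulates the *detected* clone universe of a
patient-compartment: 200 baseline clones with frequencies from a
symmetric Dirichlet (concentration 5), sampled multinomially at depth
10,000 per visit over the marrow schedule (pre, d14, d42, m6, m12).
Planted effects: 15 five-fold expansions, 15 five-fold contractions, 8
transient new clones (day 14 only) and 8 stable new clones (day 14
through 42, hence medium-lived in truth) at 2×10⁻³ frequency, all
planted on clones with ≥ 10 expected baseline copies.  Blood
repertoires share 70% of marrow base clones plus blood-private clones
and are static over time (planted dynamics act in marrow, where the
clone-tracking questions live).

Two self-consistency requirements shaped the design.  First, planted
truth must mean what it says: multiplying planted frequencies and
renormalizing transfers mass *away from every unplanted clone*, and
with arbitrary planting the ~20% compositional shrinkage makes
"Unchanged" labels false by construction.  Contractions are therefore
planted on the largest eligible clones and expansions on the smallest,
so the mass gained by expansions approximately cancels the mass lost to
contractions ((fold−1)·m_inc ≈ (1−1/fold)·m_dec) and unplanted relative
frequencies stay essentially unchanged — which also mirrors the biology
(vaccine-responsive clones start rare; receding dominant clones are
large).  Second, baseline clones must be reliably detectable at the
design depth, hence the concentrated Dirichlet.  Real repertoires
instead carry a long power-law tail of rare clones whose sampling noise
produces apparent one-off "new" singletons; the generator deliberately
does not emulate that tail, so the measured New-clone precision
describes the planted regime, not the behavior of detection-based
new-clone calls on real data.  That limitation is the main caveat when
transferring the recovery numbers to patient repertoires.

Expression: 45 signature genes + 340 filler genes + the 13
mitochondrial genes; per-gene base means from a Gamma(2, 1.5)
(mean 3); negative-binomial counts with dispersion 0.5
(var = m + 0.5 m²).  Eight planted clusters of 40 cells: the seven
annotatable phenotypes plus a terminally exhausted cluster whose truth
label is `unclassified` (it matches no rule).  Each cluster multiplies
its program's marker means by a fold (default 6; the exhaustion program
enters at √fold in the T_PEX and T_RM clusters, full fold in the
exhausted cluster); recirculation markers are expressed by the naive
and both effector clusters but not the T_RM cluster, since the negative
T_RM signature is a recirculation program.  Mitochondrial means are set
per cluster to hit a target mito fraction (default 5%); planted
low-quality cells (six at 18% mito, six at 0.15× library scale) are the
QC filter's targets.  A clone-linked variant emits pre/d14 cells for
planted Inc/Dec/new clones with cytotoxic upregulation in Inc cells at
day 14 and an exhaustion program in Dec cells, providing ground truth
for the clone-group expression readout.

Clinical: four synthetic patients whose deterministic blast
trajectories realize CRi, PR, SD, and PD by construction (closure under
the classifier is a test), with iNKT/NK series applying planted folds
at day 14 under multiplicative lognormal noise (σ = 0.2; σ = 0 gives
exact folds).

A single integer seed drives a hierarchical `numpy.random.SeedSequence`;
the repertoire, blood, expression, and clinical streams are independent
children, so each data kind is reproducible in isolation.  Everything
is emitted in the exact on-disk dialects the readers consume (contig
CSV with TRA-only and unproductive decoy rows, bulk TSV with an
out-of-frame decoy, Matrix-Market triplet, tidy TSVs) plus truth tables
and a parameter manifest.

## Pipeline and determinism

Stages (simulate → repertoire → annotate → dynamics → kinetics →
response → report) are pure functions of (inputs, config, seed); all
randomness lives in simulate.  Missing inputs fail before anything is
written.  Outputs are TSV/JSON with sorted keys and no timestamps
(timings go to the log), so fixed-seed reruns are byte-identical — a
property the test suite asserts.  A run manifest records the config,
package version, and seed.

## Problem sizes in the standard experiments

The self-evaluation experiments run at the generator's study
conditions: the null calibration uses 50 seeds × 200 clones at depth
10⁴; planted recovery uses 20 seeds; phenotype recovery one seed of the
default expression design; the enumeration cross-check covers all
k ≤ n ≤ 50 on a six-point p₀ grid; determinism runs the full pipeline
twice at one seed.  These sizes keep the whole suite in the
tens-of-seconds range on a single core while leaving the statistical
conclusions stable across seeds.

## Known limitations

* Clone identity by aaCDR3b merges convergent rearrangements; this is
  intrinsic to cross-platform matching, not recoverable here.
* Detection-based "new" clone calls have no abundance floor; on real
  repertoires with a rare-clone tail they will include sampling
  singletons (see above).  A floor could be added at the cost of
  sensitivity to genuinely rare new clones.
* "Medium-lived" spans day 28–56 by convention; no external definition
  exists, and reports should be read with that convention in mind.
* The ELN classifier covers CR/CRi/PR/SD/PD only; MLFS and CR_MRD
  require inputs outside the data model.
* Reference-signature cross-labeling correlates centroids over shared
  genes; whether an external atlas is best compared on all genes or
  signature genes only is a user decision (`genes=` parameter).
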