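# Methods

This note documents the models, algorithms and design choices behind
`crossrppa`, in the spirit of a statistical software methods appendix.

## The synthetic study

The generator emulates a three-site RPPA comparison study.  Its design
defaults are the study conditions, not tuning knobs:

- **Design**: 6 breast cancer cell lines (MCF7, MDA-MB-231, MDA-MB-468,
  MDA-MB-453, HCC1954, SKBR3 with ER+/TN/Her2+ receptor annotations) ×
  3 treatments (DMSO vehicle, 1 µM lapatinib, 1 µM selumetinib) ×
  2 timepoints (20 min, 24 h) × 3 biological replicates = 108 lysates.
- **Panels**: 27 antigen classes covered by all three platforms, probed
  by 29 (paris), 31 (heidelberg) and 27 (edinburgh) antibodies.  Most
  classes are measured by one shared catalogue antibody; Her2 is probed
  by five distinct antibodies, phospho-Erk1/2 by two shared ones, and
  EGFR and phospho-S6 carry a second heidelberg antibody.  Over the 18
  vehicle controls this yields 522/558/486 readings per platform (1,566
  integrated) and 9,396 readings over all 108 samples.

**Latent abundance model.** The true log2 abundance of antigen *a* in
sample *s* is

    x(a, s) = λ_a f_c + β(a, c) + δ(a, treatment, timepoint) + ε,

where *c* is the sample's cell line, f_c ~ N(0, 1) is a cell-line
factor, λ_a ~ N(0.4, 0.35) a per-antigen loading (most proteins co-vary
weakly and positively with overall cellular abundance, which gives
unrelated antibody pairs the mildly positive correlations seen in real
RPPA data), β ~ N(0, 1) an antigen-by-cell-line baseline, and
ε ~ N(0, 0.25) biological replicate noise (log2 units throughout).

**Drug effects** δ apply only in lines flagged sensitive (lapatinib:
SKBR3, HCC1954; selumetinib: MDA-MB-231, MDA-MB-468; MCF7 responds to
neither).  Magnitudes are benchmark values, not estimates: e.g.
phospho-Her2 −2.0/−2.5 log2 under lapatinib at 20 min/24 h with
downstream phospho-Akt and phospho-Erk1/2 reductions; phospho-Erk1/2
−2.0/−2.5 under selumetinib with a +0.5/+1.5 phospho-MEK1/2 feedback
rise at 24 h.  One- to two-and-a-half-fold-per-day changes of pathway
phosphosites are the magnitude range routinely reported for these
inhibitors in sensitive lines.

**Rendering.** Each platform renders x(a, s) into spot intensities:
log2 signal = gain·x + offset + sample loading − dilution step + spot
noise, linear intensity = 2^signal censored at the detection floor.
Dilution is exactly −1.0 log2 per step (serial two-fold), with 4 steps
and 2 technical replicate spots per sample.  Platform gains/offsets are
1.0/10, 1.1/11 and 0.9/9; spot noise defaults to 0.15 log2.  The
per-sample loading term (default sd 0, set positive to study loading
confounders) is shared by the total-protein stain, so total-protein
normalisation removes it while the dilution-fit intercept does not.

**What the generator does not emulate** — and hence what green tests do
not establish about real data: spatial array artefacts, antibody
off-target binding and epitope-specific affinity differences, saturation
nonlinearity (only floor censoring is modelled), and batch structure
beyond a scalar gain/offset.  Because like-antigen antibodies differ
only by independent Gaussian noise, their correlations (median r_s
≈ 0.99) are higher than in real studies, and concordance fractions on
default settings are near 1.  The pipeline's claims are therefore about
correctness and calibration of the *analysis*, not about reproducing any
particular laboratory's variance components.

## Processing and integration

Technical replicates are combined by their median (robust to single bad
spots; the aggregation rule is a package choice, as sites do not publish
theirs).  The dilution fit is ordinary least squares of log2 intensity
on the integer dilution step over points above the detection floor;
series with every point censored are flagged unquantifiable, series with
fewer than two distinct usable steps insufficient.  The QC report counts
slopes within a band around the ideal −1 (default −1.5 … −0.5).

Full re-implementations of site-specific normalisation suites are out of
scope; the two strategies provided (dilution-fit intercept and
total-protein division) are deliberately *different* representative
normalisations, which is what a cross-platform concordance analysis
needs.

Integration median-centres each antibody column and concatenates
platforms.  The centring subset is configurable: medians over the
analysed samples (default) or over the vehicle controls only — useful
when treated samples should be expressed relative to control level.
Missing values are carried, never imputed (distances and correlations
use pairwise-complete observations); only PCA, which needs complete
data, imputes column medians and records how many cells it filled.
Antigen classes absent from any platform are removed entirely, with the
dropped classes listed in the integration manifest.

## Clustering

Average linkage is implemented with the Lance-Williams update
d(A∪B, K) = (|A| d(A,K) + |B| d(B,K)) / (|A|+|B|), equal to the
unweighted mean over member pairs; the test suite checks it against a
brute-force O(n³) re-computation.  Numerical choices:

- **Tie-break**: among minimum-distance pairs the lexicographically
  smallest (left id, right id) pair merges first.  Distances within a
  relative 1e-9 are treated as tied, because rank metrics on few
  observations produce exact mathematical ties whose floating-point
  values differ in the last bit depending on summation order.
- **Leaf order**: the earlier-created subtree goes left, matching the
  clustered-data-table convention and making antigen-map columns
  reproducible.
- **Inversions**: average linkage does not guarantee monotone heights;
  inversions are counted and reported, not silently reordered.
- **Distances**: Spearman distance is 1 − r_s (the uncentred adaptation;
  recorded in output metadata since a (1 − r)/2 variant also exists);
  Kendall uses the tie-corrected τ_b, appropriate because centred
  intensity data contain ties.  Rank-metric pairs need ≥ 3
  pairwise-complete observations, otherwise the distance is missing and
  clustering refuses to run.

CDT/GTR/ATR files store node scores as 1 − height for every metric (one
self-describing convention rather than a per-metric switch); the bundled
reader inverts it, recovering heights to one ulp, and a second
write/read cycle is byte-identical.  Tree files cannot carry comment
headers in-dialect, so their provenance lives in the run manifest rather
than in-file.

## Antigen map and concordance

The map has alphabetised antigen classes as rows and clustered antibody
columns as columns; each column's single filled cell holds the
antibody's fixed integer index within its class (distinct uids sorted,
enumerated from 1), so the index identifies the physical antibody
independently of the clustering.

"Clusters with" needs a formal rule to turn a dendrogram into
percentages.  The default **sibling rule** takes, for each antibody
column, the leaves of the sibling subtree at its parent merge node; a
class is cross-platform concordant if any of its columns has a
same-class companion from another platform (cross-antibody: a different
uid).  A **k-nearest-cophenetic-neighbour** rule (default k = 3) is the
configurable alternative; it is more permissive for same-class columns
separated by one merge level.  Because published concordance percentages
depend on this unstated membership choice, the report always carries the
eligibility denominators (classes on ≥ 2 platforms, classes with ≥ 2
distinct antibodies) next to the fractions.

## Correlation statistics

All-pairs Spearman correlations are computed between antibody-platform
columns (not pooled identifiers), which is what platform-pair
comparisons require.  Kernel density estimates use a Gaussian kernel
with Silverman's rule-of-thumb bandwidth 0.9·min(sd, IQR/1.34)·n^(−1/5)
on 512 grid points spanning the data ± 3 bandwidths.  The Fisher
comparison z = (atanh m₁ − atanh m₂)/√(2/(n_eff − 3)) treats each group
median as a single correlation observed on n_eff samples; this ignores
the dependence among pairs and the fact that a median of correlations is
not one correlation, so the result object carries that caveat and n_eff
is an explicit parameter (default: the number of samples underlying each
correlation).

## Differential testing

The moderated statistic adds a constant s0 (default 1.0, "artificial
within-groups variance") to the pooled standard error, damping the
inflated statistics that near-zero-variance antibodies produce at
n = 3 per group; s0 = 0 recovers the classical pooled t.

The permutation FDR enumerates all distinct balanced label splits when
fewer exist than the requested randomisations (default 1,000), otherwise
draws a seeded random subset without replacement.  The observed
labelling and its mirror are excluded from the permutation set: they
reproduce |t_obs| exactly, and for 3 vs 3 they would be 2 of the
C(6,3) = 20 splits, imposing a floor of 2/20 = 10% on every attainable
FDR — a 5% threshold would then be unsatisfiable by construction.  With
the 18 informative splits, FDR(c) = mean permuted count of |t| ≥ c over
the observed count, and the applied cut is the smallest observed |t|
with FDR ≤ the threshold (the largest significant set).  `n_perm_used`
is always reported.  Calibration on the study's own geometry (3 vs 3,
50 antibodies): mean false calls on null data ≈ 0.1 per dataset at 5%
FDR; effects of 5 standard deviations are recovered with sensitivity
> 0.99.  Testing is two-sided on |t_mod|; each (cell line, drug,
timepoint) contrast is tested independently.

## Reproducibility

One top-level seed derives all per-stage seeds through SHA-256 hashing
of stage labels (keeping derived seeds below 2³¹), so any configuration
reproduces its outputs byte for byte; TSV/JSON outputs carry a
provenance header with the configuration hash, seed and stage.  Problem
sizes used by the test suite and the acceptance script — the full
108-sample study, 200 random matrices of up to 7 items for the
clustering oracle, 100 null and 50 effect datasets for FDR calibration —
were chosen so the whole analysis re-runs from scratch in seconds while
still exercising every code path at the study's true dimensions.
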