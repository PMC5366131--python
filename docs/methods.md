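# Methods

This note documents the models and procedures implemented in `mbtraj`, the
assumptions behind them, the parameters that matter, and what the synthetic
cohort does and does not emulate.

## Input model

The pipeline's entry point is an OTU count table (samples × OTUs, integer
counts, every sample total positive) with per-sample metadata: subject,
collection day relative to confinement entry (day 0; exit day 520), and a
phase flag (`pre` / `confinement` / `post`) that must be consistent with
the day. Taxonomy is consumed as Greengenes-style 7-rank lineage strings;
phylogenies as rooted Newick trees with non-negative branch lengths whose
leaves are OTU ids. Tables are accepted as classic QIIME TSV (OTUs as rows,
first header `#OTU ID`; the transposed orientation is detected from the
header) or BIOM v1.0 JSON (sparse or dense). HDF5 BIOM is intentionally
unsupported — the package has no binary-format dependency.

## Trajectory normalization

Three steps per subject, in order:

1. **Fractional abundances.** Counts divided by the sample total; every row
   sums to 1 (tolerance 1e−9 everywhere downstream).
2. **Highly abundant OTUs.** Each OTU's median fractional abundance across
   the subject's time points is computed; OTUs are ranked by that median
   (ties broken lexicographically by id) and the smallest prefix whose
   summed medians reach 90% of the total is kept. The alternative reading
   of "90% of median time-point reads" — the median *sample* rather than
   per-OTU medians — is noted but not implemented; the per-OTU-median
   prefix is the reading consistent with the upstream procedure this step
   follows, and it is the one the prefix-oracle tests pin down.
3. **Reference normalization.** For target sample *s*, every time point *t*
   (including *s* itself, with weight (1−0)² = 1) gets weight
   *w(t) = (1 − j(t,s))²*, where *j* is the JSD computed over the selected
   OTUs after renormalizing to that support — weights then live on the same
   support as the values being normalized, and since JSD (log base 2) is
   bounded by 1, *w* ∈ [0,1]. The per-OTU reference is the *w*-weighted
   median (smallest value whose cumulative weight reaches half the total).
   The scale factor is the median of reference/observed ratios over OTUs
   nonzero in both — a zero-robust compositional depth correction; the
   normalized series is the scale factor times the observed values.

Normalization is strictly per subject; profiles are never pooled across
subjects at this stage.

**Horizon transform.** Per OTU: subtract the median; bands are
sign(centered)·min(4, ceil(|centered|/MAD)) with the raw (unscaled) MAD,
zero MAD sending any nonzero deviation to the outermost band. Four bands
per side match the usual horizon-graph display convention.

## Distances

JSD is √(Jensen-Shannon divergence) with base-2 logarithms (0·log 0 = 0),
so it is a metric bounded by 1 — required for the (1−j)² weights. UniFrac
is computed from a single postorder pass that records, for every non-root
branch, its length and descendant-taxon set. Unweighted UniFrac is the
branch length leading exclusively to leaves present in one sample over the
branch length leading to leaves present in either (presence = abundance
> 0; no rarefaction is performed, as the pipeline operates on fractional
profiles). Weighted UniFrac is Σ b·|A−B| / Σ b·(A+B) with A, B the
per-branch abundance fractions — the normalized variant; the raw numerator
is available behind a flag. Inter-subject series match collection days by
greedy binning with a ±3-day tolerance (configurable); each bin contributes
every pairwise distance among the subjects sampled in it.

## Beta-diversity trend test

Distance is regressed on day by L1 (median) regression. For n ≤ 200 points
the fit is exact: an optimal L1 line passes through two data points in
general position, so all pairwise lines (plus the flat median line) are
searched; above that, iteratively reweighted quantile regression
(statsmodels, q = 0.5) is used. The slope's p-value is a two-sided
percentile bootstrap: resample pairs with replacement, refit,
p = 2·min(frac(b* ≤ 0), frac(b* ≥ 0)) with a +1/(n_boot+1) continuity
correction. Two rescaled coefficients are reported: RC_range = slope ×
(day span)/(observed distance range) and RC_sd = slope × (day span)/(SD of
distances) — the fitted change over the whole study expressed in units of
the full distance variation and of one standard deviation respectively.
These scalings are the package's own explicit definitions; they are chosen
for interpretability, not to match any particular published magnitude.

## Steady states

Ward linkage is computed by the Lance–Williams update applied to squared
JSDs; merge heights are reported as the square root of the criterion (the
`ward.D2` convention), and ties break on the smallest cluster-index pair so
the merge order is fully deterministic. Cutting at height *h* keeps merges
with height ≤ h; states are numbered by first appearance in time, and
episodes are maximal runs of consecutive same-state samples.

**Validation.** (i) Every within-state sample pair's Spearman correlation
(over the subject's high-abundance OTUs) gets a p-value;
Benjamini–Hochberg q-values are computed across all pairs and every pair in
a state must have q < 0.05. Spearman is used because the correlation flavor
is a free choice here; BH is the q-value method implemented (Storey's
estimator would be a drop-in alternative). (ii) PERMANOVA — Anderson's
pseudo-F from the distance matrix with label permutations — must separate
every state pair at p < 0.05, and an overall test is reported. Pairwise
tests are not multiplicity-corrected by default (a flag enables BH).
Singleton states block certification: a steady state is by definition a
recurring *group* of configurations.

Two small-sample realities are handled explicitly. First, pairwise tests
with few samples are computed by exact enumeration of label assignments
(used whenever the count is ≤ 500); second, a pair whose exact-p floor
exceeds 0.05 (e.g. two 2-sample states: floor 1/3) passes only when its
exact p *is* the floor — the observed separation is the most extreme
achievable at that size. The p-values themselves are always reported
unmodified.

**Automatic cut height.** The natural rule — the lowest height whose states
all pass validation — is anti-conservative in a specific, measurable way:
the labels being tested are produced by Ward on the same data, so
PERMANOVA certifies chance sub-splits of a homogeneous cloud and the scan
over-splits (measured: 2/20 planted-regime recoveries at concentration
500). Auto mode therefore ranks candidate heights (the merge-height grid)
by mean silhouette width on the JSD matrix — the standard criterion for
choosing a cluster number on JSD structure — and returns the best-ranked
cut whose states all pass validation (20/20 recovery under the same
conditions). A fixed height remains available as a parameter; no claim is
made that any particular numeric height transfers across datasets, since
Ward heights are data-scale dependent.

State profiles are per-OTU medians over member samples, renormalized to
sum to 1 (the median of compositions is not itself a composition).

## Source attribution

Profiles are compositions but the sampler needs reads, so sinks and sources
are rescaled to a pseudo-depth (default 10,000; largest-remainder rounding).
The collapsed Gibbs sampler assigns each sink read a latent source; for a
read of taxon *t*:

- known source *k*: P ∝ (c_kt + α₁)/(C_k + α₁T) · (n_k + β)
- unknown: P ∝ (u_t + α₂)/(U + α₂T) · (n_unk + β)

with c the fixed source counts, u/U the current unknown-assigned counts,
n the per-source sink assignment counts, and T the taxon universe size.
Defaults follow the published source-tracking values: α₁ = 0.001, α₂ = 0.1,
β = 10, burn-in 100 sweeps, 10 retained draws spaced 10 apart, 10 restarts;
mixing proportions are posterior means over retained draws and restarts.
The inner loop is numba-compiled; chains are seeded, so results are exactly
reproducible. Burn-in matters more than draw count here: the unknown source
competes with well-matching known sources early in a chain, and ~100+
sweeps are needed for that competition to resolve.

For each subject's transition (state *i* → *i+1*), the sink is the new
state's profile and the sources are the subject's state *i* plus **all** of
the other subjects' state profiles (no temporal restriction — offering only
past states is available behind a flag). The exogenous score is
e = 1 − π(own state *i*); z-scores use the population (n-denominator) SD
within each subject, so z = 0 means the transition changed the community as
much as that subject's average transition. The major-change threshold
defaults to z > 1.5 — with 4–6 transitions per subject, a single outlying
transition reaches z ≈ 1.73–1.9, so 1.5 flags clear outliers without being
attainable by ordinary fluctuation alone.

## Co-abundance groups

Observations are the steady-state profiles themselves — deliberately few
(5–7 per subject), which the model records as a small-n caveat: Kendall
τ-b p-values are exact-enumeration for ≤ 10 observations, and no edge can
reach p < 0.05 with fewer than 5 states. OTUs enter when their mean
relative abundance across state profiles exceeds 0.1%. Groups come from
Ward linkage on 1 − Spearman ρ cut at k ∈ {3,4}, k chosen by mean
silhouette (ties → 3). Certification cannot use naive label-permutation
PERMANOVA — the groups are cluster-derived, so that test sits at its p
floor even for independent noise. Instead each OTU's values are permuted
independently across states, the whole distance/Ward/silhouette pipeline is
re-run on the permuted data, and the observed pseudo-F is compared with
the re-clustered null's pseudo-F distribution; certified means p < 0.001
(which requires > 999 permutations; the pipeline default is 1,999).
Measured behavior: independent noise is left uncertified in ~96/100 nulls;
planted correlation blocks are recovered exactly and certified. Edges are
the positive Kendall correlations with p < 0.05, weighted by τ;
over-abundance ratios use the across-state median profile as background
with a pseudocount of 1e−6 in numerator and denominator.

## Synthetic cohort

The generator emulates the study's shape: 6 subjects (ids 5001–5006), 27
samples each on a fixed grid over days −10…700 (2 pre-entry, 21 during
confinement, 4 post-exit), uniform read depths in 7,759–91,366, and
per-subject planted regime counts (6,5,6,5,6,7). All draws flow from one
seeded generator; output is byte-reproducible.

- **Noise model**: Dirichlet-multinomial. Each sample's composition is
  Dirichlet(concentration × regime baseline); reads are multinomial at the
  drawn depth. The concentration (default 500) is the single
  overdispersion knob.
- **Baselines**: each subject has a master profile on its OTU support
  (a cohort-shared core plus subject-private taxa; shared-core taxa follow
  one cohort-level weight profile with higher expected mass, so every
  subject's high-abundance set contains a shared tranche of ~20–40%, and
  private taxa carry subject-skewed phylum signatures over five phyla).
  Later regimes are abundance-weighted rearrangements of the master: 30% of
  taxa rescaled by lognormal factors (σ = 2) and renormalized — states
  differ by abundance shifts of resident members, not by community
  replacement.
- **Injection events**: by default subjects 5002, 5004 and 5006 receive one
  90%-allochthonous injection near day 340 (330–360), snapped to the
  nearest regime switch so the injected community spans a whole episode and
  appears as its own state; the source is another subject's current
  baseline (an environmental source is available).
- **Sharing trend**: a pool of rare shared taxa is mixed into every
  post-entry sample with weight min(0.05, convergence_rate × day); the
  default rate 5e−5/day yields ~2.6% mixed mass by exit day — enough to
  drive presence/absence (unweighted UniFrac, Jaccard) convergence without
  visibly moving abundance-weighted distances. The rate is a free
  parameter, not calibrated to any measured effect size.
- **Tree**: random coalescent-style joining with exponential branch
  lengths; topology is not taxonomy-constrained — sufficient to exercise
  phylogenetic-distance code, not a model of 16S evolution.

**What passing tests do and do not show.** The generator plants exactly the
structures the pipeline looks for, so recovery results demonstrate
correctness of the machinery, not performance on real data. Two known
emulation gaps: (1) there is no within-regime temporal autocorrelation —
consecutive samples are exchangeable within an episode; (2) the taxon
universe (300 OTUs) is small relative to read depth, the opposite regime
from real 16S data (tens of thousands of OTUs, depth in the tens of
thousands). The second gap matters for source attribution: at
concentration 500 the overdispersion between a state's median profile and
the next state's profile exceeds read-sampling noise on most taxa, so the
self-fitting unknown source absorbs most reads for *every* transition
(median e ≈ 0.97 in the end-to-end cohort run) and planted injections are
only cleanly separable when scored on exact profiles (the recovery
analyses do this). With a realistically huge, sparse taxon universe the
α₂T smoothing handicaps the unknown source and indigenous contributions
dominate ordinary transitions; reproducing that regime is out of reach at
desk scale and is recorded here rather than papered over.

## Numerical and reproducibility choices

- All validation thresholds (q < 0.05, p < 0.05, p < 0.001 for CAO) follow
  the conventional nominal levels; permutation p-values use the
  (count+1)/(n_perm+1) estimator.
- Stage-local seeds derive from the global seed by stable hashing of stage
  names (CRC32), all below 2³¹; rerunning a pipeline with the same config
  and seed reproduces identical output hashes, which the manifest records.
- Degenerate inputs fail loudly with named samples/OTUs: zero-total
  samples, all-zero medians, single-day trend axes, sinks with no mass,
  missing tree leaves.
- Problem sizes in the test suite and acceptance script (e.g., 100–300 OTU
  universes, 20-seed recovery loops, 200-null calibrations at 199–999
  permutations) were chosen to give stable pass/fail behavior at desk
  scale; the statistical criteria themselves are unchanged by these sizes.
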