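# mbtraj — longitudinal gut-microbiota trajectory analysis

`mbtraj` re-implements, as a tested and reusable pipeline, the longitudinal
analysis style used for multi-subject gut microbiome time series collected
under long confinement: a small cohort sampled densely for ~2 years (before,
during and after a 520-day confinement), profiled as OTU count tables. It is
aimed at microbiome researchers who want the individual building blocks —
time-series normalization, steady-state detection, source attribution,
co-abundance groups, beta-diversity trend tests — as callable, validated
functions rather than a one-off collection of notebook snippets.

Because the original sequencing data require external download, the package
ships a first-class synthetic cohort generator that plants known ground
truth (regime schedules, injection events, sharing trends) so that every
downstream stage is testable end to end.

## What it computes

**Trajectory normalization** (per subject). Time points are made fractional
(Σ_o a(t,o) = 1); highly abundant OTUs are selected as the smallest
median-ranked prefix reaching 90% of the summed per-OTU medians; each time
point *s* is then normalized to a reference community built from similar
time points: with *j(t,s)* the Jensen-Shannon distance (JSD) between *t*
and *s*, each time point gets weight *w = (1 − j)²*, the reference value of
OTU *o* is the *w*-weighted median of *a(t,o)* across *t*, and the sample is
rescaled by the median reference/observed ratio over mutually nonzero OTUs.
A horizon transform (median-centered bands of width one median absolute
deviation, capped at ±4) summarizes each OTU's variation for display.

**Steady states.** Samples of a subject are clustered by Ward linkage on the
JSD matrix, JSD(p,q) = √(½KL(p‖m) + ½KL(q‖m)), m = (p+q)/2, log₂. Cutting
the tree at a height *h* yields candidate states; an automatic mode picks
the certified cut with the best mean silhouette width. States are validated
by within-state Spearman correlations (Benjamini–Hochberg *q* < 0.05) and
pairwise PERMANOVA (Anderson's pseudo-F on the distance matrix). Succession
is summarized as episodes, recurrences and a return-to-initial flag.

**Source attribution.** Each transition's new state profile (sink) is
decomposed over the subject's preceding state, all other subjects' state
profiles, and an implicit unknown source, by a collapsed Gibbs sampler with
per-read conditionals
P(z=k) ∝ (c_kt + α₁)/(C_k + α₁T) · (n_k + β). The exogenous score
e = 1 − π(own preceding state) is z-scored within subject (population SD);
large z flags a major change event.

**Co-abundance groups (CAO).** OTUs above 0.1% mean abundance across state
profiles are correlated (Kendall τ-b, exact p at small n), clustered by Ward
linkage on 1 − Spearman ρ into 3–4 groups chosen by silhouette, certified by
a selection-aware permutation test, and exported as a weighted edge list
with per-state over-abundance ratios.

**Beta-diversity trend.** Pairwise inter-subject UniFrac distances
(unweighted and weighted, computed on the supplied phylogeny) at matched
collection days are regressed on day by L1 (median) regression with a
bootstrap p-value on the slope, plus the rescaled coefficients RC_range and
RC_sd.

## Worked example

The numbered scripts under `analysis/` run the full study on the default
synthetic cohort (6 subjects, 27 samples each, days −10…700, read depths
7,759–91,366):

```
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_normalize_trajectories.py
python analysis/03_beta_diversity_trend.py
python analysis/04_steady_states.py
python analysis/05_source_attribution.py
python analysis/06_cao_groups.py
```

Sample output (seed 1):

```
subject 5001: 6 states at height 0.287, validated, returned_to_initial=False, ARI vs planted 1.00
subject 5002: 5 states at height 0.295, validated, returned_to_initial=False, ARI vs planted 1.00
...
subject 5006: 7 states at height 0.290, validated, returned_to_initial=True, ARI vs planted 1.00

unifrac-u: slope -7.527e-05/day (downward), RC_range -0.148, RC_sd -1.121, bootstrap p 0.002 over 405 pairs

OTUs highly abundant in every subject: 7
  5001: 20% of its high-abundance set is cohort-core
```

Reading this: steady-state detection recovers each subject's planted regime
count exactly (adjusted Rand index 1.0 against the generator's truth
labels); subjects flagged by the generator return to their initial
community configuration after exit; the unweighted UniFrac distances
between subjects decline significantly over the study (the planted
rare-taxon sharing), falling by ~15% of their full observed range
(RC_range −0.148) over the sampled span; and each subject shares a fifth to
a third of its highly abundant OTUs with every other subject.

The same pipeline is available as one command (`mbtraj run --seed 1 --out
results/run`) or stage-by-stage through the `mbtraj` CLI
(`simulate | normalize | distance | trend | states | sources | cao | run |
report`), and programmatically through `mbtraj.pipeline.run_pipeline`.

## Layout

```
src/mbtraj/        library: core, simulate, normalize, distance, states,
                   sources, cao, pipeline, cli
analysis/          numbered narrative drivers over the library
tests/             unit, property and statistical acceptance tests
docs/methods.md    models, assumptions, parameter choices, limitations
scripts/           acceptance script
```
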