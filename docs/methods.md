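# Methods

This note documents the models behind `finchnet`, the assumptions they make,
the parameters that matter, what the synthetic-data generator does and does
not emulate, and the measured operating characteristics of the permutation
test. Nothing here is asserted that the test suite or
`scripts/acceptance.py` does not itself compute.

## The synthetic colony generator

The generator (`finchnet.synthetic`) emulates a two-aviary breeding colony
observed through automated feeders. Its defaults are the study conditions the
pipeline is meant for: 7 and 6 families per aviary (each a father, a mother
and a brood of 2–4 fledglings), 33 days of feeder logging, 2 feeders per
aviary, and within each brood a balanced split of chicks into CORT-treated
and control (|#CORT − #control| ≤ 1, mirroring age-standardized hormone
dosing before sex is known — so daughters are treated too, although only
sons sing).

**Latent social structure.** Every within-aviary dyad gets a latent affinity
`a_ij = baseline + within-family bonus + symmetric jitter` (defaults 0.3,
1.5, sd 0.2), clipped at zero; father–son dyads of CORT sons are shifted by
`cort_affinity_effect` (default −0.15, a deliberately small perturbation —
treatment effects on affiliation are subtle in this system, and the size is
exposed as a free parameter). Each bird also carries a gregariousness
offset, N(0, 0.5) on the log-odds scale.

**Visit streams.** Events per feeder-day are Poisson(30) with centres at
least 900 s apart (centres drawn uniformly under that constraint). Each
event is seeded with one uniformly chosen bird; the rest of the roster is
visited in a per-event shuffled order and joins with probability
`sigmoid(−1.5 + gregariousness_i + mean affinity to current members)` —
the simplest sequential-recruitment rule that makes downstream association
indices recover the affinity ordering. Joining birds receive timestamps
jittered N(0, 30 s) around the centre, truncated to the day; with ~10-bird
events this yields durations of order 10² s, the same order as real
flock-feeding bouts. Detections are instantaneous tag reads; entry/exit
pairing is not modelled.

**Songs.** Adult males receive founder motifs: 4 elements, each a smooth
random trajectory (sum of three low-order random sinusoids plus a gentle
trend) of 20–30 frames in k = 2 features. Each son copies his *true tutor*
elementwise with additive Gaussian noise of sd
`copy_noise_sd + cort_copy_noise_effect · 1[CORT]` (defaults 0.12 + 0.08).
True tutors are drawn among the aviary's **adult males** with probability
∝ affinity^w (w = 2 by default): restricting generation to adult tutors
keeps song synthesis acyclic (son-copies-son would need an arbitrary copy
order), while brother–brother similarity still arises indirectly through
shared tutors — which is also the observation the ranking stage should
reproduce. Females receive no motifs.

**What the generator does not emulate.** Real acoustic variability
(elements here are smooth feature traces, not spectrogram-derived
measurements), song development over time (motifs appear fully
crystallized), multi-stage tutor switching, horizontal transmission between
juveniles, observation loss, tag misreads, and any physiological effect of
the hormone treatment beyond the two effect parameters. Tests passing on
synthetic colonies therefore validate the *computational* chain — event
clustering, index computation, alignment, model fitting, permutation
machinery — not the biological fidelity of any particular effect size.

## Event detection

Both detectors operate independently per (aviary, feeder, day). The GMM
detector fits 1-D Gaussian mixtures over timestamps for k = 1..⌈n/3⌉
(k-means++ initialization, 2 restarts, seed derived from (day, feeder) via
crc32 so runs are reproducible across processes), selects k by BIC, assigns
detections to their maximum-responsibility component, and merges components
whose means are within 60 s. The BIC scan stops early once the criterion has
not improved for 10 consecutive k (the BIC profile is near-unimodal here; a
tighter patience of 5 can truncate before the minimum on dense days, 10
reproduced the full scan on every feeder-day we checked at ~5× less cost).
`reg_covar = 1e-3` guards against zero-variance components from repeated
timestamps. The gap detector splits sorted timestamps at gaps > 120 s; it is
the default in large simulation studies because it is two orders of
magnitude faster and agrees with the GMM wherever clusters are separated by
much more than their spread.

## Association indices

The simple ratio index is computed by event-level counting (a bird in an
event counts once): with x = events containing both birds and y_i, y_j the
single-bird counts, `SRI = x / (x + y_i + y_j)`; never-observed dyads get 0
rather than missing so daily matrices are complete predictors. Matrices are
per aviary; cross-aviary dyads are structurally zero and excluded from
models. All metrics include female associates; gregariousness is the focal
bird's summed SRI excluding one named partner.

## Song dissimilarity

Features are z-scored per feature over all frames in the dataset before any
comparison, so no feature dominates the Euclidean frame cost. Element DTW is
the standard full-alignment recursion with boundary matching and no warping
window (element traces are short); ties between predecessor cells prefer the
diagonal, then the left step, making the reported path length — and hence
path-length-normalized scores — deterministic. Motifs are compared by a
second DTW over their element sequences using element dissimilarities as
step costs, normalized by path length (so motifs of different element counts
are comparable; the raw accumulated cost is available via a flag). Males are
compared by symmetrized best-fit averaging over motif renditions: mean over
A's renditions of the best fit onto B's, averaged with the reverse
direction. Tutor ranks sort candidates ascending by dissimilarity with ties
broken by bird ID.

## Regression models

Model tables are built at day-level resolution by default — one row per son
and day, the (single) song score repeated across days against the daily
network predictors, matching a daily-network reading of the design — with a
per-son aggregated variant (network predictors averaged over days) always
reported alongside, since the day-level choice is a genuine judgement call.
Estimation backends: statsmodels `MixedLM` (REML) for linear mixed models
and the Laplace/MAP fit of `BinomialBayesMixedGLM` for the binomial tutor-
choice model (fixed-effect prior sd 5, variance-parameter prior sd 2 — wide
enough to leave moderate effects essentially unshrunk). The LMM fit tries
lbfgs, powell and cg and keeps the best finite-restricted-likelihood
solution: optimizers can report convergence at a degenerate point with an
infinite restricted likelihood, and trusting such a fit corrupts everything
downstream. Designs that make the random intercept unidentifiable (one
observation per group) collapse to OLS with the random variance reported as
zero. Constant predictors raise an error naming the column; complete
separation in the binomial model is flagged in the result, not silenced.
Variance components are reported as percent of total (family + residual =
100; the binomial model uses the latent-logistic residual π²/3). The brood
size and number-of-male-offspring covariates are strongly correlated and are
never co-included; the pipeline runs them as paired model variants.

## Permutation inference

The null model permutes the *datastream*: one step picks a block (aviary,
day, feeder) uniformly among blocks with ≥ 2 events, two events in it, and
two birds A ∈ e1∖e2, B ∈ e2∖e1 uniformly among candidates, and exchanges
them. Event sizes, per-bird bout counts, rosters and the blocking structure
are exactly conserved (audited every 1,000 swaps). After every swap the
affected day's SRI matrix and father–son metrics are recomputed and the
model refit; the default records one statistic per swap from swap 1
(incremental chain, burn-in 0), with thinning and burn-in exposed. The
reference refit is a full REML fit per swap; the fast mode (`refit="gls"`,
non-reference but the default for large chains) freezes the variance
components at the observed REML fit and solves the GLS normal equations in
closed form — at the observed variance components the GLS fixed effects
equal the REML fixed effects, so the observed slope is identical between
modes and only the null draws differ slightly. Two-tailed p-values use the
add-one rule with a cap at 1; one-tailed options exist.

**Measured operating characteristics (and a caution).** On null synthetic
colonies (tutor choice independent of the network, both CORT effects zero)
the association-slope test rejects at α = 0.05 in about 20% of colonies with
1,000-swap chains (200 replicates; `experiments.type1_calibration`), about
17% with 10,000-swap chains, and over 50% when the null is sampled from the
fully mixed chain (20,000-swap burn-in). The mechanism: the chain starts at
the observed network and drifts toward the margin-homogenized network, so
the null distribution's spread understates the sampling variability of the
observed slope's beyond-margin component — the test partially re-detects the
observed slope's own noise. This is the known weakness of datastream-
permutation regression tests (Weiss et al. 2021, *Methods Ecol. Evol.*;
Farine & Carter 2022, *Methods Ecol. Evol.*); the proposed remedy (double
permutation) layers node-label permutations on top, which is outside this
package's scope. Power against strong generated association–similarity
coupling is correspondingly modest at these chain lengths (13–25% across
1,000–10,000-swap designs; `experiments.permutation_power`). Interpret
`p_rand` from this procedure as a descriptive comparison against
margin-preserving rearrangements, not as an exactly calibrated test, and
treat marginal significance with particular caution.

## Numerical and design choices

- **Seed fan-out:** one global seed is hashed (SHA-256, stage name) into
  child seeds per stage, so stages can be rerun in isolation; all seeds are
  < 2³¹.
- **Degenerate inputs:** empty streams yield empty event lists (not errors);
  a day with no events yields a 0 × N GBI and an all-zero SRI matrix;
  single-event feeder-days are legal but unswappable (logged, left
  unchanged).
- **Duplicated-row invariance:** duplicating every table row leaves LMM
  slopes exactly unchanged only when the random-intercept variance is ~0
  (the OLS regime); with a nonzero variance, group sizes enter the GLS
  weights `c_g = ρ/(1 + n_g ρ)` and the estimate shifts slightly. The test
  suite exercises the invariance in the regime where it holds exactly.
- **Problem sizes in the validation experiments:** oracle checks use 1,000
  random instances each; conservation chains 10,000 swaps over a full
  33-day colony; calibration 200 null colonies × 1,000 swaps; power 50
  strong-effect colonies × 1,000 swaps; tutor recovery 3 colonies
  (~50 sons); LMM recovery 200 tables of n = 200. Event-detection recovery
  uses 2-day streams so the GMM's BIC scans stay cheap.

## Known limitations

- The generator's dissimilarity scale is set by the founder-motif geometry
  and copy noise; its absolute values are not comparable to any particular
  acoustic pipeline's scores.
- The GMM detector assumes roughly Gaussian within-event timestamp spread;
  heavily overlapping events degrade both detectors (the generator's 900 s
  minimum spacing sidesteps this regime, deliberately).
- The permutation test's calibration caveat above is the dominant
  statistical limitation; parametric mixed-model p-values for network
  predictors inherit the usual non-independence concerns instead.
- With only ~11–13 families, between-family covariates (brood size,
  treatment composition) are estimated from few effective units; standard
  errors for those slopes are wide and model variants can disagree.
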