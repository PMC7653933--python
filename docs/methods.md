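# Methods

`synthcohort` generates synthetic patient cohorts from a hybrid Bayesian
network and audits the result on three axes: distributional fidelity,
machine-learning equivalence, and re-identification risk. This note
records the models, the numerical choices, and what the built-in
simulated world does and does not demonstrate.

## The generative model

A cohort over variables `x_1 … x_n` is modelled by a directed acyclic
graph and per-node conditional distributions, factorising the joint as

    p(x) = ∏_i p(x_i | pa_i)

where `pa_i` are the parents of node `i`. Categorical nodes carry
conditional probability tables. Continuous nodes carry a Gaussian
mixture per parent configuration (3 components by default) — enough to
represent the skewed, multi-modal shapes of clinical measurements
without committing to a parametric family. When a continuous variable
*conditions* another node, it is discretised into quantile bins
(quintiles by default) purely for conditioning; its own distribution
stays continuous. This is a pragmatic hybrid: fully conditional
Gaussian models were rejected because real primary-care variables are
neither Gaussian nor linearly related.

Synthetic records are drawn by logic (ancestral forward) sampling in
topological order. Evidence nodes are clamped rather than
rejection-sampled: entering `{gender: female}` produces a female-only
cohort drawn from the mutilated network. All sampling, fitting and
search flows from explicit integer seeds; bootstrap resample `i` uses
`seed + i`, and identical (configuration, seed) pairs reproduce every
report byte for byte.

## Parameter fitting

With complete data, categorical CPDs are empirical conditional
frequencies with an add-one-half pseudo-count (so unseen parent
configurations fall back to a flat prior and are flagged), and mixtures
are fitted by weighted EM per parent configuration, warm-started
between outer iterations.

With latent nodes or missing cells, parameters are fitted by EM. The
E-step enumerates, per row group (rows sharing a missingness pattern),
the joint configurations of the unobserved discrete quantities: latent
states, missing categorical states, and the quantile bin of a missing
continuous *parent* (its bin prior is the mixture mass in each bin; a
missing continuous leaf simply integrates out). Enumeration is capped
at 1024 configurations per row; rows needing more have surplus cells
hard-imputed to the column mode first — in the intended regimes
(latents of cardinality 2–4 plus a handful of missing cells) the cap is
never reached. The observed-data log-likelihood is tracked and is
non-decreasing across iterations; because the hidden-state likelihood
is multimodal and the uniform initialisation is a saddle point, CPDs
touched by latent variables receive a small seeded jitter before the
first E-step, and `EMConfig.restarts` keeps the best of several
initialisations (the restarts default to 1; tests of latent recovery
use 3).

## Structure learning

Greedy hill-climbing on the BIC score over discretised data, with
add/delete/reverse moves, at most 3 parents per node, 3 random
restarts, and deterministic lexicographic tie-breaking. The climb runs
on each of B = 10 bootstrap resamples; an arc's confidence is the
fraction of resamples containing it in either orientation, orientation
is by majority, and arcs below confidence 0.5 are dropped. Search is
capped at 20,000 rows (a seeded uniform subsample) — structure recovery
saturates well below that, and the cap keeps 100,000-row cohorts
tractable on one core. Missing cells are completed by seeded draws from
each column's observed empirical distribution before each climb; this
single-completion scheme is a deliberate simplification of full
structural EM (which would re-complete under the current model each
round) — it recovers planted structures reliably in our tests and costs
a fraction of the time. Rows are canonically sorted before resampling,
making the result invariant to input row order. Expert edits
(`whitelist_edit`) add or remove arcs after learning, with cycle
checking; added arcs get confidence 1.0.

## Missing data

Three strategies, selectable in the pipeline:

* **delete** — complete-case analysis; simple, and biased whenever
  missingness correlates with values (MNAR).
* **miss_nodes_states** — each categorical variable gains a
  `"Miss State"` category; each continuous variable gains a binary
  miss-node parent. Missingness becomes part of the joint, is learned
  like any other dependency, and is reproduced faithfully in synthetic
  output. The encoding is exactly invertible (`strip_missing_markers`);
  a sampled value under a `missing` indicator is discarded in favour of
  the sentinel, which is the mechanism, not an error.
* **latent** — on top of the augmented encoding, a constraint-based
  search proposes discrete latent parents. The full pipeline applies
  augmentation first so the EM enumerates only latent states; the
  harder variant — marginalising genuinely missing continuous values
  under a latent that drives both the value and its missingness — is
  exercised directly by the MNAR tests.

The latent search is deliberately the conservative core of
hidden-confounder discovery rather than a full orientation algorithm:
on each of 10 bootstrap resamples it keeps the variable pairs that are
dependent marginally *and* conditioned on every single other variable
(G-test on discretised data, alpha 0.01), aggregates pair support
across resamples, and merges pairs at support ≥ 0.6 into connected
clusters, one latent (cardinality 2 by default) per cluster. Directly
adjacent variables can therefore also attract a latent; that is
accepted — an extra mixture parent over a genuine dependency is
harmless for generation, and the support threshold suppresses noise.
The support threshold, cardinality and resample count are configuration
knobs.

## Fidelity evaluation

* **Chi-squared** per categorical variable, with synthetic relative
  frequencies (scaled to the ground-truth total) as the expected
  distribution and ground-truth counts as observed.
* **Kolmogorov–Smirnov** per continuous variable, with seeded
  subsampling at configurable sizes (1,000 / 5,000 / 10,000 in the
  reference design) because at large n the test rejects on negligible
  differences; D is always reported alongside p.
* **Histogram KLD** with 20 equal-width bins over the pooled range and
  epsilon = 1e-9 added to each bin mass before normalisation.
* **diff_KL protocol**: per iteration, a base sample and 10 disjoint
  resamples of size i are drawn without replacement from the
  population, 10 equal-sized synthetic sets are generated, and
  `diff_KL = mean_{m,n} KLD²(GT^m‖SY^n) − mean_n KLD²(GT‖GT^n)` is
  reported per variable with mean and sample SD over iterations.
  "Mean squared" is read as the mean of squared per-pair divergences
  (config-switchable). A generator that literally resamples the
  population is centred on zero, which the tests assert.
* **Kernel MMD**: biased MMD² with an RBF kernel, bandwidth from the
  median heuristic on pooled pairwise distances, H0 decided against the
  (1−alpha) quantile of a 200-permutation null at alpha 0.05. Mixed
  rows are encoded as one-hot categoricals plus z-scored continuous
  values with missing-indicator columns. The joint sweep runs the test
  on every k-variable subset and reports the H0 acceptance percentage.

## Classifier equivalence

Three classifier families: forward–backward stepwise logistic
regression on AIC, linear discriminant analysis, and logistic
regression with a Gaussian (L2) prior standing in for a Bayesian GLM.
Curves are evaluated on a 100-point score-quantile threshold grid; ROC
AUC by the trapezoid rule over the endpoint-augmented curve (ties in
FPR ordered by TPR), PR AUC by step-wise interpolation walking
thresholds high→low so each recall increment is credited with the
precision at the threshold that first achieves it. Whether the
synthetic curve predicts the ground-truth curve is tested by a
bivariate Granger F-test at lag 1 on the y-sequences. The primary
orientation trains on synthetic and tests on ground truth (the utility
question); the reverse is emitted as secondary. Note that the Granger
null calibration is asserted on stationary AR(1) pairs: independent
random walks are the textbook spurious-regression case and no F-test is
calibrated there.

## Privacy audit

Distances from each synthetic row to the real cohort use a Gower-style
mixed metric by default: range-normalised absolute difference on
continuous variables, 0/1 mismatch on categorical ones, and "missing"
as its own category (missing matches only missing). Clones are exact,
sentinel-sensitive row matches; the default R_clone is the fraction of
synthetic rows cloned, and a combined-denominator variant (clone count
over the pooled cohort size) is available — it is the reading under
which, for a fixed synthetic cohort, clone risk falls as the real
population grows. Inlier pairs are synthetic rows whose nearest
distance falls below the Pr = 0.001 quantile of the positive
nearest-distance distribution with exactly one real record within that
radius; outlier pairs are analogous above the Pt = 0.999 quantile with
a unique nearest record. Exact-zero distances are excluded from the
quantiles so clones are reported separately. A tied nearest record is
deliberately not a pair: ambiguity protects. k-anonymity of a record is
the count of real records within the Pt radius; the audit reports the
smallest k across flagged records. EPV-based sizing
(`epv_sample_size`, default 22.2 events per model degree of freedom)
supports audit-sample design.

## The simulated world

Because real primary-care extracts are access-restricted, all
end-to-end behaviour is demonstrated on a hand-specified true network
over a 23-variable cardiovascular-risk schema (18 categorical, 5
continuous; `strokeha` is the outcome). The DAG encodes clinically
recognised dependencies (age→type 2 diabetes, atrial
fibrillation→stroke/heart attack, smoking→impotence, age→systolic
blood pressure, systolic pressure→its variability, …); every parameter
is an invented fixture constant, not a clinical estimate. Continuous
marginals are skewed mixtures. Missingness: age complete; choleratio
88.47%, bmi 15.85%, sbp 8.37%, sbps 38.25%; categorical variables 5%
MCAR (a default, since only continuous rates were specified upstream).
Choleratio is MNAR: a hidden binary "health-seeking" factor
(prevalence 0.3) both lowers the value (non-seekers +0.9) and controls
measurement (72% missing among seekers vs ~95.5% among non-seekers —
chosen so both hidden states are substantially represented among
observed values, making the mechanism identifiable from the
value/missingness joint while preserving the overall 88.47% rate).

What passing tests show: the pipeline recovers planted structures and
parameters, reproduces marginals at population scale (≥16 of 18
categorical variables non-rejected by chi-squared at n = 100,000), and
the latent strategy reconstructs the MNAR variable's complete-data
marginal strictly better than deletion. What they do not show: fidelity
on real data with unmodelled pathologies — measurement drift, coding
artefacts, temporal structure, rare-category sparsity — none of which
the fixture emulates.

## Problem sizes and defaults

Default sizes used by the test suite and the acceptance script, chosen
to exercise each claim at meaningful scale: world populations of
100,000 (end-to-end fidelity) and 200,000 (missingness rates);
structure/parameter recovery at 50,000 rows with B = 10 bootstraps;
calibration suites at 500 trials; privacy planting at 3,000 synthetic
vs 4,000 real rows. Structure search subsamples to 20,000 rows;
pipeline privacy audits subsample to 2,000 synthetic rows by default.

## Known limitations

* Exact inference is enumeration-only (used in tests); generation needs
  only forward sampling.
* The latent search does not orient edges or distinguish a hidden
  common cause from a direct dependency; it proposes mixture structure,
  not causal claims.
* EM with many missing discrete cells per row falls back to partial
  hard imputation beyond the enumeration cap.
* Gower distances cap the contribution of a missing cell at 1, which
  creates exact ties among equally-incomplete records; tied records are
  never flagged as unique re-identification pairs.
* No differential-privacy accounting and no attack simulation; the
  audit quantifies proximity risk only.
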