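# Methods

## The question and the two routes to a management decision

A clinical management decision for a skin lesion (`NONE` — no further
examination, `CLNC` — clinical follow-up, `EXC` — excision) can be produced
two ways from the same inputs `x` (clinical features, dermoscopic features,
patient metadata):

* **direct** — train a classifier on the management labels:
  `m̂(x) = argmax_m p̂(m | x)`;
* **inferred** — train a diagnosis classifier over the five groups
  `{BCC, NEV, MEL, MISC, SK}` and marginalize its output against the
  empirical conditional priors of the training split,
  `P(m | x) = Σ_d p̂(d | x) · p̂(m | d)`, or, as a binary baseline, map
  malignant predictions (MEL, BCC) to `EXC` and everything else to `NOEXC`.

The inferred route is information-limited: any management variability
*within* a diagnosis — the clinician excising one nevus and reassuring
another because of the severity of its atypical features — is invisible to
it. The package's synthetic cohort makes that mechanism explicit and
testable.

## Synthetic cohort generator

The generator reproduces, exactly, the label structure of the published
1011-case seven-point-checklist evaluation cohort that motivates the
comparison: the 3x5 management-by-diagnosis joint count table (605 EXC,
296 CLNC, 110 NONE; 575 NEV, 252 MEL, 97 MISC, 45 SK, 42 BCC) and the
management-stratified 413:203:395 train/valid/test split, both shipped as
packaged constants. In exact mode every cell count is reproduced
bit-exactly for every seed; a sampled mode draws labels i.i.d. from the
normalized table for large-n property tests. Per-split joint counts beyond
the management stratification are not published, so splits stratify by
management only.

**Severity.** Each case carries a latent severity `s ∈ [0, 1]`, drawn from
a per-management Beta law (NONE ~ Beta(2,6), CLNC ~ Beta(4,4), EXC ~
Beta(6,2); means 0.25/0.50/0.75). Within each diagnosis, management labels
are then reassigned by severity rank — the least severe cases fill the
diagnosis's NONE quota, the most severe its EXC quota — so cell counts stay
exact while management is a monotone function of severity within a
diagnosis.

**Features.** Each modality (clinical, dermoscopic; default 8 dimensions
each) places the five diagnosis class means at `class_mean_scale · e_d` on
the first five coordinates and adds isotropic Gaussian noise
(`noise_sd = 1`). Severity enters along the sixth coordinate — orthogonal
to the class-mean span — with strength `severity_weight · s`, in both
modalities by default (configurable to one modality for planted-signal
ablation tests). With `severity_weight = 0`, management is conditionally
independent of the features given diagnosis, the null configuration.

**Default geometry.** `class_mean_scale = 0.9` puts the diagnosis task in
the realistic partially-confusable regime (test accuracy ≈ 0.65 for the
default models, matching the difficulty implied by the study's reported
managing accuracies of 55–74%); a widely separated geometry makes diagnosis
nearly perfect and collapses the phenomenon under study, because inferred
management then inherits almost no malignancy-probability leakage.
`severity_weight = 6` against unit noise makes within-diagnosis management
learnable but far from deterministic. These two values are the package's
study conditions and are used by every driver and test.

**Criteria and metadata.** The seven dermoscopic criteria are integers in
0..2 drawn Binomial(2, p) with `p = 0.15 + 0.5·s + 0.2·[malignant]`
(clipped), so they correlate with both severity and malignancy — useful as
auxiliary tasks. Sex is uniform over 2 levels, site over 8; elevation (3
ordered levels) increases with severity. Metadata is one-hot encoded (13
columns), with missing values representable as an all-zero block.

**What the generator does not emulate.** Real image feature covariance and
texture structure, the 20 fine-grained diagnosis labels, inter-feature
correlations beyond the single severity direction, rater-specific bias in
panels. Mechanism-level conclusions (which route wins and why) transfer;
absolute accuracy values do not and are not asserted anywhere.

## Classifiers

Softmax models with per-task parameter blocks over the concatenated
modality representation — optionally a per-task tanh hidden layer (default
16 units) before the affine head. The objective is the class-weighted
cross-entropy with inverse-frequency weights `w_j = N/(K·n_j)` (natural
log, probability floor 1e-12), summed over tasks for the 9-head multi-task
model; mini-batches (size 32) are class-balanced on the primary task's
labels (management, or diagnosis for the diagnosis-only model). Both the
balanced sampling and the weighting are applied together, as the training
recipe under study prescribes; note this double-corrects the class
imbalance — the effective posterior is tilted by `1/π_m²` — which is
visible in the results (below). Optimization is plain mini-batch gradient
descent with momentum 0.9, learning rate 0.05, up to 120 epochs with an
epoch-loss plateau stop (tolerance 1e-6), deterministic given the seed.

The hidden layer matters: a purely linear management model is misspecified
(its class-conditionals are mixtures over diagnosis clusters while the
diagnosis model's are single Gaussians), which asymmetrically handicaps
the direct arm and corrupts the null comparison. Sixteen tanh units are
enough for both arms to approximate their tilted Bayes rules.

## Evaluation and statistics

Confusion matrices carry an optional per-cell diagnosis breakdown.
Class-wise metrics are one-vs-rest; zero-denominator cases return 0 with a
flag so macro averages stay defined (an unpredicted class yields precision
0, not NaN). AUROC is the Mann–Whitney probability with half-credit ties,
macro-averaged over defined classes. Probabilistic predictions are scored
against one-hot targets with four distances: 1−cosine; Jensen–Shannon with
base-2 logs (range [0, 1] — the base is a convention choice); Wasserstein-1
over the severity ordering NONE < CLNC < EXC at unit spacing (the ground
metric is a convention choice); Hellinger in the √(1−Bhattacharyya) form.

Paired profiles are compared with the two-sided Wilcoxon signed-rank test
(exact sign-pattern enumeration up to 15 nonzero differences, normal
approximation with tie correction above), Cohen's d on the pooled
(n−1)-denominator SD of the two sets, and percentile 95% CIs from 1000
resamples of size ⌈N/2⌉ — without replacement (sub-sampling) by default,
with replacement available, since the protocol under study names both.
Paired classifiers are compared with the mid-p McNemar test,
`p = 2·(P(X ≤ k) − ½P(X = k))` for `X ~ Binomial(n01+n10, ½)`, `p = 1`
when there are no discordant pairs. Note the mid-p value is guaranteed to
lie between the binomial tail bounds `2P(X < k)` and `2P(X ≤ k)`, but not
universally between the exact-conditional and chi-square p-values.

Rater agreement: Cohen's kappa with marginal-product chance agreement;
Fleiss' kappa from per-item agreement; majority votes with ties defaulting
to EXC (clinically conservative; irrelevant for odd panels); the
leave-one-out Cohen protocol (each rater vs the majority of the rest); and
the panel+model Fleiss protocols — all raters minus one plus the model, and
9 random raters plus the model repeated 1000 times. Argmax decisions break
exact ties toward the more severe management, the clinically conservative
default (a first-index rule is available).

## What the default conditions produce

At the defaults, over ten seeds: the direct model beats the inferred route
by ≈ 9 accuracy points (positive in 10/10 seeds), makes ≈ 20% fewer false
excisions (fewer in 9/10 seeds), and misses fewer malignant cases than the
diagnose-then-map route in 10/10 seeds; the 9-task model is within half a
point of the single-task management model. With `severity_weight = 0` the
mean gap shrinks to ≈ −1.4 points: not exactly zero, because the double
imbalance correction tilts the direct model's decisions toward rare
management classes, costing ~1.7 points on the NEV bulk — a structural
property of the prescribed recipe, inside the ±2-point band the comparison
is judged against, and worth remembering when reading the null.

## Numerical and design notes

* One master seed per run; every stochastic stage (labels, severity,
  features, criteria, metadata, splits, batches, resampling) uses an
  independent child stream, so outputs are bit-reproducible.
* Priors default to smoothing 0 with a hard error on an empty diagnosis
  row; Laplace smoothing is exposed (`(count + α)/(row + 3α)`).
* The weight formula `N/(K·n_j)` is the standard balanced weighting; its
  count-weighted mean is 1, so it rescales rather than inflates the loss.
* Cross-validation partitions into three management-stratified folds and
  reports fold means.
* Problem sizes: drivers use the 1011-case cohort with 10 seeds
  (≈ 0.5 s per trained model); large-n checks use 50,000 sampled cases.
  At n = 50,000 the smallest diagnosis row (SK, ≈ 2,200 cases) has
  binomial sd ≈ 0.01 per cell, so the 0.02 recovery bound is a ≈ 2σ
  statement per draw.
* Known limitations: no calibration analysis; no cost-sensitive decision
  rules beyond the conservative tie-break; the multi-task model shares no
  representation across heads (per-task blocks), so task transfer effects
  are deliberately out of scope; real-image domain shift is only
  approximated by generator-config shifts.
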