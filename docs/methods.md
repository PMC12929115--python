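# Methods

## Study design and data model

The package analyzes multi-reader multi-case grading studies of optic nerve
head elevation. The atomic observation is one grader's integer grade (0–5) of
one eye under one imaging-modality condition. Three diagnostic classes are
recognized: healthy controls and optic disc drusen (both without true edema,
true grade 0) and optic disc edema (true grade 5). Eight modality conditions
are modeled: four single modalities (color fundus photography, FAF, NIR, OCT
RNFL analysis), three duals pairing color with each other modality, and the
all-modality condition.

Eyes of the same subject are treated as independent statistical units by
default (`EYE_BY_GRADER`: one unit per subject × eye × grader). Bilateral
disease makes this assumption optimistic — fellow eyes share anatomy and the
grader saw both — so a `SUBJECT_BY_GRADER` switch averages fellow-eye
accuracies per modality before analysis. Neither choice is privileged by the
data model; the default follows the convention of counting eyes in
ophthalmic reader studies.

## Weighted accuracy scale

The scale maps an assigned grade to a percent accuracy against the true
grade. Four values are structural: A(0|t=5)=0, A(5|t=5)=100, and the interior
anchors A(3|t=5)=70 and A(2|t=5)=30, which fix a 40-point penalty for
crossing the edema/no-edema boundary at constant confidence. The default
fills the two unprinted grades by equal 15-point within-side steps,
A(·|t=5) = (0, 15, 30, 70, 85, 100), the minimal structure consistent with a
two-tier penalty (mild for hesitation, heavy for a wrong-side call). The
no-edema column is the mirror image A(g|t=0) = A(5−g|t=5), which makes
controls and drusen eyes score identically and gives the suite its mirror
and relabeling invariances. Any six-vector satisfying the endpoint, anchor,
monotonicity and two-tier constraints may be supplied instead; note that once
the anchors and strict monotonicity hold, every within-side step is
necessarily below 30 points, so the boundary drop dominates automatically.

Cell summaries are arithmetic means of per-record accuracies per (diagnosis,
modality, grader), with SE = sample SD/√n (undefined at n = 1 and reported
missing, never zero). Grader-pooled tables average the two graders' cell
means so each grader carries equal weight regardless of n.

## Split-plot mixed ANOVA

Accuracy is decomposed in a split-plot design: diagnosis (3 levels) and
grader (2) between units, modality (k = 8) within units. Units lacking any
modality response are excluded listwise (the repeated-measures transform
needs complete profiles) and reported. The decomposition runs in two
orthogonal strata:

- **Between:** ordinary two-way ANOVA on unit means, scaled by k; error is
  units-within-cells with df N − 6.
- **Within:** modality and its interactions with the between terms, fitted to
  per-unit deviations from the unit mean; error df (k−1)(N − 6).

Sums of squares are Type III, computed by full-versus-reduced model
comparison under sum-to-zero contrast coding. The cohort is intrinsically
unbalanced (60/59/30 eyes), and Type III with effect coding is what the
mainstream statistical packages report for such designs; on balanced data
the result coincides with the classical expected-mean-squares decomposition
to machine precision (verified against an independent cell-means oracle and
against R's `car::Anova(type = 3)` during development; pingouin cross-checks
the one-between reduction in the suite).

Sphericity is assessed on S_c = C S Cᵀ, where S is the pooled within-cell
covariance of the k responses (residuals from cell means, divided by the
between-error df n_e) and C is any orthonormal contrast basis (normalized
Helmert by default; the statistics are basis-invariant). Mauchly's
W = det(S_c)/(tr(S_c)/(k−1))^(k−1) is referred to the first-order Box
chi-square approximation, χ² = −(n_e − (2d²+d+2)/(6d))·ln W with
d = k−1 on d(d+1)/2 − 1 df. (R and pingouin add a second-order series term;
the p-values agree to ~10⁻³, and W itself is exact.) Greenhouse–Geisser
ε = (tr S_c)²/((k−1)·tr S_c²) multiplies both df of every within-stratum F
before corrected p-values are computed; ε is clipped to its mathematical
range [1/(k−1), 1], attains 1 exactly under sphericity and the lower bound
for rank-one contrast covariance, and k = 2 forces W = ε = 1. Huynh–Feldt is
deliberately not offered. Note the GG-corrected p is only guaranteed to be ≥
the uncorrected p when F ≥ 1; for F < 1 shrinking the df can move p the
other way, which is expected behavior, not an error.

Degenerate inputs: constant responses produce zero SS everywhere (a numeric
floor of 10⁻¹² × ΣY² absorbs lstsq rounding residue) with F reported as
missing rather than infinite; a singular contrast covariance is flagged and ε
falls back to its lower bound.

Post-hoc comparisons are Bonferroni-corrected over all pairs of the requested
factor: paired t-tests on unit-level differences for modality pairs,
two-sample t-tests on unit means for diagnosis/grader pairs (Welch by
default; pooled-variance available since the choice is not dictated by the
design). Effect sizes are partial η² = SS_effect/(SS_effect + SS_error)
against the effect's own error stratum.

## Confidence analysis

Grades partition into high ({0,5}), medium ({1,4}) and low ({2,3})
confidence. For each diagnosis and each unordered pair of modality
conditions, a 3 × 2 contingency table of level counts is tested for
independence with the plain Pearson chi-square (no Yates correction at any
size, so collapsed 2 × 2 tables are not silently altered). Confidence levels
with zero counts across both columns are collapsed before testing — each
dropped row reduces df accordingly, which is how df = 1 rows arise — and the
action is recorded in the result. Expected counts ≤ 5 set a validity warning
flag but never block the test. Standardized residuals are the Pearson form
(O−E)/√E, chosen over the adjusted form because Σr² = χ² then holds exactly
and is enforced as a property test; cells with |r| > 2 are flagged. The
Bonferroni family for the pairwise listing is all 28 modality pairs within
one diagnosis. A pair whose confidence mix is degenerate (a single non-zero
level) carries no evidence of association and is listed with χ² = 0, df = 0,
p = 1.

## Interrater agreement

Agreement in a (diagnosis, modality) cell is the proportion of eyes, among
those graded by both readers, on which the two integer grades are identical
— all six levels distinct, so a 4 vs 5 disagreement counts as disagreement
even though both are edema calls. A secondary boundary statistic counts
same-side agreement (grades 0–2 vs 3–5). Raw proportion is used rather than
a chance-corrected kappa by design; agreement is insensitive to accuracy
(two graders jointly wrong still agree). Eyes graded by only one reader are
excluded and tallied.

## Synthetic cohort generator

The simulator emulates the cohort shape of the motivating study: 30 control
eyes from 27 subjects, 59 drusen eyes from 32 subjects, 60 edema eyes from
51 subjects (149 eyes, 98 subjects; bilateral subjects are laid out
deterministically), two graders, eight modality conditions, one grade per
(eye, grader, condition) — 2384 records. Each (diagnosis, modality, grader)
cell draws grades i.i.d. from a probability vector over 0–5.

Profiles are specified by two targets: a mean weighted accuracy a\* and a
confidence mix (h, m, l). Within each confidence pair, fraction s of the
pair's mass goes to the correct-side grade and 1−s to its mirror grade — the
unique minimal parameterization consistent with the confidence partition.
Under the default scheme the expected accuracy is then linear in s,
s(100h+85m+70l) + (1−s)(0h+15m+30l) = a\*, and the solver inverts this
exactly, erroring with the achievable interval when a\* lies outside it.

The shipped preset calibrates each cell to the summary percentages printed
for the motivating study where available (e.g. control color 86.7%, control
all-modality 99.5%, drusen FAF 82.3%, edema FAF 65.4%, edema all-modality
93.4%; high-confidence shares 97/73/82% for all-modality), and fills
unprinted cells with values preserving the reported qualitative orderings
(multimodal > dual > single; controls easiest; FAF the best single modality
for drusen; RNFL/color the best singles for edema). One cell (control RNFL)
prints an accuracy and a confidence share that are jointly unreachable under
the mirror-pair model; the accuracy was kept and the confidence share
raised. The preset is an illustrative calibration, not ground truth: it
reproduces cell means and confidence mixes in expectation, not any
eye-level structure.

By default grades are independent across eyes, graders and modalities, so
simulated data are approximately spherical and the ANOVA's assumptions hold
by construction — passing tests therefore certify the machinery, not the
robustness of the design to correlated real data. An optional per-eye random
effect (`eye_effect_sd`, the SD of a latent difficulty added to the
side-split log-odds, shared by all of an eye's observations) induces
positive within-eye correlation across modalities and deliberate sphericity
violation while leaving each cell's confidence mix intact; real reader data
certainly carry such correlation (and grader learning, fatigue and
fellow-eye effects the generator does not model).

## Problem sizes in the test suite

Statistical checks use the cohort sizes the generator defaults to (149 eyes,
2384 records); the empirical-recovery check enlarges to 600 eyes per
diagnosis so that 3-SE bands are tight; the power check runs 200 simulated
cohorts through the full ANOVA at the preset's configured modality effects.
Oracle checks (closed-form EMS decomposition, brute-force chi-square,
eigenvalue-based ε) run on small balanced toys where the closed forms are
exact.

## Known limitations

- The between-unit independence default ignores fellow-eye correlation; the
  `SUBJECT_BY_GRADER` unit definition is a coarse remedy, not a mixed-effects
  model. REML-based random-effect modeling is out of scope.
- The Mauchly p-value uses the first-order Box approximation only.
- The chi-square stage offers no exact (Fisher/permutation) alternative, so
  very sparse tables rely on the validity flag to warn the analyst.
- Agreement is reported without chance correction; kappa-family statistics
  are a possible extension, not included.
- The simulator draws grades i.i.d. given the cell; it does not model
  presentation order, training effects or image-level difficulty beyond the
  optional latent eye effect.
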