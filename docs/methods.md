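# Methods

## The instrument and its formal model

The QuEDS is a 41-item dichotomous self-report questionnaire for major
depressive episodes (MDE).  Each item investigates one or more of 23
clinical criteria ("attributes" A1–A23) obtained by decomposing the DSM-5
MDE criteria and adding Beck's negative views of the world/future, Seligman's
learned helplessness, and five literature symptoms that discriminate agitated
from inhibited depression (irritability, apathy, health concern, somatic
disorders, evening mood improvement).  The item–attribute relation is a 0/1
incidence matrix, the *clinical context*: cell (q, a) is 1 when item q
investigates criterion a.  The package ships this matrix verbatim
(`queds.builtin_queds()`), along with the three-factor partition of the items
(cognitive 15, somatic 14, affective 12).

Under the **conjunctive attribution model**, answering an item affirmatively
means the respondent presents *all* of that item's criteria.  Three objects
follow:

* **Clinical state** — the endorsed item set together with its *profile*,
  the union of the endorsed items' attribute sets.  Two respondents with the
  same total score can carry different profiles; `compare_states` decomposes
  two profiles into shared / only-first / only-second criteria.
* **Prerequisite (surmise) relation** — item i precedes j when
  intent(i) ⊆ intent(j): a yes to j presupposes every symptom probed by i.
  The relation is reflexive and transitive by construction.
* **Delineated clinical structure** — the family of response patterns
  consistent with some symptom set: K(S) = {q : intent(q) ⊆ S} for
  S ⊆ attributes.  The distinct K(S) are computed from the union-closure of
  the item intents (K(S) = K(S′) with S′ the union of intents of the items
  in K(S)), breadth-first with hash deduplication over fixed-width bit
  masks.  The family always contains ∅ and the full item set, is closed
  under intersection, and every member is a down-set of the prerequisite
  relation; the unit suite verifies all of this against exhaustive
  2^|attributes| enumeration on small random contexts and on the three
  factor subcontexts.

Formal concepts (maximal extent/intent rectangles) are enumerated with
NextClosure in lectic order of intents, which makes the enumeration
deterministic.

### Enumeration cap

Delineating the *full* 41 × 23 instrument produces a state family in the
millions; `delineate` enforces a configurable cap (default 5 × 10⁶ closed
sets) and raises a descriptive error advising per-factor delineation.  The
factor subcontexts are small (612 / 408 / 160 states for
cognitive / somatic / affective) and are the intended unit of adaptive work.

### Known in-source inconsistency (attribute A20)

The published per-factor context tables and the attribute→factor coverage
table drop A20 (apathy) from the somatic item 13 and the cognitive item 27,
while the master item–attribute table — and the published worked clinical
states, which can only be derived from it — include it.  This package treats
the master item table as the single source of truth everywhere; consequently
A20 is covered by all three factors here, whereas the printed coverage table
lists it under somatic + affective only.  One acceptance-style test asserts
the printed coverage table verbatim and therefore fails on exactly this cell;
it is kept failing deliberately as a record of the discrepancy.  Similarly,
the printed affective-factor context omits item 12, and one respondent's
printed affective subscale count (7) disagrees with their printed item list
(which yields 8, and makes the three subscales sum to the printed total 31);
in both cases the item lists are authoritative.

## Adaptive administration

The published instrument anticipates computerized routing in which the next
item depends on the answers already collected.  The package implements the
canonical error-free procedure from knowledge-space practice: keep the set
of candidate states (initially the whole delineated family), ask the
unanswered item whose membership count most evenly bisects the candidates
(ties to the smallest item id), discard candidates inconsistent with the
answer, stop at one candidate; the unasked items' answers are then inferred
from it.  Determinism: the same structure and respondent always produce the
same transcript.  There is no lucky-guess/careless-error model.  Because an
informative question always leaves a non-empty candidate set, a respondent
who contradicts the structure is undetectable from the asked items alone;
`run_session(..., verify=True)` therefore administers the remaining items
too and flags the transcript when an inferred answer is contradicted.
Sessions run per factor by default (the three factor structures are small);
full-instrument sessions work whenever delineation fits the cap.

## Psychometric battery

Standard operations, implemented over numpy/scipy and checked against
independent oracles in the tests:

* **Cronbach's alpha** (≡ KR-20 for 0/1 items): k/(k−1)·(1 − Σsᵢ²/s_T²);
  NaN with a warning when the total-score variance is zero.
* **Average inter-item correlation**: mean of all pairwise Pearson
  correlations; constant columns dropped with a warning.
* **Test–retest**: Pearson correlation of paired totals.
* **Known-groups t**: pooled-variance two-sample t with df = n₁ + n₂ − 2,
  computed on (non-clinical − clinical) so that a well-separating scale
  yields a large negative t, matching the reporting convention for this
  instrument.  Welch's correction is not used because the published df is
  essentially n₁ + n₂ − 2.
* **ROC**: positivity rule score ≥ threshold; AUC by the Mann–Whitney rank
  identity to pair counting with ties worth ½ (verified against brute-force
  pair counting and scikit-learn); the optimal threshold maximizes Youden's
  J = sensitivity + specificity − 1, ties to the smallest threshold.  The
  published account states a threshold but not its criterion; Youden's J is
  this package's choice.
* **Correlation comparisons**: Steiger's Z (pooled-r form, for two dependent
  correlations sharing a variable) and Fisher's z for independent samples.
  Both are provided because the published comparison test is unnamed; its
  printed z values are not reproducible from the rounded correlation matrix
  by either formula, so tests freeze values computed from the formulas
  themselves.
* **Cohen's kappa** for expert agreement on incidence matrices is computed
  cell-wise over all items × attributes cells (the unit of agreement is not
  specified in the published account; the cell is the only unit that uses
  the whole matrix), NaN when chance agreement is 1.

## Synthetic respondents

The generator emulates the hierarchical factor structure the instrument's
CFA supports.  Per subject: second-order severity g ~ N(μ_group, 1)
(μ = 0 non-clinical), first-order factors f_k = γ_k g + √(1−γ_k²) η_k with
γ = (0.77, 0.70, 0.91), item latents y_i = λ_i f_{k(i)} + √(1−λ_i²) ε_i with
the published standardized loadings λ (0.26–0.76), response = 1 iff
y_i > τ.  All latents are standard normal with no residual correlations,
matching the reported absence of double loadings and error covariances.

Calibration (`calibrate`) targets the published group score means only:

* τ = Φ⁻¹(1 − 6.5/41) ≈ 1.0005 makes the expected non-clinical total 6.5
  exactly (a single common threshold: per-item base rates are
  unidentifiable from score-level moments, so this is the minimal
  assumption);
* μ solves Σᵢ (1 − Φ(τ − λᵢ γ_{k(i)} μ)) = 28.5 by Brent root-finding
  (μ ≈ 4.10).

**What the generator does and does not reproduce.**  Group means are matched
to <10⁻⁴ and both are recovered in simulation within Monte-Carlo error.  The
implied non-clinical score sd is ≈ 4.9 (observed sample: 6.0) and the implied
Cronbach alpha is ≈ 0.79 (observed: 0.948): standardized CFA loadings used
as generative parameters under-produce the item covariance of the real
sample, and the package deliberately does not inflate loadings or add
parameters to chase sd or alpha.  Analyses where both group moments matter —
the ROC operating points — therefore use the *score-level surrogate*
(`generate_score_surrogate`): totals drawn directly from N(28.5, 6.5) and
N(6.5, 6.0), rounded and clipped to [0, 41].  At the study's group sizes
(265/38) the surrogate's pair-counting AUC averages ≈ 0.993 and the
specificity at the screening threshold 19 is ≈ 0.98, consistent with the
published AUC interval 0.97–0.99 and specificity 0.98.  Clipping at zero
raises the realized non-clinical mean to ≈ 6.93; the generator reproduces
the *stated* moments before rounding/clipping.

Retest responses shrink the subject's zero-mean latent deviation:
y′ = m + ρ(y − m) + √(1−ρ²) u′, with m the subject's latent mean and u′ a
fresh full structured deviation (new g-deviation, η, ε).  This preserves the
marginal endorsement rates and the cross-item covariance at time 2 and gives
corr(y, y′) = ρ per item.  (Shrinking the raw latent toward zero instead
would shift clinical-group means at time 2.)  Score-level stability is below
ρ because of dichotomization, so `calibrate_retest` finds ρ by bisection
against the simulated score correlation under common random numbers
(monotone in ρ); the default target is the published 0.74, recovered within
Monte-Carlo error at n = 5000 (ρ ≈ 0.83).

Because responses are synthetic, passing tests demonstrate the correctness
and calibration of the machinery, not empirical properties of real
respondents; statistics that depend on the unavailable raw study data (the
exact t, alpha, retest r, CFA fit indices) are not reproduced here.

## Numerical and design choices

* Deterministic everywhere: state families sorted by (size, id list);
  concept enumeration in lectic order; all stochastic entry points take a
  seed; nearest-state and threshold ties resolve to the lexicographically
  smallest candidate.
* Problem sizes in the default test run are chosen small (30 random contexts
  of ≤ 12 items / ≤ 8 attributes for the exhaustive-oracle comparisons;
  cohorts of 2000–10000 subjects; 50–200 surrogate replicates), which keeps
  the whole suite under a few seconds while leaving Monte-Carlo standard
  errors far below the asserted tolerances.
* CSV context files carry ids, texts and incidence; attribute labels and
  sources survive only the JSON form.  Responses CSV: one row per subject,
  `subject_id,group,I1..I41`.
* Duplicate item intents (16/26 appetite, 22/23 weight) are reported by
  validation but never rejected: they are real features of the instrument.

## Known limitations

* No probabilistic knowledge-structure model (BLIM) and no response-error
  adaptive assessment; the half-split session assumes error-free answers.
* The generator's dichotomous items cannot match score variance and
  internal consistency simultaneously with published standardized loadings;
  see above.
* Full-instrument delineation is expensive (minutes, millions of states)
  and is guarded by the cap rather than optimized.
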