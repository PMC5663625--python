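# Methods

## Support semantics under missing data

A conjunctive query is evaluated per instance into one of three states:
*in* (every condition holds and every referenced value is observed), *out*
(at least one condition is violated by an observed value), *unknown*
(no violation, but at least one referenced value is missing).  A definite
violation dominates missingness: a conjunction is falsified by one false
literal regardless of the other conjuncts, so an instance with a violating
observed value is *out* even if other referenced values are missing.

Crossing the two query states yields the nine-cell partition E₍x,y₎ used by
the accuracy measure.  The query non-missing Jaccard index

    Jqnm = |E1,1| / (|E1,1| + |E?,1| + |E1,?| + |E0,1| + |E1,0|)

penalizes instances described by one query but unevaluable by the other
(E?,1, E1,?) and ignores E?,?, E0,?, E?,0.  When no missing values
interfere it equals the plain Jaccard index (a property test enforces
this).  A 0/0 denominator (both supports empty) is defined as 0 — no
evidence of association — with a warning.

## Significance

The supports are modelled as independently sampled with marginals
p₁ = |supp(q₁)|/|D| and p₂ = |supp(q₂)|/|D|; the overlap is then
Binomial(|D|, p₁p₂) and the p-value is the upper tail at the observed
overlap, computed with `scipy.stats.binom.sf` (`logsf` provides a finite
log-space value far past float underflow; the test suite pins both against
an exact rational term-summation oracle).  Choices worth stating:

- |D| is the full dataset size, not a non-missing subset.
- |supp(qᵢ)| counts only *definite* members; `unknown` instances are
  excluded.  Whether they should count is genuinely open; excluding them is
  consistent with the support semantics above and is the documented choice.
- p-values are reported raw, with a user threshold (default 0.01); no
  multiple-testing correction is applied — downstream users filtering large
  mined sets should apply their own.

## Tree induction

Queries are generated from multi-target predictive clustering trees: binary
trees whose split at each node maximizes impurity reduction summed over all
binary targets (variance reduction; for 0/1 targets the gain of a split of
m rows into L and R is Σₜ [S²_L/|L| + S²_R/|R| − S²/m] over per-target sums
S).  Every non-root node becomes a rule: the conjunction of split outcomes
on its root path, with one-sided numeric outcomes canonicalized to closed
intervals over observed values (`x > t` → `[succ(t), max_obs]`) and
same-attribute conditions merged by interval intersection.

Policies the PCT literature leaves open, fixed here for determinism:

- Candidate thresholds are midpoints between consecutive distinct sorted
  values; categorical splits are one-vs-rest equality tests.
- Instances missing the split attribute are excluded from gain computation
  and routed to the child with more non-missing members (tie → left).
- Equal-gain ties break to the lowest column index, then the smallest
  threshold (strict improvement required to switch).
- `min_leaf_size` is enforced on non-missing child membership, which is
  conservative for children that also receive routed-missing instances.
- Categorical right branches denote "≠ c", which a pure equality condition
  cannot express; categorical conditions are therefore value-set
  memberships (singleton sets print as equalities).

Defaults: `max_depth` 8 (aligned with the 8-condition query cap) and
`min_leaf_size` equal to the lower bound of the support interval — smaller
nodes cannot yield acceptable supports.

## The mining loop

Initialization stacks each view on attribute-wise shuffled copies of itself
(each synthetic cell is drawn with replacement from a random original row,
preserving marginals while destroying inter-attribute correlation) and
grows a tree separating originals (target 1) from copies (target 0); its
nodes seed the rule sets.  Note that a *single-attribute* association leaves
per-column marginals untouched, so initialization only detects
within-view structure; cross-view structure is found by the iterations.

Each iteration turns the opposite view's previous rules into binary
targets (unknown membership counts as 0), grows a tree per view, and
crosses the *new* rules of each view with the *previous* iteration's rules
of the other view — never same-iteration pairings (a structural test pins
this).  Survivors of quality screening go to the set optimizer; iterations
that produce no rules are skipped with a warning, keeping the previous
rules live.  The default iteration budget is 50; the bundled scaled-down
scenarios use 5–25, which recovers the planted associations they contain.

Query minimization (greedy removal of conditions, insertion order, to a
fixpoint; a removal sticks iff Jqnm does not decrease and quality still
holds) runs on every member at the end of the run.  In strict and soft
constraint modes it additionally runs before insertion, and a redescription
whose minimization pruned a constraint attribute is discarded — the
attribute of interest evidently carried no support information.  Suggested
mode deliberately skips both the pre-insertion pass and the discard rule so
that with a zero constraint weight it reproduces unconstrained mining
bit-for-bit (a test enforces this equivalence).

## Set optimization

The bounded set (default capacity 100) keeps live counters of how often
each instance is covered and each attribute used.  A member's score is

    sc(R) = α₁(1 − Jqnm) + α₂ redScoreInst + α₃ redScoreAttr [+ α₄(1 − redScoreConst)]

with redScoreInst(R) = Σ_{i∈supp(R)} cover(i by others) / Σ_{R'} |supp(R')|
and the attribute analogue over the attribute multiset.  A candidate's
numerator counts coverage by *all* current members and its denominator
includes its own contribution.  Below capacity candidates append; at
capacity the member with the largest sc(member) − sc(candidate) is replaced
iff the difference is strictly positive (ties: discard the candidate;
among members, earliest-inserted wins) — strict improvement keeps the
policy deterministic and monotone.  Default weights are ⅓ each
(constraint weight 0); constrained runs typically use ¼ each.  Inadmissible
constraint scores (strict/soft gates) map to +∞ and never enter the set.

## Constraint modes

For constraint sets C = {C₁…Cₙ} over attribute names, the graded score is
½·maxᵢ |attrs(R)∩Cᵢ|/|Cᵢ| + ½·|attrs(R)∩(∪Cᵢ)|/|attrs(R)|.  Strict mode
requires some Cᵢ ⊆ attrs(R); soft mode requires a non-empty overlap;
suggested mode only scores.  Rule *pairs* are pre-screened on their joint
attribute set (strict: some Cᵢ jointly covered; soft: any overlap) — a
deliberately weak filter, with the full predicate enforced on the
assembled redescription, since requiring each individual rule to satisfy a
multi-attribute constraint would wrongly reject pairs that satisfy it
jointly.  Instance-level constraints are an acknowledged non-goal; the API
keeps a granularity slot.

## Post-hoc analysis

Support-set entropy is Shannon entropy (base 2) of the class labels within
supp(R), over the classes *present* in the support — a homogeneous group
scores 0 regardless of how many classes the cohort has.  Co-occurrence
tables count each unordered attribute pair within a redescription's
attribute set once per redescription, split by view-pair class (e.g.
bio-bio / clin-clin / bio-clin).  Pair correlations on the raw columns drop
missing entries pairwise and choose the method by a normality screen:
one-sample Kolmogorov–Smirnov against a normal with estimated parameters at
α = 0.05 on each attribute; Pearson iff both pass and neither is ordinal,
Spearman otherwise.  Estimating the parameters makes the screen liberal
(the classical KS null assumes fixed parameters); it is a screen for
choosing a coefficient, not a test of normality, and is flagged as such.
Group-vs-control distribution comparisons (Anderson–Darling,
Kolmogorov–Smirnov, Mann–Whitney U) are deliberately delegated to standard
statistical routines; the module only exposes the group-extraction step.

## Synthetic data

The generator emulates a two-view cohort: uniform background values on
[0, 100], a five-level ordinal status label (CN, SMC, EMCI, LMCI, AD), and
planted subgroups whose values on chosen attributes fall in narrow
intervals (width ≤ 20% of the range, so chance overlap stays improbable
and the binomial p-value stays discriminative at n ≈ 500) in both views.
Planted subsets are label-homogeneous; background instances that land
inside a plant's full box by chance are evicted so the ground-truth queries
describe exactly the planted subset when noise is zero.  Noise perturbs a
fraction ε of planted cells outside their interval; missingness masks every
cell independently at rate m.  What it does **not** emulate: realistic
biomarker distributions, inter-attribute covariance of real cohorts,
informative missingness, or label noise — so passing recovery tests shows
the machinery works, not that real-data mining will be as clean.

In the bundled recovery scenario (n = 500, one 100-instance plant, support
interval [50, 200], 20% missingness) the plant uses one attribute per view:
with k planted attributes per view the plant's expected definite support is
100·0.8^(2k), and the interval's lower bound of 50 requires k = 1.

## Known limitations

- Conjunctive queries only; disjunction and negation are out of scope.
- Single-threaded; the Cartesian combination pass is quadratic in rule-list
  sizes (bounded in practice by `min_leaf_size` limiting tree size).
- The set optimizer is greedy and order-dependent (by design, matching the
  replace-on-improvement policy); it does not globally optimize the set.
- Numeric tree splits assume totally ordered attributes; dates and ordinals
  are treated as numbers by the reader unless declared categorical.
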