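# Methods

This note records the statistical model, the generative model behind the
synthetic cohorts, the numerical conventions, and the design choices made
where the design was genuinely open.  It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## The abridged multiple decrement life table

The analysis treats six ordered stages — egg; pre-parasitism larva
(sampling weeks 2–4); parasitism-window larva (weeks 5–9); overwintered
larva before the adult flight period; overwintered larva after it; adult —
and five mutually exclusive causes of death in fixed column order:
parasitism (parasitoids pooled with the rare predators), plant defense
(antibiosis killing neonates), cannibalism (obligate: one larva per
infested stem eventually consumes all co-occupants), unknown factors, and
pathogens (entomopathogenic fungi on overwintering larvae).  The stage
labels deliberately skip an intermediate larval instar; the field protocol
never distinguishes one, and we do not invent a stage the data cannot fill.

Stage-specific probabilities of dying are estimated independently per stage
from examined counts, `aq_x = d_x / l_x`, and the cohort schedule follows
the recursion `al_0 = 1`, `ad_x = al_x·aq_x`, `al_{x+1} = al_x − ad_x`.
Within a stage, `ad_x` is apportioned among causes proportionally to the
observed cause counts, with no within-stage competing-risk correction —
this is the standard abridged-table arithmetic, and it is what makes the
cause columns sum exactly to `ad_x`.  Stage probabilities estimated from
independent cross-sections are treated as conditional-on-entry
probabilities; no correction is attempted for the same cohort being sampled
repeatedly across windows (see "what the weekly design can and cannot
estimate" below).

Two cause columns exist internally: the conditional within-stage
probabilities `cq_ix = d_ix / l_x` and the unconditional cohort proportions
`ad_ix = al_x·cq_ix`.  Printed tables in this literature conventionally
label the columns as conditional while printing the unconditional values
(they sum to `ad_x` down the column); serialisation therefore emits the
unconditional values, and both are stored.

### Counting rule for `l_x`

A dissected stem reveals its whole history: a live larva implies a hatched
egg, a parasitoid cocoon implies a larva that reached the vulnerable
window.  The aggregator therefore uses *entrant counting*: each occupant
contributes one unit to `l_x` for every stage it is observed to have
reached, and one death to `d_ix` at its death stage.  Death stages are
taken from the evidence where it is stage-diagnostic (consumed-egg codes →
egg; neonate evidence and cannibalised-larva remains → pre-parasitism
larva; parasitoid evidence in a stem sample → the vulnerable window, since
parasitism cannot act earlier) and from sampling time otherwise.  Entrant
counting is what makes estimated tallies agree exactly with a complete
necropsy (see the simulator section); its visible consequence is that raw
`l_x` is monotone non-increasing, unlike raw field tables built from
point-in-time bins, whose `l_x` column can be non-monotone.  The life table
never uses raw `l_x` for cohort survival in either case — survival comes
from the `aq_x` recursion.

The obligate-cannibalism bookkeeping is applied at aggregation: whenever a
unit holds more than one live occupant, all but one presumptive survivor
(a larva when present, else one egg) are recorded as cannibalism decrements
immediately — live eggs at the egg stage, extra live larvae at their
observed stage.  This mirrors how dissectors score multiply-occupied stems
and is exact whenever a resident larva is already present; scored before
any larva has established, it can misattribute a death that plant defense
would have claimed (quantified below).

## Elimination of cause and irreplaceable mortality

For two competing causes the net probabilities solve the system
`q_1/q_2 = D_1/D_2` (proportionality of risks) and
`(1−q_1)(1−q_2) = 1−D_1−D_2` (joint survival under independence), which
reduces to `D_1·q_2² − (D_1+D_2)·q_2 + D_2·(D_1+D_2) = 0`.  The smaller
root is taken: whenever `D_1+D_2 < 1` the larger root exceeds 1, which a
20×20 grid property test verifies along with agreement (1e−10) with an
independent bisection solver.  Degenerate inputs short-circuit: a cause
with zero crude mortality leaves its competitor's net equal to its crude.
Crude totals summing to ≥ 1 (no survivors) raise a domain error — net
probabilities are undefined without survivors.

With five causes, each cause is solved *against the pooled remainder*
rather than through a simultaneous five-equation system; the simultaneous
solution exists in the test suite only, as an oracle.  Two elimination
modes are exposed.  `totals` (default) operates on whole-cohort crude
totals `aD_i` — this is how pooled headline statements read.  `per_stage`
eliminates within each stage's conditional probabilities and recombines
survival multiplicatively across stages before subtracting — this is how
spreadsheet implementations of the method operate on tables.  Reports
record the mode.

Irreplaceable mortality of a focal cause is
`D_total − [1 − Π_{j≠focal}(1−q_j)]`, truncated to `[0, D_focal]`.  The
lower truncation guards floating-point negatives.  The upper truncation
enforces the interpretation that a cause cannot be credited with more
unreplaced deaths than it produced: under the exact simultaneous solution
the bound holds automatically, but the pooled-remainder approximation can
overshoot it when total mortality is extreme (survival of a few percent)
and the focal cause is small.  The truncation corrects that approximation
error; it never binds on profiles like the published pooled totals.

Combined "in the presence of all causes" percentages for cause subsets are
crude sums `100·Σ D_i`, reported at half-up integer rounding (the
convention that reproduces published combination claims); joint *net*
mortalities `1 − Π(1−q_i)` are computed alongside as a diagnostic.  The two
agree only approximately, and the package makes no attempt to force them
to match.

## The synthetic cohort generator

### Generative model

Eggs per stem are negative binomial (dispersion configurable; Poisson as a
special case).  The overdispersion represents multiple females
concentrating eggs in attractive stems — the behaviour that makes obligate
cannibalism a first-order mortality force.  No distribution for
eggs-per-stem is published for this system; the default (mean per cultivar
0.8–3.2, dispersion 1) was chosen once for testability and realistic
infestation levels, not calibrated to field data.

Time runs in sampling weeks.  Eggs arrive in the first three oviposition
weeks (offsets 0–2 relative to the first sampling week, weights
0.40/0.35/0.25), are visible as live eggs exactly one week after arrival,
and hatch two weeks after arrival unless consumed.  The first neonate to
hatch and survive plant defense becomes the *resident*; it consumes every
other occupant: eggs are eaten before they can hatch (egg cannibalism, egg
stage), and co-hatching neonates that also survived plant defense are
consumed as young larvae (larval cannibalism) one week later.  Hatching
within an arrival group is sequential with a configurable overlap
probability (default 0.15) governing how often co-hatching — and hence
larval cannibalism and observable multi-larva stems — occurs.  With this
timing, every neonate and cannibalism event falls in sampling weeks 2–4,
matching the pre-parasitism window, and plant defense acts only on
neonates.

The resident then faces parasitism (probability per cultivar, struck at a
uniform week in 5–9) and early unknown-factor death (same window); the
earlier event wins, ties favour parasitism, and parasitism never occurs
outside the vulnerable window.  A survivor cuts the stem at maturity and
overwinters through the two stub stages, each with sequential
pathogen-then-unknown risks, then emerges as an adult.

Structural consequences, enforced as tests: at most one occupant per stem
ever survives; every stem that is multiply occupied when cannibalism
resolves has exactly one resolution survivor and at least one cannibalism
death; per stem, eggs laid equal deaths plus the emerged adult.  (A stem
whose occupants all hatch and all die of plant defense has no cannibalism
death — with per-neonate antibiosis risk no generative model can avoid
that corner, so the cannibalism guarantee is stated conditional on reaching
the resolution multiply occupied.)

Ground truth is the realized event log — one (stem, stage, cause) row per
death — so true decrement proportions are tallies divided by the cohort
size, exactly, per stratum.

### Sampling operators

`weekly` reproduces the field design.  Each plot's stems are assigned to
weekly uproot samples (3 bags × 35 stems, weeks 1–9) without replacement;
a sampled stem is destroyed and contributes one record of its state at that
week — live occupants, plus evidence of all deaths so far (death evidence
is treated as persistent).  Stems never summer-sampled whose larva cut the
stem form the stub pool, from which 25 stubs are dissected before the
flight period (alive or dead overwintered larva) and 25 after (emerged or
dead).  Truth is generated for the full stand independent of sampling, so
destructive observation censors records but never the truth.

`census` is an idealised complete necropsy: every infested stem yields one
stem record carrying its full summer history, and every cut stem one stub
record at the phase that reveals its overwinter fate.  Under census
observation, aggregation reproduces the ground-truth event log *exactly* —
stage by stage, cause by cause — which the test suite asserts both at
n ≤ 50 stems (exhaustive comparison) and at 10,000 stems × 20 replicates
(the parameter-recovery acceptance check, with binomial standard errors at
the realized cohort size reported alongside).

### What the weekly design can and cannot estimate

The weekly operator exists to emulate the field method, and it inherits
that method's biases, which the simulator makes measurable: deaths are
visible cumulatively from their event week while survivors are visible
only within their stage window; stubs subsample the survivors; and the
doomed-occupant inference is occasionally wrong before a resident larva
establishes.  In development runs at ~20,000 eggs per replicate these
effects shifted crude totals by up to ±0.03 (absolute) for the affected
causes — several binomial standard errors at that cohort size.  Passing
recovery tests on census records therefore demonstrates that the
*pipeline* is correct; it does not certify that a destructively sampled
field study is unbiased, and the weekly-mode tests assert only that
estimates improve with scale and preserve structure, not exact recovery.
This limitation is a property of single-dissection cross-sectional
designs, not of the implementation.

## Numerical conventions

* All life-table and elimination arithmetic is carried in double precision;
  conservation (`Σ ad_x + final survival = 1`) and the product identity
  (`final survival = Π(1−aq_x)`) hold to 1e−12 and are property-tested.
* Rounding is a display concern.  Serialisation rounds half-up to 3
  decimals, keeping a 4th digit for values below 0.002 — the threshold
  below which a value is not representable on the 3-decimal grid relative
  to its own magnitude, and the rule that reproduces published tables'
  mixed 3/4-decimal cells.  An optional per-step rounding mode reproduces
  printed schedules whose entries were rounded stage by stage.
* Published totals rows are not always self-consistent with their own
  printed stage cells (rounding artifacts accumulate); reproduction tests
  assert stage cells everywhere but totals only where the printed
  arithmetic is self-consistent.
* Integer percentages use half-up rounding, never banker's rounding.
* The adult row of a serialised table shows final survival in the
  "proportion dying" position, replicating the conventional printed
  layout; internally the value is survival and the adult stage absorbs no
  decrements.
* Empty non-terminal stages are an error by default; an explicit option
  bridges them with `aq_x = 0` and a warning.  Week-1 larvae (week 1
  normally contains eggs only) are assigned to the pre-parasitism stage
  with a warning rather than rejected.
* Random streams are hierarchical (site → plot → stem, with a separate
  per-plot sampling stream), so enlarging a design leaves existing plots'
  draws untouched, and a fixed config and seed reproduce record streams
  byte-identically.

## Known limitations

* Independence of competing risks is assumed throughout the elimination
  analysis, as in the joint-survival product; no dependent-risks (copula or
  frailty) variant is provided.
* No confidence intervals on life-table entries; uncertainty is summarised
  only across replicate plots (mean ± SE of per-plot percentages), and
  inferential comparisons (mixed models, post-hoc letters) are out of
  scope by design.
* The simulator has no spatial structure within plots and no mechanistic
  oviposition behaviour; attractiveness is a scalar intensity, so
  attractiveness–antibiosis correlations can be emulated but are not
  hard-coded.
* Evidence codes are assumed pre-assigned by the dissector; there is no
  specimen-level diagnosis, and missing strata are never imputed.
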