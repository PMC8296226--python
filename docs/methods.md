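# Methods

This note documents the models, parameter choices and numerical conventions
behind `orflow`, and what the synthetic data can and cannot establish.

## 1. Data model and preprocessing

Tracks are point tables (case, role, tag, t, x, y, z) in seconds and
millimetres; four staff roles (anesthetist, assistant nurse, scrub nurse,
surgeon) and six surgical phases (Preparation, Craniotomy, TR, MRI, Close,
End).  All analytics run on a uniform 1 Hz grid obtained by linear
interpolation within the observed time span (never extrapolating); at 1 Hz
the planar distance between consecutive samples is read as speed in mm/s.
Tracking hardware samples much faster (tens of Hz); 1 Hz is the analysis
rate at which the speed interpretation holds and LCSS matrices stay small.
Conventions:

- Phase intervals are half-open `[t_start, t_end)`, so consecutive phases
  partition the samples exactly; a sample on a boundary belongs to the
  following phase.
- Speeds and LCSS distances use (x, y) only; z is carried through I/O but
  ignored (the activity-space analysis is planar).
- Tag dropouts longer than 5 s (configurable) are not interpolated across;
  `split_on_gaps` severs the trajectory there rather than fabricating
  movement.
- Speed histograms report both the mode (the distribution's peak) and the
  mean per group; the two differ for skewed step-length distributions, so
  both are exposed rather than conflated.

## 2. Interaction measurement (LCSS)

Samples `a_i`, `b_j` match when their planar distance is ≤ ε **and**
|i − j| ≤ δ.  The LCSS is the longest monotone (order-preserving) matching;
similarity = LCSS / min(|a|, |b|), which is robust to one member's brief
presence.  Defaults ε = 500 mm (≈ within-reach distance, well above the
80 mm tracking-noise floor) and δ = 5 samples; both are free parameters of
`LCSSParams` because no canonical values exist for this setting, and the
test suite sweeps them.  The DP is banded: with a temporal window δ no
match can occur outside |i − j| ≤ δ, so only the band is recursed
(O(n·δ)); outside the band the table is filled by running maxima.  The
banded recursion is verified against exhaustive enumeration of all monotone
matchings on short trajectories.

Per phase segment all 16 ordered role pairs are measured (4² including
self-pairs, which are identically 1 and excluded from modelling).  A role
absent from a segment yields similarity 0 with a missing flag; missing
attributes are treated as the "Low" level when fitting (absence ≈ no
interaction) and omitted from the evidence when classifying (marginalized
over), which keeps CPTs well defined without inventing an "absent" state.

Continuous similarities are discretized per column into Low/Medium/High by
tertiles.  Boundaries are estimated on training rows only and frozen for
validation rows (the discretizer is an sklearn transformer precisely so it
can sit inside a per-split pipeline); ties go to the lower level.

## 3. Bayesian-network classifier

Everything is discrete and exact:

- **Scores.**  The maximized log-likelihood of a DAG decomposes over node
  families as Σ N(x, a)·log(N(x, a)/N(a)).  Pure likelihood provably
  prefers the complete graph, so the default structure score is BIC,
  log L̂ − (log N / 2)·Σᵢ (|states(Xᵢ)|−1)·Π_parents|states|; raw-likelihood
  scoring stays available (`score="loglik"`) for comparison.
- **Search.**  Greedy best-improvement hill climbing from the empty graph
  over single-arc additions, deletions and reversals, with acyclicity
  checked per move and optional forbidden/required arc lists.  Tie-breaking
  is lexicographic over (move kind, edge), making the search fully
  deterministic; a seed parameter is accepted for interface stability but
  has nothing left to decide.  Family scores are cached, so each candidate
  move costs one counting pass at most.
- **Parameters.**  CPT entries are (N(x, a) + α)/(N(a) + α·|states|);
  α = 0 is the pure MLE (used inside the structure score), α = 1 is the
  classification default — at a few dozen training rows unsmoothed CPTs
  produce zero posteriors on held-out level combinations.  Parent
  configurations never observed get a uniform row with a warning.
- **Inference.**  Exact variable elimination over labelled factors;
  verified against full joint enumeration to 1e-10.  The sklearn-style
  classifiers additionally cache the (tiny) full joint table and the
  posterior per evidence pattern, which makes thousand-fold holdout cheap.
  Classification is the MAP phase; exact posterior ties break by the fixed
  state order.
- **Baseline.**  Naive Bayes is the same machinery with the star DAG fixed.

Attribute state spaces widen to the full {Low, Medium, High} vocabulary
whenever the observed values are a subset of it, so a level unseen in a
small training split is still legal evidence.

## 4. Synthetic operating room

The clinical recordings behind this line of work are not deposited, so the
generator emulates their documented structure: a 5.8 × 4.8 m room with the
entrance at (4000, 0) and tool table at (1000, 3000); surgeon and scrub
nurse centred in the room with the largest and smallest activity spaces,
assistant nurse along the bottom, anesthetist in the upper-right corner;
80 mm Gaussian positional noise; 1 Hz sampling; six-phase schedule
Preparation → Craniotomy → TR → MRI → TR → Close → End, gamma-distributed
durations (means 5–14 min, CV 0.25), with a second MRI+TR imaging cycle
inserted per case with probability 0.65 so that ten cases yield ≈ 83 phase
segments — matching the data volume of the study design, whose source of
extra segments beyond 60 is otherwise unexplained.

**Movement model (invented, and labelled as such).**  While present, each
role follows a discrete mean-reverting (AR(1)) walk around its zone anchor.
Per-phase speed scaling adjusts the step size and the pull jointly so that
the stationary spread stays equal to the zone dispersion (slow phases mean
slow staff, not huddled staff).  Staff start a case in position; a role
absent for a phase re-enters later through the entrance.  Scrub nurses are
present in Preparation with probability 0.25 (they seldom appear then) and
0.85 in End.

**Cooperation.**  Pairwise cooperation intensity c ∈ [0, 1] per (pair,
phase) drives rendezvous events: with hazard 0.18·c per second the pair is
steered to a shared waypoint between their anchors for an exponential dwell
(mean 5 s, min 2 s); members are exclusive — the strongest-cooperation pair
in a segment claims shared time first.  Many short events rather than few
long ones keep the per-segment similarity variance low.  Two optional
coupling mechanisms (a log-normal per-segment teamwork factor shared by all
pairs, and the assistant nurse joining surgeon–scrub rendezvous) are off by
default and exist to generate attribute–attribute dependence on demand.

**Default cooperation table.**  The qualitative anchors are fixed by the
study system: surgeon–scrub high in Craniotomy/TR and low in
End/Preparation, and each pair's profile has a plausible clinical reading
(the assistant–surgeon axis peaks at setup and closure, the
anesthetist–assistant axis around imaging and emergence, the
assistant–scrub axis at opening and final instrument count).  Within those
anchors the six phase-intensities of the four selected pairs are laid out
as *balanced, pairwise-orthogonal level codes*: each pair's Low/Medium/High
groups cover roughly a third of the segment mass (weighted by the expected
phase frequencies, TR being over-represented by the imaging cycles), and
any two pairs map the six phases to six distinct level combinations.  This
maximizes each attribute's information about the phase while keeping the
mutual information between attributes near its combinatorial minimum
(log 6 − 2·log 3 ≈ 0.41 nats at the deterministic limit) — without it, two
highly informative attributes shortcut each other during greedy structure
search and the network drops part of the evidence.  Intensity values
L ≈ 0.02–0.05, M ≈ 0.30–0.40, H ≈ 0.70–0.95 give well-separated occupancy
fractions under the rendezvous hazard.

The generator is a pure function of (config, seed); per-case seeds derive
from the master seed by a counter-based scheme (`SeedSequence([seed, i])`),
stable under reordering.

## 5. Validation protocol

`repeated_holdout` draws uniform train/validation splits without
replacement (default 40 training segments, the remainder validating,
1000 repetitions), refits the entire pipeline — tertile boundaries,
structure, CPTs — on the training rows of each repetition, and scores
validation accuracy.  A draw whose training part misses an entire phase is
redrawn (logged, capped).  `compare_classifiers` runs the identical split
sequence through several classifiers, so per-repetition accuracies are
paired.  Splits are uniform over segments, not stratified and not grouped
by case; segments from one case are therefore not independent between train
and validation, which mirrors the original protocol but inflates absolute
accuracies somewhat — a caveat that applies to the emulated numbers below.

Two calibration facts the test suite exploits:

- Under per-repetition random labels (i.i.d. uniform over the six phases),
  expected holdout accuracy is exactly 1/6 for any classifier, because the
  validation labels are independent of everything learned.  A single fixed
  label permutation of a balanced finite pool does **not** have this
  property: train and validation class compositions are anti-correlated
  (expected accuracy falls below 1/6), and the fixed table's spurious
  feature–label dependence is shared by both sides (pushing it above).
- In parameter-recovery checks the effective sample size is per parent
  configuration, not per dataset; recovery benchmarks therefore use
  single-parent families so that ±0.05 sits at ≥ 4σ at N = 5000.

## 6. What passing tests do and do not show

On the synthetic defaults the learned network classifies the six phases
with mean holdout accuracy ≈ 0.8 and tracks naive Bayes within ≈ 0.01 —
the same qualitative picture as the clinical study (BN ≈ naive Bayes, far
above chance), at somewhat higher absolute accuracy because the generator's
interaction contrasts are cleaner than clinical reality: no intern
surgeons rotating in, no tag occlusion or multipath noise beyond isotropic
Gaussian error, no within-phase workflow drift, independent cases with
identical geometry.  The clinical accuracies themselves (≈ 0.70/0.68) are
properties of undeposited data and are not reproduction targets.  What the
suite does establish: the LCSS and inference implementations are exact
(oracle equivalence), structure and parameters of a known workflow-shaped
network are recoverable from realistic sample sizes, the holdout protocol
is chance-calibrated and leakage-free, and the full pipeline is
deterministic given a seed.

## 7. Problem sizes

Default experiment sizes were chosen so every check runs on a laptop core:
10 cases × ~8.3 segments of 4–14 simulated minutes at 1 Hz (~44k track
points), 1000 holdout repetitions per classifier, 20-seed recovery and
monotonicity sweeps, 100-pair LCSS and 50-network inference oracles.  The
full test suite runs in about a minute; the acceptance script in well under
a minute.
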