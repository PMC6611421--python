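# Methods

## Design

The stimulus space is the full Cartesian crossing of non-word token ×
duration profile × intensity profile × pitch profile, each profile one
of the three stress positions AP/PE/U (stress on syllable 1/2/3). With
the canonical three non-words this is 81 conditions; the package
generalises to k non-words (27k conditions) but every balance property
used below only needs the profile factors to be fully crossed, which
holds for any k. Trial lists are unbiased seeded permutations of the
complete design (one pass per list); the permutation algorithm is
numpy's Fisher–Yates under `SeedSequence` spawning, so lists are
mutually independent and exactly reproducible. The number of lists and
the seed are parameters rather than the fixed three lists of the
original procedure — presentation order does not enter any statistic, so
this generalisation is free.

## Consistency scores

Responses are scored per cue as binary matches between the chosen
position and that cue's profile; the match proportion p is rescaled as
1.5p − 0.5, mapping chance (1/3 on a balanced design) to 0. OC is
defined as DC + IC + PC. The same rescaled proportion within each
(non-word × position × cue) cell (9 trials per cell at k = 3) gives the
27 cell subscores, and within each (cue × position) pool (27 trials)
the 9 cue-by-position subscores. Exact identities on an equal-cell
design, enforced by tests: the mean of a cue's three position subscores
equals the cue's overall score, and the mean of all 27 cells equals
OC/3. We keep OC = DC + IC + PC as the primary definition rather than
the mean of the 27 cells (which differs by the factor 3); both are
available through the identities.

The SD across the 27 cells uses the sample convention (ddof = 1). The
cell SD is what separates two behaviours with identical OC ≈ 0: a true
guesser (all cells near 0, small SD) and a responder with opposite
consistencies cancelling out (cells split between high and low, large
SD). The extreme illustration is a constant responder: all aggregate
scores are exactly 0, yet 9 cells sit at 1.0 and 18 at −0.5
(SD = √(13.5/26) ≈ 0.72), far outside the calibrated SD bound.

Incomplete response sets are a hard error by default; an opt-in mode
scores available trials with raw proportions, flagging that the
chance-level interpretation then holds only approximately.

## Responder model

Synthetic participants are i.i.d. per-trial mixtures: follow cue X with
probability w_X (routing the profile through an optional fixed
permutation of the positions), otherwise respond stimulus-independently
from a bias distribution (uniform by default). Independence across
trials is the minimal model consistent with frequency statements like
"follows duration on half the trials"; such statements are honored in
expectation (0.5 · 81 is not an integer, so no exact-frequency responder
exists on one pass). Closed form on a balanced design: with f the
number of fixed points of the permutation, E[XC] = 0.5 · w_X · (f − 1)
— w_X for the identity (f = 3), −0.5 · w_X for a derangement (f = 0) —
and cross-cue and bias terms vanish exactly by full crossing.

`position_weights` lets a cue's weight depend on the position its own
profile indicates on the current trial (e.g. "uses pitch only for
final-stress contours"), emulating cue-by-position interactions; the
remainder is absorbed by the guessing component and only simulation
(not the closed form) supports it. Batch simulations derive
per-participant generators by `SeedSequence(seed).spawn(n)`.

## Null calibration

The random-response region is calibrated by simulating n_sims
(default 10,000, the convention for this design) uniform guessers on
the complete design and taking empirical quantiles of OC (central
`level` range, default 95%) and of the cell SD (upper `level` bound).
Quantiles are nearest-rank (inverse empirical CDF): on one pass of the
81-trial design OC is lattice-valued (multiples of 1/54, since
OC = total matches/54 − 1.5) and interpolation would manufacture
off-lattice bounds. The choice is corroborated analytically: the null
OC has variance 54/54² and P(OC ≤ 14/54) ≈ 0.976, so the 97.5%
nearest-rank quantile sits at 14/54 ≈ 0.259 for most seeds and one
lattice step above for the rest. Box membership is boundary-inclusive
(conservative toward the null) and the one-sided Monte-Carlo exceedance
p-value uses the add-one convention, (1 + #{null ≥ OC})/(n_sims + 1),
so it is never zero.

The joint box coverage for a true guesser is not level² by fiat: the
two axes are calibrated marginally, so coverage lies between
2·level − 1 and level (measured ≈ 0.91 at level = 0.95). Tests of
cohort proportions therefore allow three binomial standard errors
around that interval.

## Reporting

Group summaries are descriptive: per-group means, SDs and t-based 95%
confidence intervals of DC/IC/PC/OC (swappable for a bootstrap if
needed), counts and proportions inside the random box, and the 3 × 3
cue-by-position mean profile. Inferential machinery (repeated-measures
GLMs, sphericity corrections, rank tests, effect sizes) is deliberately
out of scope; only Monte-Carlo exceedance p-values are exposed.

## Synthetic cohorts and what tests do (and do not) show

The demo pipeline simulates three cohorts of 15/18/15 participants:
an adult-like pitch-dominant mixture (weights 0.078/0.042/0.614 for
duration/intensity/pitch), a child-like weak-pitch mixture
(0.075/0.023/0.131), and a guessing cohort (all weight on the random
component) standing in for a clinical group whose published behaviour
is near-random. The cue weights equal the group mean consistencies
they emulate, since E[XC] = w_X. The generator reproduces mixture
behaviour and cue-by-position interactions but not reaction times,
learning or fatigue across trials, individual weight heterogeneity
within a cohort, or the audio itself — so passing tests validate the
statistical machinery on its stated model, not the perceptual claims
of any particular dataset.

## Problem sizes and numerical conventions

Default simulations use 10,000 null responders (seconds of CPU;
vectorised over participants × trials × cues). Parameter-recovery
tests stack 100 passes of the design (8,100 trials), bringing the
binomial standard error of each cue score below 0.01; assertions allow
three standard errors. Proportions are validated to [0, 1] before
rescaling; scores are plain floats; CSV artifacts are UTF-8 with
headers and decimal points, and every random draw in the package flows
from an explicit seed, making pipelines bit-reproducible.
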