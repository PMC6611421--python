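# stresscue

Cue-weighting analysis for three-alternative lexical-stress perception
experiments.

## The problem

In a stress-perception task a listener hears a trisyllabic non-word
(e.g. */tatata/*) and reports which syllable carries the stress:
antepenultimate (**AP**, first), penultimate (**PE**, second) or
ultimate (**U**, third). Three acoustic cues signal stress — syllable
**duration**, RMS **intensity** and the **pitch** contour — and the
experimental trick is to dissociate them: each cue independently carries
the profile of one of the three positions, fully crossed with the
non-word token (3 × 3 × 3 × 3 = **81 conditions**, of which 9 are
congruent and 72 dissociated). Because the crossing is complete, how
often a listener's responses track each cue reveals that listener's cue
weighting, uncontaminated by any response bias.

This package provides the full analysis chain for such designs:
design/trial-list generation, consistency scoring, Monte-Carlo
calibration of the "random responder" region, synthetic responder
simulation, and group-level reporting. It is aimed at psycholinguists
and auditory psychophysicists running (or re-analysing) balanced
cue-dissociation experiments.

## The statistic

For cue X ∈ {D, I, P}, let *p*ₓ be the proportion of trials on which the
response equals X's profile. Under stimulus-independent responding on a
balanced design *p*ₓ = 1/3 exactly, so the **consistency score** is the
affine rescaling

&nbsp;&nbsp;&nbsp;&nbsp;XC = 1.5 *p*ₓ − 0.5 ∈ [−0.5, 1],

with 0 at chance, 1 when cue X determines every response, and −0.5 when
the response *never* matches X. **Overall consistency** is
OC = DC + IC + PC. Key properties (all unit-tested):

- a mixture responder that follows cue X with probability wₓ has
  E[XC] = wₓ and E[OC] = w_D + w_I + w_P;
- any response bias cancels exactly (a constant responder scores 0);
- a responder that systematically mislabels a cue (a permutation with no
  fixed points) scores −0.5 · wₓ on that cue.

The same rescaled proportion computed inside each of the 27
(non-word × position × cue) cells gives the **cell subscores**; the SD
across them separates true guessers (low SD) from responders whose
positive and negative consistencies cancel in OC (high SD). The
**random-response region** is the rectangle in (OC, SD) space holding
95% of Monte-Carlo uniform guessers on each axis; on the 81-trial
design it comes out at OC ∈ [−0.259, +0.259] and SD ≤ ≈0.293.

## Worked example

```python
from stresscue import *

design = full_design()                         # 81 conditions
trials = randomized_lists(design, 3, seed=7)[0]

# a responder who follows duration on 1/4 of trials, intensity on 1/4,
# and guesses the rest
model = ResponderModel(w_duration=0.25, w_intensity=0.25)
print(expected_scores(model))
# ExpectedScores(dc=0.25, ic=0.25, pc=0.0, oc=0.5)

rs = simulate_responses(trials, model, seed=11)
s = consistency_scores(trials, rs)
# DC=0.278 IC=0.148 PC=0.037 OC=0.463 sd_cells=0.265

calib = simulate_null(trials, n_sims=10_000, seed=0)
# null box: OC in [-0.259, 0.259], sd_cells <= 0.292
print(classify(calib, s, participant_id="demo"))
# in_random_region=False, oc_exceedance_p=0.0004
```

The observed scores scatter around their expectations (81 trials is a
noisy estimate of a single participant's weights), the simulated OC of
0.463 falls well outside the ±0.259 random range, and fewer than 4 in
10,000 null simulations reached it.

Scikit-learn-style estimators wrap the same core
(`ConsistencyScorer().fit(trials).transform(response_sets)`;
`RandomResponseClassifier(n_sims=10_000).fit(trials).predict(scores)`),
and a CLI exposes each stage:

```sh
stresscue run --demo --seed 3 --out demo_out   # full synthetic pipeline
stresscue design --seed 4 --out out/           # or stage by stage:
stresscue simulate|score|calibrate|classify|report --help
```

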