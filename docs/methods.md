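# Methods

## The model

`twentyq` simulates linguistic communication as active inference under a
shared, two-level (deep temporal) generative model of a simplified "Twenty
Questions" game. Two objects are stacked vertically; each is a square or a
triangle, coloured green or red, giving 16 possible scenes. Agents reduce
their uncertainty about the scene by asking closed questions and listening
to answers, exchanged as discrete words.

### Conceptual level (one step per phrase)

Nine categorical hidden factors:

| factor | states | control |
|---|---|---|
| narrative | prompt, question, answer | fixed cyclic transitions |
| question type | shape, location, colour | controllable |
| noun | square, triangle | controllable (semiotic) |
| adjective | green, red | controllable (semiotic) |
| adverb | below, above | controllable (semiotic) |
| upper/lower colour, upper/lower shape | 2 states each | uncontrollable, absorbing |

Policies are the 24 combinations of targets for the controllable factors; a
policy's transitions move those factors to their targets at the first step
and hold them there, so the topic committed to in a question remains in
play for the answer. The narrative cycles prompt → question → answer over
the conceptual horizon of T = 3 (one exchange).

### Lexical level (one step per word)

A *syntax* factor (20 word-slot states chained into phrase templates, with
"?" and "!" as absorbing terminal grammar states) and three *semantic*
factors copied from the semiotics. The likelihood maps syntax × semantics
to one of 16 word tokens. Phrase templates: "Ready ?" (prompt), "Is a
[noun] [adverb] ?" (shape), "Is the [noun] [adverb] ?" (location), "Is a
[adjective] [noun] [adverb] ?" (colour), "Yes !", "No !", "Not sure !".
The lexical horizon is 6 (the longest phrase); shorter phrases pad with the
absorbing terminal.

### The link between levels

The lexical level's initial-state prior is a tensor conditioned on the
conceptual state combination. Prompts start at "Ready"; questions at the
"Is" slot of the template selected by the question type; answers at "Yes" /
"No" / "Not sure" according to the *congruence rule*: "Yes" is generated
when, and only when, the attributes the question interrogates match the
scene at the location named by the adverb. Shape and location questions
interrogate the shape (noun) at the location; colour questions interrogate
shape and colour together (the location question's semantics are a
modelling choice — the figure defining the game leaves it open). The
"not sure" initial state receives a configurable likelihood
(`not_sure_likelihood`, default 1/6) irrespective of the scene, with
"Yes"/"No" sharing the remainder. Setting it to zero removes agnostic
answers entirely (the folie-à-deux variant).

The same tensor serves as the conceptual level's likelihood mapping: its
"outcomes" are the lexical level's inferred initial states. Descending
messages contract the tensor with conceptual expectations to give the
lexical prior; ascending messages contract it with the lexical posterior
over initial states to update conceptual beliefs once per phrase, after the
terminal grammar state is reached.

## Belief updating

State expectations are factorised over factors and represented for every
time of the level's horizon (past and future alike). Each new outcome
triggers a fixed number of update iterations (default 16, read as 16 ms
bins of simulated time, so a word lasts 256 ms): the log expectation
("depolarisation") accumulates a state prediction error combining

* a forward message — the log of the transition-propagated expectation from
  the previous time (the initial prior at the first time),
* a backward message — the log of the transposed-transition-propagated
  expectation from the next time,
* likelihood messages — the expected log likelihood of observed outcomes
  under the other factors' current expectations,

minus the current log expectation; expectations are recovered by softmax.
The step size `kappa` (default 0.25) makes updates partial, so inference
deliberately fails to converge within an epoch — residual uncertainty
carries over, as intended for a model of neural dynamics.

Numerical choices:

* All probabilities are floored at `exp(-16)` inside logarithms, bounding
  every message and prediction error.
* The forward/backward messages are logs of propagated expectations, not
  expectations of logs. The two coincide for sharp beliefs; around ties the
  expectation-of-log variant has a gain of the order of the floor magnitude
  and amplifies float-level asymmetries into spurious belief collapse
  within a single epoch, whereas the propagated-expectation form is stable.
  The cost is the well-known overconfidence of this family of schemes, and
  that free-energy descent is exact only for single-step models (any
  factorisation); over multiple represented times occasional transient
  increases of order 0.01 nats occur near the fixed point. The test suite
  asserts monotone descent in the single-step regime.
* Lexical perception re-infers the phrase from the descending prior at each
  word, given all words heard so far, rather than continuing the
  variational iterate across words. Evidence still accumulates word by word
  (each re-inference sees one more likelihood message); what is avoided is
  the premature lock-in of a parse on near-deterministic syntax chains
  before a disambiguating word arrives.
* Conceptual beliefs carry across the phrases of an exchange; across
  exchanges, the scenic posterior becomes the next exchange's empirical
  prior, clipped at the probability floor so that a single contradictory
  answer can always revise it.

## Policies, precision, action

Expected free energy `G` is evaluated per policy over the exchange from its
opening beliefs, as minus the mutual information between predicted states
and outcomes (epistemic value) minus the expected log preference (pragmatic
value, with preferences entered as costs: -1/4 for "Yes", +1/4 for "No").
The algebraically equivalent risk + ambiguity form is computed alongside
and cross-checked to 1e-10 in the tests. The policy posterior is
`softmax(-F - gamma G)`; policies whose posterior falls below `exp(-3)` of
the best are pruned (Occam's window, configurable).

Precision (`gamma = 1/beta`) follows the standard fixed-point update
`beta <- beta_prior + (pi - pi0) . G` with `pi0 = softmax(-gamma G)`
(`update_precision`, with `beta_prior = 1`, tolerance 1e-4, at most 16
iterates). Within a dialogue, the session-level gamma trace uses a damped
version of the same update — one step per variational iteration, damping
16, carried across epochs — so gamma rises while evidence discriminates
among policies and relaxes toward `1/beta_prior` during uninformative
prompts. The resulting phasic peaks fall in answer epochs. Note that under
this update the phasic deflection scales with the gap between the best
policy's G and the prior-average G; as knowledge accumulates that gap
*grows* (late in the game a single informative question stands out against
many uninformative ones), so per-answer peaks grow over the first four
exchanges rather than attenuate. We report the dynamics as the update
produces them.

Speaking is outcome selection, applied level by level: the conceptual level
commits to the lexical initial states that minimise expected surprise
`-(E[ln A] . o)` under the selected policy's predicted states, and the
lexical level then emits, word by word, the least surprising token. Ties
break to the lowest index, making transcripts reproducible; a seeded
sampling mode over the policy posterior is available and is the default for
the storytelling scenario (deterministic selection would repeat a single
confirmatory question). Committing at the conceptual level is what lets
"Not sure" emerge: under the floored expected-log criterion a definitive
answer is selected only when the relevant scenic belief exceeds roughly
0.9, otherwise the scene-independent "not sure" state wins.

## Dialogue scenarios

Turn-taking is a fixed schedule (agency is not modelled): within each
exchange the answerer speaks the prompt, the questioner the question, the
answerer the answer. Every party — speaker included — assimilates the same
word stream through the identical perception path, so belief updates depend
on words alone (pure communication; asserted by a replay test). The
generative process of the solo scenario is simply a second agent with delta
scenic priors. Scenarios: `solo` and `dyad_qa` (uncertain agent questions
for four exchanges, then answers two), `role_reversal` (the confident
partner questions throughout), `storytelling` (the confident partner asks
and answers its own questions for four exchanges), `folie_a_deux` (both
uncertain, alternating questioner; with the default "not sure" likelihood
they maintain mutual ignorance, with it at zero they converge on a shared
fantasy). The violation paradigm reruns the fifth exchange of the solo
protocol with a scripted question about the lower object's colour and
shape, supplying either the confirming or the contradicting answer.

## Synthetic electrophysiology

Traced expectations (one value per 16 ms bin, i.e. 62.5 Hz) are read as
population firing rates and their logs as depolarisations. Derivations:

* **rasters** — one binomial draw per unit per bin at the expected rate,
  fully seeded (the only stochastic element in the pipeline);
* **LFP/ERP** — zero-phase two-pass Butterworth band-pass, order 2 per
  pass, 4–32 Hz; edges can be trimmed by a warm-up length;
* **time–frequency** — complex Morlet wavelet amplitude (width 7) at 1 Hz
  steps from 4 to 32 Hz;
* **cross-frequency coupling** — Pearson correlation between amplitude
  time-courses of every frequency pair (constant rows report 0);
* **violation comparison** — matched-run difference waveforms with latency
  measured as time from answer onset to the peak absolute pooled filtered
  response;
* **dopamine** — the concatenated gamma iterates with per-exchange peak
  detection.

## What the simulations do and do not show

The generative process *is* the model: answers are produced by an agent
with delta priors under the same likelihoods the listener inverts, so the
study conditions are exactly self-consistent — there is no model mismatch,
no acoustic noise, no open vocabulary, and no learning of the likelihood or
transition parameters. Passing tests therefore demonstrate properties of
inference and communication under a shared model, not robustness to
misspecification. Turn-taking is scripted; agents have no representation of
who is speaking. The continuous acoustic level (words-to-sound) is out of
scope, as are structure learning and metacognitive states.

## Problem sizes and runtimes

Default runs use the study conditions throughout: six exchanges of three
phrases, 16 iterations per outcome, 24 policies over a 3×3×2⁷ conceptual
state space and a 20×2×2×2 lexical space. A full scenario takes roughly
10–15 s on one CPU core; the complete test suite, which runs six scenarios
plus the paired violation runs and several hundred brute-force oracle
comparisons on random fixtures (state/outcome/policy counts capped at 4),
runs in a few minutes.
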