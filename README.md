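# twentyq

Deep discrete active inference for simulated linguistic communication.

`twentyq` is for computational neuroscientists and cognitive modellers who
want to simulate *communication as inference*: two agents (or an agent and
a generative process) that share a hierarchical generative model of a
simple visual scene and align their beliefs purely by exchanging words.
The package provides a generic discrete active-inference engine, a
two-level ("Twenty Questions") generative model of question–answer
dialogue, scenario runners, and derivations of the synthetic
neurophysiology implied by the belief updating — rasters, local field
potentials, event-related responses, time–frequency maps, theta–gamma
cross-frequency coupling, violation (mismatch) waveforms and a simulated
phasic dopamine signal.

## The model in brief

A hidden scene comprises two stacked objects, each a square or triangle in
green or red (16 scenes). A *conceptual* level evolves once per phrase and
carries the narrative (prompt → question → answer), the question type, the
semiotic topic (noun, adjective, adverb) and the four scenic attributes; a
*lexical* level evolves once per word and turns syntax × semantics into
word tokens. Perception inverts the model by a variational message-passing
scheme: with `ν = ln s` the depolarisation of a population encoding the
expectation `s` of a hidden state under policy `π`,

    ε(π,τ) = ln(B(π,τ−1) s(π,τ−1)) + ln(B(π,τ)ᵀ s(π,τ+1)) + E[ln A·o(τ)] − ln s(π,τ)
    ν̇ = ε,    s = σ(ν)

run for 16 iterations of 16 ms per outcome. Action *is* outcome
generation: the speaker emits the outcomes that maximise accuracy,
`o = argmin −(E[ln A]·o)·s`, level by level (phrase commitment, then word
emission). Policies — which question to ask about what — are scored by
expected free energy `G = −(epistemic value) − (pragmatic value)`,
equivalently risk + ambiguity, with preferences `C = −¼` for "Yes" and
`+¼` for "No", and selected through `softmax(−F − γG)` with precision `γ`
whose update trace is read as phasic dopamine.

Questions are chosen for their epistemic value: an agent with uniform
scenic beliefs asks single-attribute questions (binary congruence, 1 bit),
then conditions later questions on what it has learned, resolving the
scene in four questions.

## Worked example

```python
import twentyq as tq

result = tq.run_scenario({"scenario": "solo", "seed": 1})
print(result.transcript.to_text())
```

prints the six exchanges of the default game (true scene: green square
above a red square):

```
[1:prompt] partner: Ready ?
[1:question] agent: Is a square below ?
[1:answer] partner: Yes !
[2:prompt] partner: Ready ?
[2:question] agent: Is a square above ?
[2:answer] partner: Yes !
[3:prompt] partner: Ready ?
[3:question] agent: Is a red square above ?
[3:answer] partner: No !
[4:prompt] partner: Ready ?
[4:question] agent: Is a green square below ?
[4:answer] partner: No !
[5:prompt] agent: Ready ?
[5:question] partner: Is a green square above ?
[5:answer] agent: Yes !
[6:prompt] agent: Ready ?
[6:question] partner: Is a red square below ?
[6:answer] agent: Yes !
```

The agent's first four questions each resolve one scenic attribute — note
that the negative answers are just as informative as the affirmative ones:
"No" to "red square above" (having established the upper object is a
square) implies it is green, and "No" to "green square below" implies the
lower square is red. After exchange 4 the questioner's posterior is
essentially certain:

```python
agent = result.agents["agent"]
print(agent.snapshots[3]["lower_colour"])   # [~0, ~1]  (green, red) -> red
print(agent.map_scene())
# Scene(upper_colour='green', upper_shape='square',
#       lower_colour='red', lower_shape='square')
```

and it answers the partner's two questions (exchanges 5–6) correctly. The
same API runs the dyadic scenarios (`dyad_qa`, `role_reversal`,
`storytelling`, `folie_a_deux`); `tq.run_violation` produces the paired
standard/deviant runs of the mismatch paradigm, and `twentyq.ephys` turns
any recorded traces into rasters, LFPs, spectrograms, coupling matrices and
dopamine traces.

From a shell:

```
twentyq run --scenario solo --seed 1 --out results/solo
twentyq ephys --trace results/solo/traces.npz --out results/solo_ephys
twentyq violation --seed 1 --out results/violation
```

## Evidence dilution

The report model behind "I'm not sure" answers is exposed directly: with
report likelihood `r`, option `i` is reported with probability
`r·belief_i` and "not sure" with probability `1 − r`. With `r = 0.9` and a
belief concentrated on one of 100 options, reporting that option is 9 times
more likely than "not sure"; with a uniform belief each option falls below
1 % and "not sure" becomes more than 10 times more likely than any single
option:

```python
import numpy as np
per_option, not_sure = tq.report_probabilities(np.full(100, 0.01), 0.9)
print(per_option[0], not_sure / per_option[0])   # 0.009  11.11...
```

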