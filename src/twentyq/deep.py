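"""Deep (two-level) temporal composition of discrete generative levels.

Hidden states at a higher level generate the *initial* states of the level
below: the initial-state prior of the lower level becomes a tensor (a
:class:`LinkTensor`) conditioned on the higher level's state combination.
The lower level cycles over its full sequence (here, the words of a phrase)
for every single transition of the level above (a phrase of the narrative),
and is re-initialised at each higher-level step.

Two messages couple the levels:

* **descending** — the link tensor contracted with the higher level's
  (Bayesian-model-averaged) state expectations yields an empirical prior
  over the lower level's initial states (:func:`descend`);
* **ascending** — once the lower level has completed its sequence, its
  posterior over initial states is contracted back through the link to give
  a likelihood message over higher-level state combinations
  (:func:`ascend`), which enters the higher level's update for the current
  epoch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .mdp import (
    BeliefState,
    EpochTrace,
    LevelModel,
    SIMPLEX_TOL,
    bayesian_model_average,
    expected_free_energy,
    free_energy,
    policy_posterior,
    select_outcome,
    update_states,
)

__all__ = ["LinkTensor", "DeepModel", "descend", "ascend", "run_deep", "DeepRunResult"]


@dataclass
class LinkTensor:
    """Per lower-level factor: P(lower initial state | higher state combo).

    ``arrays[i]`` has shape ``[K_lower_i, *higher_state_dims]`` and every
    column (fixed higher combination) is a simplex over lower states.
    """

    arrays: list[np.ndarray]

    def __post_init__(self):
        self.arrays = [np.asarray(a, dtype=float) for a in self.arrays]
        for i, a in enumerate(self.arrays):
            if np.any(a < -SIMPLEX_TOL) or not np.allclose(
                a.sum(axis=0), 1.0, atol=SIMPLEX_TOL
            ):
                raise ValueError(f"link array {i} columns are not simplices")

    @property
    def higher_dims(self) -> tuple[int, ...]:
        return self.arrays[0].shape[1:]


@dataclass
class DeepModel:
    """Ordered levels (index 0 = lowest) plus the link between adjacent pairs."""

    levels: list[LevelModel]
    link: LinkTensor | None = None

    def __post_init__(self):
        if self.link is not None:
            lower, upper = self.levels[0], self.levels[1]
            if self.link.higher_dims != upper.state_dims:
                raise ValueError("link tensor does not match higher-level state space")
            for a, f in zip(self.link.arrays, lower.factors):
                if a.shape[0] != f.n:
                    raise ValueError(
                        f"link for lower factor {f.name} has {a.shape[0]} states, "
                        f"expected {f.n}"
                    )


def _contract_higher(array: np.ndarray, higher_belief: Sequence[np.ndarray]) -> np.ndarray:
    out = array
    for q in higher_belief:
        out = np.tensordot(out, np.asarray(q, dtype=float), axes=([1], [0]))
    return out


def descend(link: LinkTensor, higher_belief: Sequence[np.ndarray]) -> list[np.ndarray]:
    """Empirical prior over lower initial states given higher expectations.

    ``higher_belief`` holds one simplex per higher-level factor (typically
    the Bayesian model average at the current higher-level time).
    """
    if len(higher_belief) != len(link.higher_dims):
        raise ValueError("one belief per higher-level factor is required")
    for q, k in zip(higher_belief, link.higher_dims):
        if np.asarray(q).shape != (k,):
            raise ValueError("higher-level belief dimensions do not match the link")
    priors = []
    for a in link.arrays:
        d = _contract_higher(a, higher_belief)
        priors.append(d / d.sum())
    return priors


def ascend(
    link: LinkTensor, lower_posterior_initial: Sequence[np.ndarray]
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Likelihood message over higher-level state combinations.

    For each higher combination, the probability its descending prior assigns
    to the lower level's inferred initial states.  Returns the normalised
    product over lower factors (a tensor over the higher state dims) together
    with the per-factor messages.
    """
    if len(lower_posterior_initial) != len(link.arrays):
        raise ValueError("one posterior per lower-level factor is required")
    per_factor = []
    for a, q in zip(link.arrays, lower_posterior_initial):
        q = np.asarray(q, dtype=float)
        if q.shape != (a.shape[0],):
            raise ValueError("lower posterior dimensions do not match the link")
        per_factor.append(np.tensordot(q, a, axes=([0], [0])))
    combined = np.ones(link.higher_dims)
    for m in per_factor:
        combined = combined * m
    total = combined.sum()
    if total > 0:
        combined = combined / total
    return combined, per_factor


@dataclass
class DeepRunResult:
    """Outputs of :func:`run_deep`."""

    upper_belief: BeliefState
    lower_beliefs: list[BeliefState]
    upper_traces: list[EpochTrace]
    lower_traces: list[list[EpochTrace]]
    emitted: list[list[int]]
    observed: list[list[int]]


def run_deep(
    deep: DeepModel,
    n_epochs: int | None = None,
    sources: Sequence[Sequence[int] | None] | None = None,
    *,
    iterations: int = 16,
    kappa: float = 0.25,
    gamma: float = 1.0,
) -> DeepRunResult:
    """Run a deep model over its higher-level horizon.

    ``sources[e]`` designates the outcome source for epoch ``e``: ``None``
    means self-generation (the model emits the outcomes that maximise
    accuracy under its own predictions), otherwise a sequence of lower-level
    outcome indices (one per lower time step, single lower modality) to
    observe.  A one-level model degenerates to a plain single-level run in
    which each epoch observes/generates one outcome.
    """
    upper = deep.levels[-1]
    n_epochs = upper.T if n_epochs is None else n_epochs
    if n_epochs > upper.T:
        raise ValueError("epoch count exceeds the higher-level horizon")
    sources = [None] * n_epochs if sources is None else list(sources)

    upper_belief = BeliefState.initialise(upper)
    upper_obs: list = [None] * upper.T
    upper_traces: list[EpochTrace] = []
    lower_traces: list[list[EpochTrace]] = []
    lower_beliefs: list[BeliefState] = []
    emitted: list[list[int]] = []
    observed: list[list[int]] = []

    G = expected_free_energy(upper, upper_belief)
    upper_belief.G = G
    upper_belief.pi = policy_posterior(np.zeros(upper.n_policies), G, gamma)

    single_level = len(deep.levels) == 1

    for e in range(n_epochs):
        if single_level:
            src = sources[e]
            if src is None:
                bma = bayesian_model_average(upper_belief)
                o = select_outcome(upper, [bma[f][e] for f in range(upper.n_factors)])
                emitted.append(list(o))
                upper_obs[e] = list(o)
            else:
                upper_obs[e] = list(np.atleast_1d(src))
            observed.append(list(upper_obs[e]))
            upper_belief, tr = update_states(
                upper, upper_obs, upper_belief, iterations=iterations, kappa=kappa,
                label=f"epoch{e}",
            )
            upper_traces.append(tr)
            lower_traces.append([])
            continue

        lower = deep.levels[0]
        bma = bayesian_model_average(upper_belief)
        d_low = descend(deep.link, [bma[f][e] for f in range(upper.n_factors)])
        lower_model = lower.replace_D(d_low)
        lb = BeliefState.initialise(lower_model)
        lb_obs: list = [None] * lower.T
        phrase_traces: list[EpochTrace] = []
        words: list[int] = []
        src = sources[e]
        for w in range(lower.T):
            if src is None:
                o = select_outcome(
                    lower_model, [lb.s[f][0, w, :] for f in range(lower.n_factors)]
                )[0]
            else:
                o = int(src[w])
            words.append(o)
            lb_obs[w] = [o]
            lb, tr = update_states(
                lower_model, lb_obs, lb, iterations=iterations, kappa=kappa,
                label=f"epoch{e}.word{w}",
            )
            phrase_traces.append(tr)
        lower_beliefs.append(lb)
        lower_traces.append(phrase_traces)
        (emitted if src is None else observed).append(words)
        # ascending message: posterior over lower initial states, fed to the
        # higher level as a (soft) observation for the current epoch
        q_init = [lb.s[f][0, 0, :] for f in range(lower.n_factors)]
        upper_obs[e] = q_init
        upper_belief, tr = update_states(
            upper, upper_obs, upper_belief, iterations=iterations, kappa=kappa,
            label=f"epoch{e}",
        )
        F = upper_belief.F
        upper_belief.pi = policy_posterior(F, G, gamma)
        upper_traces.append(tr)

    return DeepRunResult(
        upper_belief=upper_belief,
        lower_beliefs=lower_beliefs,
        upper_traces=upper_traces,
        lower_traces=lower_traces,
        emitted=emitted,
        observed=observed,
    )
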