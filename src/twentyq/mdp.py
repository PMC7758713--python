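"""Single-level discrete active-inference engine.

This module implements variational state estimation, free energies, policy
evaluation, outcome selection and precision dynamics for a generic partially
observed Markov decision process with categorical (factorised) hidden states.

The generative model is parameterised in the field's standard notation:

* ``A`` — likelihood arrays, one per outcome modality, giving the probability
  of each outcome under every combination of hidden states;
* ``B`` — probability transition matrices, one set per hidden factor, indexed
  by a control state (uncontrollable factors have a single control);
* ``C`` — prior costs over outcomes (negative log preferences, in nats);
* ``D`` — prior expectations about initial hidden states, one simplex per
  factor;
* policies — sequences of control states evaluated by their variational free
  energy ``F`` and expected free energy ``G``.

Belief updating follows a gradient descent on variational free energy: the
log state expectation ("depolarisation") ``v`` accumulates a state prediction
error built from forward, backward and likelihood messages, and the state
expectation is recovered by a softmax.  Messages are expectations of
log-probabilities under neighbouring beliefs, which makes each coordinate
update an exact (partial) minimiser of the free-energy functional evaluated
by :func:`free_energy`, so descent is monotone for step sizes ``kappa <= 1``.
Updates are run for a fixed, small number of iterations per outcome (neural
dynamics are modelled as not fully converging), and every iterate is recorded
in an :class:`EpochTrace` whose 16 ms bins are the raw material for the
synthetic electrophysiology in :mod:`twentyq.ephys`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.special import xlogy

__all__ = [
    "LOG_FLOOR",
    "SIMPLEX_TOL",
    "softmax",
    "safe_log",
    "Factor",
    "Modality",
    "Policy",
    "LevelModel",
    "BeliefState",
    "EpochTrace",
    "update_states",
    "free_energy",
    "expected_free_energy",
    "policy_posterior",
    "occam_prune",
    "update_precision",
    "PrecisionResult",
    "bayesian_model_average",
    "select_outcome",
    "outcome_surprise",
]

#: probabilities are floored at exp(-16) before logs are taken, bounding all
#: prediction errors; see the methods note for the rationale.
LOG_FLOOR = float(np.exp(-16.0))

#: tolerance used when validating that distributions sum to one.
SIMPLEX_TOL = 1e-8


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Stable softmax; returns a proper probability distribution."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("softmax requires finite input")
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def safe_log(p: np.ndarray, floor: float = LOG_FLOOR) -> np.ndarray:
    """Natural log with probabilities floored at ``floor``.

    Entries must be nonnegative; zeros map to ``log(floor)`` so that log
    messages (and hence prediction errors) remain bounded.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("safe_log requires nonnegative entries")
    return np.log(np.maximum(p, floor))


def _as_onehot(o, n: int) -> np.ndarray:
    """Coerce an observation (index or soft vector) to a length-``n`` vector."""
    if isinstance(o, (int, np.integer)):
        v = np.zeros(n)
        v[int(o)] = 1.0
        return v
    v = np.asarray(o, dtype=float)
    if v.shape != (n,):
        raise ValueError(f"observation vector has shape {v.shape}, expected ({n},)")
    return v


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Factor:
    """A hidden factor: a name and its mutually exclusive state labels."""

    name: str
    states: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class Modality:
    """An outcome modality: a name and its outcome labels."""

    name: str
    outcomes: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.outcomes)


@dataclass(frozen=True)
class Policy:
    """A sequence of control states, one per controllable factor per step.

    ``controls`` has shape ``[T - 1, n_factors]``; uncontrollable factors
    carry control index 0 throughout.
    """

    id: int
    controls: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "controls", np.asarray(self.controls, dtype=int))


@dataclass
class LevelModel:
    """One discrete generative level (A, B, C, D, policies, horizon)."""

    factors: list[Factor]
    modalities: list[Modality]
    A: list[np.ndarray]
    B: list[list[np.ndarray]]
    C: list[np.ndarray]
    D: list[np.ndarray]
    policies: list[Policy]
    T: int
    name: str = ""
    _logA: list[np.ndarray] = field(default=None, repr=False)
    _logB: list[list[np.ndarray]] = field(default=None, repr=False)

    def __post_init__(self):
        self.validate()
        self._logA = [safe_log(a) for a in self.A]
        self._logB = [[safe_log(b) for b in bs] for bs in self.B]

    # -- structure -------------------------------------------------------
    @property
    def n_factors(self) -> int:
        return len(self.factors)

    @property
    def n_modalities(self) -> int:
        return len(self.modalities)

    @property
    def n_policies(self) -> int:
        return len(self.policies)

    @property
    def state_dims(self) -> tuple[int, ...]:
        return tuple(f.n for f in self.factors)

    def cost(self, m: int, t: int) -> np.ndarray:
        """Prior cost vector for modality ``m`` at time ``t``."""
        c = np.asarray(self.C[m], dtype=float)
        return c[:, t] if c.ndim == 2 else c

    def validate(self) -> None:
        if self.T < 1:
            raise ValueError("horizon T must be >= 1")
        if not self.policies:
            raise ValueError("at least one policy is required")
        dims = self.state_dims
        if len(self.A) != len(self.modalities):
            raise ValueError("one likelihood array per modality is required")
        for m, a in zip(self.modalities, self.A):
            a = np.asarray(a, dtype=float)
            if a.shape != (m.n, *dims):
                raise ValueError(
                    f"A[{m.name}] has shape {a.shape}, expected {(m.n, *dims)}"
                )
            margins = a.sum(axis=0)
            if np.any(a < -SIMPLEX_TOL) or not np.allclose(margins, 1.0, atol=SIMPLEX_TOL):
                raise ValueError(f"A[{m.name}] outcome margins are not simplices")
        if len(self.B) != self.n_factors:
            raise ValueError("one transition set per factor is required")
        for f, bs in zip(self.factors, self.B):
            if not bs:
                raise ValueError(f"factor {f.name} needs at least one control matrix")
            for b in bs:
                b = np.asarray(b, dtype=float)
                if b.shape != (f.n, f.n):
                    raise ValueError(f"B[{f.name}] matrices must be {f.n}x{f.n}")
                if np.any(b < -SIMPLEX_TOL) or not np.allclose(
                    b.sum(axis=0), 1.0, atol=SIMPLEX_TOL
                ):
                    raise ValueError(f"B[{f.name}] columns are not simplices")
        for f, d in zip(self.factors, self.D):
            d = np.asarray(d, dtype=float)
            if d.shape != (f.n,) or np.any(d < -SIMPLEX_TOL) or not np.isclose(
                d.sum(), 1.0, atol=SIMPLEX_TOL
            ):
                raise ValueError(f"D[{f.name}] is not a simplex over {f.n} states")
        if len(self.C) != len(self.modalities):
            raise ValueError("one cost vector per modality is required")
        for m, c in zip(self.modalities, self.C):
            c = np.asarray(c, dtype=float)
            if not np.all(np.isfinite(c)):
                raise ValueError(f"C[{m.name}] must be finite")
            if c.shape[0] != m.n:
                raise ValueError(f"C[{m.name}] must have {m.n} rows")
        for p in self.policies:
            if p.controls.shape != (self.T - 1, self.n_factors):
                raise ValueError(
                    f"policy {p.id} controls have shape {p.controls.shape}, "
                    f"expected {(self.T - 1, self.n_factors)}"
                )
            for fi, bs in enumerate(self.B):
                if self.T > 1 and (
                    p.controls[:, fi].min() < 0 or p.controls[:, fi].max() >= len(bs)
                ):
                    raise ValueError(
                        f"policy {p.id} control out of range for factor {fi}"
                    )

    def replace_D(self, D: list[np.ndarray]) -> "LevelModel":
        """A copy of the model with new initial priors (beliefs carry over)."""
        return dataclasses.replace(self, D=[np.asarray(d, float) for d in D],
                                   _logA=None, _logB=None)


# ---------------------------------------------------------------------------
# beliefs and traces
# ---------------------------------------------------------------------------


@dataclass
class BeliefState:
    """Per-policy, per-time, per-factor posterior expectations.

    ``s[f]`` has shape ``[n_policies, T, K_f]`` and satisfies
    ``s = softmax(v)`` distribution-wise.  ``pi`` is the posterior over
    policies, ``gamma`` its precision, and ``F``/``G`` the accumulated
    variational and expected free energies per policy.
    """

    s: list[np.ndarray]
    v: list[np.ndarray]
    pi: np.ndarray
    gamma: float
    F: np.ndarray
    G: np.ndarray

    @classmethod
    def initialise(cls, model: LevelModel) -> "BeliefState":
        """Prior beliefs: D propagated through each policy's transitions."""
        P, T = model.n_policies, model.T
        s = []
        for fi, f in enumerate(model.factors):
            arr = np.zeros((P, T, f.n))
            for pi_, pol in enumerate(model.policies):
                arr[pi_, 0] = model.D[fi]
                for t in range(1, T):
                    u = pol.controls[t - 1, fi]
                    arr[pi_, t] = model.B[fi][u] @ arr[pi_, t - 1]
            s.append(arr)
        v = [safe_log(a) for a in s]
        pi = np.full(P, 1.0 / P)
        return cls(s=s, v=v, pi=pi, gamma=1.0, F=np.zeros(P), G=np.zeros(P))

    def copy(self) -> "BeliefState":
        return BeliefState(
            s=[a.copy() for a in self.s],
            v=[a.copy() for a in self.v],
            pi=self.pi.copy(),
            gamma=self.gamma,
            F=self.F.copy(),
            G=self.G.copy(),
        )


@dataclass
class EpochTrace:
    """Iteration-resolved record of belief updating within one epoch.

    Each row is one update iteration, modelled as one 16 ms bin of simulated
    time.  Units are (time step, factor, state) triples of the level being
    traced: their expectations ``s`` play the role of firing rates, their log
    expectations ``v`` of depolarisations, and ``epsilon`` of state
    prediction errors.  ``F`` holds the per-policy free energy at each
    iterate and ``gamma`` the expected precision (filled in by the caller
    that owns the precision dynamics).
    """

    label: str
    bin_ms: float
    unit_labels: list[tuple[int, str, str]]
    s: np.ndarray
    v: np.ndarray
    epsilon: np.ndarray
    F: np.ndarray
    gamma: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return self.s.shape[0]

    def units_for(self, factor: str, t: int | None = None) -> tuple[list[int], list[tuple[int, str, str]]]:
        """Column indices (and labels) of units of one factor, optionally one time."""
        idx, labels = [], []
        for j, (tt, fname, state) in enumerate(self.unit_labels):
            if fname == factor and (t is None or tt == t):
                idx.append(j)
                labels.append((tt, fname, state))
        return idx, labels


def _unit_labels(model: LevelModel) -> list[tuple[int, str, str]]:
    labels = []
    for t in range(model.T):
        for f in model.factors:
            for st in f.states:
                labels.append((t, f.name, st))
    return labels


def _flatten_units(model: LevelModel, per_factor: list[np.ndarray]) -> np.ndarray:
    """[T, K_f] arrays per factor -> flat vector ordered like unit labels."""
    return np.concatenate(
        [np.concatenate([per_factor[fi][t] for fi in range(model.n_factors)])
         for t in range(model.T)]
    )


# ---------------------------------------------------------------------------
# observation pre-processing
# ---------------------------------------------------------------------------


def _prepare_observations(model: LevelModel, observations) -> list[list[np.ndarray] | None]:
    """Normalise the observation structure to per-time per-modality vectors."""
    obs: list[list[np.ndarray] | None] = [None] * model.T
    if observations is None:
        return obs
    for t, ot in enumerate(observations):
        if ot is None:
            continue
        if t >= model.T:
            raise ValueError("more observations than time steps")
        row = []
        for m, o in zip(model.modalities, ot):
            row.append(None if o is None else _as_onehot(o, m.n))
        obs[t] = row
    return obs


def _likelihood_tensors(model: LevelModel, obs) -> dict[tuple[int, int], np.ndarray]:
    """E_o[ln A] contracted with each observation -> tensor over state dims."""
    W: dict[tuple[int, int], np.ndarray] = {}
    for t, row in enumerate(obs):
        if row is None:
            continue
        for mi, o in enumerate(row):
            if o is None:
                continue
            W[(t, mi)] = np.tensordot(o, model._logA[mi], axes=([0], [0]))
    return W




def _joint(s_at_t: list[np.ndarray]) -> np.ndarray:
    """Product over factors of per-policy beliefs: [P, K1*K2*...]."""
    out = s_at_t[0]
    for s in s_at_t[1:]:
        out = out[:, :, None] * s[:, None, :]
        out = out.reshape(out.shape[0], -1)
    return out


# ---------------------------------------------------------------------------
# state estimation
# ---------------------------------------------------------------------------


def update_states(
    model: LevelModel,
    observations,
    belief: BeliefState | None = None,
    *,
    iterations: int = 16,
    kappa: float = 0.25,
    label: str = "",
    record: bool = True,
    compute_F: bool = True,
) -> tuple[BeliefState, EpochTrace | None]:
    """Gradient descent on variational free energy for all represented times.

    For every policy, time and factor the state prediction error combines a
    forward message (the initial prior at the first time), a backward message
    from the following time, and the likelihood of any observed outcomes; the
    depolarisation moves a fraction ``kappa`` along the error and the state
    expectation is its softmax.  Past and future times are updated at every
    iteration.  Finite ``iterations`` model neural dynamics; non-convergence
    is not an error.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if belief is None:
        belief = BeliefState.initialise(model)
    else:
        belief = belief.copy()
    obs = _prepare_observations(model, observations)
    W = _likelihood_tensors(model, obs)
    P, T, nF = model.n_policies, model.T, model.n_factors
    controls = np.stack([p.controls for p in model.policies]) if T > 1 else None

    trace_s = np.zeros((iterations, T * sum(model.state_dims))) if record else None
    trace_v = np.zeros_like(trace_s) if record else None
    trace_e = np.zeros_like(trace_s) if record else None
    trace_F = np.zeros((iterations, P)) if record else None

    eps_store = [np.zeros_like(a) for a in belief.s]

    obs_times = sorted({t for (t, _) in W})
    dims = model.state_dims

    for it in range(iterations):
        # cumulative left/right products of factor beliefs, per observed time,
        # so each factor's likelihood message is two small tensor products
        LR: dict[int, tuple[list, list]] = {}
        for t in obs_times:
            s_at_t = [belief.s[f][:, t, :] for f in range(nF)]
            left = [np.ones((P, 1))]
            for g in range(nF - 1):
                left.append(
                    (left[-1][:, :, None] * s_at_t[g][:, None, :]).reshape(P, -1)
                )
            right = [np.ones((P, 1))]
            for g in range(nF - 1, 0, -1):
                right.append(
                    (s_at_t[g][:, :, None] * right[-1][:, None, :]).reshape(P, -1)
                )
            right.reverse()
            LR[t] = (left, right)
        for t in range(T):
            s_at_t = [belief.s[f][:, t, :] for f in range(nF)]
            for fi in range(nF):
                B = model.B[fi]
                # forward message: log of the propagated expectation
                if t == 0:
                    fwd = np.broadcast_to(safe_log(model.D[fi]), (P, model.factors[fi].n)).copy()
                else:
                    fwd = np.zeros((P, model.factors[fi].n))
                    u_arr = controls[:, t - 1, fi]
                    for u in np.unique(u_arr):
                        idx = u_arr == u
                        fwd[idx] = safe_log(belief.s[fi][idx, t - 1, :] @ B[u].T)
                # backward message from beliefs about the next time
                if t == T - 1:
                    bwd = 0.0
                else:
                    bwd = np.zeros((P, model.factors[fi].n))
                    u_arr = controls[:, t, fi]
                    for u in np.unique(u_arr):
                        idx = u_arr == u
                        bwd[idx] = safe_log(belief.s[fi][idx, t + 1, :] @ B[u])
                # likelihood messages
                lik = np.zeros((P, model.factors[fi].n))
                if t in LR:
                    left, right = LR[t]
                    a = left[fi].shape[1]
                    b = right[fi].shape[1] if fi < nF - 1 else 1
                    for mi in range(model.n_modalities):
                        w = W.get((t, mi))
                        if w is None:
                            continue
                        wr = w.reshape(a, dims[fi], b)
                        tmp = np.tensordot(left[fi], wr, axes=([1], [0]))  # [P,K,b]
                        if b == 1:
                            lik += tmp[:, :, 0]
                        else:
                            lik += (tmp * right[fi][:, None, :]).sum(axis=-1)
                v = belief.v[fi][:, t, :]
                vmax = v.max(axis=-1, keepdims=True)
                lns = v - vmax - np.log(np.exp(v - vmax).sum(axis=-1, keepdims=True))
                eps = fwd + bwd + lik - lns
                eps -= eps.mean(axis=-1, keepdims=True)  # gauge: softmax-invariant
                v_new = v + kappa * eps
                v_new -= v_new.max(axis=-1, keepdims=True)
                belief.v[fi][:, t, :] = v_new
                belief.s[fi][:, t, :] = softmax(v_new, axis=-1)
                eps_store[fi][:, t, :] = eps
                s_at_t[fi] = belief.s[fi][:, t, :]
        if record:
            bma_s = [np.einsum("p,ptk->tk", belief.pi, belief.s[f]) for f in range(nF)]
            bma_v = [np.einsum("p,ptk->tk", belief.pi, belief.v[f]) for f in range(nF)]
            bma_e = [np.einsum("p,ptk->tk", belief.pi, eps_store[f]) for f in range(nF)]
            trace_s[it] = _flatten_units(model, bma_s)
            trace_v[it] = _flatten_units(model, bma_v)
            trace_e[it] = _flatten_units(model, bma_e)
            if compute_F:
                trace_F[it] = free_energy(model, belief, observations)[1]

    if compute_F:
        belief.F = free_energy(model, belief, observations)[1]
    trace = None
    if record:
        trace = EpochTrace(
            label=label,
            bin_ms=16.0,
            unit_labels=_unit_labels(model),
            s=trace_s,
            v=trace_v,
            epsilon=trace_e,
            F=trace_F if compute_F else np.zeros((iterations, P)),
            gamma=np.full(iterations, belief.gamma),
            meta={"level": model.name},
        )
    return belief, trace


# ---------------------------------------------------------------------------
# free energies
# ---------------------------------------------------------------------------


def free_energy(
    model: LevelModel, belief: BeliefState, observations
) -> tuple[np.ndarray, np.ndarray]:
    """Variational free energy per (policy, time) and summed per policy.

    Each term is complexity minus accuracy: the expected KL divergence of the
    current belief from its transition-propagated predecessor (the initial
    prior at the first time), minus the expected log likelihood of observed
    outcomes under the (factorised) state beliefs.
    """
    obs = _prepare_observations(model, observations)
    W = _likelihood_tensors(model, obs)
    P, T, nF = model.n_policies, model.T, model.n_factors
    controls = np.stack([p.controls for p in model.policies]) if T > 1 else None
    F_t = np.zeros((P, T))
    for t in range(T):
        # complexity
        for fi in range(nF):
            q = belief.s[fi][:, t, :]
            ent = xlogy(q, q).sum(axis=-1)
            if t == 0:
                cross = q @ safe_log(model.D[fi])
            else:
                cross = np.zeros(P)
                u_arr = controls[:, t - 1, fi]
                for u in np.unique(u_arr):
                    idx = u_arr == u
                    m = belief.s[fi][idx, t - 1, :] @ model._logB[fi][u].T
                    cross[idx] = np.sum(q[idx] * m, axis=-1)
            F_t[:, t] += ent - cross
        # accuracy
        s_at_t = [belief.s[f][:, t, :] for f in range(nF)]
        joint = None
        for mi in range(model.n_modalities):
            w = W.get((t, mi))
            if w is None:
                continue
            if joint is None:
                joint = _joint(s_at_t)
            F_t[:, t] -= joint @ w.reshape(-1)
    return F_t, F_t.sum(axis=1)


def expected_free_energy(
    model: LevelModel,
    belief: BeliefState,
    future_times: Iterable[int] | None = None,
    *,
    return_parts: bool = False,
):
    """Expected free energy ``G`` per policy over the given future times.

    The predictive joint over outcomes and states is ``Q(o, s) =
    P(o | s) Q(s | pi)`` with ``Q(s | pi)`` taken from the (predictive)
    beliefs held in ``belief``.  G is returned in its epistemic + pragmatic
    decomposition: minus the mutual information between predicted states and
    outcomes (intrinsic value) minus the expected log prior preference
    (extrinsic value, with ``ln P(o) = -C``).  The algebraically equivalent
    risk + ambiguity form is also computed and returned in the parts.
    """
    if future_times is None:
        future_times = range(model.T)
    future_times = list(future_times)
    P = model.n_policies
    G = np.zeros(P)
    intrinsic = np.zeros((P, len(future_times)))
    extrinsic = np.zeros((P, len(future_times)))
    risk = np.zeros((P, len(future_times)))
    ambiguity = np.zeros((P, len(future_times)))
    for ti, t in enumerate(future_times):
        s_at_t = [belief.s[f][:, t, :] for f in range(model.n_factors)]
        joint = _joint(s_at_t)  # [P, N]
        for mi, modality in enumerate(model.modalities):
            A2 = np.asarray(model.A[mi], dtype=float).reshape(modality.n, -1)
            Qo = joint @ A2.T  # [P, n_out]
            C = model.cost(mi, t)
            # conditional entropy of outcomes given states, weighted by Q(s)
            HA = -xlogy(A2, A2).sum(axis=0)  # [N]
            amb = joint @ HA
            # mutual information: H(o) - H(o|s)
            Ho = -(xlogy(Qo, Qo)).sum(axis=-1)
            mi_os = Ho - amb
            ext = -(Qo @ C)
            intrinsic[:, ti] += mi_os
            extrinsic[:, ti] += ext
            ambiguity[:, ti] += amb
            risk[:, ti] += xlogy(Qo, Qo).sum(axis=-1) + Qo @ C
        G += -intrinsic[:, ti] - extrinsic[:, ti]
    if return_parts:
        parts = {
            "times": future_times,
            "intrinsic": intrinsic,
            "extrinsic": extrinsic,
            "risk": risk,
            "ambiguity": ambiguity,
            "G_risk_ambiguity": (risk + ambiguity).sum(axis=1),
        }
        return G, parts
    return G


# ---------------------------------------------------------------------------
# policies, precision, averaging, outcome selection
# ---------------------------------------------------------------------------


def policy_posterior(F: np.ndarray, G: np.ndarray, gamma: float) -> np.ndarray:
    """Posterior over policies: ``softmax(-F - gamma * G)``."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    F = np.asarray(F, dtype=float)
    G = np.asarray(G, dtype=float)
    if F.shape != G.shape:
        raise ValueError("F and G must have the same length")
    return softmax(-F - gamma * G)


def occam_prune(pi: np.ndarray, window: float = 3.0) -> np.ndarray:
    """Zero policies whose posterior falls below ``exp(-window)`` of the best."""
    pi = np.asarray(pi, dtype=float)
    keep = pi > pi.max() * np.exp(-window)
    out = np.where(keep, pi, 0.0)
    return out / out.sum()


@dataclass
class PrecisionResult:
    """Gamma iterate sequence (the simulated dopamine signal) and end state."""

    gammas: np.ndarray
    pi: np.ndarray
    pi0: np.ndarray
    beta: float
    floored: bool = False


def update_precision(
    F: np.ndarray,
    G: np.ndarray,
    *,
    beta_prior: float = 1.0,
    tol: float = 1e-4,
    max_iter: int = 16,
    beta_floor: float = 1e-2,
    gamma_init: float | None = None,
) -> PrecisionResult:
    """Fixed-point iteration for the expected precision of policy beliefs.

    Iterates ``beta <- beta_prior + (pi - pi0) . G`` with ``gamma = 1/beta``,
    ``pi0 = softmax(-gamma G)`` and ``pi = softmax(-F - gamma G)``, until the
    change in ``beta`` falls below ``tol``.  The gamma iterate sequence is the
    simulated (phasic) dopamine trace; ``beta`` is floored at ``beta_floor``
    and flagged if the floor binds.
    """
    if beta_prior <= 0:
        raise ValueError("beta_prior must be positive")
    F = np.asarray(F, dtype=float)
    G = np.asarray(G, dtype=float)
    beta = beta_prior if gamma_init is None else 1.0 / gamma_init
    gammas = []
    floored = False
    pi = pi0 = None
    for _ in range(max_iter):
        gamma = 1.0 / beta
        pi0 = softmax(-gamma * G)
        pi = softmax(-F - gamma * G)
        beta_new = beta_prior + float((pi - pi0) @ G)
        if beta_new < beta_floor:
            beta_new = beta_floor
            floored = True
        gammas.append(1.0 / beta_new)
        if abs(beta_new - beta) < tol:
            beta = beta_new
            break
        beta = beta_new
    return PrecisionResult(
        gammas=np.asarray(gammas), pi=pi, pi0=pi0, beta=beta, floored=floored
    )


def bayesian_model_average(
    s: list[np.ndarray] | BeliefState, pi: np.ndarray | None = None
) -> list[np.ndarray]:
    """Policy-weighted average of state expectations, per (time, factor)."""
    if isinstance(s, BeliefState):
        pi = s.pi if pi is None else pi
        s = s.s
    if pi is None:
        raise ValueError("policy weights are required")
    pi = np.asarray(pi, dtype=float)
    out = []
    for arr in s:
        if arr.shape[0] != pi.shape[0]:
            raise ValueError("policy axis mismatch")
        out.append(np.einsum("p,ptk->tk", pi, arr))
    return out


def outcome_surprise(model: LevelModel, s_next: list[np.ndarray]) -> list[np.ndarray]:
    """Expected surprise ``G_o = -(E[ln A] . o)`` of each outcome per modality.

    ``s_next`` holds one simplex per factor (the predicted next states).
    Lower is better; the minimiser is the most accurate (least surprising)
    outcome the agent can generate.
    """
    vals = []
    for mi in range(model.n_modalities):
        w = model._logA[mi]
        for fi, q in enumerate(s_next):
            w = np.tensordot(w, q, axes=([1], [0]))
        vals.append(-w)
    return vals


def select_outcome(model: LevelModel, s_next: list[np.ndarray]) -> list[int]:
    """Outcomes that maximise accuracy under predicted states (ties: lowest index)."""
    return [int(np.argmin(g)) for g in outcome_surprise(model, s_next)]
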