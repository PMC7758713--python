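"""Independent brute-force oracles used by the test suite.

These enumerate joint state combinations directly and are deliberately
written without reusing the engine's vectorised implementations.
"""

import itertools
import math

import numpy as np


def enumerate_posterior(D, A, o_index):
    """Exact single-factor, single-step posterior: D * A[o, :] normalised."""
    like = np.asarray(A, float)[o_index, :]
    post = np.asarray(D, float) * like
    return post / post.sum()


def _floor_log(p, floor=math.exp(-16.0)):
    return math.log(max(p, floor))


def brute_force_free_energy(model, belief, observations, policy_index):
    """F(pi, t) summed over t, by explicit enumeration over joint states."""
    dims = model.state_dims
    total = 0.0
    for t in range(model.T):
        # complexity
        for fi in range(model.n_factors):
            q = belief.s[fi][policy_index, t]
            if t == 0:
                prior_cols = {None: np.asarray(model.D[fi], float)}
                weights = {None: 1.0}
            else:
                u = model.policies[policy_index].controls[t - 1, fi]
                B = np.asarray(model.B[fi][u], float)
                prior_cols = {j: B[:, j] for j in range(dims[fi])}
                weights = {
                    j: belief.s[fi][policy_index, t - 1][j] for j in range(dims[fi])
                }
            for j, col in prior_cols.items():
                kl = sum(
                    q[i] * (_floor_log(q[i]) - _floor_log(col[i])) if q[i] > 0 else 0.0
                    for i in range(dims[fi])
                )
                total += weights[j] * kl
        # accuracy
        obs_t = observations[t] if t < len(observations) else None
        if obs_t is None:
            continue
        for mi, o in enumerate(obs_t):
            if o is None:
                continue
            o_vec = np.zeros(model.modalities[mi].n)
            if isinstance(o, (int, np.integer)):
                o_vec[int(o)] = 1.0
            else:
                o_vec = np.asarray(o, float)
            A = np.asarray(model.A[mi], float)
            acc = 0.0
            for combo in itertools.product(*[range(k) for k in dims]):
                w = 1.0
                for fi, j in enumerate(combo):
                    w *= belief.s[fi][policy_index, t][j]
                for oi in range(len(o_vec)):
                    if o_vec[oi] > 0:
                        acc += w * o_vec[oi] * _floor_log(A[(oi,) + combo])
            total -= acc
    return total


def brute_force_efe(model, belief, policy_index, t):
    """Expected free energy at time t via the risk + ambiguity decomposition,
    enumerated over joint states, independently of the engine."""
    dims = model.state_dims
    G = 0.0
    for mi, modality in enumerate(model.modalities):
        A = np.asarray(model.A[mi], float)
        C = np.asarray(model.C[mi], float)
        C = C[:, t] if C.ndim == 2 else C
        Qo = np.zeros(modality.n)
        ambiguity = 0.0
        for combo in itertools.product(*[range(k) for k in dims]):
            w = 1.0
            for fi, j in enumerate(combo):
                w *= belief.s[fi][policy_index, t][j]
            col = A[(slice(None),) + combo]
            Qo += w * col
            ambiguity += w * -sum(p * math.log(p) for p in col if p > 0)
        risk = sum(p * math.log(p) for p in Qo if p > 0) + float(Qo @ C)
        G += risk + ambiguity
    return G


def brute_force_outcome_surprise(model, s_next, floor=math.exp(-16.0)):
    """-(E[ln A] . o) per outcome of the first modality, by enumeration."""
    dims = model.state_dims
    A = np.asarray(model.A[0], float)
    out = np.zeros(model.modalities[0].n)
    for oi in range(len(out)):
        val = 0.0
        for combo in itertools.product(*[range(k) for k in dims]):
            w = 1.0
            for fi, j in enumerate(combo):
                w *= s_next[fi][j]
            val += w * _floor_log(A[(oi,) + combo], floor)
        out[oi] = -val
    return out
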