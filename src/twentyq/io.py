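"""Configuration loading, result serialisation and oracle-test fixtures."""

from __future__ import annotations

import datetime
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import ValidationError

from .dialogue import ScenarioConfig, ScenarioResult
from .mdp import Factor, LevelModel, Modality, Policy
from .model import SCENIC_FACTORS

__all__ = ["load_config", "write_outputs", "RunManifest", "make_fixture"]


def load_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a scenario configuration from a YAML file.

    An empty file yields the full default configuration; unknown or invalid
    keys are rejected with an error naming each offending field.
    """
    path = Path(path)
    data = yaml.safe_load(path.read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    try:
        return ScenarioConfig(**data)
    except ValidationError as err:
        fields = ", ".join(
            ".".join(str(p) for p in e["loc"]) or "<root>" for e in err.errors()
        )
        raise ValueError(f"{path}: invalid configuration fields: {fields}") from err


@dataclass
class RunManifest:
    """Echo of a completed run: config, seed, outputs, wall-clock metadata."""

    config: dict
    seed: int
    version: str
    outputs: dict[str, str]
    started: str
    elapsed_s: float

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "seed": self.seed,
            "package_version": self.version,
            "outputs": self.outputs,
            "started": self.started,
            "elapsed_s": self.elapsed_s,
        }


def _beliefs_frame(result: ScenarioResult) -> pd.DataFrame:
    rows = []
    for name, agent in result.agents.items():
        for k, snap in enumerate(agent.snapshots):
            for fname in SCENIC_FACTORS:
                states = (
                    ("green", "red") if "colour" in fname else ("square", "triangle")
                )
                for si, state in enumerate(states):
                    rows.append(
                        dict(
                            agent=name,
                            exchange=k,
                            factor=fname,
                            state=state,
                            probability=float(snap[fname][si]),
                        )
                    )
    return pd.DataFrame(rows)


def write_outputs(result: ScenarioResult, outdir: str | Path) -> RunManifest:
    """Write transcript (text), beliefs (CSV), traces (npz) and a manifest."""
    from . import __version__

    t0 = time.time()
    started = datetime.datetime.now(datetime.timezone.utc).isoformat()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    transcript_path = outdir / "transcript.txt"
    transcript_path.write_text(result.transcript.to_text())

    beliefs_path = outdir / "beliefs.csv"
    _beliefs_frame(result).to_csv(beliefs_path, index=False)

    traces_path = outdir / "traces.npz"
    arrays: dict[str, np.ndarray] = {}
    for name, agent in result.agents.items():
        if agent.log:
            upper, _ = agent.upper_session()
            lower, _ = agent.lower_session()
            g, labels = agent.dopamine_series()
            arrays[f"{name}_upper_s"] = upper
            arrays[f"{name}_lower_s"] = lower
            arrays[f"{name}_gamma"] = g
            arrays[f"{name}_epoch_exchange"] = np.array([x for x, _ in labels])
    np.savez_compressed(traces_path, **arrays)

    manifest = RunManifest(
        config=json.loads(result.config.model_dump_json()),
        seed=result.config.seed,
        version=__version__,
        outputs={
            "transcript": str(transcript_path),
            "beliefs": str(beliefs_path),
            "traces": str(traces_path),
        },
        started=started,
        elapsed_s=time.time() - t0,
    )
    (outdir / "manifest.json").write_text(json.dumps(manifest.to_dict(), indent=2))
    return manifest


# ---------------------------------------------------------------------------
# fixture generator for oracle tests
# ---------------------------------------------------------------------------

_MAX_FIXTURE_SIZE = 4


def make_fixture(
    seed: int,
    *,
    n_states: int | tuple[int, ...] = 2,
    n_outcomes: int | tuple[int, ...] = 2,
    n_policies: int = 1,
    n_controls: int = 1,
    T: int = 1,
    concentration: float = 1.0,
) -> LevelModel:
    """A seeded random small model satisfying all stochasticity invariants.

    Factor, outcome and policy counts are capped at 4 so that brute-force
    enumeration oracles remain tractable; the same seed and sizes always
    produce the identical model.
    """
    states = (n_states,) if isinstance(n_states, int) else tuple(n_states)
    outs = (n_outcomes,) if isinstance(n_outcomes, int) else tuple(n_outcomes)
    for v in (*states, *outs, n_policies, n_controls, T, len(states), len(outs)):
        if v > _MAX_FIXTURE_SIZE:
            raise ValueError("fixture sizes are capped at 4 to keep oracles tractable")
        if v < 1:
            raise ValueError("fixture sizes must be positive")
    rng = np.random.default_rng(seed)
    factors = [Factor(f"f{i}", tuple(f"s{j}" for j in range(k))) for i, k in enumerate(states)]
    modalities = [Modality(f"m{i}", tuple(f"o{j}" for j in range(k))) for i, k in enumerate(outs)]
    dims = tuple(states)
    A = [rng.dirichlet(np.full(k, concentration), size=dims).transpose(
            (len(dims),) + tuple(range(len(dims)))
         ) for k in outs]
    B = [
        [rng.dirichlet(np.full(k, concentration), size=k).T for _ in range(n_controls)]
        for k in states
    ]
    C = [rng.normal(scale=0.5, size=k) for k in outs]
    D = [rng.dirichlet(np.full(k, concentration)) for k in states]
    policies = []
    for pid in range(n_policies):
        controls = rng.integers(0, n_controls, size=(T - 1, len(states)))
        policies.append(Policy(id=pid, controls=controls))
    return LevelModel(
        factors=factors,
        modalities=modalities,
        A=A,
        B=B,
        C=C,
        D=D,
        policies=policies,
        T=T,
        name=f"fixture{seed}",
    )
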