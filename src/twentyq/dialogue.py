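"""Dialogue orchestration: exchanges between agents (or a generative process).

Turn-taking is handcrafted, exactly as in the underlying scheme: agency is
not modelled, and a fixed schedule designates one speaker per phrase.  The
speaker generates words that maximise accuracy under its own beliefs; every
party — the speaker included — observes the same words and updates its
beliefs through the identical perception path, so listeners never see hidden
states, only words (pure communication).

Five scenarios are provided:

* ``solo`` — an uncertain agent questions a confident generative process
  (a second model instance with delta scenic priors), then answers two
  questions itself;
* ``dyad_qa`` — as above but framed as two synthetic subjects;
* ``role_reversal`` — the confident subject asks the questions;
* ``storytelling`` — the confident subject asks and answers its own
  questions while the other listens;
* ``folie_a_deux`` — both subjects are uncertain; with a nonzero "not sure"
  likelihood they truthfully confess ignorance, with it set to zero they
  converge on a shared fantasy.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .deep import descend
from .mdp import (
    LOG_FLOOR,
    BeliefState,
    EpochTrace,
    bayesian_model_average,
    expected_free_energy,
    occam_prune,
    policy_posterior,
    safe_log,
    select_outcome,
    softmax,
    update_states,
)
from .model import (
    COLOURS,
    SCENIC_FACTORS,
    SHAPES,
    WORDS,
    Scene,
    Semiotics,
    TwentyQModel,
    answer_for,
    build_model,
    phrase_words,
)

__all__ = [
    "ScenarioConfig",
    "Transcript",
    "Utterance",
    "Agent",
    "run_exchange",
    "run_scenario",
    "run_violation",
    "ScenarioResult",
    "ViolationResult",
    "belief_divergence",
    "total_variation",
    "parse_question",
]

PHRASE_ROLES = ("prompt", "question", "answer")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


class SceneConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    upper_colour: Literal["green", "red"] = "green"
    upper_shape: Literal["square", "triangle"] = "square"
    lower_colour: Literal["green", "red"] = "red"
    lower_shape: Literal["square", "triangle"] = "square"

    def to_scene(self) -> Scene:
        return Scene(**self.model_dump())


class ScenarioConfig(BaseModel):
    """Scenario configuration with the study's defaults.

    Six exchanges of three phrases (prompt, question, answer); belief updates
    in 16 iterations of 16 ms per outcome; answer costs -1/4 (Yes) and
    +1/4 (No); "not sure" likelihood 1/6.
    """

    model_config = ConfigDict(extra="forbid")

    scenario: Literal[
        "solo", "dyad_qa", "role_reversal", "storytelling", "folie_a_deux"
    ] = "solo"
    n_exchanges: int = Field(default=6, ge=1)
    seed: int = 0
    true_scene: Optional[SceneConfig] = Field(default_factory=SceneConfig)
    not_sure_likelihood: float = Field(default=1.0 / 6.0, ge=0.0, le=1.0)
    cost_yes: float = -0.25
    cost_no: float = 0.25
    iterations: int = Field(default=16, ge=1)
    kappa: float = Field(default=0.25, gt=0.0, le=1.0)
    beta_prior: float = Field(default=1.0, gt=0.0)
    precision_damping: float = Field(default=16.0, ge=1.0)
    occam_window: float = Field(default=3.0, gt=0.0)
    #: scenic prior precision of the uncertain subject (0 = uniform)
    agent_precision: float = Field(default=0.0, ge=0.0, le=1.0)
    #: action selection when speaking: MAP policy or seeded sampling
    action_selection: Optional[Literal["map", "sample"]] = None
    #: questioner per exchange ("agent" or "partner"); None = scenario default
    roles: Optional[list[Literal["agent", "partner"]]] = None

    def model_kwargs(self) -> dict:
        return dict(
            not_sure_likelihood=self.not_sure_likelihood,
            cost_yes=self.cost_yes,
            cost_no=self.cost_no,
            iterations=self.iterations,
            kappa=self.kappa,
            beta_prior=self.beta_prior,
            precision_damping=self.precision_damping,
            occam_window=self.occam_window,
        )


# ---------------------------------------------------------------------------
# transcripts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Utterance:
    exchange: int
    phrase_role: str
    speaker: str
    words: tuple[str, ...]

    def text(self) -> str:
        return " ".join(self.words)


@dataclass
class Transcript:
    """The dialogue record plus per-exchange belief snapshots."""

    utterances: list[Utterance] = field(default_factory=list)
    snapshots: dict[str, list[dict[str, np.ndarray]]] = field(default_factory=dict)

    def add(self, exchange: int, phrase_role: str, speaker: str, words: list[str]):
        trimmed: list[str] = []
        for w in words:
            trimmed.append(w)
            if w in ("?", "!"):
                break
        self.utterances.append(
            Utterance(exchange, phrase_role, speaker, tuple(trimmed))
        )

    def phrases(self, exchange: int | None = None, role: str | None = None):
        return [
            u for u in self.utterances
            if (exchange is None or u.exchange == exchange)
            and (role is None or u.phrase_role == role)
        ]

    def to_text(self) -> str:
        lines = []
        for u in self.utterances:
            lines.append(f"[{u.exchange + 1}:{u.phrase_role}] {u.speaker}: {u.text()}")
        return "\n".join(lines) + "\n"


def parse_question(words: list[str]) -> tuple[str, Semiotics]:
    """Decode (question type, semiotics) from a question phrase."""
    if not words or words[0] != "Is":
        raise ValueError(f"not a question phrase: {words!r}")
    if words[1] == "the":
        qtype, noun, adj, adv = "location", words[2], "green", words[3]
    elif words[2] in COLOURS:
        qtype, noun, adj, adv = "colour", words[3], words[2], words[4]
    else:
        qtype, noun, adj, adv = "shape", words[2], "green", words[3]
    return qtype, Semiotics(noun=noun, adjective=adj, adverb=adv)


# ---------------------------------------------------------------------------
# the agent
# ---------------------------------------------------------------------------


class Agent:
    """A synthetic subject: a deep model plus its evolving beliefs.

    The generative process of the solo simulation is just another ``Agent``
    whose scenic priors are delta distributions on the true scene.
    """

    def __init__(
        self,
        name: str,
        model: TwentyQModel,
        scenic_prior: list[np.ndarray],
        rng: np.random.Generator | None = None,
        action_selection: str = "map",
    ):
        self.name = name
        self.model = model
        self.config = model.config
        self.scenic_D = [np.asarray(d, float) for d in scenic_prior]
        self.rng = rng or np.random.default_rng(0)
        self.action_selection = action_selection
        self.qb = self.config.beta_prior
        self.log: list[dict] = []           # one entry per epoch (exchange-phrase)
        self.snapshots: list[dict[str, np.ndarray]] = []  # per exchange
        self.exchange_index = -1
        self._n_upper = model.upper.n_factors

    # -- exchange lifecycle ---------------------------------------------
    def begin_exchange(self):
        self.exchange_index += 1
        D = self.model.upper_D(self.scenic_D)
        self.upper_model = self.model.upper.replace_D(D)
        self.belief = BeliefState.initialise(self.upper_model)
        self.obs: list = [None] * self.upper_model.T
        self.G0 = expected_free_energy(self.upper_model, self.belief)
        self.belief.G = self.G0
        self.belief.pi = policy_posterior(
            np.zeros(self.upper_model.n_policies), self.G0, 1.0 / self.qb
        )

    def end_exchange(self):
        bma = bayesian_model_average(self.belief)
        scenic = []
        for name in SCENIC_FACTORS:
            fi = [f.name for f in self.upper_model.factors].index(name)
            # carried priors are clipped at the probability floor, so a
            # single contradictory answer can always revise them
            q = np.clip(bma[fi][-1], LOG_FLOOR, None)
            scenic.append(q / q.sum())
        self.scenic_D = scenic
        self.snapshots.append(dict(zip(SCENIC_FACTORS, scenic)))

    def scenic_beliefs(self) -> dict[str, np.ndarray]:
        return dict(zip(SCENIC_FACTORS, self.scenic_D))

    def map_scene(self) -> Scene:
        b = self.scenic_beliefs()
        return Scene(
            upper_colour=COLOURS[int(np.argmax(b["upper_colour"]))],
            upper_shape=SHAPES[int(np.argmax(b["upper_shape"]))],
            lower_colour=COLOURS[int(np.argmax(b["lower_colour"]))],
            lower_shape=SHAPES[int(np.argmax(b["lower_shape"]))],
        )

    # -- acting ----------------------------------------------------------
    def select_policy(self) -> int:
        pi = self.belief.pi
        if self.action_selection == "sample":
            return int(self.rng.choice(len(pi), p=pi))
        return int(np.argmax(pi))

    def speak(self, epoch: int) -> list[int]:
        """Generate the words of the current phrase (accuracy maximisation).

        The conceptual level commits to the lower level's initial states
        under the selected policy; the lexical level then rolls the phrase
        out word by word, each word being the least surprising outcome under
        the predicted syntax and semantics.
        """
        p = self.select_policy()
        s_pred = [self.belief.s[f][p, epoch] for f in range(self._n_upper)]
        inits = select_outcome(self.upper_model, s_pred)
        lower = self.model.lower
        D = []
        for fi, f in enumerate(lower.factors):
            d = np.zeros(f.n)
            d[inits[fi]] = 1.0
            D.append(d)
        lower_model = lower.replace_D(D)
        lb = BeliefState.initialise(lower_model)
        words = []
        for w in range(lower.T):
            s_next = [lb.s[f][0, w] for f in range(lower.n_factors)]
            words.append(select_outcome(lower_model, s_next)[0])
        return words

    # -- perceiving ------------------------------------------------------
    def hear(self, epoch: int, word_indices: list[int], *, exchange_role: str = ""):
        """Assimilate a phrase: lexical decoding, ascent, conceptual update.

        This is the shared perception path — the speaker hears its own words
        through exactly the same computation as every listener.
        """
        cfg = self.config
        bma = bayesian_model_average(self.belief)
        d_low = descend(
            self.model.deep.link, [bma[f][epoch] for f in range(self._n_upper)]
        )
        lower_model = self.model.lower.replace_D(d_low)
        lb_obs: list = [None] * lower_model.T
        lower_traces: list[EpochTrace] = []
        # Each word triggers a fresh mean-field re-inference of the phrase
        # from the empirical (descending) prior, given all words heard so
        # far.  Evidence still accumulates word by word (ever more
        # likelihood messages join the message passing); what is not carried
        # over is the variational iterate itself, because coordinate
        # dynamics on near-deterministic syntax chains can lock into a
        # premature parse before the disambiguating word arrives.
        lb = BeliefState.initialise(lower_model)
        for w, o in enumerate(word_indices):
            if not 0 <= o < len(WORDS):
                raise ValueError(f"word index {o} is not in the lexicon")
            lb_obs[w] = [int(o)]
            lb, tr = update_states(
                lower_model, lb_obs, BeliefState.initialise(lower_model),
                iterations=cfg.iterations, kappa=cfg.kappa,
                label=f"x{self.exchange_index}.{exchange_role}.w{w}",
                compute_F=False,
            )
            lower_traces.append(tr)
        q_init = [lb.s[f][0, 0] for f in range(lower_model.n_factors)]
        self.obs[epoch] = q_init
        self.belief, upper_trace = update_states(
            self.upper_model, self.obs, self.belief,
            iterations=cfg.iterations, kappa=cfg.kappa,
            label=f"x{self.exchange_index}.{exchange_role}",
        )
        # precision dynamics (simulated dopamine): damped ascent of the
        # posterior rate parameter toward its fixed point, one step per
        # variational iteration, carried across epochs
        gammas = np.zeros(cfg.iterations)
        pi0 = None
        for i in range(cfg.iterations):
            gamma = 1.0 / self.qb
            pi0 = softmax(-gamma * self.G0)
            pi_i = softmax(-upper_trace.F[i] - gamma * self.G0)
            beta_star = max(1e-2, cfg.beta_prior + float((pi_i - pi0) @ self.G0))
            self.qb += (beta_star - self.qb) / cfg.precision_damping
            gammas[i] = 1.0 / self.qb
        upper_trace.gamma = gammas
        self.belief.gamma = 1.0 / self.qb
        self.belief.pi = occam_prune(
            policy_posterior(self.belief.F, self.G0, self.belief.gamma),
            cfg.occam_window,
        )
        upper_trace.meta.update(
            exchange=self.exchange_index, phrase_role=exchange_role, level=2
        )
        for tr in lower_traces:
            tr.meta.update(
                exchange=self.exchange_index, phrase_role=exchange_role, level=1
            )
        self.log.append(
            dict(
                exchange=self.exchange_index,
                phrase_role=exchange_role,
                upper=upper_trace,
                lower=lower_traces,
            )
        )

    # -- trace assembly --------------------------------------------------
    def upper_session(self, exchanges: list[int] | None = None):
        """Concatenated conceptual-level trace: (s [bins, units], entries)."""
        rows, entries = [], []
        for entry in self.log:
            if exchanges is not None and entry["exchange"] not in exchanges:
                continue
            rows.append(entry["upper"].s)
            entries.append(entry)
        return np.concatenate(rows, axis=0), entries

    def lower_session(self, exchanges: list[int] | None = None):
        rows, entries = [], []
        for entry in self.log:
            if exchanges is not None and entry["exchange"] not in exchanges:
                continue
            for tr in entry["lower"]:
                rows.append(tr.s)
                entries.append(entry)
        return (np.concatenate(rows, axis=0) if rows else np.zeros((0, 0))), entries

    def dopamine_series(self):
        """Concatenated gamma iterates with (exchange, phrase role) labels."""
        g, labels = [], []
        for entry in self.log:
            tr = entry["upper"]
            g.append(tr.gamma)
            labels.extend(
                [(entry["exchange"], entry["phrase_role"])] * tr.n_bins
            )
        return np.concatenate(g), labels


# ---------------------------------------------------------------------------
# exchanges and scenarios
# ---------------------------------------------------------------------------


def run_exchange(
    agents: dict[str, Agent],
    questioner: str,
    answerer: str,
    exchange: int,
    transcript: Transcript,
    forced: dict[str, list[str]] | None = None,
) -> dict[str, list[str]]:
    """One exchange: prompt (answerer), question (questioner), answer (answerer).

    All agents observe the same word stream; ``forced`` optionally scripts
    the words of given phrase roles (used by the violation paradigm).
    Returns the words spoken per phrase role.
    """
    speakers = {"prompt": answerer, "question": questioner, "answer": answerer}
    spoken: dict[str, list[str]] = {}
    for ag in agents.values():
        ag.begin_exchange()
    for role in PHRASE_ROLES:
        speaker = agents[speakers[role]]
        epoch = PHRASE_ROLES.index(role)
        if forced and role in forced:
            words = forced[role]
            indices = speaker.model.words_to_indices(words)
            # pad with the terminal grammar state up to the lexical horizon
            while len(indices) < speaker.model.lower.T:
                indices.append(indices[-1])
        else:
            indices = speaker.speak(epoch)
            words = [WORDS[i] for i in indices]
        for ag in agents.values():
            ag.hear(epoch, indices, exchange_role=role)
        transcript.add(exchange, role, speakers[role], words)
        spoken[role] = words
    for ag in agents.values():
        ag.end_exchange()
    return spoken


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    transcript: Transcript
    agents: dict[str, Agent]
    roles: list[dict[str, str]]
    answers: list[dict]

    def kl_history(self, a: str = "agent", b: str = "partner") -> np.ndarray:
        """Summed scenic KL divergence between two agents after each exchange."""
        hist = []
        for sa, sb in zip(self.agents[a].snapshots, self.agents[b].snapshots):
            _, total = belief_divergence(
                [sa[f] for f in SCENIC_FACTORS], [sb[f] for f in SCENIC_FACTORS]
            )
            hist.append(total)
        return np.asarray(hist)


def _role_schedule(cfg: ScenarioConfig) -> list[dict[str, str]]:
    n = cfg.n_exchanges
    if cfg.roles is not None:
        if len(cfg.roles) != n:
            raise ValueError("roles must list one questioner per exchange")
        return [
            {"questioner": q, "answerer": "partner" if q == "agent" else "agent"}
            for q in cfg.roles
        ]
    sched = []
    for k in range(n):
        if cfg.scenario in ("solo", "dyad_qa"):
            q = "agent" if k < max(n - 2, 1) else "partner"
            sched.append({"questioner": q, "answerer": "partner" if q == "agent" else "agent"})
        elif cfg.scenario == "role_reversal":
            sched.append({"questioner": "partner", "answerer": "agent"})
        elif cfg.scenario == "storytelling":
            if k < min(4, n):
                sched.append({"questioner": "partner", "answerer": "partner"})
            else:
                sched.append({"questioner": "partner", "answerer": "agent"})
        else:  # folie_a_deux: the subjects question each other in turn
            q = "agent" if k % 2 == 0 else "partner"
            sched.append({"questioner": q, "answerer": "partner" if q == "agent" else "agent"})
    return sched


def _build_agents(cfg: ScenarioConfig, model: TwentyQModel) -> dict[str, Agent]:
    rng = np.random.default_rng(cfg.seed)
    selection = cfg.action_selection or (
        "sample" if cfg.scenario == "storytelling" else "map"
    )
    scene = cfg.true_scene.to_scene() if cfg.true_scene is not None else None
    if cfg.scenario == "folie_a_deux":
        agent_prior = model.scenic_uniform()
        partner_prior = model.scenic_uniform()
    else:
        if scene is None:
            raise ValueError(f"scenario {cfg.scenario!r} requires a true scene")
        agent_prior = (
            model.scenic_uniform()
            if cfg.agent_precision == 0.0
            else model.scenic_mixture(scene, cfg.agent_precision)
        )
        partner_prior = model.scenic_delta(scene)
    return {
        "agent": Agent(
            "agent", model, agent_prior,
            rng=np.random.default_rng(rng.integers(2**31)),
            action_selection=selection,
        ),
        "partner": Agent(
            "partner", model, partner_prior,
            rng=np.random.default_rng(rng.integers(2**31)),
            action_selection=selection,
        ),
    }


def run_scenario(config: ScenarioConfig | dict | None = None) -> ScenarioResult:
    """Execute a configured scenario and return transcript, beliefs and traces."""
    if config is None:
        config = ScenarioConfig()
    elif isinstance(config, dict):
        config = ScenarioConfig(**config)
    model = build_model(config.model_kwargs())
    agents = _build_agents(config, model)
    roles = _role_schedule(config)
    transcript = Transcript()
    answers: list[dict] = []
    scene = config.true_scene.to_scene() if config.true_scene is not None else None
    for k, role in enumerate(roles):
        spoken = run_exchange(
            agents, role["questioner"], role["answerer"], k, transcript
        )
        record = {
            "exchange": k,
            "questioner": role["questioner"],
            "answer_word": spoken["answer"][0],
        }
        try:
            qtype, sem = parse_question(spoken["question"])
            record["qtype"], record["semiotics"] = qtype, sem
            if scene is not None:
                truth = answer_for(scene, sem, qtype)
                record["correct"] = spoken["answer"][0] == truth
        except ValueError:
            pass
        answers.append(record)
    for name, ag in agents.items():
        transcript.snapshots[name] = ag.snapshots
    return ScenarioResult(
        config=config, transcript=transcript, agents=agents, roles=roles,
        answers=answers,
    )


# ---------------------------------------------------------------------------
# the violation paradigm
# ---------------------------------------------------------------------------


@dataclass
class ViolationResult:
    """Matched runs differing only in the final answer of the fifth exchange."""

    standard: Agent
    violation: Agent
    question: list[str]
    answers: dict[str, list[str]]
    transcript_standard: Transcript
    transcript_violation: Transcript

    @property
    def answer_onset_bin(self) -> int:
        """Bin index of answer onset within the fifth exchange's trace."""
        return 2 * self.standard.config.iterations


def run_violation(config: ScenarioConfig | dict | None = None) -> ViolationResult:
    """Rerun the fifth exchange with the wrong answer supplied.

    Exchanges 1-4 of the solo scenario run normally; the fifth is scripted:
    the process asks about the combination of colour and shape of the lower
    object (which the agent, by then, is confident about) and either confirms
    ("Yes !") or contradicts ("No !") that belief.
    """
    if config is None:
        config = ScenarioConfig()
    elif isinstance(config, dict):
        config = ScenarioConfig(**config)
    if config.true_scene is None:
        raise ValueError("the violation paradigm requires a true scene")
    model = build_model(config.model_kwargs())
    agents = _build_agents(config, model)
    transcript = Transcript()
    for k in range(4):
        run_exchange(agents, "agent", "partner", k, transcript)
    scene = config.true_scene.to_scene()
    sem = Semiotics(
        noun=scene.lower_shape, adjective=scene.lower_colour, adverb="below"
    )
    question = phrase_words("question", "colour", sem)
    results: dict[str, tuple] = {}
    answers = {"standard": phrase_words("answer", answer=answer_for(scene, sem, "colour")),
               "violation": phrase_words("answer", answer="No")}
    for variant in ("standard", "violation"):
        branch = {n: copy.deepcopy(a) for n, a in agents.items()}
        tscript = copy.deepcopy(transcript)
        run_exchange(
            branch, "partner", "agent", 4, tscript,
            forced={"question": question, "answer": answers[variant]},
        )
        results[variant] = (branch["agent"], tscript)
    return ViolationResult(
        standard=results["standard"][0],
        violation=results["violation"][0],
        question=question,
        answers=answers,
        transcript_standard=results["standard"][1],
        transcript_violation=results["violation"][1],
    )


# ---------------------------------------------------------------------------
# belief comparison
# ---------------------------------------------------------------------------


def belief_divergence(
    beliefs_a: list[np.ndarray],
    beliefs_b: list[np.ndarray],
    *,
    symmetrised: bool = False,
) -> tuple[np.ndarray, float]:
    """KL divergence (nats) between matching belief factors, and its sum.

    Uses the engine's probability floor inside the logs, so a delta belief
    compared with a uniform one yields a finite divergence.
    """
    if len(beliefs_a) != len(beliefs_b):
        raise ValueError("belief lists must have matching factor structure")
    per = []
    for qa, qb in zip(beliefs_a, beliefs_b):
        qa = np.asarray(qa, float)
        qb = np.asarray(qb, float)
        if qa.shape != qb.shape:
            raise ValueError("belief factors must have matching shapes")
        kl = float(np.sum(qa * (safe_log(qa) - safe_log(qb))))
        if symmetrised:
            kl = 0.5 * (kl + float(np.sum(qb * (safe_log(qb) - safe_log(qa)))))
        per.append(kl)
    per = np.asarray(per)
    return per, float(per.sum())


def total_variation(
    beliefs_a: list[np.ndarray], beliefs_b: list[np.ndarray]
) -> float:
    """Summed total-variation distance between matching belief factors."""
    return float(
        sum(
            0.5 * np.abs(np.asarray(a, float) - np.asarray(b, float)).sum()
            for a, b in zip(beliefs_a, beliefs_b)
        )
    )
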