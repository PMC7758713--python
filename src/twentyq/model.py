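"""The "Twenty Questions" generative model.

A simplified game in which two objects are stacked vertically; each is a
square or a triangle, coloured green or red (16 possible scenes).  An agent
resolves its uncertainty about the scene by asking closed questions and
listening to answers, phrased as short word sequences.

The model has two levels:

* **conceptual level** (slow, one step per phrase) with nine hidden factors:
  the *narrative* (prompt / question / answer, cycling with precise
  transitions), the *question type* (shape / location / colour,
  controllable), three *semiotic* factors (noun, adjective, adverb — the
  topic under discussion, controllable) and four *scenic* factors (colour
  and shape of the upper and lower object — uncontrollable and absorbing).
  Policies fix a target question type and semiotic content that remain
  operational across the exchange.
* **lexical level** (fast, one step per word) with a *syntax* factor (word
  slots chained into phrase templates, with terminal grammar states) and
  three *semantic* factors copied from the semiotics.  The likelihood maps
  syntax x semantics to articulated words.

The link between levels is the initial-state tensor of the lexical level:
prompts start at "Ready", questions at the "Is" slot of the template chosen
by the question type, and answers start at "Yes" / "No" / "Not sure"
according to the congruence of scenic and semiotic states — "Yes" is
generated when, and only when, the attributes interrogated by the question
match the scene at the location named by the adverb.  An "I'm not sure"
initial state receives a configurable likelihood irrespective of the scene,
which is what lets uncertain agents truthfully report their ignorance (and,
when set to zero, forces definitive answers — the folie-a-deux variant).

Answer preferences enter as prior costs on the answer initial states
(default -1/4 for "Yes", +1/4 for "No"): all else being equal, agents ask
questions they expect to be answered affirmatively.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .deep import DeepModel, LinkTensor
from .mdp import Factor, LevelModel, Modality, Policy

__all__ = [
    "Scene",
    "Semiotics",
    "Lexicon",
    "ModelConfig",
    "TwentyQModel",
    "build_model",
    "answer_for",
    "phrase_words",
    "report_probabilities",
    "WORDS",
    "SYNTAX_TABLE",
    "COLOURS",
    "SHAPES",
    "LOCATIONS",
    "QUESTION_TYPES",
]

COLOURS = ("green", "red")
SHAPES = ("square", "triangle")
LOCATIONS = ("below", "above")
QUESTION_TYPES = ("shape", "location", "colour")
NARRATIVES = ("prompt", "question", "answer")
ANSWERS = ("Yes", "No", "Not sure")

#: the closed vocabulary (word outcomes of the lexical level)
WORDS = (
    "Ready", "Is", "a", "the",
    "square", "triangle", "green", "red", "below", "above",
    "Yes", "No", "Not", "sure", "?", "!",
)

# role placeholders filled from the semantic factors
_ROLE_WORDS = {
    "noun": {s: WORDS.index(s) for s in SHAPES},
    "adjective": {c: WORDS.index(c) for c in COLOURS},
    "adverb": {l: WORDS.index(l) for l in LOCATIONS},
}

#: syntax chain: state name -> (emission, successor state).  The emission is
#: either a literal word or a semantic role; "?" and "!" are absorbing
#: terminal grammar states.  Question templates: shape "Is a [noun]
#: [adverb] ?", location "Is the [noun] [adverb] ?", colour "Is a
#: [adjective] [noun] [adverb] ?".
SYNTAX_TABLE: tuple[tuple[str, str, str], ...] = (
    ("ready", "Ready", "qmark"),
    ("qmark", "?", "qmark"),
    ("excl", "!", "excl"),
    ("q_shape_is", "Is", "q_shape_a"),
    ("q_shape_a", "a", "q_shape_noun"),
    ("q_shape_noun", "noun", "q_shape_adv"),
    ("q_shape_adv", "adverb", "qmark"),
    ("q_loc_is", "Is", "q_loc_the"),
    ("q_loc_the", "the", "q_loc_noun"),
    ("q_loc_noun", "noun", "q_loc_adv"),
    ("q_loc_adv", "adverb", "qmark"),
    ("q_col_is", "Is", "q_col_a"),
    ("q_col_a", "a", "q_col_adj"),
    ("q_col_adj", "adjective", "q_col_noun"),
    ("q_col_noun", "noun", "q_col_adv"),
    ("q_col_adv", "adverb", "qmark"),
    ("yes", "Yes", "excl"),
    ("no", "No", "excl"),
    ("ns_not", "Not", "ns_sure"),
    ("ns_sure", "sure", "excl"),
)

SYNTAX_NAMES = tuple(row[0] for row in SYNTAX_TABLE)
_SYN = {name: i for i, name in enumerate(SYNTAX_NAMES)}
QUESTION_START = {"shape": "q_shape_is", "location": "q_loc_is", "colour": "q_col_is"}
ANSWER_START = {"Yes": "yes", "No": "no", "Not sure": "ns_not"}
TERMINALS = ("qmark", "excl")

MAX_WORDS = 6  # longest phrase (the colour question) incl. terminal grammar


# ---------------------------------------------------------------------------
# scenes, semiotics, answers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Scene:
    """The hidden 4-factor scene: colour and shape at the two locations."""

    upper_colour: str = "green"
    upper_shape: str = "square"
    lower_colour: str = "red"
    lower_shape: str = "square"

    def __post_init__(self):
        for v, allowed in (
            (self.upper_colour, COLOURS), (self.lower_colour, COLOURS),
            (self.upper_shape, SHAPES), (self.lower_shape, SHAPES),
        ):
            if v not in allowed:
                raise ValueError(f"{v!r} is not one of {allowed}")

    def colour_at(self, location: str) -> str:
        return self.upper_colour if location == "above" else self.lower_colour

    def shape_at(self, location: str) -> str:
        return self.upper_shape if location == "above" else self.lower_shape

    def as_indices(self) -> tuple[int, int, int, int]:
        """(upper_colour, upper_shape, lower_colour, lower_shape) indices."""
        return (
            COLOURS.index(self.upper_colour),
            SHAPES.index(self.upper_shape),
            COLOURS.index(self.lower_colour),
            SHAPES.index(self.lower_shape),
        )


@dataclass(frozen=True)
class Semiotics:
    """The topic under discussion: noun, adjective and adverb states."""

    noun: str = "square"
    adjective: str = "green"
    adverb: str = "below"

    def __post_init__(self):
        if self.noun not in SHAPES:
            raise ValueError(f"noun {self.noun!r} is not one of {SHAPES}")
        if self.adjective not in COLOURS:
            raise ValueError(f"adjective {self.adjective!r} is not one of {COLOURS}")
        if self.adverb not in LOCATIONS:
            raise ValueError(f"adverb {self.adverb!r} is not one of {LOCATIONS}")


def congruent(scene: Scene, semiotics: Semiotics, qtype: str) -> bool:
    """Do the interrogated attributes match the scene at the named location?

    Shape and location questions interrogate the shape (noun) at the
    location named by the adverb; colour questions interrogate both the
    shape and the colour (adjective) there.
    """
    if qtype not in QUESTION_TYPES:
        raise ValueError(f"unknown question type {qtype!r}")
    loc = semiotics.adverb
    shape_ok = scene.shape_at(loc) == semiotics.noun
    if qtype in ("shape", "location"):
        return shape_ok
    return shape_ok and scene.colour_at(loc) == semiotics.adjective


def answer_for(scene: Scene, semiotics: Semiotics, qtype: str) -> str:
    """The definitive answer under the congruence rule ("Yes" iff congruent).

    The "Not sure" outcome is not returned here: it carries its configured
    likelihood irrespective of congruence and so is never the *definitive*
    answer for a fully specified scene.
    """
    return "Yes" if congruent(scene, semiotics, qtype) else "No"


def phrase_words(
    narrative: str,
    qtype: str | None = None,
    semiotics: Semiotics | None = None,
    answer: str | None = None,
) -> list[str]:
    """Deterministic rollout of the syntax chain through the lexicon."""
    if narrative == "prompt":
        state = "ready"
    elif narrative == "question":
        if qtype not in QUESTION_TYPES:
            raise ValueError(f"unknown question type {qtype!r}")
        state = QUESTION_START[qtype]
    elif narrative == "answer":
        if answer not in ANSWER_START:
            raise ValueError(f"unknown answer {answer!r}")
        state = ANSWER_START[answer]
    else:
        raise ValueError(f"unknown narrative state {narrative!r}")
    sem = semiotics or Semiotics()
    words: list[str] = []
    for _ in range(MAX_WORDS):
        name, emission, nxt = SYNTAX_TABLE[_SYN[state]]
        if emission == "noun":
            words.append(sem.noun)
        elif emission == "adjective":
            words.append(sem.adjective)
        elif emission == "adverb":
            words.append(sem.adverb)
        else:
            words.append(emission)
        if name in TERMINALS:
            break
        state = nxt
    return words


def report_probabilities(
    belief: np.ndarray, report_likelihood: float
) -> tuple[np.ndarray, float]:
    """Evidence-dilution report model.

    With report likelihood ``r``, the probability of reporting option ``i``
    is ``r * belief_i`` and the probability of saying "not sure" is
    ``1 - r`` — so a diffuse belief over many options makes the
    uninformative report the most likely outcome.
    """
    r = float(report_likelihood)
    if not 0.0 <= r <= 1.0:
        raise ValueError("report likelihood must lie in [0, 1]")
    belief = np.asarray(belief, dtype=float)
    if np.any(belief < 0) or not np.isclose(belief.sum(), 1.0, atol=1e-8):
        raise ValueError("belief must be a simplex")
    return r * belief, 1.0 - r


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


class ModelConfig(BaseModel):
    """Tunable parameters of the Twenty Questions model."""

    model_config = ConfigDict(extra="forbid")

    not_sure_likelihood: float = Field(default=1.0 / 6.0, ge=0.0, le=1.0)
    cost_yes: float = -0.25
    cost_no: float = 0.25
    iterations: int = Field(default=16, ge=1)
    kappa: float = Field(default=0.25, gt=0.0, le=1.0)
    bin_ms: float = 16.0
    beta_prior: float = Field(default=1.0, gt=0.0)
    precision_damping: float = Field(default=16.0, ge=1.0)
    occam_window: float = Field(default=3.0, gt=0.0)


# ---------------------------------------------------------------------------
# lexicon container (serialisable)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Lexicon:
    """Mapping from (syntax state, semantics) to word tokens."""

    words: tuple[str, ...] = WORDS
    syntax: tuple[tuple[str, str, str], ...] = SYNTAX_TABLE

    def word_for(self, syntax_state: str, sem: Semiotics) -> str:
        emission = self.syntax[_SYN[syntax_state]][1]
        if emission == "noun":
            return sem.noun
        if emission == "adjective":
            return sem.adjective
        if emission == "adverb":
            return sem.adverb
        return emission

    def as_dict(self) -> dict:
        return {
            "words": list(self.words),
            "syntax": [
                {"state": s, "emits": e, "next": n} for s, e, n in self.syntax
            ],
            "question_start": dict(QUESTION_START),
            "answer_start": dict(ANSWER_START),
        }


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------


# conceptual-level factor layout (order matters and is part of the contract)
UPPER_FACTORS = (
    Factor("narrative", NARRATIVES),
    Factor("qtype", QUESTION_TYPES),
    Factor("noun", SHAPES),
    Factor("adjective", COLOURS),
    Factor("adverb", LOCATIONS),
    Factor("upper_colour", COLOURS),
    Factor("upper_shape", SHAPES),
    Factor("lower_colour", COLOURS),
    Factor("lower_shape", SHAPES),
)
SCENIC_FACTORS = ("upper_colour", "upper_shape", "lower_colour", "lower_shape")

LOWER_FACTORS = (
    Factor("syntax", SYNTAX_NAMES),
    Factor("sem_noun", SHAPES),
    Factor("sem_adjective", COLOURS),
    Factor("sem_adverb", LOCATIONS),
)


@dataclass
class TwentyQModel:
    """The constructed two-level model plus its lexicon and metadata."""

    deep: DeepModel
    lexicon: Lexicon
    config: ModelConfig

    @property
    def upper(self) -> LevelModel:
        return self.deep.levels[1]

    @property
    def lower(self) -> LevelModel:
        return self.deep.levels[0]

    # -- prior helpers ---------------------------------------------------
    def scenic_uniform(self) -> list[np.ndarray]:
        return [np.full(2, 0.5) for _ in SCENIC_FACTORS]

    def scenic_delta(self, scene: Scene) -> list[np.ndarray]:
        out = []
        for name, idx in zip(SCENIC_FACTORS, scene.as_indices()):
            d = np.zeros(2)
            d[idx] = 1.0
            out.append(d)
        return out

    def scenic_mixture(self, scene: Scene, precision: float) -> list[np.ndarray]:
        """Interpolate between uniform (0) and delta (1) scenic priors."""
        delta = self.scenic_delta(scene)
        return [precision * d + (1 - precision) * 0.5 for d in delta]

    def upper_D(self, scenic: list[np.ndarray]) -> list[np.ndarray]:
        """Initial priors at exchange start: prompt narrative, open topic."""
        D = [np.zeros(3), np.full(3, 1 / 3), np.full(2, 0.5), np.full(2, 0.5),
             np.full(2, 0.5)]
        D[0][NARRATIVES.index("prompt")] = 1.0
        return D + [np.asarray(d, float) for d in scenic]

    # -- readbacks -------------------------------------------------------
    def answer_likelihood_row(self, answer: str) -> np.ndarray:
        """The answer-congruence likelihood row for one answer initial state,
        restricted to narrative = answer (flattened over remaining factors)."""
        a = self.upper.A[0]
        idx = _SYN[ANSWER_START[answer]]
        return a[idx, NARRATIVES.index("answer")].reshape(-1)

    def answer_cost(self, answer: str) -> float:
        return float(self.upper.C[0][_SYN[ANSWER_START[answer]]])

    def words_to_indices(self, words: list[str]) -> list[int]:
        out = []
        for w in words:
            if w not in WORDS:
                raise ValueError(f"token {w!r} is not in the lexicon")
            out.append(WORDS.index(w))
        return out


def _lower_level() -> LevelModel:
    nS = len(SYNTAX_NAMES)
    dims = (nS, 2, 2, 2)
    A = np.zeros((len(WORDS), *dims))
    for si, (name, emission, _) in enumerate(SYNTAX_TABLE):
        for n, adj, adv in itertools.product(range(2), range(2), range(2)):
            if emission == "noun":
                w = _ROLE_WORDS["noun"][SHAPES[n]]
            elif emission == "adjective":
                w = _ROLE_WORDS["adjective"][COLOURS[adj]]
            elif emission == "adverb":
                w = _ROLE_WORDS["adverb"][LOCATIONS[adv]]
            else:
                w = WORDS.index(emission)
            A[w, si, n, adj, adv] = 1.0
    B_syntax = np.zeros((nS, nS))
    for si, (_, _, nxt) in enumerate(SYNTAX_TABLE):
        B_syntax[_SYN[nxt], si] = 1.0
    B = [[B_syntax]] + [[np.eye(2)] for _ in range(3)]
    D = [np.full(nS, 1.0 / nS)] + [np.full(2, 0.5) for _ in range(3)]
    policies = [Policy(id=0, controls=np.zeros((MAX_WORDS - 1, 4), dtype=int))]
    return LevelModel(
        factors=list(LOWER_FACTORS),
        modalities=[Modality("word", WORDS)],
        A=[A],
        B=B,
        C=[np.zeros(len(WORDS))],
        D=D,
        policies=policies,
        T=MAX_WORDS,
        name="lexical",
    )


def _upper_level(config: ModelConfig) -> tuple[LevelModel, LinkTensor]:
    dims = tuple(f.n for f in UPPER_FACTORS)  # (3, 3, 2, 2, 2, 2, 2, 2, 2)
    nS = len(SYNTAX_NAMES)
    r = config.not_sure_likelihood

    # link / likelihood for the lexical initial syntax state
    A_syn = np.zeros((nS, *dims))
    # prompt: start at "ready", whatever else is true
    A_syn[_SYN["ready"], 0] = 1.0
    # question: start at the "Is" slot of the template named by the question type
    for qi, qt in enumerate(QUESTION_TYPES):
        A_syn[_SYN[QUESTION_START[qt]], 1, qi] = 1.0
    # answer: congruence of semiotic and scenic states
    for qi, qt in enumerate(QUESTION_TYPES):
        for n, adj, adv in itertools.product(range(2), range(2), range(2)):
            sem = Semiotics(SHAPES[n], COLOURS[adj], LOCATIONS[adv])
            for uc, us, lc, ls in itertools.product(*[range(2)] * 4):
                scene = Scene(COLOURS[uc], SHAPES[us], COLOURS[lc], SHAPES[ls])
                yes = congruent(scene, sem, qt)
                sl = (2, qi, n, adj, adv, uc, us, lc, ls)
                A_syn[(_SYN["ns_not"],) + sl] = r
                A_syn[(_SYN["yes" if yes else "no"],) + sl] = 1.0 - r

    # semantic initial states copy the semiotic factors
    def copy_A(factor_axis: int, k: int) -> np.ndarray:
        a = np.zeros((k, *dims))
        for i in range(k):
            sl = [slice(None)] * (1 + len(dims))
            sl[0] = i
            sl[1 + factor_axis] = i
            a[tuple(sl)] = 1.0
        return a

    A = [A_syn, copy_A(2, 2), copy_A(3, 2), copy_A(4, 2)]

    # transitions
    B_narr = np.zeros((3, 3))
    B_narr[1, 0] = 1.0  # prompt -> question
    B_narr[2, 1] = 1.0  # question -> answer
    B_narr[0, 2] = 1.0  # answer -> prompt (cycle)
    def set_to(k: int) -> list[np.ndarray]:
        mats = []
        for target in range(k):
            b = np.zeros((k, k))
            b[target, :] = 1.0
            mats.append(b)
        return mats

    B = [
        [B_narr],
        set_to(3),       # question type (controllable)
        set_to(2),       # noun
        set_to(2),       # adjective
        set_to(2),       # adverb
        [np.eye(2)], [np.eye(2)], [np.eye(2)], [np.eye(2)],  # scenic: absorbing
    ]

    C_syn = np.zeros(nS)
    C_syn[_SYN["yes"]] = config.cost_yes
    C_syn[_SYN["no"]] = config.cost_no
    C = [C_syn, np.zeros(2), np.zeros(2), np.zeros(2)]

    D = [np.zeros(3), np.full(3, 1 / 3)] + [np.full(2, 0.5) for _ in range(7)]
    D[0][0] = 1.0

    # policies: one per (question type, noun, adjective, adverb) target,
    # held constant across the exchange
    policies = []
    T = 3
    for pid, (qt, n, adj, adv) in enumerate(
        itertools.product(range(3), range(2), range(2), range(2))
    ):
        controls = np.zeros((T - 1, len(UPPER_FACTORS)), dtype=int)
        controls[:, 1] = qt
        controls[:, 2] = n
        controls[:, 3] = adj
        controls[:, 4] = adv
        policies.append(Policy(id=pid, controls=controls))

    modalities = [
        Modality("syntax_init", SYNTAX_NAMES),
        Modality("noun_init", SHAPES),
        Modality("adjective_init", COLOURS),
        Modality("adverb_init", LOCATIONS),
    ]
    upper = LevelModel(
        factors=list(UPPER_FACTORS),
        modalities=modalities,
        A=A,
        B=B,
        C=C,
        D=D,
        policies=policies,
        T=T,
        name="conceptual",
    )
    link = LinkTensor(arrays=[np.array(a) for a in A])
    return upper, link


def build_model(config: ModelConfig | dict | None = None) -> TwentyQModel:
    """Construct the two-level Twenty Questions model from a configuration."""
    if config is None:
        config = ModelConfig()
    elif isinstance(config, dict):
        config = ModelConfig(**config)
    lower = _lower_level()
    upper, link = _upper_level(config)
    deep = DeepModel(levels=[lower, upper], link=link)
    return TwentyQModel(deep=deep, lexicon=Lexicon(), config=config)


def policy_semantics(pid: int) -> tuple[str, Semiotics]:
    """The (question type, semiotics) targeted by policy ``pid``."""
    qt, n, adj, adv = list(
        itertools.product(range(3), range(2), range(2), range(2))
    )[pid]
    return QUESTION_TYPES[qt], Semiotics(SHAPES[n], COLOURS[adj], LOCATIONS[adv])
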