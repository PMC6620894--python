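"""Bayesian task construction, posterior computation, performance metrics and
answer-strategy classification.

The experimental task asks for the positive predictive value (PPV) of a
two-branch situation (hypothesis H, evidence E): given a base rate P(H), a
true-positive rate P(E|H) and a false-alarm rate P(E|!H), the correct answer
is P(H|E).  Tasks are presented either as natural-frequency trees scaled to a
fixed population or as branch-normalized percentage trees.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import DegenerateTaskError, InvalidAnswerError

__all__ = [
    "Format",
    "Strategy",
    "NODE_NAMES",
    "ProblemTree",
    "Answer",
    "PerformanceMetrics",
    "StrategyLabel",
    "posterior",
    "sequential_posterior",
    "build_frequency_tree",
    "build_probability_tree",
    "correctness",
    "log_relative_error",
    "log_experience_deviation",
    "classify_strategy",
    "performance_metrics",
]

#: The seven data nodes of the two-level tree, in display order.
NODE_NAMES = ("T", "F", "nF", "FA", "FnA", "nFA", "nFnA")

#: Default root population for frequency-format trees.
DEFAULT_POPULATION = 1000

#: Default strategy-matching tolerance: half a percentage point.
DEFAULT_STRATEGY_TOL = 0.005


class Format(str, enum.Enum):
    FREQUENCY = "frequency"
    PROBABILITY = "probability"


class Strategy(str, enum.Enum):
    CORRECT_PPV = "correct_ppv"
    SENSITIVITY_CONFUSION = "sensitivity_confusion"
    TOTAL_DENOMINATOR = "total_denominator"
    OTHER = "other"


def _check_probability(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be a probability in [0, 1], got {value!r}")
    return value


def posterior(base_rate: float, tpr: float, far: float) -> float:
    """Posterior P(H|E) (the PPV) by Bayes' theorem.

    Parameters
    ----------
    base_rate : prior probability P(H).
    tpr : true-positive rate P(E|H).
    far : false-alarm rate P(E|!H).

    Raises
    ------
    DegenerateTaskError
        If the evidence has zero total probability.
    """
    b = _check_probability("base_rate", base_rate)
    t = _check_probability("tpr", tpr)
    f = _check_probability("far", far)
    denom = t * b + f * (1.0 - b)
    if denom <= 0.0:
        raise DegenerateTaskError(
            "no positive-evidence mass: tpr*base + far*(1-base) == 0"
        )
    return (t * b) / denom


def sequential_posterior(
    prior: float,
    p_evidence_given_h: float,
    p_evidence_given_noth: float,
    draws: Sequence[int],
) -> float:
    """Posterior for H after a sequence of i.i.d. binary draws (with replacement).

    Each draw is 1 if the "evidence" outcome was observed (e.g. a red chip)
    and 0 otherwise.  The update is conjugate and therefore depends only on
    the outcome counts, never on their order.  An empty sequence returns the
    prior unchanged.
    """
    prior = _check_probability("prior", prior)
    ph = float(p_evidence_given_h)
    pn = float(p_evidence_given_noth)
    for name, v in (("p_evidence_given_h", ph), ("p_evidence_given_noth", pn)):
        if not 0.0 < v < 1.0:
            raise ValueError(f"{name} must lie strictly inside (0, 1), got {v!r}")
    k = 0
    n = 0
    for d in draws:
        if d not in (0, 1, True, False):
            raise ValueError(f"draws must be binary, got {d!r}")
        k += int(d)
        n += 1
    if n == 0:
        return prior
    if prior == 0.0:
        return 0.0
    if prior == 1.0:
        return 1.0
    # Work in log-odds for numerical stability with long sequences.
    log_odds = (
        math.log(prior) - math.log1p(-prior)
        + k * (math.log(ph) - math.log(pn))
        + (n - k) * (math.log1p(-ph) - math.log1p(-pn))
    )
    return 1.0 / (1.0 + math.exp(-log_odds))


@dataclass(frozen=True)
class ProblemTree:
    """One Bayesian task instance with its seven materialised node values.

    Frequency-format trees hold integer event counts that nest exactly
    (children sum to their parent); probability-format trees hold branch
    percentages where every split sums to 100.
    """

    base_rate: float
    true_positive_rate: float
    false_alarm_rate: float
    format: Format
    population: float
    nodes: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(NODE_NAMES) - set(self.nodes)
        if missing:
            raise ValueError(f"missing tree nodes: {sorted(missing)}")
        for name in NODE_NAMES:
            if self.nodes[name] < 0:
                raise ValueError(f"negative node value for {name}")
        n = self.nodes
        if self.format is Format.FREQUENCY:
            if (
                n["F"] + n["nF"] != n["T"]
                or n["FA"] + n["FnA"] != n["F"]
                or n["nFA"] + n["nFnA"] != n["nF"]
            ):
                raise ValueError("frequency tree children must sum to their parent")
        else:
            for a, b in (("F", "nF"), ("FA", "FnA"), ("nFA", "nFnA")):
                if abs(n[a] + n[b] - 100.0) > 1e-9:
                    raise ValueError(f"split {a}/{b} must sum to 100%")

    def true_posterior(self) -> float:
        """Exact PPV implied by the task rates."""
        return posterior(self.base_rate, self.true_positive_rate, self.false_alarm_rate)

    def node_posterior(self) -> float:
        """PPV read off the materialised node values (frequency trees only).

        Differs from :meth:`true_posterior` by at most the rounding error
        introduced when scaling to an integer population.
        """
        if self.format is not Format.FREQUENCY:
            return self.true_posterior()
        fa, nfa = self.nodes["FA"], self.nodes["nFA"]
        if fa + nfa == 0:
            raise DegenerateTaskError("no evidence events in the tree")
        return fa / (fa + nfa)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def build_frequency_tree(
    base: float, tpr: float, far: float, population: int = DEFAULT_POPULATION
) -> ProblemTree:
    """Scale a (base, tpr, far) triple to integer event counts.

    The first child at each split is rounded half-up to the nearest integer
    and the residual is assigned to the complement, so children always sum to
    their parent exactly.
    """
    b = _check_probability("base", base)
    t = _check_probability("tpr", tpr)
    f = _check_probability("far", far)
    population = int(population)
    if population < 1:
        raise ValueError("population must be >= 1")
    total = population
    fire = _round_half_up(b * total)
    no_fire = total - fire
    fa = _round_half_up(t * fire)
    fna = fire - fa
    nfa = _round_half_up(f * no_fire)
    nfna = no_fire - nfa
    nodes = {
        "T": total,
        "F": fire,
        "nF": no_fire,
        "FA": fa,
        "FnA": fna,
        "nFA": nfa,
        "nFnA": nfna,
    }
    return ProblemTree(b, t, f, Format.FREQUENCY, population, nodes)


def build_probability_tree(base: float, tpr: float, far: float) -> ProblemTree:
    """Build a branch-normalized percentage tree (every split sums to 100%)."""
    b = _check_probability("base", base)
    t = _check_probability("tpr", tpr)
    f = _check_probability("far", far)
    nodes = {
        "T": 100.0,
        "F": 100.0 * b,
        "nF": 100.0 * (1.0 - b),
        "FA": 100.0 * t,
        "FnA": 100.0 * (1.0 - t),
        "nFA": 100.0 * f,
        "nFnA": 100.0 * (1.0 - f),
    }
    return ProblemTree(b, t, f, Format.PROBABILITY, 100.0, nodes)


@dataclass(frozen=True)
class Answer:
    """A participant's answer as a proportion.

    Frequency-format answers are entered as ``numerator`` out of
    ``denominator`` events; probability-format answers are percentages,
    stored with denominator 100.  The web task enforced
    numerator <= denominator, and we do the same.
    """

    numerator: float
    denominator: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.numerator) and math.isfinite(self.denominator)):
            raise InvalidAnswerError("answer values must be finite")
        if self.denominator <= 0:
            raise InvalidAnswerError("denominator must be positive")
        if self.numerator < 0:
            raise InvalidAnswerError("numerator must be non-negative")
        if self.numerator > self.denominator:
            raise InvalidAnswerError("numerator cannot exceed denominator")

    @classmethod
    def from_percentage(cls, pct: float) -> "Answer":
        return cls(float(pct), 100.0)

    @property
    def as_probability(self) -> float:
        return self.numerator / self.denominator


def correctness(answer: Answer, tree: ProblemTree) -> bool:
    """Strict-rounding correctness.

    The answer (in percent) is correct iff it lies inside
    ``[floor(t), ceil(t)]`` where ``t`` is the true posterior in percent —
    i.e. it matches the true value rounded either up or down to a full
    percentage point.
    """
    t_pct = tree.true_posterior() * 100.0
    a_pct = answer.as_probability * 100.0
    # tiny tolerance so e.g. 55/100 scaled back to percent stays inside [.., 55]
    return math.floor(t_pct) - 1e-9 <= a_pct <= math.ceil(t_pct) + 1e-9


def log_relative_error(pe: float, pt: float, *, floor: float | None = None) -> float:
    """log10(Pe / Pt): positive means overestimation, negative underestimation.

    ``pe`` may be zero only when ``floor`` is supplied, in which case the
    floor is substituted (callers are expected to flag such records).
    """
    pt = float(pt)
    pe = float(pe)
    if not pt > 0:
        raise ValueError("true posterior must be positive")
    if pe <= 0:
        if floor is None:
            raise ValueError("estimated posterior is zero and no floor was given")
        pe = float(floor)
    return math.log10(pe / pt)


def log_experience_deviation(ps: float, pt: float, *, floor: float | None = None) -> float:
    """log10(Ps / Pt) with Ps the subjective posterior from the reported triple."""
    return log_relative_error(ps, pt, floor=floor)


@dataclass(frozen=True)
class StrategyLabel:
    label: Strategy
    tolerance: float


def classify_strategy(
    answer: Answer, tree: ProblemTree, tol: float = DEFAULT_STRATEGY_TOL
) -> StrategyLabel:
    """Classify an answer into one of four mutually exclusive strategies.

    Priority order: strict-rounding correct (``correct_ppv``), then answers
    matching the true-positive rate within ``tol`` (``sensitivity_confusion``),
    then frequency-format answers whose stated denominator is the whole tree
    population (``total_denominator``), else ``other``.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    if correctness(answer, tree):
        label = Strategy.CORRECT_PPV
    elif abs(answer.as_probability - tree.true_positive_rate) <= tol:
        label = Strategy.SENSITIVITY_CONFUSION
    elif (
        tree.format is Format.FREQUENCY
        and answer.denominator == tree.population
    ):
        label = Strategy.TOTAL_DENOMINATOR
    else:
        label = Strategy.OTHER
    return StrategyLabel(label, tol)


@dataclass(frozen=True)
class PerformanceMetrics:
    """Per-participant performance summary.

    ``floored`` records whether a zero estimated/subjective posterior was
    replaced by the 1/(10*population) floor before taking logs.
    """

    true_posterior: float
    estimated_posterior: float
    subjective_posterior: float | None
    correct: bool
    log_relative_error: float
    log_experience_deviation: float | None
    floored: bool = False
    strategy: StrategyLabel | None = None


def performance_metrics(
    answer: Answer,
    tree: ProblemTree,
    reported_triple: tuple[float, float, float] | None = None,
    *,
    strategy_tol: float = DEFAULT_STRATEGY_TOL,
) -> PerformanceMetrics:
    """Compute all performance metrics for one participant.

    ``reported_triple`` is the participant's own (base, tpr, far) estimate
    from the initial survey; when given, the subjective posterior Ps and the
    log-experience-deviation are computed from it.
    """
    pt = tree.true_posterior()
    pe = answer.as_probability
    floor = 1.0 / (10.0 * tree.population)
    floored = pe <= 0
    lre = log_relative_error(pe, pt, floor=floor)
    ps = None
    led = None
    if reported_triple is not None:
        ps = posterior(*reported_triple)
        floored = floored or ps <= 0
        led = log_experience_deviation(ps, pt, floor=floor)
    return PerformanceMetrics(
        true_posterior=pt,
        estimated_posterior=pe,
        subjective_posterior=ps,
        correct=correctness(answer, tree),
        log_relative_error=lre,
        log_experience_deviation=led,
        floored=floored,
        strategy=classify_strategy(answer, tree, strategy_tol),
    )
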