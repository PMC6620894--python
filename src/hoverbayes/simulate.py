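"""Synthetic cohort generator.

Produces participant tables and hover-event logs with the statistical
structure the analysis pipeline assumes: two information formats, reported
probability triples drawn from Beta priors, answers drawn from a mixture of
named strategies, and hover sequences generated by condition-specific
first-order Markov chains over the 8 AOIs with per-AOI log-normal dwell
durations.  Everything is reproducible from a single seed via a
counter-based (Philox) generator.

This is a data-shape emulator for testing the pipeline, not a cognitive
model, and it makes no claim to match any real cohort's distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .bayes import (
    Answer,
    Format,
    Strategy,
    build_frequency_tree,
    build_probability_tree,
    posterior,
)
from .errors import ConfigError
from .interaction import AOIS, HoverEvent, HoverSequence, TRANSITION_PAIRS

__all__ = [
    "CohortConfig",
    "generate_cohort",
    "markov_sequence",
    "uniform_matrix",
    "biased_matrix",
    "pair_distribution",
    "calibrate_pair_hellinger",
    "default_condition_matrices",
]

_N_AOI = len(AOIS)
_AOI_INDEX = {a: i for i, a in enumerate(AOIS)}


# ---------------------------------------------------------------------------
# Markov-chain helpers
# ---------------------------------------------------------------------------

def uniform_matrix() -> np.ndarray:
    """8x8 row-stochastic matrix, uniform over the 7 other AOIs, zero diagonal."""
    m = np.full((_N_AOI, _N_AOI), 1.0 / (_N_AOI - 1))
    np.fill_diagonal(m, 0.0)
    return m


def _validate_matrix(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.shape != (_N_AOI, _N_AOI):
        raise ConfigError(f"Markov matrix must be {_N_AOI}x{_N_AOI}")
    if np.any(np.diag(m) != 0):
        raise ConfigError("Markov matrix must have a zero diagonal")
    if np.any(m < 0) or not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
        raise ConfigError("Markov matrix rows must be non-negative and sum to 1")
    return m


def biased_matrix(
    boosts: Mapping[tuple[str, str], float], base: np.ndarray | None = None
) -> np.ndarray:
    """Multiply selected transitions of ``base`` (default: uniform) by the
    given factors, then renormalize each row."""
    m = uniform_matrix() if base is None else np.asarray(base, dtype=float).copy()
    for (a, b), factor in boosts.items():
        if a == b:
            raise ConfigError("cannot boost a self-transition")
        m[_AOI_INDEX[a], _AOI_INDEX[b]] *= float(factor)
    m /= m.sum(axis=1, keepdims=True)
    return _validate_matrix(m)


def stationary_distribution(matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution of an (assumed ergodic) chain."""
    m = _validate_matrix(matrix)
    vals, vecs = np.linalg.eig(m.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def pair_distribution(matrix: np.ndarray) -> dict[tuple[str, str], float]:
    """Long-run distribution over the 56 ordered AOI pairs:
    P(pair (a,b)) = pi_a * M[a,b].  Empirical bigram frequencies of long
    sequences converge to this."""
    m = _validate_matrix(matrix)
    pi = stationary_distribution(m)
    joint = pi[:, None] * m
    joint /= joint.sum()
    return {
        (a, b): float(joint[_AOI_INDEX[a], _AOI_INDEX[b]])
        for a, b in TRANSITION_PAIRS
    }


def calibrate_pair_hellinger(
    base: np.ndarray,
    perturbed: np.ndarray,
    target_hd: float,
    *,
    tol: float = 1e-4,
) -> np.ndarray:
    """Mix ``perturbed`` into ``base`` so that the Hellinger distance between
    the two chains' theoretical pair distributions equals ``target_hd``.

    Bisection on the mixing weight; raises ConfigError if the full
    perturbation cannot reach the target.
    """
    from .group_stats import hellinger

    base = _validate_matrix(base)
    perturbed = _validate_matrix(perturbed)
    ref = pair_distribution(base)

    def hd_at(t: float) -> float:
        mixed = (1.0 - t) * base + t * perturbed
        return hellinger(ref, pair_distribution(mixed))

    if hd_at(1.0) < target_hd:
        raise ConfigError(
            f"perturbation too weak: max attainable Hd={hd_at(1.0):.4f} "
            f"< target {target_hd:.4f}"
        )
    lo, hi = 0.0, 1.0
    while hi - lo > 1e-6:
        mid = 0.5 * (lo + hi)
        if hd_at(mid) < target_hd:
            lo = mid
        else:
            hi = mid
        if abs(hd_at(mid) - target_hd) < tol:
            return _validate_matrix((1.0 - mid) * base + mid * perturbed)
    mid = 0.5 * (lo + hi)
    return _validate_matrix((1.0 - mid) * base + mid * perturbed)


def default_condition_matrices() -> dict[str, np.ndarray]:
    """Per-format default chains.

    The frequency-format chain is biased toward leftward moves to the total
    node T; the probability-format chain is biased toward question checks.
    These defaults merely plant a detectable between-format difference.
    """
    freq = biased_matrix({("F", "T"): 3.0, ("nF", "T"): 3.0, ("FA", "T"): 2.0})
    prob = biased_matrix({("Q", "T"): 3.0, ("nF", "Q"): 3.0, ("T", "Q"): 2.0})
    return {"frequency": freq, "probability": prob}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_DEFAULT_MIXTURES = {
    "frequency": {
        Strategy.CORRECT_PPV: 0.39,
        Strategy.SENSITIVITY_CONFUSION: 0.10,
        Strategy.TOTAL_DENOMINATOR: 0.45,
        Strategy.OTHER: 0.06,
    },
    "probability": {
        Strategy.CORRECT_PPV: 0.14,
        Strategy.SENSITIVITY_CONFUSION: 0.60,
        Strategy.OTHER: 0.26,
    },
}

#: Beta(a, b) priors for the reported triple; means near (0.1, 0.5, 0.27).
_DEFAULT_TRIPLE_PRIORS = {
    "base": (2.0, 18.0),
    "tpr": (5.0, 5.0),
    "far": (2.7, 7.3),
}


@dataclass(frozen=True)
class CohortConfig:
    """Configuration for one synthetic cohort (both formats)."""

    n_per_cell: int = 75
    study: str = "experience_matched"  # or "fixed_values"
    fixed_triple: tuple[float, float, float] = (0.1, 0.5, 0.27)
    triple_priors: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_TRIPLE_PRIORS)
    )
    strategy_mixture: Mapping[str, Mapping] = field(
        default_factory=lambda: {
            fmt: dict(mix) for fmt, mix in _DEFAULT_MIXTURES.items()
        }
    )
    markov_matrices: Mapping[str, np.ndarray] | None = None
    dwell_model: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {a: (6.5, 0.6) for a in AOIS}  # log-ms
    )
    stop_param: float = 0.05
    population: int = 1000
    force_question_visit: bool = True
    adblocker_active_rate: float = 0.0
    seed: int = 0

    def validated(self) -> "CohortConfig":
        if self.n_per_cell < 1:
            raise ConfigError("n_per_cell must be >= 1")
        if self.study not in ("experience_matched", "fixed_values"):
            raise ConfigError(f"unknown study mode {self.study!r}")
        if not 0.0 < self.stop_param <= 1.0:
            raise ConfigError("stop_param must lie in (0, 1]")
        matrices = self.markov_matrices
        if matrices is None:
            matrices = default_condition_matrices()
        matrices = {
            fmt: _validate_matrix(np.asarray(m, dtype=float))
            for fmt, m in matrices.items()
        }
        for fmt in ("frequency", "probability"):
            if fmt not in matrices:
                raise ConfigError(f"missing Markov matrix for format {fmt!r}")
            mix = {
                Strategy(k): float(v)
                for k, v in self.strategy_mixture[fmt].items()
            }
            if abs(sum(mix.values()) - 1.0) > 1e-9 or any(v < 0 for v in mix.values()):
                raise ConfigError(f"strategy mixture for {fmt!r} must sum to 1")
            if fmt == "probability" and mix.get(Strategy.TOTAL_DENOMINATOR, 0.0) > 0:
                raise ConfigError(
                    "total_denominator strategy is undefined for the probability format"
                )
            self.strategy_mixture[fmt]  # noqa: B018 — keyerror above if absent
        for q in ("base", "tpr", "far"):
            a, b = self.triple_priors[q]
            if a <= 0 or b <= 0:
                raise ConfigError(f"Beta parameters for {q!r} must be positive")
        for a in AOIS:
            mu, sigma = self.dwell_model[a]
            if sigma <= 0:
                raise ConfigError(f"dwell sigma for {a!r} must be positive")
        return replace(self, markov_matrices=matrices)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        cfg = self.validated()
        return {
            "n_per_cell": cfg.n_per_cell,
            "study": cfg.study,
            "fixed_triple": list(cfg.fixed_triple),
            "triple_priors": {k: list(v) for k, v in cfg.triple_priors.items()},
            "strategy_mixture": {
                fmt: {Strategy(k).value: float(v) for k, v in mix.items()}
                for fmt, mix in cfg.strategy_mixture.items()
            },
            "markov_matrices": {
                fmt: np.asarray(m).tolist() for fmt, m in cfg.markov_matrices.items()
            },
            "dwell_model": {k: list(v) for k, v in cfg.dwell_model.items()},
            "stop_param": cfg.stop_param,
            "population": cfg.population,
            "force_question_visit": cfg.force_question_visit,
            "adblocker_active_rate": cfg.adblocker_active_rate,
            "seed": cfg.seed,
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "CohortConfig":
        kwargs = dict(payload)
        if "fixed_triple" in kwargs:
            kwargs["fixed_triple"] = tuple(kwargs["fixed_triple"])
        if "triple_priors" in kwargs:
            kwargs["triple_priors"] = {
                k: tuple(v) for k, v in kwargs["triple_priors"].items()
            }
        if "dwell_model" in kwargs:
            kwargs["dwell_model"] = {
                k: tuple(v) for k, v in kwargs["dwell_model"].items()
            }
        if kwargs.get("markov_matrices") is not None:
            kwargs["markov_matrices"] = {
                fmt: np.asarray(m, dtype=float)
                for fmt, m in kwargs["markov_matrices"].items()
            }
        try:
            cfg = cls(**kwargs)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        return cfg.validated()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Sequence generation
# ---------------------------------------------------------------------------

def markov_sequence(
    matrix: np.ndarray,
    start_dist: np.ndarray | None,
    stop_param: float,
    dwell_model: Mapping[str, tuple[float, float]],
    rng: np.random.Generator,
    participant_id: str = "sim",
    *,
    gap_ms: int = 50,
) -> HoverSequence:
    """Simulate one hover sequence from a first-order chain.

    The visit count is 1 + G with G ~ Geometric(stop_param), so sequences
    always contain at least two visits and have expected length
    1/stop_param + 1.  Dwell durations are log-normal per AOI (parameters in
    log-milliseconds); consecutive hovers are separated by ``gap_ms``.
    """
    m = _validate_matrix(matrix)
    if start_dist is None:
        start = stationary_distribution(m)
    else:
        start = np.asarray(start_dist, dtype=float)
        if start.shape != (_N_AOI,) or np.any(start < 0) or abs(start.sum() - 1.0) > 1e-9:
            raise ConfigError("start_dist must be a distribution over the 8 AOIs")
    if not 0.0 < stop_param <= 1.0:
        raise ConfigError("stop_param must lie in (0, 1]")
    length = 1 + int(rng.geometric(stop_param))
    states = np.empty(length, dtype=int)
    # inverse-CDF stepping: one uniform per visit, cheap even for 1e5 steps
    cum = np.cumsum(m, axis=1)
    u = rng.random(length)
    states[0] = min(_N_AOI - 1, int(np.searchsorted(np.cumsum(start), u[0], side="right")))
    for i in range(1, length):
        states[i] = min(
            _N_AOI - 1, int(np.searchsorted(cum[states[i - 1]], u[i], side="right"))
        )
    return _events_from_states(states, dwell_model, rng, participant_id, gap_ms)


def _events_from_states(
    states: np.ndarray,
    dwell_model: Mapping[str, tuple[float, float]],
    rng: np.random.Generator,
    participant_id: str,
    gap_ms: int,
) -> HoverSequence:
    mus = np.array([dwell_model[a][0] for a in AOIS])
    sigmas = np.array([dwell_model[a][1] for a in AOIS])
    durations = np.maximum(
        1, rng.lognormal(mus[states], sigmas[states]).astype(int)
    )
    events = []
    clock = 0
    for s, d in zip(states, durations):
        events.append(
            HoverEvent(participant_id, AOIS[int(s)], int(clock), int(clock + d))
        )
        clock += int(d) + gap_ms
    return HoverSequence(participant_id, tuple(events))


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _draw_triple(
    cfg: CohortConfig, rng: np.random.Generator
) -> tuple[tuple[int, int], tuple[int, int], tuple[int, int]]:
    """Draw a reported (base, tpr, far) triple and express each value as an
    integer numerator over 100 (the survey collected coarse fractions)."""
    out = []
    for q, lo in (("base", 1), ("tpr", 1), ("far", 0)):
        a, b = cfg.triple_priors[q]
        p = rng.beta(a, b)
        num = int(np.clip(round(p * 100), lo, 99))
        out.append((num, 100))
    return tuple(out)


def _answer_for_strategy(
    strategy: Strategy,
    fmt: Format,
    tree,
    tpr_frac: tuple[int, int],
    rng: np.random.Generator,
    population: int,
) -> tuple[float, float]:
    """(numerator, denominator) of the answer implied by a strategy."""
    ppv = tree.true_posterior()
    if fmt is Format.FREQUENCY:
        if strategy is Strategy.CORRECT_PPV:
            return (round(ppv * population), population)
        if strategy is Strategy.SENSITIVITY_CONFUSION:
            return (float(tpr_frac[0]), float(tpr_frac[1]))
        if strategy is Strategy.TOTAL_DENOMINATOR:
            return (float(tree.nodes["FA"]), float(population))
        return (float(rng.integers(0, population + 1)), float(population))
    if strategy is Strategy.CORRECT_PPV:
        return (ppv * 100.0, 100.0)
    if strategy is Strategy.SENSITIVITY_CONFUSION:
        return (100.0 * tpr_frac[0] / tpr_frac[1], 100.0)
    return (float(np.round(rng.uniform(0.0, 100.0), 1)), 100.0)


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (participant table, hover-event log) for one cohort.

    The participant table carries the reported triple as numerator/denominator
    pairs, the answer, a numeracy score, the ad-blocker flag and the true
    strategy label (kept for recovery tests).  The event log has one hover
    per row.  Identical configs and seeds yield identical frames.
    """
    cfg = config.validated()
    rng = np.random.Generator(np.random.Philox(int(cfg.seed)))
    participants = []
    events = []
    pid_counter = 0
    for fmt_name in ("frequency", "probability"):
        fmt = Format(fmt_name)
        matrix = cfg.markov_matrices[fmt_name]
        mix = {Strategy(k): float(v) for k, v in cfg.strategy_mixture[fmt_name].items()}
        # canonical enum order: generation must not depend on dict ordering
        strategies = [s for s in Strategy if s in mix]
        probs = np.array([mix[s] for s in strategies])
        for _ in range(cfg.n_per_cell):
            pid_counter += 1
            pid = f"p{pid_counter:04d}"
            base_f, tpr_f, far_f = _draw_triple(cfg, rng)
            if cfg.study == "experience_matched":
                triple = (base_f[0] / base_f[1], tpr_f[0] / tpr_f[1], far_f[0] / far_f[1])
            else:
                triple = cfg.fixed_triple
            if fmt is Format.FREQUENCY:
                tree = build_frequency_tree(*triple, population=cfg.population)
            else:
                tree = build_probability_tree(*triple)
            if cfg.study == "experience_matched":
                # In experience-matched mode the tree IS the reported triple,
                # so the sensitivity answer must use the tree's tpr.
                tpr_for_answer = (tree.true_positive_rate * 100, 100)
            else:
                tpr_for_answer = (cfg.fixed_triple[1] * 100, 100)
            strategy = strategies[int(rng.choice(len(strategies), p=probs))]
            ans_num, ans_den = _answer_for_strategy(
                strategy, fmt, tree, tpr_for_answer, rng, cfg.population
            )
            numeracy = float(np.clip(rng.normal(4.0, 0.6), 1.0, 6.0))
            adblocker_disabled = bool(rng.random() >= cfg.adblocker_active_rate)
            seq = markov_sequence(
                matrix, None, cfg.stop_param, cfg.dwell_model, rng, pid
            )
            if cfg.force_question_visit and "Q" not in {e.aoi for e in seq.events}:
                q_dur = max(1, int(rng.lognormal(*cfg.dwell_model["Q"])))
                shifted = [
                    HoverEvent(pid, e.aoi, e.enter_ms + q_dur + 50, e.exit_ms + q_dur + 50)
                    for e in seq.events
                ]
                seq = HoverSequence(pid, (HoverEvent(pid, "Q", 0, q_dur), *shifted))
            participants.append(
                {
                    "participant_id": pid,
                    "study": cfg.study,
                    "format": fmt_name,
                    "base_num": base_f[0],
                    "base_den": base_f[1],
                    "tpr_num": tpr_f[0],
                    "tpr_den": tpr_f[1],
                    "far_num": far_f[0],
                    "far_den": far_f[1],
                    "answer_num": ans_num,
                    "answer_den": ans_den,
                    "numeracy": round(numeracy, 3),
                    "adblocker_disabled": adblocker_disabled,
                    "strategy": strategy.value,
                }
            )
            for ev in seq.events:
                events.append(
                    {
                        "participant_id": pid,
                        "aoi": ev.aoi,
                        "enter_ms": ev.enter_ms,
                        "exit_ms": ev.exit_ms,
                    }
                )
    return pd.DataFrame(participants), pd.DataFrame(events)
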