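"""Group-level inference on transition distributions and performance records.

Implements the Hellinger-distance resampling test between two groups of
participant transition tables, odds-ratio screening of discriminative
transitions, chi-squared association tests with Cramér's V, and the two
reporting regressions (logistic correctness model, linear log-error model).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .errors import (
    ConstantResponseError,
    DegenerateTableError,
    EmptyGroupError,
    NormalizationError,
)
from .interaction import TRANSITION_PAIRS, TransitionTable, pool_group

__all__ = [
    "ComparisonResult",
    "ORScreenResult",
    "AssociationResult",
    "RegressionResult",
    "hellinger",
    "permutation_test",
    "transition_odds_ratio",
    "screen_discriminative",
    "chi_squared_association",
    "fit_correctness_model",
    "fit_error_model",
]

_Z95 = scipy.stats.norm.ppf(0.975)

#: Default "large F" threshold for discriminative transitions.
DEFAULT_MIN_FREQUENCY = 30


def _as_distribution(p) -> np.ndarray:
    if isinstance(p, TransitionTable):
        p = p.normalized()
    if isinstance(p, Mapping):
        keys = set(p)
        if keys == set(TRANSITION_PAIRS):
            p = np.array([p[k] for k in TRANSITION_PAIRS], dtype=float)
        else:
            p = np.array([p[k] for k in sorted(p)], dtype=float)
    else:
        p = np.asarray(p, dtype=float)
    return p


def hellinger(p, q) -> float:
    """Hellinger distance (1/sqrt2)*||sqrt(p)-sqrt(q)||_2 between two
    discrete distributions over the same support.

    Accepts arrays, mappings keyed by transition pair, or TransitionTables
    (which are normalized first).  Raises NormalizationError if either input
    does not sum to 1.
    """
    pa, qa = _as_distribution(p), _as_distribution(q)
    if pa.shape != qa.shape:
        raise ValueError("distributions must share a support")
    for name, arr in (("p", pa), ("q", qa)):
        if np.any(arr < 0) or abs(arr.sum() - 1.0) > 1e-6:
            raise NormalizationError(f"{name} is not a normalized distribution")
    return float(np.sqrt(0.5) * np.linalg.norm(np.sqrt(pa) - np.sqrt(qa)))


def _hellinger_rows(pa: np.ndarray, qa: np.ndarray) -> np.ndarray:
    """Row-wise Hellinger distance for (n, k) stacked distributions."""
    return np.sqrt(0.5 * ((np.sqrt(pa) - np.sqrt(qa)) ** 2).sum(axis=1))


@dataclass(frozen=True)
class ComparisonResult:
    hd_observed: float
    p_value: float
    n_permutations: int
    resample_mode: str
    seed: int
    group_sizes: tuple[int, int]
    n_redraws: int = 0

    def to_dict(self) -> dict:
        return {
            "hd_observed": self.hd_observed,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "resample_mode": self.resample_mode,
            "seed": self.seed,
            "group_sizes": list(self.group_sizes),
            "n_redraws": self.n_redraws,
        }


def _rng(seed: int) -> np.random.Generator:
    # Philox is counter-based: identical streams for a given seed on any platform.
    return np.random.Generator(np.random.Philox(int(seed)))


def permutation_test(
    group_a: Sequence[TransitionTable],
    group_b: Sequence[TransitionTable],
    n_perm: int = 10_000,
    seed: int = 0,
    mode: str = "with_replacement",
    *,
    chunk_size: int = 2048,
) -> ComparisonResult:
    """Compare two groups' pooled transition distributions by resampling.

    The observed statistic is the Hellinger distance between the two pooled,
    group-normalized distributions.  Null replicates rebuild pseudo-groups of
    the same sizes from the combined participant pool, either sampling
    participants with replacement (``mode='with_replacement'``) or permuting
    group labels without replacement (``mode='label_permutation'``).  The
    p-value uses the add-one estimator (1 + #{null >= observed}) / (n_perm+1).
    Replicates in which a pseudo-group has zero transitions are redrawn.
    """
    if not group_a or not group_b:
        raise EmptyGroupError("both groups must be non-empty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mode not in ("with_replacement", "label_permutation"):
        raise ValueError(f"unknown resample mode {mode!r}")

    counts_a = np.stack([t.as_array() for t in group_a])
    counts_b = np.stack([t.as_array() for t in group_b])
    n_a, n_b = len(group_a), len(group_b)
    pooled_a = counts_a.sum(axis=0)
    pooled_b = counts_b.sum(axis=0)
    if pooled_a.sum() == 0 or pooled_b.sum() == 0:
        raise EmptyGroupError("a group has zero total transitions")
    observed = hellinger(pooled_a / pooled_a.sum(), pooled_b / pooled_b.sum())

    combined = np.concatenate([counts_a, counts_b])
    n_tot = n_a + n_b
    rng = _rng(seed)
    n_exceed = 0
    n_redraws = 0
    done = 0
    while done < n_perm:
        m = min(chunk_size, n_perm - done)
        if mode == "with_replacement":
            idx_a = rng.integers(0, n_tot, size=(m, n_a))
            idx_b = rng.integers(0, n_tot, size=(m, n_b))
        else:
            perms = rng.permuted(
                np.broadcast_to(np.arange(n_tot), (m, n_tot)).copy(), axis=1
            )
            idx_a, idx_b = perms[:, :n_a], perms[:, n_a:]
        sums_a = combined[idx_a].sum(axis=1)
        sums_b = combined[idx_b].sum(axis=1)
        tot_a = sums_a.sum(axis=1)
        tot_b = sums_b.sum(axis=1)
        bad = (tot_a == 0) | (tot_b == 0)
        if bad.any():  # redraw degenerate replicates next pass
            n_redraws += int(bad.sum())
            keep = ~bad
            sums_a, sums_b = sums_a[keep], sums_b[keep]
            tot_a, tot_b = tot_a[keep], tot_b[keep]
        if len(tot_a):
            dists = _hellinger_rows(
                sums_a / tot_a[:, None], sums_b / tot_b[:, None]
            )
            n_exceed += int((dists >= observed - 1e-15).sum())
            done += len(dists)
    p_value = (1.0 + n_exceed) / (n_perm + 1.0)
    return ComparisonResult(
        hd_observed=observed,
        p_value=p_value,
        n_permutations=n_perm,
        resample_mode=mode,
        seed=int(seed),
        group_sizes=(n_a, n_b),
        n_redraws=n_redraws,
    )


@dataclass(frozen=True)
class ORScreenResult:
    transition: tuple[str, str]
    odds_ratio: float
    ci_low: float
    ci_high: float
    max_frequency: int
    discriminative: bool
    count_a: int = 0
    count_b: int = 0

    def to_dict(self) -> dict:
        return {
            "transition": f"{self.transition[0]}->{self.transition[1]}",
            "odds_ratio": self.odds_ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "max_frequency": self.max_frequency,
            "discriminative": self.discriminative,
            "count_a": self.count_a,
            "count_b": self.count_b,
        }


def transition_odds_ratio(
    count_a: int, total_a: int, count_b: int, total_b: int
) -> tuple[float, float, float]:
    """Odds ratio (p/(1-p)) / (q/(1-q)) for one transition's relative
    frequencies p = count_a/total_a and q = count_b/total_b, with a 95% Wald
    CI on the log scale from the 2x2 table {count, total-count}.

    The Haldane–Anscombe +0.5 correction is applied to every cell whenever
    any cell is zero.
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("totals must be positive")
    if not (0 <= count_a <= total_a and 0 <= count_b <= total_b):
        raise ValueError("counts must lie in [0, total]")
    a, b = float(count_a), float(total_a - count_a)
    c, d = float(count_b), float(total_b - count_b)
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_value = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_value)
    return (
        or_value,
        math.exp(log_or - _Z95 * se),
        math.exp(log_or + _Z95 * se),
    )


def screen_discriminative(
    table_a: TransitionTable,
    table_b: TransitionTable,
    min_frequency: int = DEFAULT_MIN_FREQUENCY,
) -> list[ORScreenResult]:
    """Screen all 56 transitions for discriminative ones.

    A transition is discriminative when its 95% CI excludes 1 and its maximum
    raw frequency across the two groups is at least ``min_frequency``.
    Results are sorted by |log OR| descending.
    """
    for t in (table_a, table_b):
        if t.scope != "group":
            raise ValueError("screen_discriminative expects group-scope tables")
    total_a, total_b = table_a.total, table_b.total
    if total_a == 0 or total_b == 0:
        raise EmptyGroupError("a group table has zero total transitions")
    results = []
    for pair in TRANSITION_PAIRS:
        ca, cb = int(table_a.counts[pair]), int(table_b.counts[pair])
        or_value, lo, hi = transition_odds_ratio(ca, total_a, cb, total_b)
        f_max = max(ca, cb)
        disc = (lo > 1.0 or hi < 1.0) and f_max >= min_frequency
        results.append(
            ORScreenResult(pair, or_value, lo, hi, f_max, disc, ca, cb)
        )
    results.sort(key=lambda r: abs(math.log(r.odds_ratio)), reverse=True)
    return results


@dataclass(frozen=True)
class AssociationResult:
    chi_squared: float
    df: int
    p_raw: float
    p_adjusted: float
    cramers_v: float
    correction: str

    def to_dict(self) -> dict:
        return {
            "chi_squared": self.chi_squared,
            "df": self.df,
            "p_raw": self.p_raw,
            "p_adjusted": self.p_adjusted,
            "cramers_v": self.cramers_v,
            "correction": self.correction,
        }


def chi_squared_association(table, n_comparisons: int = 1) -> AssociationResult:
    """Pearson chi-squared test (no continuity correction) with a Bonferroni
    adjustment over ``n_comparisons`` tests and Cramér's V effect size."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or np.any(arr < 0):
        raise ValueError("table must be a 2-D array of non-negative counts")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise DegenerateTableError("contingency table has a zero marginal")
    chi2, p_raw, df, _ = scipy.stats.chi2_contingency(arr, correction=False)
    n = arr.sum()
    v = math.sqrt(chi2 / (n * min(arr.shape[0] - 1, arr.shape[1] - 1)))
    correction = "bonferroni" if n_comparisons > 1 else "none"
    return AssociationResult(
        chi_squared=float(chi2),
        df=int(df),
        p_raw=float(p_raw),
        p_adjusted=min(1.0, float(p_raw) * n_comparisons),
        cramers_v=float(v),
        correction=correction,
    )


@dataclass(frozen=True)
class RegressionResult:
    model: str  # "logistic_correctness" | "linear_log_error"
    scale: str  # "odds_ratio" | "model_scale"
    coefficients: Mapping[str, tuple[float, float, float]]
    n: int
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "scale": self.scale,
            "n": self.n,
            "flags": list(self.flags),
            "coefficients": {
                k: {"estimate": est, "ci_low": lo, "ci_high": hi}
                for k, (est, lo, hi) in self.coefficients.items()
            },
        }


def _design(records: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    """Build the design matrix with documented reference classes.

    Indicator coding: format_probability = 1 for the probability format
    (frequency is the reference), dgm_fixed = 1 for the fixed-values mode
    (experience-matched is the reference).
    """
    X = pd.DataFrame(index=records.index)
    X["intercept"] = 1.0
    for term in terms:
        if term == "format_probability":
            X[term] = (records["format"].astype(str) == "probability").astype(float)
        elif term == "dgm_fixed":
            X[term] = (records["study"].astype(str) == "fixed_values").astype(float)
        else:
            X[term] = records[term].astype(float)
    return X


def fit_correctness_model(records: pd.DataFrame) -> RegressionResult:
    """Logistic regression of correctness on format, data-generating mode and
    numeracy; coefficients reported as odds ratios with 95% CIs.

    Predictors with no variation in the data (e.g. a single-study cohort) are
    dropped and noted in ``flags``.  Perfect separation is flagged and CIs
    are reported as NaN.
    """
    y = records["correct"].astype(float)
    if y.nunique() < 2:
        raise ConstantResponseError("correctness has no variation; nothing to fit")
    terms = ["format_probability", "dgm_fixed", "numeracy"]
    X = _design(records, terms)
    flags = []
    for term in terms:
        if X[term].nunique() < 2:
            X = X.drop(columns=[term])
            flags.append(f"dropped_constant:{term}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            params = fit.params
            conf = fit.conf_int(alpha=0.05)
            separated = bool(
                np.any(~np.isfinite(fit.bse)) or np.any(np.abs(params) > 15)
            )
        except Exception:
            separated = True
            params = None
    coefficients = {}
    if params is None or separated:
        flags.append("perfect_separation")
        if params is None:
            params = pd.Series(np.nan, index=X.columns)
        for term in X.columns:
            coefficients[term] = (float(np.exp(params[term])), float("nan"), float("nan"))
    else:
        for term in X.columns:
            coefficients[term] = (
                float(np.exp(params[term])),
                float(np.exp(conf.loc[term, 0])),
                float(np.exp(conf.loc[term, 1])),
            )
    return RegressionResult(
        model="logistic_correctness",
        scale="odds_ratio",
        coefficients=coefficients,
        n=len(records),
        flags=tuple(flags),
    )


def fit_error_model(records: pd.DataFrame) -> RegressionResult:
    """OLS regression of log-relative-error on format and
    log-experience-deviation; model-scale coefficients with 95% CIs."""
    y = records["log_relative_error"].astype(float)
    if y.nunique() < 2:
        raise ConstantResponseError("log_relative_error has no variation")
    terms = ["format_probability", "log_experience_deviation"]
    X = _design(records, terms)
    flags = []
    for term in terms:
        if X[term].nunique() < 2:
            X = X.drop(columns=[term])
            flags.append(f"dropped_constant:{term}")
    fit = sm.OLS(y, X).fit()
    conf = fit.conf_int(alpha=0.05)
    coefficients = {
        term: (
            float(fit.params[term]),
            float(conf.loc[term, 0]),
            float(conf.loc[term, 1]),
        )
        for term in X.columns
    }
    return RegressionResult(
        model="linear_log_error",
        scale="model_scale",
        coefficients=coefficients,
        n=len(records),
        flags=tuple(flags),
    )
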