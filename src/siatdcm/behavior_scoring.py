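"""Implicit-association D-score computation and group-level signed-rank tests.

The task contrasts reaction times (RTs) on critical trials where the self is
pooled with death (``self_death``) against trials where the self is pooled
with life (``self_life``).  The D-score standardizes the condition difference
by the spread of all critical-trial RTs.  Sign convention: positive D means a
stronger self-death association, i.e. *faster* (smaller) self-death RTs, so

    D = (mean RT self_life - mean RT self_death) / SD(all critical RTs).

Group D-scores are compared to zero with a one-sample Wilcoxon signed-rank
test (exact enumeration for small samples, tie-corrected normal approximation
otherwise).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InsufficientDataError, SchemaError

__all__ = [
    "DScoreResult",
    "GroupTestResult",
    "compute_dscore",
    "score_cohort",
    "signed_rank_vs_zero",
]

CRITICAL_CONDITIONS = ("self_life", "self_death")

#: sample-size cutoff below which the exact permutation null is enumerated
EXACT_ENUMERATION_MAX_N = 12


@dataclass(frozen=True)
class DScoreResult:
    subject_id: str
    D: float
    mean_rt_self_death: float
    mean_rt_self_life: float
    sd_critical: float
    n_self_death: int
    n_self_life: int


@dataclass(frozen=True)
class GroupTestResult:
    z: float
    p: float
    mean: float
    sd: float
    n: int


def _critical_trials(table: pd.DataFrame, correct_only: bool) -> pd.DataFrame:
    required = {"block_type", "condition", "rt_ms"}
    missing = required - set(table.columns)
    if missing:
        raise SchemaError(f"behavior table missing columns: {sorted(missing)}")
    crit = table[table["block_type"] == "critical"]
    bad = ~crit["condition"].isin(CRITICAL_CONDITIONS)
    if bad.any():
        row = crit.index[bad][0]
        raise SchemaError(
            f"critical trial at row {row} has condition "
            f"{crit.loc[row, 'condition']!r}; expected one of {CRITICAL_CONDITIONS}"
        )
    if not np.all(np.isfinite(crit["rt_ms"])) or (crit["rt_ms"] <= 0).any():
        raise SchemaError("critical-trial RTs must be finite and positive")
    if correct_only and "correct" in crit.columns:
        crit = crit[crit["correct"].astype(bool)]
    return crit


def compute_dscore(table: pd.DataFrame, correct_only: bool = False) -> DScoreResult:
    """D-score for one subject's trial table.

    Error trials are retained by default; ``correct_only=True`` restricts the
    computation to correct responses.
    """
    crit = _critical_trials(table, correct_only)
    life = crit.loc[crit["condition"] == "self_life", "rt_ms"].to_numpy(float)
    death = crit.loc[crit["condition"] == "self_death", "rt_ms"].to_numpy(float)
    if life.size < 2 or death.size < 2:
        raise InsufficientDataError(
            f"need >=2 critical trials per condition "
            f"(got self_life={life.size}, self_death={death.size})"
        )
    sd = float(np.std(np.concatenate([life, death]), ddof=1))
    if sd <= 0:
        raise DegenerateInputError("zero SD across critical trials")
    subject = str(table["subject_id"].iloc[0]) if "subject_id" in table.columns else ""
    return DScoreResult(
        subject_id=subject,
        D=float((life.mean() - death.mean()) / sd),
        mean_rt_self_death=float(death.mean()),
        mean_rt_self_life=float(life.mean()),
        sd_critical=sd,
        n_self_death=int(death.size),
        n_self_life=int(life.size),
    )


def score_cohort(tables, correct_only: bool = False) -> pd.DataFrame:
    """Score a list of subject tables into a tidy per-subject frame."""
    rows = [vars(compute_dscore(t, correct_only)) for t in tables]
    return pd.DataFrame(rows)


def _signed_rank_statistic(values: np.ndarray):
    ranks = stats.rankdata(np.abs(values))
    w_plus = float(ranks[values > 0].sum())
    n = values.size
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    return w_plus, mu, var, ranks


def _exact_two_sided_p(ranks: np.ndarray, w_obs: float) -> float:
    """Two-sided p by enumerating all sign assignments of the ranked values."""
    n = ranks.size
    totals = np.array(
        [sum(r for r, s in zip(ranks, signs) if s) for signs in
         itertools.product((False, True), repeat=n)]
    )
    lo = np.mean(totals <= w_obs + 1e-12)
    hi = np.mean(totals >= w_obs - 1e-12)
    return float(min(1.0, 2.0 * min(lo, hi)))


def signed_rank_vs_zero(values) -> GroupTestResult:
    """One-sample Wilcoxon signed-rank test of a list of D-scores against zero.

    Exact zeros are dropped before ranking.  The Z statistic uses the normal
    approximation with average-rank tie correction (no continuity correction);
    the two-sided p-value is computed by exact enumeration for n <= 12 and
    from the normal approximation otherwise.
    """
    values = np.asarray(list(values), dtype=float)
    if values.size < 5:
        raise InsufficientDataError("signed-rank test requires n >= 5")
    nonzero = values[values != 0]
    if nonzero.size == 0:
        raise DegenerateInputError("all values are exactly zero; test undefined")
    w_plus, mu, var, ranks = _signed_rank_statistic(nonzero)
    if var <= 0:
        raise DegenerateInputError("zero variance in signed-rank null")
    z = (w_plus - mu) / np.sqrt(var)
    if nonzero.size <= EXACT_ENUMERATION_MAX_N:
        p = _exact_two_sided_p(ranks, w_plus)
    else:
        p = float(2.0 * stats.norm.sf(abs(z)))
    return GroupTestResult(
        z=float(z),
        p=p,
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)),
        n=int(values.size),
    )
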