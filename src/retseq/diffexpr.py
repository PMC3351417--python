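"""Differential expression: the two routes the pipeline compares.

* ``anova_de`` -- one-way fixed-effects ANOVA on log2(RPKM + 1) with a fold
  cutoff (default 1.5) and a p-value cutoff (default 0.05).
* ``sam_de`` -- SAM-style moderated difference statistic
  ``d_i = (mean1_i - mean2_i) / (s_i + s0)`` with pooled standard error
  ``s_i``, group-label permutations, and an FDR estimated as the median
  permutation false-call count over the observed call count at each
  threshold (default cutoffs: fold 1.5, FDR 25%).

Fold changes follow the directional convention of the published tables:
a magnitude >= 1 plus an up/down flag (e.g. "2.4 (down)"), with
``signed_log2 = +log2(ratio)`` for up and ``-log2(ratio)`` for down.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import ExpressionMatrix, SampleDesign, ValidationError
from .quantify import inverse_log_transform, log_transform

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DirectionalFold:
    """Fold magnitude (>= 1) plus direction, as the published tables print it."""

    feature_id: str
    ratio: float
    direction: str  # "up" or "down"

    @property
    def signed_log2(self) -> float:
        lg = math.log2(self.ratio)
        return lg if self.direction == "up" else -lg


@dataclass
class DEResult:
    """Per-feature differential-expression results for one route.

    ``table`` columns: ``ratio``, ``direction``, ``signed_log2``,
    ``defined`` plus the route's statistic (``statistic``/``p_value`` for
    ANOVA, ``statistic``/``q_value`` for SAM) and ``passes``.
    """

    table: pd.DataFrame
    route: str
    params: dict = field(default_factory=dict)


@dataclass
class OverlapSummary:
    """Concordance of two ranked top-n lists."""

    n: int
    only_a: int
    only_b: int
    shared: int
    shared_ids: frozenset[str]


# ---------------------------------------------------------------------------
# fold change
# ---------------------------------------------------------------------------


def _rpkm_values(expr: ExpressionMatrix) -> pd.DataFrame:
    if expr.scale == "rpkm":
        return expr.values
    return inverse_log_transform(expr).values


def fold_change(
    expr: ExpressionMatrix,
    design: SampleDesign,
    contrast: tuple[str, str],
    pseudocount: float = 0.0,
    on_log_scale: bool = False,
) -> pd.DataFrame:
    """Directional fold change of group means, case vs control.

    Means are taken on the RPKM scale by default (``on_log_scale=True``
    averages the log2 values instead).  Features whose means are both zero
    are flagged ``defined=False`` and carry ratio 1.
    """
    case, control = contrast
    if on_log_scale:
        values = expr.values if expr.scale == "log2" else log_transform(expr).values
        m_case = np.exp2(values[design.samples(case)].mean(axis=1))
        m_ctrl = np.exp2(values[design.samples(control)].mean(axis=1))
    else:
        values = _rpkm_values(expr)
        m_case = values[design.samples(case)].mean(axis=1)
        m_ctrl = values[design.samples(control)].mean(axis=1)
    m_case = m_case + pseudocount
    m_ctrl = m_ctrl + pseudocount
    defined = ~((m_case == 0) & (m_ctrl == 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        up = m_case / m_ctrl
        down = m_ctrl / m_case
        ratio = np.maximum(up, down)
    direction = np.where(m_case >= m_ctrl, "up", "down")
    ratio = pd.Series(np.where(defined, ratio, 1.0), index=values.index)
    with np.errstate(divide="ignore"):
        signed = np.where(direction == "up", np.log2(ratio), -np.log2(ratio))
    return pd.DataFrame(
        {
            "ratio": ratio,
            "direction": direction,
            "signed_log2": signed,
            "defined": defined,
        },
        index=values.index,
    )


# ---------------------------------------------------------------------------
# ANOVA route
# ---------------------------------------------------------------------------


def anova_de(
    expr: ExpressionMatrix,
    design: SampleDesign,
    contrast: tuple[str, str],
    groups: Sequence[str] | None = None,
    fc_cutoff: float = 1.5,
    p_cutoff: float = 0.05,
    combine: str = "and",
    offset: float = 1.0,
) -> DEResult:
    """One-way ANOVA per feature with fold and p cutoffs.

    The F test runs on log2(RPKM + offset) across ``groups`` (default: the
    two contrast groups); the fold change is computed on RPKM-scale means
    for the named contrast.  ``combine`` is ``"and"`` (default, stricter)
    or ``"or"`` -- how the fold and p criteria are joined.
    """
    if combine not in ("and", "or"):
        raise ValidationError(f"combine must be 'and' or 'or', got {combine!r}")
    groups = list(groups) if groups is not None else list(contrast)
    log_expr = expr if expr.scale == "log2" else log_transform(expr, offset=offset)
    arrays = [log_expr.values[design.samples(g)].to_numpy() for g in groups]
    for g, a in zip(groups, arrays):
        if a.shape[1] < 2:
            raise ValidationError(f"group {g} has fewer than 2 replicates")
    with np.errstate(divide="ignore", invalid="ignore"):
        stat_res = stats.f_oneway(*arrays, axis=1)
    f_stat = np.asarray(stat_res.statistic, dtype=float)
    p_val = np.asarray(stat_res.pvalue, dtype=float)
    folds = fold_change(expr, design, contrast)
    testable = np.isfinite(p_val)
    fold_ok = (folds["ratio"] >= fc_cutoff) & folds["defined"]
    p_ok = pd.Series(np.where(testable, p_val <= p_cutoff, False), index=folds.index)
    passes = (fold_ok & p_ok) if combine == "and" else (fold_ok | p_ok)
    table = folds.copy()
    table["statistic"] = f_stat
    table["p_value"] = p_val
    table["passes"] = passes & folds["defined"]
    return DEResult(
        table,
        route="anova",
        params={
            "groups": groups,
            "contrast": tuple(contrast),
            "fc_cutoff": fc_cutoff,
            "p_cutoff": p_cutoff,
            "combine": combine,
            "offset": offset,
        },
    )


# ---------------------------------------------------------------------------
# SAM route
# ---------------------------------------------------------------------------


def label_assignments(n1: int, n2: int) -> list[tuple[int, ...]]:
    """All distinct assignments of n1 'case' slots among n1+n2 samples.

    Each assignment is the sorted tuple of case indices; the identity
    assignment ``(0..n1-1)`` is included.  A 3v3 design yields 20.
    """
    return [tuple(c) for c in itertools.combinations(range(n1 + n2), n1)]


def _sam_d(values: np.ndarray, case_idx: np.ndarray, ctrl_idx: np.ndarray, s0: float) -> np.ndarray:
    x1 = values[:, case_idx]
    x2 = values[:, ctrl_idx]
    n1, n2 = x1.shape[1], x2.shape[1]
    diff = x1.mean(axis=1) - x2.mean(axis=1)
    ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x2 - x2.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    return diff / (s + s0)


def pooled_standard_error(values: np.ndarray, n1: int) -> np.ndarray:
    """The SAM gene-wise scatter s_i for the first n1 vs remaining columns."""
    x1, x2 = values[:, :n1], values[:, n1:]
    n2 = x2.shape[1]
    ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x2 - x2.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    return np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))


def _s0_percentile_search(values: np.ndarray, n1: int) -> float:
    """The original SAM fudge-factor rule: pick the percentile of s that
    minimizes the coefficient of variation of the d-statistic's median
    absolute deviation across s-quantile windows."""
    s = pooled_standard_error(values, n1)
    diff = values[:, :n1].mean(axis=1) - values[:, n1:].mean(axis=1)
    candidates = np.percentile(s, np.arange(0, 101, 5))
    quantile_bins = np.quantile(s, np.linspace(0, 1, 11))
    bin_idx = np.clip(np.searchsorted(quantile_bins, s, side="right") - 1, 0, 9)
    best, best_cv = 0.0, np.inf
    for s0 in candidates:
        d = diff / (s + s0)
        mads = np.array(
            [
                stats.median_abs_deviation(d[bin_idx == b], scale="normal")
                for b in range(10)
                if (bin_idx == b).any()
            ]
        )
        if mads.mean() == 0:
            continue
        cv = mads.std() / mads.mean()
        if cv < best_cv:
            best, best_cv = float(s0), cv
    return best


def sam_fdr_curve(
    d_obs: np.ndarray, d_perm: np.ndarray, thresholds: np.ndarray
) -> np.ndarray:
    """Estimated FDR at each |d| threshold.

    ``FDR(t) = median over permutations of #{|d*| >= t} / #{|d| >= t}``,
    capped at 1.  The reported curve at threshold t is the minimum raw
    estimate over all thresholds t' <= t (the thresholds at which a
    feature with |d| = t is called), which makes it non-increasing in t;
    a feature's q-value is this curve evaluated at its own |d|.
    """
    abs_obs = np.sort(np.abs(d_obs))
    n_obs = len(abs_obs) - np.searchsorted(abs_obs, thresholds, side="left")
    total_perm = d_perm.shape[1]
    # median false-call count across permutations at each threshold
    false_counts = np.empty((total_perm, len(thresholds)))
    for b in range(total_perm):
        col = np.sort(np.abs(d_perm[:, b]))
        false_counts[b] = len(col) - np.searchsorted(col, thresholds, side="left")
    med_false = np.median(false_counts, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(n_obs > 0, med_false / np.maximum(n_obs, 1), 0.0)
    fdr = np.minimum(fdr, 1.0)
    # q at threshold t = best achievable FDR among thresholds <= t
    fdr = np.minimum.accumulate(fdr)
    return fdr


def sam_de(
    expr: ExpressionMatrix,
    design: SampleDesign,
    contrast: tuple[str, str],
    fc_cutoff: float = 1.5,
    fdr_cutoff: float = 0.25,
    n_perm: int | str = "exhaustive",
    s0_rule: str | float = "median",
    seed: int | None = None,
) -> DEResult:
    """SAM-style permutation differential expression for one contrast.

    The d statistic is computed on log2(RPKM + 1) -- the scale the
    moderated statistic assumes -- while the fold change and its cutoff
    work on RPKM-scale group means.  ``s0_rule``: ``"median"`` (default;
    s0 = median of the gene-wise scatter s_i), ``"percentile"`` (the
    original coefficient-of-variation search), or a numeric value.
    Permutations shuffle group labels across the contrast's samples only;
    a request for more permutations than exist falls back to exhaustive
    enumeration.  The q-value of a feature is the estimated FDR at
    threshold |d| = |d_i|.
    """
    case, control = contrast
    case_samples = design.samples(case)
    ctrl_samples = design.samples(control)
    n1, n2 = len(case_samples), len(ctrl_samples)
    if n1 < 2 or n2 < 2:
        raise ValidationError("sam_de requires >= 2 replicates per group")
    log_expr = expr if expr.scale == "log2" else log_transform(expr)
    values = log_expr.values[case_samples + ctrl_samples].to_numpy(dtype=float)

    assignments = label_assignments(n1, n2)
    if n_perm == "exhaustive" or (isinstance(n_perm, int) and n_perm >= len(assignments)):
        if isinstance(n_perm, int) and n_perm > len(assignments):
            logger.info(
                "n_perm=%s exceeds the %d distinct label assignments; using exhaustive",
                n_perm, len(assignments),
            )
        chosen = assignments
        exhaustive = True
    else:
        if seed is None:
            raise ValidationError("seed is mandatory for sampled permutations")
        if n_perm < 1:
            raise ValidationError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, len(assignments), size=int(n_perm))
        chosen = [assignments[i] for i in idx]
        exhaustive = False

    all_idx = np.arange(n1 + n2)
    if s0_rule == "median":
        s0 = float(np.median(pooled_standard_error(values, n1)))
    elif s0_rule == "percentile":
        s0 = _s0_percentile_search(values, n1)
    else:
        s0 = float(s0_rule)

    identity = tuple(range(n1))
    d_obs = _sam_d(values, np.array(identity), np.setdiff1d(all_idx, identity), s0)
    d_perm = np.column_stack(
        [
            _sam_d(values, np.array(a), np.setdiff1d(all_idx, np.array(a)), s0)
            for a in chosen
        ]
    )
    thresholds = np.unique(np.abs(d_obs))
    fdr = sam_fdr_curve(d_obs, d_perm, thresholds)
    q = fdr[np.searchsorted(thresholds, np.abs(d_obs))]

    folds = fold_change(expr, design, contrast)
    table = folds.copy()
    table["statistic"] = d_obs
    table["q_value"] = q
    table["passes"] = (
        (table["q_value"] <= fdr_cutoff)
        & (table["ratio"] >= fc_cutoff)
        & table["defined"]
    )
    return DEResult(
        table,
        route="sam",
        params={
            "contrast": tuple(contrast),
            "fc_cutoff": fc_cutoff,
            "fdr_cutoff": fdr_cutoff,
            "s0": s0,
            "s0_rule": s0_rule,
            "n_perm": len(chosen),
            "exhaustive": exhaustive,
            "permutations": chosen,
            "seed": seed,
        },
    )


def sam_permutation_distribution(
    expr: ExpressionMatrix,
    design: SampleDesign,
    contrast: tuple[str, str],
    s0: float = 0.0,
) -> np.ndarray:
    """d-statistics for every distinct label assignment (features x
    assignments), in :func:`label_assignments` order.  Exposed so the
    permutation machinery can be checked against direct enumeration."""
    case_samples = design.samples(contrast[0])
    ctrl_samples = design.samples(contrast[1])
    n1 = len(case_samples)
    values = expr.values[case_samples + ctrl_samples].to_numpy(dtype=float)
    all_idx = np.arange(values.shape[1])
    return np.column_stack(
        [
            _sam_d(values, np.array(a), np.setdiff1d(all_idx, np.array(a)), s0)
            for a in label_assignments(n1, len(ctrl_samples))
        ]
    )


# ---------------------------------------------------------------------------
# top-list concordance
# ---------------------------------------------------------------------------


def top_n_overlap(
    result_a: DEResult | pd.DataFrame,
    result_b: DEResult | pd.DataFrame,
    n: int = 100,
    rank_key: str = "signed_log2",
) -> OverlapSummary:
    """Shared and unique ids among each route's top ``n`` features.

    Features are ranked by the absolute value of ``rank_key`` (descending);
    ties break lexicographically on feature id so the output is stable.
    """
    def top_ids(res) -> set[str]:
        table = res.table if isinstance(res, DEResult) else res
        key = table[rank_key].abs()
        order = sorted(zip(-key.to_numpy(), table.index.astype(str)))
        return {fid for _, fid in order[:n]}

    a, b = top_ids(result_a), top_ids(result_b)
    shared = a & b
    return OverlapSummary(
        n=n,
        only_a=len(a - b),
        only_b=len(b - a),
        shared=len(shared),
        shared_ids=frozenset(shared),
    )
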