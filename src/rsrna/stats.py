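"""Differential expression, correlation and enrichment statistics.

Pearson correlation uses pairwise-complete deletion of missing values and a
two-sided t approximation for significance (t = r * sqrt((n-2)/(1-r^2)) on
n-2 degrees of freedom). Fold change between tumor and normal mean RPM uses
a pseudocount to stay defined at zero expression. Enrichment is an
upper-tail hypergeometric test with Bonferroni correction across
categories.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .datamodel import CountMatrix


class UndefinedCorrelationError(ValueError):
    """Correlation undefined: fewer than 3 complete pairs or zero variance."""


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n_used: int
    p_value: float


def round_half_even(x: float, ndigits: int = 2) -> float:
    """Banker's rounding used for all reported percentages and coefficients."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_EVEN))


def pearson_correlation(
    x: Sequence[float], y: Sequence[float], pairwise_complete: bool = True
) -> CorrelationResult:
    """Pearson r with pairwise-complete missing-data handling.

    Positions missing (NaN) in either vector are dropped before computing
    r; significance is the two-sided t approximation. r = +/-1 reports
    p = 0 (boundary-safe).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must have equal length")
    mask = np.isfinite(xa) & np.isfinite(ya)
    if not pairwise_complete and not mask.all():
        raise UndefinedCorrelationError("missing values present and pairwise_complete=False")
    xa, ya = xa[mask], ya[mask]
    n = len(xa)
    if n < 3:
        raise UndefinedCorrelationError(f"only {n} complete pairs (need >= 3)")
    dx = xa - xa.mean()
    dy = ya - ya.mean()
    denom = np.sqrt((dx * dx).sum() * (dy * dy).sum())
    if denom == 0:
        raise UndefinedCorrelationError("zero variance in x or y")
    r = float((dx * dy).sum() / denom)
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2 * sp_stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(r, n, p)


def welch_ttest(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Welch (unequal-variance) t-test."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 finite observations")
    if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    import warnings

    with warnings.catch_warnings():
        # constant groups yield a degenerate Welch statistic; the caller
        # sees the resulting nan/inf rather than a console warning
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = sp_stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


@dataclass(frozen=True)
class DifferentialCall:
    srna_id: str
    condition_id: str
    tumor_mean_rpm: float
    normal_mean_rpm: float
    fold_change: float
    direction: str                 # up_in_tumor | up_in_normal | unchanged
    t_statistic: float
    p_value: float


def fold_change_flags(
    cm: CountMatrix,
    fold_change_min: float = 2.0,
    pseudocount: float = 0.5,
) -> tuple[list[DifferentialCall], pd.DataFrame]:
    """Per-(sRNA, condition) fold change between tumor and normal mean RPM.

    FC = (mean tumor RPM + pseudocount) / (mean normal RPM + pseudocount);
    a sequence is flagged differentially expressed when FC >= threshold or
    FC <= 1/threshold in at least one condition. Conditions missing either
    state are skipped with a warning. The summary table tallies per-sRNA
    up_in_tumor / up_in_normal condition counts and the DE flag.
    """
    if cm.rpm is None:
        raise ValueError("RPM layer required: run rpm_normalize first")
    import logging

    log = logging.getLogger(__name__)
    groups: dict[str, dict[str, list[str]]] = {}
    for s in cm.samples:
        groups.setdefault(s.condition_id, {}).setdefault(s.state, []).append(s.sample_id)
    calls: list[DifferentialCall] = []
    summary = pd.DataFrame(
        0, index=cm.rpm.index, columns=["up_in_tumor", "up_in_normal"], dtype=np.int64
    )
    for cond, states in groups.items():
        if "tumor" not in states or "normal" not in states:
            log.warning("condition %s lacks a tumor or normal state; skipped", cond)
            continue
        t_rpm = cm.rpm[states["tumor"]]
        n_rpm = cm.rpm[states["normal"]]
        t_mean = t_rpm.mean(axis=1)
        n_mean = n_rpm.mean(axis=1)
        fc = (t_mean + pseudocount) / (n_mean + pseudocount)
        can_test = len(states["tumor"]) >= 2 and len(states["normal"]) >= 2
        for seq in cm.rpm.index:
            f = float(fc[seq])
            if f >= fold_change_min:
                direction = "up_in_tumor"
                summary.loc[seq, "up_in_tumor"] += 1
            elif f <= 1.0 / fold_change_min:
                direction = "up_in_normal"
                summary.loc[seq, "up_in_normal"] += 1
            else:
                direction = "unchanged"
            if can_test:
                try:
                    t_stat, p = welch_ttest(t_rpm.loc[seq], n_rpm.loc[seq])
                except ValueError:
                    t_stat, p = np.nan, np.nan
            else:
                t_stat, p = np.nan, np.nan
            calls.append(
                DifferentialCall(
                    seq, cond, float(t_mean[seq]), float(n_mean[seq]), f, direction, t_stat, p
                )
            )
    summary["de_flag"] = (summary["up_in_tumor"] + summary["up_in_normal"]) > 0
    return calls, summary


def anticorrelation_screen(
    srna_rpm: pd.DataFrame,
    expression: pd.DataFrame,
    pairs: Iterable[tuple[str, str]],
    pcc_max: float = -0.5,
    p_max: float = 0.05,
    log_transform: bool = False,
) -> pd.DataFrame:
    """Screen candidate (sRNA, gene) pairs for significant anti-correlation.

    Correlates each sRNA's RPM against the target's abundance over the
    shared sample columns; a pair passes iff r <= ``pcc_max`` and
    p <= ``p_max``. Works identically for RNA-seq RPKM, microarray and
    protein matrices. Pairs whose correlation is undefined are reported
    with NA and pass=False.
    """
    shared = [c for c in srna_rpm.columns if c in set(expression.columns)]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared samples between matrices (need >= 3)")
    rows = []
    for srna_id, gene_id in pairs:
        if srna_id not in srna_rpm.index or gene_id not in expression.index:
            rows.append((srna_id, gene_id, np.nan, 0, np.nan, False, "missing_row"))
            continue
        x = srna_rpm.loc[srna_id, shared].to_numpy(dtype=float)
        y = expression.loc[gene_id, shared].to_numpy(dtype=float)
        if log_transform:
            x = np.log2(x + 1.0)
            y = np.log2(y + 1.0)
        try:
            res = pearson_correlation(x, y)
        except UndefinedCorrelationError as exc:
            rows.append((srna_id, gene_id, np.nan, 0, np.nan, False, str(exc)))
            continue
        ok = res.r <= pcc_max and res.p_value <= p_max
        rows.append((srna_id, gene_id, res.r, res.n_used, res.p_value, ok, ""))
    return pd.DataFrame(
        rows, columns=["srna_id", "gene_id", "r", "n_used", "p_value", "passed", "note"]
    )


def ct_correlation_table(
    ct: pd.DataFrame, pairs: Sequence[tuple[str, str]]
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation between Ct rows.

    Each pair names one sRNA row and one gene row of the Ct table; the
    report carries full-precision r plus a 2-decimal rounded value
    (round-half-even). Pairs with fewer than 3 complete Ct pairs are
    reported as NA with a reason.
    """
    rows = []
    for a, b in pairs:
        if a not in ct.index or b not in ct.index:
            rows.append((a, b, np.nan, np.nan, 0, "missing_row"))
            continue
        try:
            res = pearson_correlation(ct.loc[a].to_numpy(), ct.loc[b].to_numpy())
        except UndefinedCorrelationError as exc:
            rows.append((a, b, np.nan, np.nan, 0, str(exc)))
            continue
        rows.append((a, b, res.r, round_half_even(res.r, 2), res.n_used, ""))
    return pd.DataFrame(rows, columns=["srna_id", "gene_id", "r", "r_2dp", "n_used", "note"])


def hypergeometric_enrichment(
    target_set: Iterable[str],
    universe: Iterable[str],
    category_map: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment with Bonferroni correction.

    p_raw = P(X >= overlap) with population |universe|, successes
    |category ∩ universe|, draws |target_set|; p_bonferroni = min(1,
    p_raw * number of categories tested). Overlap 0 gives p_raw = 1.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    targets = set(target_set)
    if not targets <= universe_set:
        raise ValueError("target_set must be a subset of the universe")
    n_tests = len(category_map)
    rows = []
    for name in sorted(category_map):
        members = set(category_map[name]) & universe_set
        overlap = len(targets & members)
        p_raw = float(
            sp_stats.hypergeom.sf(overlap - 1, len(universe_set), len(members), len(targets))
        )
        p_raw = min(1.0, p_raw)
        rows.append((name, len(members), overlap, p_raw, min(1.0, p_raw * n_tests)))
    return pd.DataFrame(
        rows, columns=["category", "category_size", "overlap", "p_raw", "p_bonferroni"]
    )


def bh_qvalues(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaN-safe)."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.sum():
        q[mask] = sp_stats.false_discovery_control(p[mask], method="bh")
    return q
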