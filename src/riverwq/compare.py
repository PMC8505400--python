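"""Phase-comparison statistics: descriptives, percent changes, Pearson
correlations with significance stars, one-way ANOVA with Fisher LSD.

Descriptive statistics use the sample (n−1) standard deviation.  Percent
changes are computed on unrounded statistics.  The LSD step is the classic
Fisher procedure: unadjusted pairwise t tests on the pooled within-group
mean square after the omnibus F — no multiplicity correction.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError
from .registry import SampleRecord

__all__ = [
    "ComparisonRow",
    "CorrelationCell",
    "AnovaRow",
    "describe",
    "percent_change",
    "compare_phases",
    "correlation_matrix",
    "correlation_frame",
    "anova_lsd",
    "significance_stars",
]


@dataclass(frozen=True)
class ComparisonRow:
    """Per-parameter phase A vs phase B statistics and percent changes."""

    code: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    mean_diff_pct: float
    sd_diff_pct: float


@dataclass(frozen=True)
class CorrelationCell:
    """One Pearson pair with two-sided p and significance stars."""

    code_x: str
    code_y: str
    r: float
    p: float
    stars: str


@dataclass(frozen=True)
class AnovaRow:
    """One-way ANOVA across phases for one parameter, with LSD decisions.

    ``lsd_pairs`` maps (phase_a, phase_b) to True when the pair separates
    at α = 0.05.
    """

    code: str
    F: float
    p: float
    lsd_pairs: Mapping[tuple[str, str], bool]


def significance_stars(p: float) -> str:
    """'' / '*' / '**' / '***' at p < 0.05 / 0.01 / 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _values_by_code(samples: Iterable[SampleRecord]) -> dict[str, list[float]]:
    out: dict[str, list[float]] = {}
    for rec in samples:
        for code, value in rec.values.items():
            out.setdefault(code, []).append(float(value))
    return out


def describe(phase_samples: Sequence[SampleRecord]) -> dict[str, tuple[float, float]]:
    """Per-parameter arithmetic mean and sample (n−1) standard deviation."""
    if len(phase_samples) < 2:
        raise InsufficientDataError(
            f"describe needs at least 2 samples, got {len(phase_samples)}"
        )
    return {
        code: (float(np.mean(vals)), float(np.std(vals, ddof=1)))
        for code, vals in _values_by_code(phase_samples).items()
    }


def percent_change(a: float, b: float) -> float:
    """(b − a)/a × 100; undefined for a = 0."""
    if a == 0:
        raise ZeroDivisionError("percent change undefined for a zero baseline")
    return (b - a) / a * 100.0


def compare_phases(
    samples_a: Sequence[SampleRecord], samples_b: Sequence[SampleRecord]
) -> list[ComparisonRow]:
    """Phase A vs phase B means/SDs and percent changes, per parameter."""
    stats_a = describe(samples_a)
    stats_b = describe(samples_b)
    rows = []
    for code in stats_a:
        if code not in stats_b:
            continue
        mean_a, sd_a = stats_a[code]
        mean_b, sd_b = stats_b[code]
        rows.append(
            ComparisonRow(
                code=code,
                mean_a=mean_a,
                sd_a=sd_a,
                mean_b=mean_b,
                sd_b=sd_b,
                mean_diff_pct=percent_change(mean_a, mean_b) if mean_a else math.nan,
                sd_diff_pct=percent_change(sd_a, sd_b) if sd_a else math.nan,
            )
        )
    return rows


def correlation_matrix(
    phase_samples: Sequence[SampleRecord], codes: Sequence[str] | None = None
) -> list[CorrelationCell]:
    """All pairwise Pearson correlations with two-sided p (t on n−2 df).

    A zero-variance parameter has no defined correlation; its pairs are
    reported with ``r = nan`` and no stars rather than dropped silently.
    """
    by_code = _values_by_code(phase_samples)
    if codes is None:
        codes = [c for c, v in by_code.items() if len(v) == len(phase_samples)]
    for code in codes:
        if len(by_code.get(code, ())) < 3:
            raise InsufficientDataError(f"correlation needs ≥ 3 samples for {code}")
    cells = []
    for cx, cy in itertools.combinations_with_replacement(codes, 2):
        x = np.asarray(by_code[cx])
        y = np.asarray(by_code[cy])
        if cx == cy:
            cells.append(CorrelationCell(cx, cy, 1.0, 0.0, "***"))
            continue
        if np.std(x) == 0 or np.std(y) == 0:
            cells.append(CorrelationCell(cx, cy, math.nan, math.nan, ""))
            continue
        res = stats.pearsonr(x, y)
        r, p = float(res.statistic), float(res.pvalue)
        cells.append(CorrelationCell(cx, cy, r, p, significance_stars(p)))
    return cells


def correlation_frame(cells: Sequence[CorrelationCell]) -> pd.DataFrame:
    """Square symmetric matrix of r values from correlation cells."""
    codes = list(dict.fromkeys(itertools.chain.from_iterable((c.code_x, c.code_y) for c in cells)))
    frame = pd.DataFrame(np.nan, index=codes, columns=codes)
    for cell in cells:
        frame.loc[cell.code_x, cell.code_y] = cell.r
        frame.loc[cell.code_y, cell.code_x] = cell.r
    return frame


def anova_lsd(
    phase_groups: Mapping[str, Sequence[float]], code: str, alpha: float = 0.05
) -> AnovaRow:
    """One-way fixed-effects ANOVA across phases plus Fisher LSD pairs.

    The omnibus F and p come from the standard between/within decomposition;
    each LSD pair uses t = (x̄_i − x̄_j) / √(MS_W (1/n_i + 1/n_j)) on the
    pooled error df, compared two-sided at ``alpha``.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in phase_groups.items()}
    for phase, vals in groups.items():
        if len(vals) < 2:
            raise InsufficientDataError(f"{code}: phase {phase} has n < 2")
    F, p = stats.f_oneway(*groups.values())
    n_total = sum(len(v) for v in groups.values())
    df_error = n_total - len(groups)
    ms_within = sum(
        ((v - v.mean()) ** 2).sum() for v in groups.values()
    ) / df_error
    lsd: dict[tuple[str, str], bool] = {}
    for a, b in itertools.combinations(groups, 2):
        va, vb = groups[a], groups[b]
        se = math.sqrt(ms_within * (1 / len(va) + 1 / len(vb)))
        if se == 0:
            lsd[(a, b)] = va.mean() != vb.mean()
            continue
        t = (va.mean() - vb.mean()) / se
        p_pair = 2 * stats.t.sf(abs(t), df_error)
        lsd[(a, b)] = p_pair < alpha
    # degenerate no-variation case: scipy returns nan, the classical
    # convention is F = 0 with no evidence against the null
    if math.isnan(F):
        F, p = 0.0, 1.0
    return AnovaRow(code=code, F=float(F), p=float(p), lsd_pairs=lsd)
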