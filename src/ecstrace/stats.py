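"""Group statistics: one-way ANOVA (raw and summary forms), LSD post-hoc
pairwise tests, Pearson correlation inference, and a sample-size consistency
auditor for published summary tables.

The summary-statistics ANOVA reconstructs the classical one-way F test from
per-group (n, mean, SD) alone:

    MS_between = Σ nᵢ (mᵢ − m̄)² / (g − 1),   m̄ the n-weighted grand mean
    MS_within  = Σ (nᵢ − 1) sᵢ² / Σ (nᵢ − 1)
    F = MS_between / MS_within,  df = (g − 1, Σnᵢ − g)

which is algebraically identical to the raw-data ANOVA.  LSD (Fisher's least
significant difference) performs unadjusted pairwise t tests on the pooled
ANOVA error term.  All p-values are two-sided.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .forward_model import ValidationError

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "LsdResult",
    "CorrelationResult",
    "AuditResult",
    "anova_from_summary",
    "anova_oneway",
    "lsd_posthoc",
    "pearson",
    "pearson_p_from_r",
    "audit_equal_n",
    "summaries_from_values",
]


@dataclass(frozen=True)
class GroupSummary:
    """Per-group sample size, mean and SD for one parameter."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError(f"group {self.label!r}: n must be >= 2")
        if self.sd < 0:
            raise ValidationError(f"group {self.label!r}: sd must be >= 0")


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    ms_between: float
    ms_within: float

    @property
    def degenerate(self) -> bool:
        """True when the within-group variance vanished and F is undefined."""
        return not math.isfinite(self.f_stat)


@dataclass(frozen=True)
class LsdResult:
    pair: tuple[str, str]
    mean_diff: float
    t_stat: float
    p_value: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    t_stat: float
    p_value: float


def _f_and_p(ms_between: float, ms_within: float, df_between: int, df_within: int):
    """F ratio and p, treating a vanishing pooled variance as degenerate.

    ``ms_within`` is compared against the between-group scale so that pure
    floating-point residue from identical values (e.g. an all-equal group
    whose recomputed mean differs from its members in the last bit) is still
    recognised as zero.
    """
    if ms_within <= 1e-12 * ms_between or (ms_within == 0.0 and ms_between == 0.0):
        f = float("inf") if ms_between > 0 else float("nan")
        p = 0.0 if ms_between > 0 else float("nan")
        return f, p
    f = ms_between / ms_within
    return float(f), float(sps.f.sf(f, df_between, df_within))


def anova_from_summary(summaries: list[GroupSummary]) -> AnovaResult:
    """One-way ANOVA reconstructed from per-group (n, mean, SD) summaries."""
    if len(summaries) < 2:
        raise ValidationError("ANOVA requires at least 2 groups")
    ns = np.array([s.n for s in summaries], dtype=float)
    means = np.array([s.mean for s in summaries], dtype=float)
    sds = np.array([s.sd for s in summaries], dtype=float)
    g = len(summaries)
    df_between = g - 1
    df_within = int(ns.sum()) - g
    if df_within < 1:
        raise ValidationError("ANOVA requires Σn − g >= 1")
    grand = float(np.sum(ns * means) / ns.sum())
    ms_between = float(np.sum(ns * (means - grand) ** 2) / df_between)
    ms_within = float(np.sum((ns - 1) * sds**2) / (ns.sum() - g))
    f, p = _f_and_p(ms_between, ms_within, df_between, df_within)
    return AnovaResult(
        f_stat=f, df_between=df_between, df_within=df_within,
        p_value=p, ms_between=ms_between, ms_within=ms_within,
    )


def summaries_from_values(values: dict[str, np.ndarray]) -> list[GroupSummary]:
    """Exact per-group summaries (sample SD, ddof=1) of raw value lists."""
    out = []
    for label, v in values.items():
        v = np.asarray(v, dtype=float)
        if v.size < 2:
            raise ValidationError(f"group {label!r}: needs >= 2 values")
        out.append(GroupSummary(label=label, n=v.size, mean=float(v.mean()),
                                sd=float(v.std(ddof=1))))
    return out


def anova_oneway(values: dict[str, np.ndarray]) -> AnovaResult:
    """One-way ANOVA on raw per-group values via explicit sums of squares.

    Algebraically identical to :func:`anova_from_summary` applied to the
    groups' exact means/SDs/ns (a tested consistency contract).
    """
    if len(values) < 2:
        raise ValidationError("ANOVA requires at least 2 groups")
    groups = []
    for label, v in values.items():
        v = np.asarray(v, dtype=float)
        if v.size < 2:
            raise ValidationError(f"group {label!r}: needs >= 2 values")
        groups.append(v)
    all_values = np.concatenate(groups)
    grand = all_values.mean()
    g = len(groups)
    df_between = g - 1
    df_within = all_values.size - g
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in groups)
    ss_within = sum(float(np.sum((v - v.mean()) ** 2)) for v in groups)
    ms_between = float(ss_between / df_between)
    ms_within = float(ss_within / df_within)
    f, p = _f_and_p(ms_between, ms_within, df_between, df_within)
    return AnovaResult(
        f_stat=float(f), df_between=df_between, df_within=df_within,
        p_value=p, ms_between=float(ms_between), ms_within=float(ms_within),
    )


def lsd_posthoc(
    summaries: list[GroupSummary], ms_within: float, df_within: int
) -> list[LsdResult]:
    """Fisher's LSD: unadjusted pairwise t tests on the pooled error term.

    t = (mᵢ − mⱼ) / sqrt(MS_within (1/nᵢ + 1/nⱼ)), two-sided p on df_within.
    """
    if df_within < 1:
        raise ValidationError("LSD requires df_within >= 1")
    if ms_within <= 0:
        raise ValidationError("LSD requires a positive MS_within")
    out = []
    for a, b in itertools.combinations(summaries, 2):
        diff = a.mean - b.mean
        se = math.sqrt(ms_within * (1.0 / a.n + 1.0 / b.n))
        t = diff / se
        p = float(2.0 * sps.t.sf(abs(t), df_within))
        out.append(LsdResult(pair=(a.label, b.label), mean_diff=diff, t_stat=t, p_value=p))
    return out


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p for a product-moment correlation r at sample size n.

    Uses the exact t transform t = r sqrt((n−2)/(1−r²)) on n−2 df.
    """
    if n < 3:
        raise ValidationError("Pearson inference requires n >= 3")
    if not -1.0 <= r <= 1.0:
        raise ValidationError("r must lie in [-1, 1]")
    if abs(r) == 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), n - 2))


def pearson(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with two-sided t inference."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValidationError("Pearson correlation requires n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("Pearson correlation requires nonzero variance in both vectors")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        t = math.copysign(math.inf, r)
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return CorrelationResult(r=r, n=n, t_stat=float(t), p_value=p)


# ---------------------------------------------------------------------------
# Sample-size consistency auditor
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AuditResult:
    """Outcome of scanning equal sample sizes against published F statistics."""

    candidates: tuple[int, ...]
    max_rel_dev: dict[int, float]     # worst relative |F_candidate/F_printed − 1| per n
    consistent: tuple[int, ...]       # candidates within rtol on every parameter
    best_n: int | None                # unique consistent n, else None
    rtol: float


def audit_equal_n(
    summaries_by_param: dict[str, list[GroupSummary]],
    printed_f: dict[str, float],
    candidates=range(5, 11),
    rtol: float = 0.005,
) -> AuditResult:
    """Find equal per-group sample sizes consistent with published F values.

    For each candidate n, recompute every parameter's summary-statistics F
    with that n substituted into all groups and record the worst relative
    deviation from the printed F.  A candidate is consistent when all
    parameters agree within ``rtol``; ``best_n`` is set only when exactly one
    candidate qualifies.  With equal n the F statistic is proportional to n,
    so at the sub-percent agreement seen here the answer is sharply unique.
    """
    missing = set(printed_f) - set(summaries_by_param)
    if missing:
        raise ValidationError(f"no summaries for parameters: {sorted(missing)}")
    candidates = tuple(int(n) for n in candidates)
    max_rel_dev: dict[int, float] = {}
    consistent = []
    for n in candidates:
        worst = 0.0
        for param, f_printed in printed_f.items():
            subs = [GroupSummary(s.label, n, s.mean, s.sd) for s in summaries_by_param[param]]
            f_n = anova_from_summary(subs).f_stat
            worst = max(worst, abs(f_n / f_printed - 1.0))
        max_rel_dev[n] = worst
        if worst <= rtol:
            consistent.append(n)
    best = consistent[0] if len(consistent) == 1 else None
    return AuditResult(
        candidates=candidates,
        max_rel_dev=max_rel_dev,
        consistent=tuple(consistent),
        best_n=best,
        rtol=rtol,
    )
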