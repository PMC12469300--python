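"""Per-condition summaries and two-group comparisons.

The study's statistics layer: mean ± SEM per condition, unpaired two-sided
Student's t-tests (pooled variance by default, Welch behind a flag) with
the usual significance stars, orientation-distribution summaries over
nucleus records, and the simple percentage endpoints (cell detachment,
wound closure).  No multiple-testing correction is applied by default;
Benjamini–Hochberg is available for callers who want it.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .morphometry import NucleusRecord

__all__ = [
    "GroupComparison",
    "OrientationSummary",
    "stars_from_p",
    "compare_groups",
    "orientation_summary",
    "detachment_percent",
    "wound_closure_percent",
    "benjamini_hochberg",
]


@dataclass
class GroupComparison:
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    mean_difference: float        # mean_a − mean_b
    se_difference: float
    t_statistic: float
    degrees_of_freedom: float
    p_two_sided: float
    stars: str
    welch: bool = False
    degenerate: bool = False      # zero pooled variance with unequal means

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class OrientationSummary:
    n: int
    mean_cos2phi: float           # over defined-orientation records only
    fraction_perpendicular: float
    fraction_parallel: float
    fraction_oblique: float
    fraction_undefined: float


def stars_from_p(p: float) -> str:
    """Significance stars at the conventional strict cutoffs.

    p < 0.05 → *, p < 0.01 → **, p < 0.001 → ***, p < 0.0001 → ****;
    boundary values (e.g. p exactly 0.05) are not significant.
    """
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(a, b, welch: bool = False) -> GroupComparison:
    """Unpaired two-sided Student's t-test between two samples.

    Pooled-variance by default (df = n_a + n_b − 2); ``welch=True`` drops
    the equal-variance assumption.  The mean difference is reported with
    its standard error.  Two identical constant samples give t = 0, p = 1;
    zero pooled variance with unequal means is degenerate and reported as
    p = 0 with the ``degenerate`` flag set.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(f"need at least 2 observations per group, got {a.size}, {b.size}")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in input")
    na, nb = a.size, b.size
    ma, mb = float(a.mean()), float(b.mean())
    va, vb = float(a.var(ddof=1)), float(b.var(ddof=1))
    sem_a = np.sqrt(va / na)
    sem_b = np.sqrt(vb / nb)
    diff = ma - mb

    degenerate = False
    if welch:
        se = float(np.sqrt(va / na + vb / nb))
        if se == 0.0:
            t, p, df = (0.0, 1.0, float(na + nb - 2)) if diff == 0 else (np.inf, 0.0, float(na + nb - 2))
            degenerate = diff != 0
        else:
            df = (va / na + vb / nb) ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
            res = stats.ttest_ind(a, b, equal_var=False)
            t, p = float(res.statistic), float(res.pvalue)
    else:
        df = float(na + nb - 2)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se = float(np.sqrt(sp2 * (1.0 / na + 1.0 / nb)))
        if se == 0.0:
            if diff == 0:
                t, p = 0.0, 1.0
            else:
                t, p = np.inf if diff > 0 else -np.inf, 0.0
                degenerate = True
        else:
            res = stats.ttest_ind(a, b, equal_var=True)
            t, p = float(res.statistic), float(res.pvalue)

    return GroupComparison(
        n_a=na, n_b=nb, mean_a=ma, mean_b=mb, sem_a=float(sem_a),
        sem_b=float(sem_b), mean_difference=diff, se_difference=se,
        t_statistic=t, degrees_of_freedom=float(df), p_two_sided=p,
        stars=stars_from_p(p), welch=welch, degenerate=degenerate)


def orientation_summary(records) -> OrientationSummary:
    """Class fractions and mean cos(2φ) over a set of nucleus records.

    Accepts NucleusRecord objects or anything exposing ``cos2phi`` and
    ``orientation_class``.  Undefined-orientation records count toward
    ``fraction_undefined`` but are excluded from the mean cos(2φ).
    """
    records = list(records)
    if not records:
        raise ValueError("no records")
    classes = [r.orientation_class for r in records]
    n = len(records)
    frac = lambda c: classes.count(c) / n
    defined = [r.cos2phi for r in records if r.orientation_class != "undefined"]
    mean_c = float(np.mean(defined)) if defined else float("nan")
    return OrientationSummary(
        n=n, mean_cos2phi=mean_c,
        fraction_perpendicular=frac("perpendicular"),
        fraction_parallel=frac("parallel"),
        fraction_oblique=frac("oblique"),
        fraction_undefined=frac("undefined"))


def detachment_percent(n_initial: int, n_remaining: int) -> float:
    """Attached cells remaining, as a percentage of the initial count."""
    if n_initial <= 0:
        raise ValueError("n_initial must be > 0")
    if not (0 <= n_remaining <= n_initial):
        raise ValueError(f"n_remaining must be in [0, {n_initial}], got {n_remaining}")
    return 100.0 * n_remaining / n_initial


def wound_closure_percent(area_0h: float, area_t: float) -> float:
    """Wound closure 100·(A₀ − Aₜ)/A₀.  A widening wound (Aₜ > A₀) yields a
    negative percentage, reported with a warning rather than rejected."""
    if area_0h <= 0:
        raise ValueError("area_0h must be > 0")
    if area_t < 0:
        raise ValueError("area_t must be >= 0")
    pct = 100.0 * (area_0h - area_t) / area_0h
    if pct < 0:
        import warnings
        warnings.warn(f"wound widened: closure {pct:.1f}% < 0", stacklevel=2)
    return pct


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted q-values (off by default everywhere; provided for callers
    running many comparisons)."""
    p = np.asarray(list(p_values), dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(q)
    out[order] = np.clip(q, 0, 1)
    return out
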