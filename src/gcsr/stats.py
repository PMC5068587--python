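"""Contrast-based inference for the goal-conflict rhythmicity biomarker.

The published analyses reduce the Stop/Go x SSD x frequency cell structure
to single-degree-of-freedom orthogonal polynomial contrasts:

* trial type enters as Stop - Go (weights +1, -1);
* SSD (short, medium, long) enters through its quadratic contrast
  (1, -2, 1 up to sign), isolating conflict-specific power;
* frequency (4..12 Hz, nine 1 Hz bins) enters through a linear, quadratic or
  cubic polynomial contrast describing the spectral shape of the effect.

A participant's composite contrast score is the triple product of these
weights summed over all 54 cells.  Group effects are then ordinary one-way
ANOVAs on the scores, within-group effects are one-sample t tests reported
as F = t^2 with df (1, n-1), per-frequency personality relations are Pearson
correlations, and the frequency-selective personality relation is probed by
classical forward stepwise regression with an F-change entry test.  All
p values are uncorrected.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import gcd

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ContrastWeights",
    "TestResult",
    "StepwiseStep",
    "poly_weights",
    "contrast_score",
    "one_sample_contrast_test",
    "group_contrast_anova",
    "trait_correlations",
    "stepwise_forward",
    "channel_gradient",
]

ORDER_NAMES = {1: "linear", 2: "quadratic", 3: "cubic"}
SSD_LEVELS = ("short", "medium", "long")
TRIAL_TYPES = ("stop", "go")
FREQ_BINS_HZ = tuple(range(4, 13))


@dataclass(frozen=True)
class ContrastWeights:
    factor: str
    levels: tuple
    weights: tuple
    order: str

    def as_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)


@dataclass(frozen=True)
class TestResult:
    effect: str
    f_value: float
    df: tuple[int, int]
    p_value: float
    direction: float  # sign of the underlying mean/estimate
    degenerate: bool = False


def poly_weights(n_levels: int, order: int | str, factor: str = "") -> ContrastWeights:
    """Integer orthogonal polynomial contrast weights for equally spaced levels.

    Computed by exact Gram-Schmidt over the rationals and scaled to the
    smallest integer vector, which reproduces the classical tables:
    (3, linear) -> (-1, 0, 1); (3, quadratic) -> (1, -2, 1); and for nine
    levels the familiar (-4..4), (28, 7, -8, ...) and cubic sets.
    """
    if isinstance(order, str):
        order_num = {v: k for k, v in ORDER_NAMES.items()}[order]
    else:
        order_num = int(order)
    if not 1 <= order_num < n_levels:
        raise ValueError(f"order {order_num} needs at least {order_num + 1} levels")
    x = [Fraction(i) for i in range(n_levels)]
    # Gram-Schmidt of 1, x, x^2, ... under the uniform inner product
    basis: list[list[Fraction]] = []
    for k in range(order_num + 1):
        v = [xi**k for xi in x]
        for b in basis:
            bb = sum(bi * bi for bi in b)
            vb = sum(vi * bi for vi, bi in zip(v, b))
            coef = vb / bb
            v = [vi - coef * bi for vi, bi in zip(v, b)]
        basis.append(v)
    v = basis[order_num]
    denom_lcm = 1
    for vi in v:
        denom_lcm = denom_lcm * vi.denominator // gcd(denom_lcm, vi.denominator)
    ints = [int(vi * denom_lcm) for vi in v]
    g = 0
    for i in ints:
        g = gcd(g, abs(i))
    ints = [i // g for i in ints]
    # conventional sign: last weight positive for odd orders, first positive even
    lead = ints[-1] if order_num % 2 else ints[0]
    if lead < 0:
        ints = [-i for i in ints]
    return ContrastWeights(
        factor=factor,
        levels=tuple(range(n_levels)),
        weights=tuple(ints),
        order=ORDER_NAMES.get(order_num, f"order{order_num}"),
    )


def contrast_score(
    cells: pd.DataFrame,
    freq_order: int | str = "cubic",
    ssd_weights: tuple[float, ...] | None = None,
) -> float:
    """Stop-Go x SSD-quadratic x frequency-polynomial composite score.

    ``cells`` must hold the complete 2 x 3 x 9 structure for one participant,
    block and channel (columns trial_type, ssd_level, frequency_hz,
    log_power).  The score is

        sum_cells  mean(cell) * w_stopgo * w_ssd_quad * w_freq

    with w_stopgo = (+1 Stop, -1 Go) and w_ssd_quad = (-1, 2, -1) (the sign
    convention making conflict-specific excess positive).  Returns NaN if any
    cell is missing.
    """
    w_freq = poly_weights(len(FREQ_BINS_HZ), freq_order).as_array()
    # quadratic contrast signed so the medium (conflict) level counts positively
    w_ssd = np.asarray(ssd_weights if ssd_weights is not None else (-1.0, 2.0, -1.0))
    w_tt = {"stop": 1.0, "go": -1.0}
    pivot = cells.pivot_table(
        index=["trial_type", "ssd_level"],
        columns="frequency_hz",
        values="log_power",
        aggfunc="first",
    )
    total = 0.0
    for tt in TRIAL_TYPES:
        for li, lvl in enumerate(SSD_LEVELS):
            if (tt, lvl) not in pivot.index:
                return float("nan")
            row = pivot.loc[(tt, lvl)].reindex(FREQ_BINS_HZ)
            if row.isna().any():
                return float("nan")
            total += w_tt[tt] * w_ssd[li] * float(np.dot(row.to_numpy(), w_freq))
    return total


def one_sample_contrast_test(scores: np.ndarray | pd.Series, effect: str = "") -> TestResult:
    """Single-df within-subject contrast test: F = t^2 on the mean score."""
    x = np.asarray(scores, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 scores")
    sd = float(np.std(x, ddof=1))
    mean = float(np.mean(x))
    if sd == 0:
        return TestResult(effect, 0.0 if mean == 0 else np.inf, (1, n - 1),
                          1.0 if mean == 0 else 0.0, np.sign(mean), degenerate=True)
    t = mean / (sd / np.sqrt(n))
    f = t**2
    p = float(sps.f.sf(f, 1, n - 1))
    return TestResult(effect, float(f), (1, n - 1), p, float(np.sign(mean)))


def group_contrast_anova(
    scores: np.ndarray | pd.Series,
    groups: np.ndarray | pd.Series,
    effect: str = "",
) -> TestResult:
    """One-way between-group ANOVA on per-participant contrast scores."""
    s = np.asarray(scores, dtype=float)
    g = np.asarray(groups)
    keep = np.isfinite(s)
    s, g = s[keep], g[keep]
    labels = pd.unique(g)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [s[g == lab] for lab in labels]
    if any(len(x) < 2 for x in samples):
        raise ValueError("every group needs n >= 2")
    f, p = sps.f_oneway(*samples)
    df = (len(labels) - 1, len(s) - len(labels))
    means = [np.mean(x) for x in samples]
    return TestResult(effect, float(f), df, float(p), float(np.sign(means[0] - np.mean(means))))


def trait_correlations(
    gcsr_table: pd.DataFrame,
    traits: pd.Series,
    trait_name: str = "trait",
) -> pd.DataFrame:
    """Pearson r between GCSR and a trait, per block x frequency.

    ``gcsr_table`` is tidy with columns participant, block, frequency_hz,
    gcsr; ``traits`` maps participant -> score.  Returns r and uncorrected
    two-sided p per (block, frequency); cells where either variable is
    constant yield NaN.
    """
    rows = []
    for (block, f), chunk in gcsr_table.groupby(["block", "frequency_hz"]):
        merged = chunk.set_index("participant")["gcsr"].to_frame().join(
            traits.rename("trait"), how="inner"
        ).dropna()
        if len(merged) < 3 or merged["gcsr"].std() == 0 or merged["trait"].std() == 0:
            r, p = np.nan, np.nan
        else:
            r, p = sps.pearsonr(merged["gcsr"], merged["trait"])
        rows.append(
            dict(trait=trait_name, block=block, frequency_hz=f,
                 r=float(r) if np.isfinite(r) else np.nan,
                 p=float(p) if np.isfinite(p) else np.nan,
                 n=len(merged))
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class StepwiseStep:
    predictor: str
    r: float  # multiple correlation of the model after entry
    f_change: float
    df: tuple[int, int]
    p_value: float


def stepwise_forward(
    predictors: pd.DataFrame,
    response: np.ndarray | pd.Series,
    p_enter: float = 0.05,
) -> list[StepwiseStep]:
    """Classical forward stepwise regression with an F-change entry test.

    At each step the candidate predictor with the largest F-change (nested
    model comparison, df (1, n - k - 1)) enters if its uncorrected p value is
    below ``p_enter``.  There is no removal step.  Returns one record per
    entered predictor; the list may be empty.
    """
    y = np.asarray(response, dtype=float)
    X = predictors.copy()
    keep = np.isfinite(y) & np.isfinite(X.to_numpy()).all(axis=1)
    y, X = y[keep], X.loc[keep]
    n = y.size
    selected: list[str] = []
    steps: list[StepwiseStep] = []

    def rss(cols: list[str]) -> float:
        design = np.column_stack([np.ones(n)] + [X[c].to_numpy() for c in cols])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        return float(resid @ resid)

    rss_current = rss([])
    tss = rss_current
    while tss > 0 and rss_current > 1e-12 * tss:
        remaining = [c for c in X.columns if c not in selected]
        if not remaining:
            break
        k_new = len(selected) + 1
        df2 = n - k_new - 1
        if df2 < 1:
            break
        best = None
        for c in remaining:
            rss_new = rss(selected + [c])
            if rss_new <= 0:
                f_change = np.inf
            else:
                f_change = (rss_current - rss_new) / (rss_new / df2)
            if best is None or f_change > best[1]:
                best = (c, f_change, rss_new)
        c, f_change, rss_new = best
        p = float(sps.f.sf(f_change, 1, df2)) if np.isfinite(f_change) else 0.0
        if p >= p_enter:
            break
        selected.append(c)
        r_multiple = float(np.sqrt(max(0.0, 1.0 - rss_new / tss))) if tss > 0 else 0.0
        steps.append(StepwiseStep(c, r_multiple, float(f_change), (1, df2), p))
        rss_current = rss_new
    return steps


def channel_gradient(gcsr_table: pd.DataFrame, focus: str = "F8") -> pd.DataFrame:
    """Descriptive channel topography: per-channel GCSR means and the
    focus-minus-others gradient, per block.

    Stands in for the omnibus channel-interaction ANOVA: the biomarker's
    localization claim is that the conflict contrast is maximal at F8 and
    falls away toward F7.
    """
    rows = []
    for block, chunk in gcsr_table.groupby("block"):
        means = chunk.groupby("channel")["gcsr"].mean()
        others = means.drop(focus, errors="ignore")
        rows.append(
            dict(
                block=block,
                **{f"mean_{ch}": float(v) for ch, v in means.items()},
                gradient=float(means.get(focus, np.nan) - others.mean())
                if len(others)
                else np.nan,
            )
        )
    return pd.DataFrame(rows)
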