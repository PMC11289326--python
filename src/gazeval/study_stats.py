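"""Inferential layer: paired t-tests, 2x3 repeated-measures ANOVA with partial
eta squared, Pearson / point-biserial correlations, task-load-index scoring,
and z-scored overall accuracy."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import DomainError

__all__ = [
    "TLXResponse",
    "TLX_SCALES",
    "tlx_percent",
    "paired_t",
    "rm_anova_2x3",
    "AnovaEffect",
    "correlate",
    "overall_accuracy_z",
]

log = logging.getLogger(__name__)

TLX_SCALES = ("mental", "physical", "temporal", "performance", "effort", "frustration")


@dataclass(frozen=True)
class TLXResponse:
    """Six workload scales, each recorded as a tick 1..21 on a 21-tick line."""

    mental: int
    physical: int
    temporal: int
    performance: int
    effort: int
    frustration: int

    def __post_init__(self) -> None:
        for name in TLX_SCALES:
            tick = getattr(self, name)
            if not (isinstance(tick, (int, np.integer)) and 1 <= tick <= 21):
                raise DomainError(f"TLX tick for {name!r} must be an integer in [1, 21]")


def tlx_percent(response: TLXResponse) -> dict[str, float]:
    """Convert ticks to 0-100% scores: percent = (tick - 1) / 20 * 100."""
    return {
        name: (getattr(response, name) - 1) / 20.0 * 100.0 for name in TLX_SCALES
    }


def paired_t(a, b) -> tuple[float, int, float]:
    """Paired-samples t-test with pairwise deletion of missing pairs.

    Returns ``(t, df, p)`` with two-sided p and ``df = n - 1``.  Differences
    with zero variance are a degenerate case and raise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DomainError("paired_t requires equal-length inputs")
    keep = np.isfinite(a) & np.isfinite(b)
    d = a[keep] - b[keep]
    n = d.size
    if n < 2:
        raise DomainError("paired_t requires at least 2 complete pairs")
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        raise DomainError("zero variance of paired differences (degenerate t-test)")
    t = float(np.mean(d)) / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return t, df, p


@dataclass(frozen=True)
class AnovaEffect:
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float


def rm_anova_2x3(data: pd.DataFrame) -> dict[str, AnovaEffect]:
    """Two-way fully repeated-measures ANOVA (factors A and B, within subjects).

    ``data`` is long format with columns ``participant``, ``A``, ``B``,
    ``value``.  Participants with any missing cell are dropped (listwise
    deletion).  Each effect is tested against its own effect-by-subject error
    term; partial eta squared is ``SS_effect / (SS_effect + SS_error)``.  No
    sphericity correction is applied.
    """
    required = {"participant", "A", "B", "value"}
    if not required.issubset(data.columns):
        raise DomainError(f"rm_anova_2x3 requires columns {sorted(required)}")
    df = data.dropna(subset=["value"])
    a_levels = sorted(df["A"].unique())
    b_levels = sorted(df["B"].unique())
    a, b = len(a_levels), len(b_levels)
    cell = df.pivot_table(
        index="participant", columns=["A", "B"], values="value", aggfunc="mean"
    )
    cell = cell.dropna(axis=0, how="any")  # listwise deletion
    n = cell.shape[0]
    if n < 2:
        raise DomainError("rm_anova_2x3 requires at least 2 complete participants")
    # Y[s, i, j]: subject x A x B
    Y = np.empty((n, a, b))
    for i, ai in enumerate(a_levels):
        for j, bj in enumerate(b_levels):
            Y[:, i, j] = cell[(ai, bj)].to_numpy(dtype=float)
    G = Y.mean()
    mA = Y.mean(axis=(0, 2))
    mB = Y.mean(axis=(0, 1))
    mS = Y.mean(axis=(1, 2))
    mAB = Y.mean(axis=0)
    mAS = Y.mean(axis=2)
    mBS = Y.mean(axis=1)
    ss_a = n * b * np.sum((mA - G) ** 2)
    ss_b = n * a * np.sum((mB - G) ** 2)
    ss_s = a * b * np.sum((mS - G) ** 2)
    ss_ab = n * np.sum((mAB - mA[:, None] - mB[None, :] + G) ** 2)
    ss_as = b * np.sum((mAS - mA[None, :] - mS[:, None] + G) ** 2)
    ss_bs = a * np.sum((mBS - mB[None, :] - mS[:, None] + G) ** 2)
    ss_total = np.sum((Y - G) ** 2)
    ss_abs = ss_total - (ss_a + ss_b + ss_s + ss_ab + ss_as + ss_bs)
    out: dict[str, AnovaEffect] = {}
    for name, ss_eff, df1, ss_err, df2 in (
        ("A", ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        ("B", ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        ("A*B", ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1)),
    ):
        if ss_err <= 0:
            F = 0.0 if ss_eff == 0 else np.inf
        else:
            F = (ss_eff / df1) / (ss_err / df2)
        p = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
        pes = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        out[name] = AnovaEffect(F=float(F), df1=df1, df2=df2, p=p, partial_eta_sq=float(pes))
    return out


def correlate(x, y) -> tuple[float, float]:
    """Pearson correlation with two-sided p; pairwise deletion of missing pairs.

    With a binary ``x`` this is the point-biserial correlation.  Constant input
    is a domain error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DomainError("correlate requires equal-length inputs")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise DomainError("correlate requires at least 3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DomainError("correlate requires non-constant inputs")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def overall_accuracy_z(accuracies: pd.DataFrame) -> pd.Series:
    """Per-participant overall accuracy: z-score within each condition column
    (sample SD, n-1), then average each participant's available z-scores.

    Zero-variance conditions are skipped with a warning; a participant missing
    a condition is averaged over the remaining ones.
    """
    if accuracies.shape[0] < 2:
        raise DomainError("overall_accuracy_z requires at least 2 participants")
    zcols = {}
    for col in accuracies.columns:
        vals = accuracies[col].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        if np.count_nonzero(ok) < 2:
            log.warning("condition %r has <2 observations; skipped", col)
            continue
        sd = np.std(vals[ok], ddof=1)
        if sd == 0:
            log.warning("condition %r has zero variance; skipped", col)
            continue
        z = np.full(vals.shape, np.nan)
        z[ok] = (vals[ok] - vals[ok].mean()) / sd
        zcols[col] = z
    if not zcols:
        raise DomainError("no usable conditions for z-scoring")
    zdf = pd.DataFrame(zcols, index=accuracies.index)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return zdf.mean(axis=1, skipna=True)
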