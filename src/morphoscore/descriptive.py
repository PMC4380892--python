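"""Five-number summaries and normality screening per parameter and outcome group.

Morphokinetic timings are mostly skewed, so the cohort is described by
median/quartiles/range rather than mean/sd.  Normality is screened with two
tests — Kolmogorov–Smirnov with the Lilliefors correction (estimated mean and
sd) and Shapiro–Wilk — and a group/parameter cell is called normal only when
*both* tests fail to reject at the 5 % level, the conservative reading of a
two-test screen with a single verdict.

Quantiles everywhere in this package use linear interpolation between order
statistics (the "type 7" convention, numpy's default); the convention is fixed
globally so compartment boundaries, descriptives and score quartiles agree.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateSampleError, InsufficientDataError
from .io import PARAMETERS, MorphokineticTable

ALPHA = 0.05


@dataclass(frozen=True)
class FiveNumberSummary:
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    n: int

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.minimum, self.q1, self.median, self.q3, self.maximum)


@dataclass(frozen=True)
class NormalityResult:
    test_name: str  # "lilliefors" | "shapiro_wilk"
    statistic: float
    p_value: float

    @property
    def normal_at_5pct(self) -> bool:
        return self.p_value >= ALPHA


def five_number_summary(values) -> FiveNumberSummary:
    """Min, Q1, median, Q3, max of the non-missing values (type-7 quantiles)."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 4:
        raise InsufficientDataError(
            f"five-number summary needs >= 4 values, got {v.size}"
        )
    q1, me, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    return FiveNumberSummary(float(v.min()), float(q1), float(me), float(q3),
                             float(v.max()), int(v.size))


# --- Lilliefors --------------------------------------------------------------

def _lilliefors_statistic(x: np.ndarray) -> np.ndarray:
    """Sup-distance between the ECDF and the normal CDF with estimated
    mean/sd.  ``x`` is (m, n): one row per sample; returns (m,) statistics."""
    x = np.sort(x, axis=-1)
    n = x.shape[-1]
    mu = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, ddof=1, keepdims=True)
    z = stats.norm.cdf((x - mu) / sd)
    i = np.arange(1, n + 1)
    d_plus = (i / n - z).max(axis=-1)
    d_minus = (z - (i - 1) / n).max(axis=-1)
    return np.maximum(d_plus, d_minus)


@lru_cache(maxsize=64)
def _lilliefors_null(n: int, replicates: int, seed: int) -> np.ndarray:
    """Sorted Monte-Carlo null distribution of the Lilliefors statistic.

    The null law depends only on n, so the table is computed once per
    (n, replicates, seed) and shared across calls.
    """
    rng = np.random.default_rng(seed)
    # chunked so n * replicates never allocates more than ~4e6 doubles
    chunk = max(1, int(4_000_000 // n))
    out = np.empty(replicates)
    done = 0
    while done < replicates:
        m = min(chunk, replicates - done)
        out[done:done + m] = _lilliefors_statistic(rng.standard_normal((m, n)))
        done += m
    out.sort()
    return out


def lilliefors_test(values, mc_replicates: int = 10_000, seed: int = 0) -> NormalityResult:
    """Kolmogorov–Smirnov test for normality with estimated parameters.

    The p-value comes from a seeded Monte-Carlo null of ``mc_replicates``
    normal samples of the same size, with the add-one correction
    ``p = (1 + #{D* >= D}) / (R + 1)`` so it is never exactly zero.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 5:
        raise InsufficientDataError(f"Lilliefors test needs n >= 5, got {v.size}")
    if np.ptp(v) == 0:
        raise DegenerateSampleError("Lilliefors test: sample has zero variance")
    d = float(_lilliefors_statistic(v[None, :])[0])
    null = _lilliefors_null(v.size, int(mc_replicates), int(seed))
    n_ge = null.size - np.searchsorted(null, d, side="left")
    p = (1.0 + n_ge) / (null.size + 1.0)
    return NormalityResult("lilliefors", d, float(p))


def shapiro_wilk_test(values) -> NormalityResult:
    """Shapiro–Wilk W with Royston's approximation (scipy implementation)."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if not 5 <= v.size <= 5000:
        raise InsufficientDataError(
            f"Shapiro-Wilk supported for 5 <= n <= 5000, got {v.size}"
        )
    if np.ptp(v) == 0:
        raise DegenerateSampleError("Shapiro-Wilk: sample has zero variance")
    w, p = stats.shapiro(v)
    return NormalityResult("shapiro_wilk", float(w), float(p))


# --- per-group report --------------------------------------------------------

GROUP_LABELS = {1: "developed", 0: "not_developed"}


def group_descriptives(
    table: MorphokineticTable,
    mc_replicates: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Five-number summary and normality verdict per (parameter, outcome group).

    One row per parameter in {t2..t5, cc2, s2} per group in
    {developed, not_developed}.  A group empty (or too small) for some
    parameter yields a row with missing statistics rather than an exception.
    The ``normal`` column is True only when both the Lilliefors and the
    Shapiro–Wilk test have p >= 0.05.
    """
    lab = table.labeled()
    rows = []
    for parameter in PARAMETERS:
        for outcome, group in GROUP_LABELS.items():
            v = lab.loc[lab["blastocyst"] == outcome, parameter].to_numpy(dtype=float)
            v = v[~np.isnan(v)]
            row: dict = {"parameter": parameter, "group": group, "n": int(v.size)}
            try:
                s = five_number_summary(v)
                row.update(min=s.minimum, q1=s.q1, median=s.median, q3=s.q3, max=s.maximum)
            except InsufficientDataError:
                row.update(min=np.nan, q1=np.nan, median=np.nan, q3=np.nan, max=np.nan)
            try:
                lf = lilliefors_test(v, mc_replicates=mc_replicates, seed=seed)
                sw = shapiro_wilk_test(v)
                row.update(
                    lilliefors_stat=lf.statistic, lilliefors_p=lf.p_value,
                    shapiro_stat=sw.statistic, shapiro_p=sw.p_value,
                    normal=bool(lf.normal_at_5pct and sw.normal_at_5pct),
                )
            except (InsufficientDataError, DegenerateSampleError):
                row.update(
                    lilliefors_stat=np.nan, lilliefors_p=np.nan,
                    shapiro_stat=np.nan, shapiro_p=np.nan, normal=None,
                )
            rows.append(row)
    return pd.DataFrame(rows)
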