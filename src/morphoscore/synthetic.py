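"""Synthetic morphokinetic cohorts with the statistical structure the
pipeline assumes.

No raw per-embryo dataset accompanies the reference cohort, so the generator
reconstructs one from its published summaries: per-outcome-group five-number
summaries of the division times t2..t5, the overall 36.11 % blastocyst-
formation rate, and heavy missingness of t5 among embryos that never reached
five cells.  Each group's marginal of each division time is the piecewise-
linear quantile function through the five summary knots (truncated at the
observed min/max); the joint law couples the four times with a latent
Gaussian chain.

Three departures from a textbook copula draw keep the generator faithful to
its own targets:

* **Stratified marginals.**  Within each group, the latent column ranks are
  mapped onto a jittered uniform grid (rank + U)/m, so each marginal is a
  stratified sample of its quantile function and sample quartiles match the
  targets to O(1/m) instead of O(1/sqrt(m)) — the long upper-tail segments of
  the summaries would otherwise leave >1 h of noise in the sample quartiles.
  The copula's rank structure is untouched.
* **High adjacent correlations with a min-clamp repair.**  Division times are
  near-comonotone in real embryos (the synchrony interval t4 - t3 is tiny
  relative to the spread of either time), and the group marginals overlap
  heavily, so default adjacent rank correlations are (t2-t3: 0.90,
  t3-t4: 0.995, t4-t5: 0.95).  The rare residual order violations are
  repaired by clamping each time down to its successor
  (t_k := min(t_k, t_{k+1})), which leaves t5 untouched, confines the
  perturbation to the overlapping tails, and incidentally produces a point
  mass at s2 = 0 — as in real imaging data, where more than a quarter of
  embryos divide from three to four cells within one imaging interval.
* **Stratified t5 blanking.**  Missing t5 is applied to the non-developed
  group by blanking every k-th record in t5 rank order rather than by
  i.i.d. coin flips: the published t5 summaries describe the *observed*
  values, and Bernoulli blanking would re-inject large quantile noise into
  the surviving subsample.

The relative parameters cc2 = t3 - t2 and s2 = t4 - t3 are derived from the
generated times; their marginals are therefore implied by the joint law of
the absolute times and are *not* calibrated to the published cc2/s2 rows
(no copula on absolute times can match both at once).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidSpecError
from .io import MorphokineticTable, derive_relative_parameters

PROBS = np.array([0.0, 0.25, 0.5, 0.75, 1.0])

#: reference per-group five-number summaries (hours): min, Q1, median, Q3, max
REFERENCE_SUMMARIES = {
    "developed": {
        "t2": (19.7, 24.4, 26.2, 28.6, 40.1),
        "t3": (23.2, 34.7, 37.8, 40.3, 50.4),
        "t4": (25.8, 36.0, 39.2, 42.3, 57.6),
        "t5": (32.8, 48.1, 53.6, 58.1, 78.0),
        "cc2": (0.0, 10.3, 11.6, 12.5, 17.3),
        "s2": (0.00, 0.00, 0.67, 2.00, 15.9),
    },
    "not_developed": {
        "t2": (19.8, 26.7, 30.1, 34.5, 57.4),
        "t3": (23.8, 34.0, 38.5, 46.2, 84.2),
        "t4": (26.2, 36.6, 42.2, 50.4, 84.2),
        "t5": (33.7, 42.8, 50.3, 58.5, 104.7),
        "cc2": (0.0, 1.8, 10.7, 13.7, 55.4),
        "s2": (0.00, 0.00, 0.82, 8.00, 40.01),
    },
}

#: overall blastocyst-formation probability of the reference cohort
REFERENCE_BLASTOCYST_RATE = 0.3611

#: fraction of non-developed embryos with no recorded fifth-cell division,
#: implied by the reference cohort's complete-case accounting (191 of 276)
REFERENCE_P_MISSING_T5 = 0.69

#: mean embryos per patient in the reference cohort (432 / 77)
REFERENCE_EMBRYOS_PER_PATIENT = 5.61

_ABSOLUTE = ("t2", "t3", "t4", "t5")


@dataclass(frozen=True)
class QuantileFunction:
    """Piecewise-linear quantile function through five summary knots."""

    knots: tuple[float, float, float, float, float]

    def __post_init__(self):
        k = np.asarray(self.knots, dtype=float)
        if k.size != 5:
            raise InvalidSpecError(f"need 5 knots, got {k.size}")
        if np.any(np.diff(k) < 0):
            raise InvalidSpecError(f"non-monotone five-number summary: {self.knots}")

    def __call__(self, p) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        return np.interp(p, PROBS, np.asarray(self.knots, dtype=float))


def quantile_function_from_summary(summary) -> QuantileFunction:
    """Quantile function for a five-number summary (tuple or
    :class:`~morphoscore.descriptive.FiveNumberSummary`)."""
    if hasattr(summary, "as_tuple"):
        summary = summary.as_tuple()
    return QuantileFunction(tuple(float(x) for x in summary))


@dataclass(frozen=True)
class GroupDistributionSpec:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the reference cohort: the per-group five-number
    summaries, a 36.11 % blastocyst-formation rate, and t5 missing for 69 %
    of non-developed embryos.  ``adjacent_rank_corr`` sets the latent
    Gaussian-chain correlations between (t2, t3), (t3, t4) and (t4, t5).
    """

    developed: dict = field(default_factory=lambda: dict(REFERENCE_SUMMARIES["developed"]))
    not_developed: dict = field(default_factory=lambda: dict(REFERENCE_SUMMARIES["not_developed"]))
    adjacent_rank_corr: tuple[float, float, float] = (0.90, 0.995, 0.95)
    p_blastocyst: float = REFERENCE_BLASTOCYST_RATE
    p_missing_t5: float = REFERENCE_P_MISSING_T5
    embryos_per_patient: float = REFERENCE_EMBRYOS_PER_PATIENT

    def __post_init__(self):
        for prob, name in ((self.p_blastocyst, "p_blastocyst"),
                           (self.p_missing_t5, "p_missing_t5")):
            if not 0.0 <= prob <= 1.0:
                raise InvalidSpecError(f"{name} must lie in [0, 1], got {prob}")
        for r in self.adjacent_rank_corr:
            if not -1.0 < r < 1.0:
                raise InvalidSpecError(f"adjacent_rank_corr must lie in (-1, 1), got {r}")
        for group in (self.developed, self.not_developed):
            for p in _ABSOLUTE:
                if p not in group:
                    raise InvalidSpecError(f"five-number targets missing for {p}")
                quantile_function_from_summary(group[p])  # validates monotonicity

    def quantile_functions(self, group: str) -> dict[str, QuantileFunction]:
        targets = self.developed if group == "developed" else self.not_developed
        return {p: quantile_function_from_summary(targets[p]) for p in _ABSOLUTE}


def _stratified_uniforms(z: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Map each latent column's ranks onto a jittered uniform grid.

    Preserves the copula (rank structure) of ``z`` exactly while making each
    marginal a stratified uniform sample.
    """
    m = z.shape[0]
    u = np.empty_like(z)
    for j in range(z.shape[1]):
        ranks = stats.rankdata(z[:, j], method="ordinal") - 1
        u[:, j] = (ranks + rng.uniform(size=m)) / m
    return u


def _draw_group_times(
    spec: GroupDistributionSpec, group: str, m: int, rng: np.random.Generator
) -> np.ndarray:
    """(m, 4) monotone division times for one outcome group."""
    qfs = spec.quantile_functions(group)
    z = np.empty((m, 4))
    z[:, 0] = rng.standard_normal(m)
    for k, r in enumerate(spec.adjacent_rank_corr):
        z[:, k + 1] = r * z[:, k] + np.sqrt(1.0 - r * r) * rng.standard_normal(m)
    u = _stratified_uniforms(z, rng)
    t = np.column_stack([qfs[p](u[:, i]) for i, p in enumerate(_ABSOLUTE)])
    # backward min-clamp: rare order violations are pulled down to the
    # successor time; t5 is never modified
    for k in (2, 1, 0):
        t[:, k] = np.minimum(t[:, k], t[:, k + 1])
    return t


def _stratified_missing_mask(t5: np.ndarray, p_missing: float,
                             rng: np.random.Generator) -> np.ndarray:
    """Blank ~p_missing of the values, evenly spaced in rank order, so the
    surviving values remain a stratified sample of the marginal."""
    m = t5.size
    n_keep = m - int(round(p_missing * m))
    mask = np.ones(m, dtype=bool)  # True = missing
    if n_keep <= 0:
        return mask
    order = np.argsort(t5, kind="stable")
    phase = rng.uniform()
    keep_ranks = np.unique(np.floor((np.arange(n_keep) + phase) * m / n_keep).astype(int))
    keep_ranks = keep_ranks[keep_ranks < m]
    mask[order[keep_ranks]] = False
    return mask


def simulate_cohort(spec: GroupDistributionSpec, n: int, seed: int) -> MorphokineticTable:
    """Draw a labeled synthetic cohort of ``n`` embryos.

    Outcomes are Bernoulli(``p_blastocyst``); division times come from the
    group-conditional quantile functions coupled by the latent chain (see the
    module docstring); t5 is blanked for ``p_missing_t5`` of non-developed
    embryos; cc2/s2 are derived.  A fixed seed yields an identical table.
    """
    if n < 1:
        raise InvalidSpecError(f"cohort size must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < spec.p_blastocyst).astype(float)

    times = np.full((n, 4), np.nan)
    for group, outcome in (("developed", 1.0), ("not_developed", 0.0)):
        idx = np.flatnonzero(y == outcome)
        if idx.size:
            times[idx] = _draw_group_times(spec, group, idx.size, rng)

    nodev = np.flatnonzero(y == 0.0)
    if nodev.size and spec.p_missing_t5 > 0:
        miss = _stratified_missing_mask(times[nodev, 3], spec.p_missing_t5, rng)
        times[nodev[miss], 3] = np.nan

    n_patients = max(1, int(round(n / spec.embryos_per_patient)))
    width = len(str(n))
    df = pd.DataFrame({
        "embryo_id": [f"E{i+1:0{width}d}" for i in range(n)],
        "patient_id": [f"P{(i * n_patients) // n + 1:03d}" for i in range(n)],
        "t2": times[:, 0], "t3": times[:, 1], "t4": times[:, 2], "t5": times[:, 3],
        "blastocyst": y,
    })
    table = MorphokineticTable(df, provenance=f"synthetic(seed={seed}, n={n})")
    return derive_relative_parameters(table)


def simulate_from_logistic(
    true_betas: dict[str, float],
    score_distribution: dict[str, tuple[float, float, float]],
    n: int,
    seed: int,
    intercept: float = 0.0,
) -> pd.DataFrame:
    """Scored, labeled table drawn from a known logistic model.

    ``true_betas`` maps score column names to log-odds per unit;
    ``score_distribution`` maps the same names to the category probabilities
    of the 0/1/2 levels.  Used as the oracle input for parameter-recovery
    tests.
    """
    if n < 1:
        raise InvalidSpecError(f"n must be >= 1, got {n}")
    names = list(true_betas)
    if set(score_distribution) != set(names):
        raise InvalidSpecError("score_distribution keys must match true_betas keys")
    rng = np.random.default_rng(seed)
    cols = {}
    eta = np.full(n, float(intercept))
    for name in names:
        probs = np.asarray(score_distribution[name], dtype=float)
        if probs.size != 3 or np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise InvalidSpecError(
                f"score_distribution[{name!r}] must be 3 non-negative "
                f"probabilities summing to 1"
            )
        s = rng.choice(3, size=n, p=probs).astype(float)
        cols[name] = s
        eta += true_betas[name] * s
    p = 1.0 / (1.0 + np.exp(-eta))
    cols["blastocyst"] = (rng.random(n) < p).astype(float)
    return pd.DataFrame(cols)
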