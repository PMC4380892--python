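"""Quartile compartmentalisation and rate-ranked individual scores.

Each morphokinetic parameter is split into four compartments C1–C4 at the
first quartile, median and third quartile of the *pooled* population (both
outcome groups together).  Intervals are left-closed, right-open:

    C1 = (-inf, Q1)   C2 = [Q1, Me)   C3 = [Me, Q3)   C4 = [Q3, +inf)

so at apply time every real value falls in exactly one compartment, including
values outside the fitting range.  When a boundary collapses (e.g. more than a
quarter of the values sit at the minimum, as happens for the synchrony
interval s2 where Min = Q1 = 0) the zero-width compartment is structurally
merged with its right neighbour before any rate is computed.

The per-compartment blastocyst-formation rates are then ranked into a
three-level individual score 0/1/2: with four effective compartments, the two
compartments with the nearest rates share a level — except that pairing the
two middle compartments C2/C3 is forbidden (any other pair, adjacent or not,
is admissible) — and the three resulting levels are ranked by rate; with three
effective compartments (after a structural merge) the compartments are ranked
directly.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import (
    AmbiguousRankingError,
    DegenerateCompartmentError,
    InsufficientDataError,
    InsufficientVariationError,
)
from .io import PARAMETERS, MorphokineticTable

#: the structurally forbidden score pairing: the two middle compartments
FORBIDDEN_PAIR = ("C2", "C3")

#: numerical tolerance for a boundary coinciding with another edge
_BOUNDARY_TOL = 1e-12


@dataclass(frozen=True)
class CompartmentScheme:
    """Quartile boundaries of one parameter plus merged-compartment bookkeeping.

    ``merged`` lists adjacent base-compartment pairs fused structurally at fit
    time (zero-width interval), e.g. ``[("C1", "C2")]`` for s2-like data.
    """

    parameter: str
    boundaries: tuple[float, float, float]  # (q1, median, q3)
    merged: tuple[tuple[str, str], ...] = ()
    n_fit: int = 0

    def __post_init__(self):
        q1, me, q3 = self.boundaries
        if not (q1 <= me <= q3):
            raise InsufficientVariationError(
                f"{self.parameter}: non-monotone boundaries {self.boundaries}"
            )

    @property
    def effective_labels(self) -> tuple[str, ...]:
        """Compartment labels after structural merging, left to right."""
        labels = ["C1", "C2", "C3", "C4"]
        for a, b in self.merged:
            ia = next(i for i, l in enumerate(labels) if a in l.split("+"))
            ib = next(i for i, l in enumerate(labels) if b in l.split("+"))
            if abs(ia - ib) != 1:
                raise InsufficientVariationError(
                    f"{self.parameter}: merge {a}+{b} is not adjacent"
                )
            lo, hi = min(ia, ib), max(ia, ib)
            labels[lo:hi + 1] = [labels[lo] + "+" + labels[hi]]
        if len(labels) < 3:
            raise InsufficientVariationError(
                f"{self.parameter}: fewer than 3 effective compartments after merging"
            )
        return tuple(labels)

    @property
    def effective_edges(self) -> np.ndarray:
        """Interior edges of the effective compartments (ascending)."""
        q1, me, q3 = self.boundaries
        base_edges = {("C1", "C2"): q1, ("C2", "C3"): me, ("C3", "C4"): q3}
        labels = self.effective_labels
        edges = []
        for left, right in zip(labels[:-1], labels[1:]):
            a = left.split("+")[-1]
            b = right.split("+")[0]
            edges.append(base_edges[(a, b)])
        return np.asarray(edges, dtype=float)


def build_compartment_scheme(table: MorphokineticTable, parameter: str) -> CompartmentScheme:
    """Fit the C1–C4 boundaries for one parameter on the pooled population.

    Pooling uses every record with a non-missing value for the parameter,
    regardless of outcome or label.  A boundary that coincides with the sample
    minimum (or another boundary) produces a structural merge of the
    zero-width compartment with its right neighbour; if fewer than three
    effective compartments remain, the parameter carries too little variation.
    """
    if parameter not in PARAMETERS:
        raise KeyError(f"unknown parameter {parameter!r}")
    v = table.values(parameter)
    if v.size < 8:
        raise InsufficientDataError(
            f"{parameter}: compartment scheme needs >= 8 values, got {v.size}"
        )
    if np.ptp(v) == 0:
        raise InsufficientVariationError(f"{parameter}: all values identical")
    q1, me, q3 = (float(q) for q in np.quantile(v, [0.25, 0.5, 0.75]))

    merged: list[tuple[str, str]] = []
    vmin = float(v.min())
    # left-to-right scan for zero-width compartments: [min,q1), [q1,me), [me,q3)
    if q1 - vmin <= _BOUNDARY_TOL:
        merged.append(("C1", "C2"))
    if me - q1 <= _BOUNDARY_TOL:
        merged.append(("C2", "C3"))
    if q3 - me <= _BOUNDARY_TOL:
        merged.append(("C3", "C4"))
    scheme = CompartmentScheme(parameter, (q1, me, q3), tuple(merged), n_fit=int(v.size))
    scheme.effective_labels  # validates >= 3 effective compartments
    return scheme


def assign_compartment(value: float, scheme: CompartmentScheme) -> str:
    """Effective compartment label for one value (left-closed convention)."""
    if value is None or np.isnan(value):
        raise ValueError("cannot assign a missing value to a compartment")
    return scheme.effective_labels[int(np.searchsorted(scheme.effective_edges, value, side="right"))]


def assign_compartments(values: np.ndarray, scheme: CompartmentScheme) -> np.ndarray:
    """Vectorised :func:`assign_compartment`; NaN maps to ``None``."""
    values = np.asarray(values, dtype=float)
    idx = np.searchsorted(scheme.effective_edges, values, side="right")
    labels = np.array(scheme.effective_labels, dtype=object)
    out = np.where(np.isnan(values), None, labels[np.clip(idx, 0, len(labels) - 1)])
    return out


@dataclass(frozen=True)
class CompartmentRates:
    """Observed blastocyst-formation fraction per effective compartment."""

    parameter: str
    labels: tuple[str, ...]
    totals: tuple[int, ...]
    developed: tuple[int, ...]

    @property
    def rates(self) -> tuple[float, ...]:
        return tuple(d / t for d, t in zip(self.developed, self.totals))


def compartment_rates(table: MorphokineticTable, scheme: CompartmentScheme) -> CompartmentRates:
    """Development fraction per effective compartment, on labeled records
    non-missing for the parameter."""
    lab = table.labeled()
    v = lab[scheme.parameter].to_numpy(dtype=float)
    keep = ~np.isnan(v)
    v, y = v[keep], lab["blastocyst"].to_numpy(dtype=float)[keep]
    comp = assign_compartments(v, scheme)
    totals, developed = [], []
    for label in scheme.effective_labels:
        m = comp == label
        if not m.any():
            raise DegenerateCompartmentError(
                f"{scheme.parameter}: compartment {label} is empty; "
                f"consider a structural merge"
            )
        totals.append(int(m.sum()))
        developed.append(int(y[m].sum()))
    return CompartmentRates(scheme.parameter, scheme.effective_labels,
                            tuple(totals), tuple(developed))


@dataclass(frozen=True)
class ScoreMap:
    """Compartment -> individual score (0/1/2) with the observed rates.

    ``paired`` names the two effective compartments sharing a score level
    (rate-based pairing with four compartments), or ``None`` after a
    structural merge left only three.
    """

    parameter: str
    labels: tuple[str, ...]
    rates: tuple[float, ...]
    scores: tuple[int, ...]
    paired: tuple[str, str] | None = None

    @property
    def score_of(self) -> dict[str, int]:
        return dict(zip(self.labels, self.scores))

    @property
    def rate_of(self) -> dict[str, float]:
        return dict(zip(self.labels, self.rates))


def assign_individual_scores(
    rates,
    labels: tuple[str, ...] | None = None,
    parameter: str = "",
    forbidden_pair: tuple[str, str] = FORBIDDEN_PAIR,
) -> ScoreMap:
    """Rank per-compartment rates into the 0/1/2 individual score.

    With four effective compartments: among all pairs *except* the forbidden
    middle pair (C2, C3) — non-adjacent pairs are admissible — fuse the pair
    with the smallest absolute rate difference into one level (equal
    differences prefer the pair containing the lower-indexed compartment),
    rank the three levels by rate descending (a fused level ranks by the mean
    of its two rates) and assign 2/1/0; both members of the fused pair share
    their level's score.  With three effective compartments the ranking is
    direct.  A three-way tie in rates is not deterministically rankable and
    raises :class:`AmbiguousRankingError`.
    """
    rates = tuple(float(r) for r in rates)
    if labels is None:
        labels = ("C1", "C2", "C3") if len(rates) == 3 else ("C1", "C2", "C3", "C4")
    if len(labels) != len(rates):
        raise ValueError("labels and rates differ in length")
    if len(rates) not in (3, 4):
        raise ValueError(f"need 3 or 4 effective compartments, got {len(rates)}")
    if len(set(rates)) <= len(rates) - 2:
        raise AmbiguousRankingError(
            f"{parameter or 'rates'}: three or more compartments share a rate; "
            f"ranking is ambiguous"
        )

    paired: tuple[str, str] | None = None
    if len(rates) == 4:
        forbidden = {labels.index(forbidden_pair[0]), labels.index(forbidden_pair[1])}
        candidates = [
            (abs(rates[i] - rates[j]), i, j)
            for i, j in combinations(range(4), 2)
            if {i, j} != forbidden
        ]
        _, i, j = min(candidates)  # ties prefer the lower-indexed pair
        paired = (labels[i], labels[j])
        levels = [((rates[i] + rates[j]) / 2.0, (i, j))] + [
            (rates[k], (k,)) for k in range(4) if k not in (i, j)
        ]
    else:
        levels = [(r, (k,)) for k, r in enumerate(rates)]

    # rank levels by rate descending; equal level rates break ties toward the
    # lower-indexed compartment (deterministic, documented)
    levels.sort(key=lambda lv: (-lv[0], min(lv[1])))
    scores = [0] * len(rates)
    for rank, (_, members) in enumerate(levels):
        for k in members:
            scores[k] = 2 - rank
    return ScoreMap(parameter, tuple(labels), rates, tuple(scores), paired)


def build_score_map(table: MorphokineticTable, scheme: CompartmentScheme) -> ScoreMap:
    """Convenience: observed rates + score assignment for a fitted scheme."""
    cr = compartment_rates(table, scheme)
    return assign_individual_scores(cr.rates, cr.labels, parameter=scheme.parameter)


def score_embryos(
    table: MorphokineticTable,
    schemes_and_maps: dict[str, tuple[CompartmentScheme, ScoreMap]],
) -> pd.DataFrame:
    """Annotate every record with the individual score of each parameter.

    Returns the table's frame plus one ``s_<parameter>`` column per fitted
    parameter; a missing parameter value yields a missing score.
    """
    df = table.frame
    for parameter, (scheme, smap) in schemes_and_maps.items():
        v = df[parameter].to_numpy(dtype=float)
        comp = assign_compartments(v, scheme)
        score_of = smap.score_of
        df[f"s_{parameter}"] = [
            np.nan if c is None else float(score_of[c]) for c in comp
        ]
    return df


def score_table_report(maps: dict[str, ScoreMap],
                       rates: dict[str, CompartmentRates]) -> pd.DataFrame:
    """Tabular mirror of the fitted scoring scheme: one row per parameter per
    effective compartment with n, observed rate (%) and assigned score."""
    rows = []
    for parameter, smap in maps.items():
        cr = rates[parameter]
        for label, total, dev, rate, score in zip(
            cr.labels, cr.totals, cr.developed, smap.rates, smap.scores
        ):
            rows.append({
                "parameter": parameter, "compartment": label, "n": total,
                "developed": dev, "rate_pct": round(100 * rate, 1), "score": score,
            })
    return pd.DataFrame(rows)
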