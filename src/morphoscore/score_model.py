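"""The frozen Sc scoring model, its serialization, and the group statistics.

Sc is the odds-ratio-weighted sum of the retained individual scores,

    Sc = sum_k  s_k * OR_k

with the per-unit odds ratios taken from the multivariate logistic model at
full floating precision (printed 3-decimal ORs are a reporting format only —
carrying rounded weights would shift the score's quartile boundaries).  The
model artifact freezes everything needed to score a new embryo: the retained
parameters, their weights, the compartment schemes and score maps, the
Sc-quartile boundaries of the derivation cohort and the chosen cut-off.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import IO, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .compartments import CompartmentScheme, ScoreMap
from .errors import (
    DegenerateQuarterError,
    DegenerateTableError,
    IncompleteRecordError,
    InsufficientDataError,
    ModelValidationError,
    SchemaVersionError,
)

SCHEMA = "morphoscore-model-v1"


@dataclass(frozen=True)
class BlastFormationModel:
    """Frozen, serializable blastocyst-formation scoring model."""

    parameters: tuple[str, ...]              # retained individual-score names, ordered
    weights: dict                            # parameter -> OR (full precision)
    schemes: dict                            # parameter -> CompartmentScheme
    score_maps: dict                         # parameter -> ScoreMap
    sc_quartiles: tuple[float, float, float] | None = None  # (q1, me, q3) of Sc at fit
    cutoff: float | None = None
    fit_metadata: dict = field(default_factory=dict)
    version: str = SCHEMA

    def __post_init__(self):
        problems = []
        for p in self.parameters:
            if p not in self.weights:
                problems.append(f"weight missing for {p}")
            elif not self.weights[p] > 0:
                problems.append(f"non-positive weight for {p}")
            if p not in self.schemes:
                problems.append(f"scheme missing for {p}")
            if p not in self.score_maps:
                problems.append(f"score map missing for {p}")
        if problems:
            raise ModelValidationError("; ".join(problems))

    @property
    def max_sc(self) -> float:
        return 2.0 * sum(self.weights[p] for p in self.parameters)


def compute_sc(model: BlastFormationModel, scores: Mapping[str, float]) -> float:
    """Sc = sum of individual scores times their odds-ratio weights.

    Every model parameter must be present and non-missing in ``scores``;
    otherwise :class:`IncompleteRecordError` names the offender.
    """
    total = 0.0
    for p in model.parameters:
        s = scores.get(p)
        if s is None or (isinstance(s, float) and math.isnan(s)):
            raise IncompleteRecordError(f"missing required score {p!r}")
        total += float(s) * float(model.weights[p])
    return total


# --- group-comparison statistics ---------------------------------------------

def chi_square_independence(counts) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence on a 2 x k count table.

    No continuity correction; df = k - 1; upper-tail p.  An all-zero row or
    column makes the table degenerate.
    """
    t = np.asarray(counts, dtype=float)
    if t.ndim != 2:
        raise ValueError("counts must be a 2-D table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DegenerateTableError("contingency table has an all-zero row or column")
    stat, p, df, expected = stats.chi2_contingency(t, correction=False)
    if (expected <= 0).any():
        raise DegenerateTableError("expected count of zero in contingency table")
    return float(stat), int(df), float(p)


def mann_whitney_u(group_a, group_b, exact_max_n: int = 12):
    """Mann–Whitney U with midranks; exact two-sided p for tiny samples.

    Returns ``(U, z, p)`` where U counts pairs in which ``group_a`` exceeds
    ``group_b`` (ties count half).  For ``n_a + n_b <= exact_max_n`` the
    p-value enumerates all label arrangements and doubles the smaller tail
    (capped at 1); otherwise it uses the normal approximation with
    tie-corrected variance and a 0.5 continuity correction.  Identical
    samples give z = 0, p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("Mann-Whitney requires both groups non-empty")
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u = float(ranks[:na].sum() - na * (na + 1) / 2.0)

    mu = na * nb / 2.0
    n = na + nb
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var = na * nb / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u, 0.0, 1.0
    diff = u - mu
    cc = 0.5 if diff != 0 else 0.0
    z = (diff - math.copysign(cc, diff)) / math.sqrt(var)

    if n <= exact_max_n:
        lo = hi = total = 0
        for idx in combinations(range(n), na):
            u_perm = ranks[list(idx)].sum() - na * (na + 1) / 2.0
            total += 1
            if u_perm <= u + 1e-12:
                lo += 1
            if u_perm >= u - 1e-12:
                hi += 1
        p = min(1.0, 2.0 * min(lo, hi) / total)
    else:
        p = float(2.0 * stats.norm.sf(abs(z)))
    return u, float(z), float(p)


# --- Sc quartile report ------------------------------------------------------

QUARTER_LABELS = ("C1", "C2", "C3", "C4")


@dataclass(frozen=True)
class ScQuartileReport:
    """Blastocyst-formation rates across the four Sc quarters.

    ``boundaries`` are the (Q1, Me, Q3) of Sc used to cut the quarters
    (left-closed, right-open, consistent with the compartment convention);
    ``chi2``/``df``/``p`` test independence of formation and quarter on the
    2 x 4 table.
    """

    boundaries: tuple[float, float, float]
    n: tuple[int, ...]
    developed: tuple[int, ...]
    chi2: float
    df: int
    p_value: float

    @property
    def rates(self) -> tuple[float, ...]:
        return tuple(d / t for d, t in zip(self.developed, self.n))

    @property
    def rates_pct(self) -> tuple[float, ...]:
        """Rates as one-decimal percentages (the printed report format)."""
        return tuple(round(100.0 * r, 1) for r in self.rates)

    def as_frame(self) -> pd.DataFrame:
        q1, me, q3 = self.boundaries
        ranges = (
            f"Sc < {q1:g}", f"{q1:g} <= Sc < {me:g}",
            f"{me:g} <= Sc < {q3:g}", f"Sc >= {q3:g}",
        )
        return pd.DataFrame({
            "quarter": QUARTER_LABELS, "range": ranges, "n": self.n,
            "developed": self.developed, "rate_pct": self.rates_pct,
        })


def quartile_report_from_counts(totals, developed,
                                boundaries=(float("nan"),) * 3) -> ScQuartileReport:
    """Build the quartile report directly from per-quarter counts."""
    totals = tuple(int(t) for t in totals)
    developed = tuple(int(d) for d in developed)
    if any(t <= 0 for t in totals):
        raise DegenerateQuarterError("every quarter needs at least one record")
    table = np.array([developed, [t - d for t, d in zip(totals, developed)]])
    chi2, df, p = chi_square_independence(table)
    return ScQuartileReport(tuple(boundaries), totals, developed, chi2, df, p)


def sc_quartile_report(
    sc_values,
    labels,
    boundaries: tuple[float, float, float] | None = None,
) -> ScQuartileReport:
    """Quartile the labeled Sc values and test rate differences.

    ``boundaries`` default to the (Q1, Me, Q3) of the supplied Sc values
    (type-7); a frozen model's stored boundaries may be passed instead when
    reporting on a validation cohort.
    """
    sc = np.asarray(sc_values, dtype=float)
    y = np.asarray(labels, dtype=float)
    keep = ~(np.isnan(sc) | np.isnan(y))
    sc, y = sc[keep], y[keep]
    if sc.size < 8:
        raise InsufficientDataError(f"Sc quartile report needs >= 8 labeled values, got {sc.size}")
    if boundaries is None:
        boundaries = tuple(float(q) for q in np.quantile(sc, [0.25, 0.5, 0.75]))
    edges = np.asarray(boundaries, dtype=float)
    quarter = np.searchsorted(edges, sc, side="right")
    totals, developed = [], []
    for k in range(4):
        m = quarter == k
        if not m.any():
            raise DegenerateQuarterError(
                f"Sc quarter {QUARTER_LABELS[k]} holds no records (massive ties?)"
            )
        totals.append(int(m.sum()))
        developed.append(int(y[m].sum()))
    table = np.array([developed, [t - d for t, d in zip(totals, developed)]])
    chi2, df, p = chi_square_independence(table)
    return ScQuartileReport(tuple(boundaries), tuple(totals), tuple(developed),
                            chi2, df, p)


# --- serialization -----------------------------------------------------------

def _scheme_to_json(s: CompartmentScheme) -> dict:
    return {
        "parameter": s.parameter,
        "boundaries": list(s.boundaries),
        "merged": [list(m) for m in s.merged],
        "n_fit": s.n_fit,
    }


def _scheme_from_json(d: dict) -> CompartmentScheme:
    return CompartmentScheme(
        parameter=d["parameter"],
        boundaries=tuple(d["boundaries"]),
        merged=tuple(tuple(m) for m in d.get("merged", [])),
        n_fit=int(d.get("n_fit", 0)),
    )


def _scoremap_to_json(m: ScoreMap) -> dict:
    return {
        "parameter": m.parameter,
        "labels": list(m.labels),
        "rates": list(m.rates),
        "scores": list(m.scores),
        "paired": list(m.paired) if m.paired else None,
    }


def _scoremap_from_json(d: dict) -> ScoreMap:
    return ScoreMap(
        parameter=d["parameter"],
        labels=tuple(d["labels"]),
        rates=tuple(d["rates"]),
        scores=tuple(int(s) for s in d["scores"]),
        paired=tuple(d["paired"]) if d.get("paired") else None,
    )


def serialize_model(model: BlastFormationModel) -> str:
    """Serialize to the versioned JSON document (deterministic byte layout).

    Floats are emitted with ``repr`` precision, so serialize → deserialize →
    serialize is byte-identical and Sc values survive the round trip exactly.
    """
    doc = {
        "schema": model.version,
        "parameters": list(model.parameters),
        "weights": {p: model.weights[p] for p in model.parameters},
        "schemes": {p: _scheme_to_json(model.schemes[p]) for p in model.parameters},
        "score_maps": {p: _scoremap_to_json(model.score_maps[p]) for p in model.parameters},
        "sc_quartiles": list(model.sc_quartiles) if model.sc_quartiles else None,
        "cutoff": model.cutoff,
        "metadata": model.fit_metadata,
    }
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def deserialize_model(document: str | dict) -> BlastFormationModel:
    """Parse and validate a model document.

    Raises :class:`SchemaVersionError` on an unknown schema tag and
    :class:`ModelValidationError` listing every missing/invalid field.
    """
    if isinstance(document, str):
        try:
            doc = json.loads(document)
        except json.JSONDecodeError as e:
            raise ModelValidationError(f"not valid JSON: {e}") from e
    else:
        doc = document
    schema = doc.get("schema")
    if schema != SCHEMA:
        raise SchemaVersionError(f"unsupported schema {schema!r}; expected {SCHEMA!r}")
    problems = []
    for key in ("parameters", "weights", "schemes", "score_maps"):
        if key not in doc:
            problems.append(f"missing key {key!r}")
    if problems:
        raise ModelValidationError("; ".join(problems))
    params = tuple(doc["parameters"])
    for p in params:
        for key in ("weights", "schemes", "score_maps"):
            if p not in doc[key]:
                problems.append(f"{key} missing entry for {p!r}")
    if problems:
        raise ModelValidationError("; ".join(problems))
    try:
        schemes = {p: _scheme_from_json(doc["schemes"][p]) for p in params}
        score_maps = {p: _scoremap_from_json(doc["score_maps"][p]) for p in params}
    except (KeyError, TypeError) as e:
        raise ModelValidationError(f"malformed scheme or score map: {e}") from e
    return BlastFormationModel(
        parameters=params,
        weights={p: float(doc["weights"][p]) for p in params},
        schemes=schemes,
        score_maps=score_maps,
        sc_quartiles=tuple(doc["sc_quartiles"]) if doc.get("sc_quartiles") else None,
        cutoff=doc.get("cutoff"),
        fit_metadata=doc.get("metadata", {}),
    )


def save_model(model: BlastFormationModel, sink: str | IO[str]) -> None:
    text = serialize_model(model)
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        with open(sink, "w", encoding="utf-8") as fh:
            fh.write(text)


def load_model(source: str | IO[str]) -> BlastFormationModel:
    if hasattr(source, "read"):
        return deserialize_model(source.read())
    with open(source, "r", encoding="utf-8") as fh:
        return deserialize_model(fh.read())
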