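"""Embryo morphokinetic records and the tabular formats the pipeline touches.

The central container is :class:`MorphokineticTable`, a thin, validated
wrapper around a :class:`pandas.DataFrame` with one row per embryo.  Columns:

``embryo_id, patient_id, t2, t3, t4, t5, cc2, s2, blastocyst``

Timings are hours post-ICSI stored as floats; missing values are ``NaN``.
``blastocyst`` is 0/1 or missing (unlabeled cohorts are accepted so a frozen
model can score them, but unlabeled records never enter a fitting stage).

Input dialect: comma-separated UTF-8 with a header row, ``.`` decimal
separator, missing encoded as an empty cell or ``NA``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import IO, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError, ParseError

TIMING_COLUMNS = ("t2", "t3", "t4", "t5")
RELATIVE_COLUMNS = ("cc2", "s2")
PARAMETERS = TIMING_COLUMNS + RELATIVE_COLUMNS
REQUIRED_COLUMNS = ("embryo_id", "patient_id") + TIMING_COLUMNS + ("blastocyst",)
ALL_COLUMNS = ("embryo_id", "patient_id") + TIMING_COLUMNS + RELATIVE_COLUMNS + ("blastocyst",)

#: tolerance for a supplied cc2/s2 disagreeing with the derived difference
DERIVED_MISMATCH_TOL = 1e-9

_NA_VALUES = ["", "NA"]


def _isna(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class EmbryoRecord:
    """One embryo: absolute timings, derived intervals and the outcome label.

    ``cc2 = t3 - t2`` (duration of the second cell cycle) and ``s2 = t4 - t3``
    (synchrony of the second cleavage) are carried explicitly; ``s2 = 0`` is
    legitimate — it means the interval was shorter than the imaging cadence,
    not that the divisions were simultaneous.
    """

    embryo_id: str
    patient_id: str
    t2: float | None = None
    t3: float | None = None
    t4: float | None = None
    t5: float | None = None
    cc2: float | None = None
    s2: float | None = None
    blastocyst: int | None = None

    def timing(self, parameter: str) -> float | None:
        if parameter not in PARAMETERS:
            raise KeyError(parameter)
        return getattr(self, parameter)


class MorphokineticTable:
    """Ordered, validated collection of embryo records.

    Construction validates the ingest invariants:

    * ``embryo_id`` values are unique;
    * on present fields, ``t2 <= t3 <= t4 <= t5``;
    * timings are non-negative;
    * a supplied ``cc2``/``s2`` that is also derivable must equal the derived
      difference to :data:`DERIVED_MISMATCH_TOL` (single source of truth).
    """

    def __init__(self, frame: pd.DataFrame, provenance: str = ""):
        self._frame = _normalise_frame(frame)
        self.provenance = provenance
        _validate_frame(self._frame)

    # -- container surface ----------------------------------------------------

    def __len__(self) -> int:
        return len(self._frame)

    @property
    def frame(self) -> pd.DataFrame:
        """The underlying DataFrame (copy; mutation cannot corrupt the table)."""
        return self._frame.copy()

    @property
    def records(self) -> list[EmbryoRecord]:
        out = []
        for row in self._frame.itertuples(index=False):
            out.append(
                EmbryoRecord(
                    embryo_id=row.embryo_id,
                    patient_id=row.patient_id,
                    **{
                        c: (None if pd.isna(getattr(row, c)) else float(getattr(row, c)))
                        for c in PARAMETERS
                    },
                    blastocyst=None if pd.isna(row.blastocyst) else int(row.blastocyst),
                )
            )
        return out

    def labeled(self) -> pd.DataFrame:
        """Rows with a 0/1 outcome — the only rows any fitting stage sees."""
        return self._frame[self._frame["blastocyst"].notna()].copy()

    def values(self, parameter: str, labeled_only: bool = False) -> np.ndarray:
        """Non-missing values of one parameter, in record order."""
        df = self.labeled() if labeled_only else self._frame
        v = df[parameter].to_numpy(dtype=float)
        return v[~np.isnan(v)]


def _normalise_frame(frame: pd.DataFrame) -> pd.DataFrame:
    df = frame.copy().reset_index(drop=True)
    for col in ("embryo_id", "patient_id"):
        if col in df.columns:
            df[col] = df[col].astype(str)
    for col in PARAMETERS:
        if col not in df.columns:
            df[col] = np.nan
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
    if "blastocyst" not in df.columns:
        df["blastocyst"] = np.nan
    df["blastocyst"] = pd.to_numeric(df["blastocyst"], errors="raise").astype(float)
    return df[list(ALL_COLUMNS)]


def _validate_frame(df: pd.DataFrame) -> None:
    missing = [c for c in ("embryo_id", "patient_id") if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")

    dup = df["embryo_id"][df["embryo_id"].duplicated()]
    if len(dup):
        raise IntegrityError(f"duplicate embryo_id values: {sorted(set(dup))}")

    bad_label = df["blastocyst"].dropna()
    if not bad_label.isin([0.0, 1.0]).all():
        bad = sorted(set(bad_label[~bad_label.isin([0.0, 1.0])]))
        raise IntegrityError(f"blastocyst must be 0, 1 or missing; found {bad}")

    for col in PARAMETERS:
        neg = df[col] < 0
        if neg.any():
            row = int(np.flatnonzero(neg.to_numpy())[0])
            raise IntegrityError(
                f"negative {col} at row {row} (embryo_id={df['embryo_id'].iloc[row]!r})"
            )

    # division-order invariant on present fields
    for lo, hi in zip(TIMING_COLUMNS[:-1], TIMING_COLUMNS[1:]):
        both = df[lo].notna() & df[hi].notna()
        viol = both & (df[lo] > df[hi])
        if viol.any():
            row = int(np.flatnonzero(viol.to_numpy())[0])
            raise IntegrityError(
                f"{lo} > {hi} at row {row} (embryo_id={df['embryo_id'].iloc[row]!r}): "
                f"{df[lo].iloc[row]} > {df[hi].iloc[row]}"
            )

    # supplied relative parameters must agree with the derivable difference
    for rel, (a, b) in (("cc2", ("t2", "t3")), ("s2", ("t3", "t4"))):
        have = df[rel].notna() & df[a].notna() & df[b].notna()
        if have.any():
            diff = (df.loc[have, b] - df.loc[have, a]) - df.loc[have, rel]
            bad = diff.abs() > DERIVED_MISMATCH_TOL
            if bad.any():
                row = int(bad.index[bad.to_numpy()][0])
                raise IntegrityError(
                    f"supplied {rel} disagrees with {b}-{a} at row {row} "
                    f"(embryo_id={df['embryo_id'].iloc[row]!r})"
                )


def read_morphokinetic_table(
    source: str | IO[str],
    column_map: Mapping[str, str] | None = None,
    provenance: str = "",
) -> MorphokineticTable:
    """Read a cohort CSV into a validated table.

    Parameters
    ----------
    source
        Path or open text stream holding comma-separated text with a header.
    column_map
        Optional mapping ``canonical name -> name in the file`` for inputs
        whose headers differ from ``embryo_id,patient_id,t2,...,blastocyst``.
    provenance
        Free-text source label stored on the table.

    Missing cells stay missing; ``cc2``/``s2`` are *not* derived here (see
    :func:`derive_relative_parameters`).
    """
    raw = pd.read_csv(
        source, sep=",", na_values=_NA_VALUES, keep_default_na=False, dtype=str
    )
    if column_map:
        rename = {src: canon for canon, src in column_map.items()}
        miss = [src for src in rename if src not in raw.columns]
        if miss:
            raise FormatError(f"column_map names absent from input: {', '.join(miss)}")
        raw = raw.rename(columns=rename)

    absent = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if absent:
        raise FormatError(f"missing required column(s): {', '.join(absent)}")

    for col in PARAMETERS + ("blastocyst",):
        if col not in raw.columns:
            continue
        parsed = pd.to_numeric(raw[col], errors="coerce")
        bad = parsed.isna() & raw[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric value {raw[col].iloc[row]!r} in column {col!r} at row {row}"
            )
        raw[col] = parsed
    return MorphokineticTable(raw, provenance=provenance)


def derive_relative_parameters(table: MorphokineticTable) -> MorphokineticTable:
    """Fill ``cc2 = t3 - t2`` and ``s2 = t4 - t3`` wherever both parents are
    present; missingness propagates silently.  Idempotent."""
    df = table.frame
    for rel, (a, b) in (("cc2", ("t2", "t3")), ("s2", ("t3", "t4"))):
        can = df[a].notna() & df[b].notna()
        df.loc[can, rel] = df.loc[can, b] - df.loc[can, a]
    return MorphokineticTable(df, provenance=table.provenance)


def write_scored_table(
    table: MorphokineticTable,
    extra_columns: Mapping[str, Mapping[str, object]] | None,
    sink: str | IO[str],
) -> None:
    """Write the cohort CSV plus per-record annotation columns.

    ``extra_columns`` maps column name to ``{embryo_id: value}``; every
    annotation column must cover every record (an incomplete annotation raises
    :class:`IntegrityError` listing the uncovered ids).  Numeric values are
    written with full ``repr`` precision so a read-back reproduces them
    bit-for-bit.
    """
    df = table.frame
    ids = list(df["embryo_id"])
    if extra_columns:
        for name, mapping in extra_columns.items():
            absent = [i for i in ids if i not in mapping]
            if absent:
                raise IntegrityError(
                    f"annotation column {name!r} missing for embryo_id(s): {absent}"
                )
            df[name] = [mapping[i] for i in ids]
    df.to_csv(sink, index=False, na_rep="")


@dataclass(frozen=True)
class CohortSummary:
    """Cohort accounting: headline counts with printed-precision percentages.

    Percentages are of ``n_embryos`` and are reported rounded to two decimals
    (the convention of the reference cohort report: 36.11 % developed, etc.).
    """

    n_embryos: int
    n_patients: int
    n_developed: int
    n_not_developed: int
    n_labeled: int
    n_transferred: int | None = None
    n_frozen: int | None = None

    def _pct(self, k: int) -> float:
        return round(100.0 * k / self.n_embryos, 2)

    @property
    def embryos_per_patient(self) -> float:
        return round(self.n_embryos / self.n_patients, 2)

    @property
    def pct_developed(self) -> float:
        return self._pct(self.n_developed)

    @property
    def pct_not_developed(self) -> float:
        return self._pct(self.n_not_developed)

    @property
    def pct_transferred(self) -> float | None:
        return None if self.n_transferred is None else self._pct(self.n_transferred)

    @property
    def pct_frozen(self) -> float | None:
        return None if self.n_frozen is None else self._pct(self.n_frozen)

    def as_dict(self) -> dict:
        out = {
            "n_embryos": self.n_embryos,
            "n_patients": self.n_patients,
            "embryos_per_patient": self.embryos_per_patient,
            "n_developed": self.n_developed,
            "pct_developed": self.pct_developed,
            "n_not_developed": self.n_not_developed,
            "pct_not_developed": self.pct_not_developed,
        }
        if self.n_transferred is not None:
            out["n_transferred"] = self.n_transferred
            out["pct_transferred"] = self.pct_transferred
        if self.n_frozen is not None:
            out["n_frozen"] = self.n_frozen
            out["pct_frozen"] = self.pct_frozen
        return out


def summarize_cohort(
    table: MorphokineticTable,
    n_transferred: int | None = None,
    n_frozen: int | None = None,
) -> CohortSummary:
    """Headline cohort accounting (embryos, patients, development rate)."""
    df = table.frame
    lab = df["blastocyst"].dropna()
    return CohortSummary(
        n_embryos=len(df),
        n_patients=df["patient_id"].nunique(),
        n_developed=int((lab == 1).sum()),
        n_not_developed=int((lab == 0).sum()),
        n_labeled=len(lab),
        n_transferred=n_transferred,
        n_frozen=n_frozen,
    )
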