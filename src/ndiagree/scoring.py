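"""Scoring engine for the three Neck Disability Index versions.

The Neck Disability Index (NDI) is a 10-item patient-reported outcome for
neck-pain-related disability.  Each item is answered on six ordered
categories scored 0..5; the classic total ("NDI-10") is the plain sum,
0-50, higher = worse.  Two Rasch-derived short forms are supported:

* **NDI-8** drops the *headaches* and *lifting* items (ordinal sum 0-40)
  and converts the ordinal sum to an interval-level 0-50 score through a
  score-to-measure lookup table.
* **NDI-5** keeps only the five functional items (*personal care*,
  *concentration*, *work*, *driving*, *recreation*), collapses the top two
  response options of the driving item (0,1,2,3,4,5 -> 0,1,2,3,3,4) to fix
  its disordered thresholds, sums to an ordinal 0-24, and rescales to 0-50.

The exact Rasch score-to-measure tables for the short forms are published
as supplementary material of the source studies and are therefore taken as
*configuration*: :class:`TransformTable` validates any user-supplied table,
and :meth:`TransformTable.linear` provides a clearly labelled linear
rescale (sum x 50/max) that is used as the default/testing placeholder.

Estimator interface
-------------------
:class:`NDIScorer` is a scikit-learn compatible transformer
(``fit``/``transform``/``get_params``) operating on a DataFrame with one
column per item; the module-level functions (:func:`score_ndi10`,
:func:`score_ndi5`, ...) are thin per-record wrappers around the same
rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "CANONICAL_ITEMS",
    "DRIVING_RECODE",
    "NDI8_ITEMS",
    "NDI5_ITEMS",
    "ValidationError",
    "MissingResponseError",
    "TransformTableError",
    "ResponseRecord",
    "TransformTable",
    "VersionSpec",
    "ScoreTriple",
    "ndi10_spec",
    "ndi8_spec",
    "ndi5_spec",
    "validate_record",
    "recode_item",
    "ordinal_sum",
    "score_ndi10",
    "score_ndi8",
    "score_ndi5",
    "score_record",
    "score_all",
    "score_frame",
    "load_transform_table",
    "NDIScorer",
]

#: The ten NDI items in canonical questionnaire order.
CANONICAL_ITEMS: tuple[str, ...] = (
    "pain_intensity",
    "personal_care",
    "lifting",
    "reading",
    "headaches",
    "concentration",
    "work",
    "driving",
    "sleeping",
    "recreation",
)

#: Driving-item rescore collapsing the top two options: 012345 -> 012334.
DRIVING_RECODE: dict[int, int] = {0: 0, 1: 1, 2: 2, 3: 3, 4: 3, 5: 4}

#: Items retained by the 8-item short form (headaches and lifting removed).
NDI8_ITEMS: tuple[str, ...] = tuple(
    it for it in CANONICAL_ITEMS if it not in ("headaches", "lifting")
)

#: The five functional items retained by the 5-item short form.
NDI5_ITEMS: tuple[str, ...] = (
    "personal_care",
    "concentration",
    "work",
    "driving",
    "recreation",
)

MAX_RESPONSE = 5


class ValidationError(ValueError):
    """An item response violates the questionnaire's constraints."""


class MissingResponseError(ValidationError):
    """A required item response is missing."""


class TransformTableError(ValueError):
    """A score-to-measure table is incomplete or non-monotone."""


@dataclass(frozen=True)
class ResponseRecord:
    """One respondent's raw item responses.

    Parameters
    ----------
    subject_id : str
        Opaque respondent identifier.
    responses : tuple of int or None
        Ten responses in canonical item order, each 0..5 (``None`` marks a
        missing answer).
    age, sex : optional demographics, presentation only.
    """

    subject_id: str
    responses: tuple
    age: float | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "responses", tuple(self.responses))
        if len(self.responses) != len(CANONICAL_ITEMS):
            raise ValidationError(
                f"subject {self.subject_id!r}: expected "
                f"{len(CANONICAL_ITEMS)} responses, got {len(self.responses)}"
            )

    def response(self, item: str) -> int | None:
        """Return the response for *item* (addressed by name, not index)."""
        return self.responses[CANONICAL_ITEMS.index(item)]

    def as_dict(self) -> dict[str, int | None]:
        return dict(zip(CANONICAL_ITEMS, self.responses))


def validate_record(record: ResponseRecord, *, allow_missing: bool = False) -> ResponseRecord:
    """Check every response is an integer in 0..5; return the record unchanged.

    Raises
    ------
    MissingResponseError
        If a response is ``None``/NaN and ``allow_missing`` is False.
    ValidationError
        If a response is out of range or not an integer, naming the item
        and the offending value.
    """
    for item, value in zip(CANONICAL_ITEMS, record.responses):
        if value is None or (isinstance(value, float) and np.isnan(value)):
            if allow_missing:
                continue
            raise MissingResponseError(
                f"subject {record.subject_id!r}: missing response for item {item!r}"
            )
        if isinstance(value, float) and not float(value).is_integer():
            raise ValidationError(
                f"subject {record.subject_id!r}: non-integer response "
                f"{value!r} for item {item!r}"
            )
        iv = int(value)
        if not 0 <= iv <= MAX_RESPONSE:
            raise ValidationError(
                f"subject {record.subject_id!r}: response {value!r} for item "
                f"{item!r} outside 0..{MAX_RESPONSE}"
            )
    return record


def recode_item(value: int, recode_map: Mapping[int, int]) -> int:
    """Apply a category recode map to a single response."""
    try:
        return recode_map[int(value)]
    except KeyError:
        raise ValidationError(
            f"value {value!r} outside recode-map domain {sorted(recode_map)}"
        ) from None


class TransformTable:
    """Monotone lookup from an ordinal raw sum to an interval 0-50 score.

    The table must cover every integer sum ``0..max_ordinal``, be weakly
    non-decreasing and anchor the scale ends: ``table[0] == 0`` and
    ``table[max_ordinal] == 50``.
    """

    def __init__(self, entries: Mapping[int, float], max_ordinal: int,
                 provenance: str = "user-supplied"):
        self.max_ordinal = int(max_ordinal)
        self.provenance = provenance
        values = []
        for s in range(self.max_ordinal + 1):
            if s not in entries:
                raise TransformTableError(
                    f"transform table missing entry for ordinal sum {s} "
                    f"(must cover 0..{self.max_ordinal})"
                )
            values.append(float(entries[s]))
        self._values = np.asarray(values)
        if np.any(np.diff(self._values) < 0):
            bad = int(np.argmax(np.diff(self._values) < 0))
            raise TransformTableError(
                f"transform table not monotone: entry({bad})={self._values[bad]} "
                f"> entry({bad + 1})={self._values[bad + 1]}"
            )
        if self._values[0] != 0.0 or self._values[-1] != 50.0:
            raise TransformTableError(
                "transform table must map 0 -> 0 and "
                f"{self.max_ordinal} -> 50 (got {self._values[0]}, {self._values[-1]})"
            )

    @classmethod
    def linear(cls, max_ordinal: int) -> "TransformTable":
        """Linear placeholder rescale ``sum * 50 / max_ordinal``.

        Stands in for a Rasch score-to-measure table when the published
        lookup is not supplied; provenance is labelled accordingly.
        """
        entries = {s: 50.0 * s / max_ordinal for s in range(max_ordinal + 1)}
        return cls(entries, max_ordinal, provenance=f"linear (sum x 50/{max_ordinal})")

    def __call__(self, ordinal_sum: float) -> float:
        s = float(ordinal_sum)
        if s.is_integer():
            i = int(s)
            if not 0 <= i <= self.max_ordinal:
                raise ValidationError(
                    f"ordinal sum {i} outside table domain 0..{self.max_ordinal}"
                )
            return float(self._values[i])
        # prorated (fractional) sums interpolate between adjacent entries
        if not 0 <= s <= self.max_ordinal:
            raise ValidationError(
                f"ordinal sum {s} outside table domain 0..{self.max_ordinal}"
            )
        return float(np.interp(s, np.arange(self.max_ordinal + 1), self._values))

    def apply(self, sums: Sequence[float]) -> np.ndarray:
        """Vectorised lookup (with interpolation for fractional sums)."""
        s = np.asarray(sums, dtype=float)
        if np.any((s < 0) | (s > self.max_ordinal)):
            raise ValidationError(
                f"ordinal sums outside table domain 0..{self.max_ordinal}"
            )
        return np.interp(s, np.arange(self.max_ordinal + 1), self._values)

    def __repr__(self) -> str:  # pragma: no cover
        return f"TransformTable(max_ordinal={self.max_ordinal}, provenance={self.provenance!r})"


def load_transform_table(path, max_ordinal: int, provenance: str | None = None) -> TransformTable:
    """Read a two-column ``ordinal_sum,transformed_score`` CSV into a table.

    Validation (completeness over ``0..max_ordinal``, monotonicity, anchored
    ends) is delegated to :class:`TransformTable`.
    """
    df = pd.read_csv(path, comment="#")
    expected = ["ordinal_sum", "transformed_score"]
    if list(df.columns[:2]) != expected:
        raise TransformTableError(
            f"{path}: expected columns {expected}, got {list(df.columns)}"
        )
    entries = {int(r.ordinal_sum): float(r.transformed_score) for r in df.itertuples()}
    if len(entries) != len(df):
        raise TransformTableError(f"{path}: duplicate ordinal_sum rows")
    return TransformTable(entries, max_ordinal,
                          provenance=provenance or f"file:{path}")


@dataclass(frozen=True)
class VersionSpec:
    """A scoring rule: retained items, per-item recodes, and the 0-50 transform."""

    name: str
    retained_items: tuple[str, ...]
    max_ordinal: int
    recode_maps: Mapping[str, Mapping[int, int]] = field(default_factory=dict)
    transform: TransformTable | None = None  # None = raw ordinal sum is the score

    def __post_init__(self) -> None:
        unknown = set(self.retained_items) - set(CANONICAL_ITEMS)
        if unknown:
            raise ValidationError(f"{self.name}: unknown items {sorted(unknown)}")
        for item, m in self.recode_maps.items():
            vals = [m[k] for k in sorted(m)]
            if vals != sorted(vals):
                raise ValidationError(f"{self.name}: recode map for {item!r} not monotone")
            if sorted(set(vals)) != list(range(max(vals) + 1)):
                raise ValidationError(
                    f"{self.name}: recode map for {item!r} not surjective onto 0..{max(vals)}"
                )
        if self.transform is not None and self.transform.max_ordinal != self.max_ordinal:
            raise TransformTableError(
                f"{self.name}: transform covers 0..{self.transform.max_ordinal}, "
                f"need 0..{self.max_ordinal}"
            )


def ndi10_spec() -> VersionSpec:
    """Original 10-item version: plain sum on the ordinal 0-50 scale."""
    return VersionSpec("NDI-10", CANONICAL_ITEMS, 50)


def ndi8_spec(transform: TransformTable | None = None) -> VersionSpec:
    """8-item version: headaches and lifting removed, ordinal 0-40 -> 0-50."""
    return VersionSpec("NDI-8", NDI8_ITEMS, 40,
                       transform=transform or TransformTable.linear(40))


def ndi5_spec(transform: TransformTable | None = None) -> VersionSpec:
    """5-item functional version with the driving recode, ordinal 0-24 -> 0-50."""
    return VersionSpec("NDI-5", NDI5_ITEMS, 24,
                       recode_maps={"driving": DRIVING_RECODE},
                       transform=transform or TransformTable.linear(24))


def ordinal_sum(record: ResponseRecord, spec: VersionSpec, *,
                prorate_missing: bool = False) -> float:
    """Sum the retained (recoded) items of *record* on the version's ordinal scale.

    With ``prorate_missing=True`` a partially answered record is scaled by
    ``k_total / k_answered`` (the mean of answered items carried to the
    full item count); by default any missing answer is a hard error so the
    published scoring rule is never silently altered.
    """
    validate_record(record, allow_missing=prorate_missing)
    total = 0.0
    answered = 0
    for item in spec.retained_items:
        value = record.response(item)
        if value is None or (isinstance(value, float) and np.isnan(value)):
            continue
        recode = spec.recode_maps.get(item)
        total += recode_item(value, recode) if recode else int(value)
        answered += 1
    if answered == 0:
        raise MissingResponseError(
            f"subject {record.subject_id!r}: no answered items for {spec.name}"
        )
    if answered < len(spec.retained_items):
        total *= len(spec.retained_items) / answered
    return total


def score_record(record: ResponseRecord, spec: VersionSpec, *,
                 prorate_missing: bool = False) -> float:
    """Score one record under *spec*; result is on the common 0-50 scale."""
    s = ordinal_sum(record, spec, prorate_missing=prorate_missing)
    return float(s) if spec.transform is None else spec.transform(s)


def score_ndi10(record: ResponseRecord, *, prorate_missing: bool = False) -> float:
    """Classic NDI total: arithmetic sum of the 10 raw responses (ordinal 0-50)."""
    return score_record(record, ndi10_spec(), prorate_missing=prorate_missing)


def score_ndi8(record: ResponseRecord, transform: TransformTable | None = None, *,
               prorate_missing: bool = False) -> float:
    """8-item score: sum of retained raw responses (0-40) mapped to 0-50."""
    return score_record(record, ndi8_spec(transform), prorate_missing=prorate_missing)


def score_ndi5(record: ResponseRecord, transform: TransformTable | None = None, *,
               prorate_missing: bool = False) -> float:
    """5-item score: driving recode, sum of five items (0-24) mapped to 0-50."""
    return score_record(record, ndi5_spec(transform), prorate_missing=prorate_missing)


@dataclass(frozen=True)
class ScoreTriple:
    """The three version scores for one respondent, all on 0-50."""

    subject_id: str
    ndi10: float
    ndi8: float
    ndi5: float


def score_all(records: Iterable[ResponseRecord],
              specs: Sequence[VersionSpec] | None = None, *,
              prorate_missing: bool = False) -> list[ScoreTriple]:
    """Score every record under all three versions.

    Any record-level error is re-raised with the subject id in context.
    """
    if specs is None:
        specs = (ndi10_spec(), ndi8_spec(), ndi5_spec())
    if len(specs) != 3:
        raise ValueError("score_all expects exactly three version specs")
    out = []
    for rec in records:
        try:
            scores = [score_record(rec, sp, prorate_missing=prorate_missing)
                      for sp in specs]
        except ValidationError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raise with subject context
            raise ValidationError(f"subject {rec.subject_id!r}: {exc}") from exc
        out.append(ScoreTriple(rec.subject_id, *scores))
    return out


def score_frame(df: pd.DataFrame,
                ndi8_transform: TransformTable | None = None,
                ndi5_transform: TransformTable | None = None) -> pd.DataFrame:
    """Score a responses DataFrame (one column per item) under all versions.

    Returns a DataFrame with columns ``subject_id, ndi10, ndi8, ndi5``.
    Vectorised; equivalent to :func:`score_all` on the corresponding records.
    """
    specs = (ndi10_spec(), ndi8_spec(ndi8_transform), ndi5_spec(ndi5_transform))
    missing = [c for c in CANONICAL_ITEMS if c not in df.columns]
    if missing:
        raise ValidationError(f"responses frame missing item columns {missing}")
    items = df[list(CANONICAL_ITEMS)]
    arr = items.to_numpy()
    if not np.isin(arr, np.arange(MAX_RESPONSE + 1)).all():
        bad = np.argwhere(~np.isin(arr, np.arange(MAX_RESPONSE + 1)))[0]
        raise ValidationError(
            f"row {bad[0]}: response {arr[tuple(bad)]!r} for item "
            f"{CANONICAL_ITEMS[bad[1]]!r} outside 0..{MAX_RESPONSE}"
        )
    out = pd.DataFrame(index=df.index)
    out["subject_id"] = (df["subject_id"] if "subject_id" in df.columns
                         else df.index.astype(str))
    for spec, col in zip(specs, ("ndi10", "ndi8", "ndi5")):
        cols = items[list(spec.retained_items)].to_numpy(dtype=int)
        for item, m in spec.recode_maps.items():
            j = spec.retained_items.index(item)
            lut = np.array([m[k] for k in range(MAX_RESPONSE + 1)])
            cols[:, j] = lut[cols[:, j]]
        sums = cols.sum(axis=1)
        out[col] = sums.astype(float) if spec.transform is None else spec.transform.apply(sums)
    return out


class NDIScorer(BaseEstimator, TransformerMixin):
    """Scikit-learn transformer computing one NDI version's total score.

    Parameters
    ----------
    version : {"ndi10", "ndi8", "ndi5"}
        Which scoring rule to apply.
    transform_table : TransformTable, optional
        Score-to-measure lookup for the short forms; defaults to the linear
        rescale placeholder.  Ignored for ``ndi10``.

    After :meth:`fit`, ``spec_`` holds the resolved :class:`VersionSpec`.
    ``transform(X)`` on a DataFrame with item-name columns returns an
    ``(n, 1)`` array of 0-50 scores.
    """

    _FACTORIES = {"ndi10": ndi10_spec, "ndi8": ndi8_spec, "ndi5": ndi5_spec}

    def __init__(self, version: str = "ndi10",
                 transform_table: TransformTable | None = None):
        self.version = version
        self.transform_table = transform_table

    def _resolve_spec(self) -> VersionSpec:
        if self.version not in self._FACTORIES:
            raise ValueError(
                f"version must be one of {sorted(self._FACTORIES)}, got {self.version!r}"
            )
        factory = self._FACTORIES[self.version]
        if self.version == "ndi10":
            return factory()
        return factory(self.transform_table)

    def fit(self, X: pd.DataFrame, y=None) -> "NDIScorer":
        self.spec_ = self._resolve_spec()
        X = self._check_frame(X)
        self.n_features_in_ = len(CANONICAL_ITEMS)
        self.feature_names_in_ = np.asarray(CANONICAL_ITEMS, dtype=object)
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "spec_"):
            raise AttributeError("NDIScorer instance is not fitted yet")
        X = self._check_frame(X)
        col = {"ndi10": "ndi10", "ndi8": "ndi8", "ndi5": "ndi5"}[self.version]
        scores = score_frame(
            X,
            ndi8_transform=self.transform_table if self.version == "ndi8" else None,
            ndi5_transform=self.transform_table if self.version == "ndi5" else None,
        )[col]
        return scores.to_numpy()[:, None]

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray([self.version], dtype=object)

    @staticmethod
    def _check_frame(X: pd.DataFrame) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X), columns=list(CANONICAL_ITEMS))
        missing = [c for c in CANONICAL_ITEMS if c not in X.columns]
        if missing:
            raise ValidationError(f"responses frame missing item columns {missing}")
        return X
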