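"""Cohort data model: validated records, reference coding, CSV I/O, cross-tabs.

A cohort is a table of patient records with a binary outcome (1 = natural
dental caries, 0 = non-natural) and five categorical covariates.  Level sets
are fixed; anything outside them is rejected at read time with the offending
row and column named.  Dummy (reference) coding expands a cohort into the
8-column design matrix used by every regression in the package:
``intercept, Male, Rural, SNNPR, 18-25, 26-35, >=35, Yes``.
"""

from __future__ import annotations

import dataclasses
import re
from collections import namedtuple
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COVARIATES",
    "LEVELS",
    "DEFAULT_CODING",
    "Cohort",
    "CodingScheme",
    "CrossTab",
    "DesignMatrix",
    "PatientRecord",
    "ValidationError",
    "ZeroCellError",
    "cohort_from_counts",
    "cross_tabulate",
    "crude_odds_ratio",
    "crude_risk_ratio",
    "encode",
    "read_cohort",
    "write_cohort",
]

#: Covariate column order; the outcome column is named "outcome".
COVARIATES: tuple[str, ...] = (
    "gender",
    "residence",
    "region",
    "age_group",
    "clean_teeth",
)

#: Allowed levels per covariate; the reference level comes first.
LEVELS: dict[str, tuple[str, ...]] = {
    "gender": ("Female", "Male"),
    "residence": ("Urban", "Rural"),
    "region": ("Others", "SNNPR"),
    "age_group": ("<18", "18-25", "26-35", ">=35"),
    "clean_teeth": ("No", "Yes"),
}

# Age-group spellings vary in the field literature ("<=18", en dashes,
# "> = 35"); we canonicalise at read time.  Keys are lower-cased,
# whitespace-stripped, dash-normalised aliases.
_AGE_ALIASES = {
    "<18": "<18",
    "<=18": "<18",
    "≤18": "<18",
    "18-25": "18-25",
    "26-35": "26-35",
    "25-35": "26-35",
    ">=35": ">=35",
    ">35": ">=35",
    "≥35": ">=35",
}


class ValidationError(ValueError):
    """A cohort cell is missing or takes a value outside its level set."""


class ZeroCellError(ValueError):
    """A 2x2 crude-measure cell is zero and continuity correction is off."""


PatientRecord = namedtuple(
    "PatientRecord", ("outcome",) + COVARIATES
)


def _normalise_level(covariate: str, raw: object, row: int | None = None) -> str:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        raise ValidationError(
            f"missing value in column '{covariate}'"
            + (f" at row {row}" if row is not None else "")
        )
    text = re.sub(r"\s+", "", str(raw)).replace("–", "-").replace("—", "-")
    if covariate == "age_group":
        canonical = _AGE_ALIASES.get(text.lower())
        if canonical is not None:
            return canonical
    else:
        for level in LEVELS[covariate]:
            if text.lower() == level.lower():
                return level
    raise ValidationError(
        f"unknown level {raw!r} for column '{covariate}'"
        + (f" at row {row}" if row is not None else "")
        + f"; expected one of {list(LEVELS[covariate])}"
    )


def _normalise_outcome(raw: object, row: int | None = None) -> int:
    text = str(raw).strip()
    if text in ("0", "1"):
        return int(text)
    raise ValidationError(
        f"outcome must be literal 0 or 1, got {raw!r}"
        + (f" at row {row}" if row is not None else "")
    )


class Cohort:
    """Validated patient-level cohort table.

    Parameters
    ----------
    data
        Mapping or DataFrame with columns ``outcome`` plus the five
        covariates.  Values are validated and level spellings canonicalised;
        any unknown level or missing cell raises :class:`ValidationError`
        naming the row and column.
    """

    def __init__(self, data: pd.DataFrame | Mapping[str, Sequence]):
        frame = pd.DataFrame(data)
        missing = [c for c in ("outcome", *COVARIATES) if c not in frame.columns]
        if missing:
            raise ValidationError(f"cohort is missing columns {missing}")
        if len(frame) < 1:
            raise ValidationError("cohort must contain at least one record")
        clean = pd.DataFrame(index=pd.RangeIndex(len(frame)))
        outcome_raw = frame["outcome"].tolist()
        clean["outcome"] = [
            _normalise_outcome(v, row=i) for i, v in enumerate(outcome_raw)
        ]
        for cov in COVARIATES:
            values = frame[cov].tolist()
            clean[cov] = [
                _normalise_level(cov, v, row=i) for i, v in enumerate(values)
            ]
        clean["outcome"] = clean["outcome"].astype(np.int64)
        self._frame = clean

    # -- container protocol -------------------------------------------------
    @property
    def n(self) -> int:
        """Number of records."""
        return len(self._frame)

    def __len__(self) -> int:
        return self.n

    def __eq__(self, other) -> bool:
        return isinstance(other, Cohort) and self._frame.equals(other._frame)

    @property
    def frame(self) -> pd.DataFrame:
        """The cohort as a DataFrame (copy; row order preserved)."""
        return self._frame.copy()

    @property
    def records(self) -> list[PatientRecord]:
        """The cohort as a list of named records."""
        return [PatientRecord(*row) for row in self._frame.itertuples(index=False)]

    @property
    def outcome(self) -> np.ndarray:
        """Binary outcome vector (1 = natural caries)."""
        return self._frame["outcome"].to_numpy()

    # -- I/O ----------------------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path) -> "Cohort":
        """Read a cohort from a comma-separated UTF-8 file with header."""
        frame = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
        return cls(frame)

    def to_csv(self, path: str | Path) -> None:
        """Write the cohort with canonical level spellings."""
        self._frame.to_csv(path, index=False, encoding="utf-8")


def read_cohort(path: str | Path) -> Cohort:
    """Read and validate a cohort CSV (columns: outcome + five covariates)."""
    return Cohort.from_csv(path)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort CSV that :func:`read_cohort` round-trips exactly."""
    cohort.to_csv(path)


# ---------------------------------------------------------------------------
# Reference coding
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class CodingScheme:
    """Dummy-coding scheme: per covariate, the reference level absorbed into
    the intercept; each non-reference level gets a 0/1 indicator column."""

    references: Mapping[str, str] = dataclasses.field(
        default_factory=lambda: {c: LEVELS[c][0] for c in COVARIATES}
    )
    intercept: bool = True

    def __post_init__(self):
        for cov, ref in self.references.items():
            if cov not in LEVELS:
                raise ValueError(f"unknown covariate {cov!r}")
            if ref not in LEVELS[cov]:
                raise ValueError(f"{ref!r} is not a level of {cov!r}")

    @property
    def slots(self) -> tuple[str, ...]:
        """Named coefficient slots in fixed order."""
        names: list[str] = ["intercept"] if self.intercept else []
        for cov in COVARIATES:
            ref = self.references[cov]
            names.extend(lv for lv in LEVELS[cov] if lv != ref)
        return tuple(names)


DEFAULT_CODING = CodingScheme()


@dataclasses.dataclass(frozen=True)
class DesignMatrix:
    """Reference-coded numeric expansion of a cohort.

    ``X`` is n x p with an intercept column of ones and 0/1 indicators;
    ``y`` the outcome vector; ``columns`` the slot names.
    """

    X: np.ndarray
    y: np.ndarray
    columns: tuple[str, ...]

    def __post_init__(self):
        if self.X.shape != (len(self.y), len(self.columns)):
            raise ValueError("design shape does not match y/columns")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.X, columns=list(self.columns))
        frame["outcome"] = self.y
        return frame


def encode(cohort: Cohort, scheme: CodingScheme = DEFAULT_CODING) -> DesignMatrix:
    """Expand a cohort into a dummy-coded design matrix.

    Column order is fixed: intercept, Male, Rural, SNNPR, 18-25, 26-35,
    >=35, Yes (for the default scheme).
    """
    frame = cohort.frame
    cols: list[np.ndarray] = []
    names: list[str] = []
    if scheme.intercept:
        cols.append(np.ones(cohort.n))
        names.append("intercept")
    for cov in COVARIATES:
        ref = scheme.references[cov]
        for level in LEVELS[cov]:
            if level == ref:
                continue
            cols.append((frame[cov] == level).to_numpy(dtype=float))
            names.append(level)
    X = np.column_stack(cols)
    return DesignMatrix(X=X, y=cohort.outcome.astype(float), columns=tuple(names))


# ---------------------------------------------------------------------------
# Cross-tabulation and crude measures
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class CrossTab:
    """Outcome cross-tabulation for one covariate.

    ``counts`` maps level -> (count of outcome 0, count of outcome 1);
    percentages are row-wise (within level).
    """

    covariate: str
    counts: dict[str, tuple[int, int]]

    @property
    def levels(self) -> tuple[str, ...]:
        return tuple(self.counts)

    def total(self) -> int:
        return sum(c0 + c1 for c0, c1 in self.counts.values())

    def percentages(self) -> dict[str, tuple[float, float]]:
        """Row percentages (non-natural %, natural %) per level."""
        out = {}
        for level, (c0, c1) in self.counts.items():
            tot = c0 + c1
            if tot == 0:  # declared level unobserved in this cohort
                out[level] = (0.0, 0.0)
            else:
                out[level] = (100.0 * c0 / tot, 100.0 * c1 / tot)
        return out

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages()
        rows = [
            {
                "covariate": self.covariate,
                "level": level,
                "count_nonnatural": c0,
                "count_natural": c1,
                "pct_nonnatural": pct[level][0],
                "pct_natural": pct[level][1],
            }
            for level, (c0, c1) in self.counts.items()
        ]
        return pd.DataFrame(rows)


def cross_tabulate(cohort: Cohort, covariate: str) -> CrossTab:
    """Cross-tabulate the outcome against one covariate.

    Counts partition the cohort (level counts sum to ``cohort.n``).
    """
    if covariate not in COVARIATES:
        raise ValueError(
            f"unknown covariate {covariate!r}; expected one of {COVARIATES}"
        )
    frame = cohort.frame
    counts: dict[str, tuple[int, int]] = {}
    for level in LEVELS[covariate]:
        sub = frame.loc[frame[covariate] == level, "outcome"]
        counts[level] = (int((sub == 0).sum()), int((sub == 1).sum()))
    return CrossTab(covariate=covariate, counts=counts)


def crosstabs_frame(cohort: Cohort) -> pd.DataFrame:
    """All five covariate cross-tabs stacked into one exportable table."""
    return pd.concat(
        [cross_tabulate(cohort, cov).to_frame() for cov in COVARIATES],
        ignore_index=True,
    )


def cohort_from_counts(
    covariate: str, counts: Mapping[str, tuple[int, int]]
) -> Cohort:
    """Build a cohort whose (covariate, outcome) joint matches given counts.

    Every other covariate is filled with its reference level; useful for
    reconstructing one covariate's published cross-tabulation when only the
    marginal counts are available.
    """
    if covariate not in COVARIATES:
        raise ValueError(f"unknown covariate {covariate!r}")
    rows: dict[str, list] = {c: [] for c in ("outcome", *COVARIATES)}
    for level, (c0, c1) in counts.items():
        for outcome, reps in ((0, c0), (1, c1)):
            for _ in range(reps):
                rows["outcome"].append(outcome)
                for cov in COVARIATES:
                    rows[cov].append(level if cov == covariate else LEVELS[cov][0])
    return Cohort(rows)


def _crude_cells(
    a: int, b: int, c: int, d: int, correction: bool
) -> tuple[float, float, float, float]:
    cells = {"a": a, "b": b, "c": c, "d": d}
    for name, value in cells.items():
        if value < 0:
            raise ValueError(f"cell {name} is negative")
    if any(v == 0 for v in cells.values()):
        if not correction:
            zero = next(k for k, v in cells.items() if v == 0)
            raise ZeroCellError(
                f"cell {zero!r} is zero; pass correction=True for the "
                "Haldane-Anscombe +0.5 correction"
            )
        return a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float(a), float(b), float(c), float(d)


def crude_odds_ratio(
    a: int, b: int, c: int, d: int, *, correction: bool = False
) -> float:
    """Crude odds ratio from a 2x2 table.

    Rows are exposure levels — (a, b) the reference level, (c, d) the index
    level — and columns the outcome (non-natural, natural), so
    ``OR = (d/c) / (b/a) = (a*d) / (b*c)``.  A zero cell raises
    :class:`ZeroCellError` unless ``correction=True`` adds 0.5 to every
    cell (Haldane-Anscombe).
    """
    a, b, c, d = _crude_cells(a, b, c, d, correction)
    return (a * d) / (b * c)


def crude_risk_ratio(
    a: int, b: int, c: int, d: int, *, correction: bool = False
) -> float:
    """Crude risk ratio from a 2x2 table: ``(d/(c+d)) / (b/(a+b))``.

    Same cell layout and zero-cell policy as :func:`crude_odds_ratio`.
    """
    a, b, c, d = _crude_cells(a, b, c, d, correction)
    return (d / (c + d)) / (b / (a + b))
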