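"""Study variables, their integer codings, and derivation rules.

The analysis works on 11 categorical variables: ten predictors
(physical activity, sex, age band, education, residence, marital status,
night sleep band, nap band, smoking, alcohol) and the binary multimorbidity
outcome ``mmd``. Multimorbidity is the co-occurrence of two or more of 14
surveyed chronic conditions. Physical activity is banded from weekly
MET-minutes computed IPAQ-style from intensity/frequency/duration triples.

Codes are integers; missing cells carry the sentinel :data:`MISSING` (-1),
which is outside every variable's code domain.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "MISSING",
    "N_CONDITIONS",
    "MET_WEIGHTS",
    "VariableScheme",
    "ActivityRecord",
    "CODEBOOK",
    "VARIABLES",
    "CodingError",
    "DatasetError",
    "ValidationIssue",
    "ValidationReport",
    "derive_mmd",
    "met_minutes",
    "categorize_activity",
    "encode_record",
    "decode_value",
    "validate_dataset",
    "load_codebook",
]

#: Sentinel for a missing categorical value; distinct from every valid code.
MISSING = -1

#: Number of chronic-condition indicators in the survey instrument
#: (hypertension, dyslipidemia, diabetes, cancer, chronic lung disease,
#: liver disease, heart disease, stroke, kidney disease, digestive disease,
#: emotional/psychiatric problems, memory-related disease, arthritis, asthma).
N_CONDITIONS = 14

#: MET weight per activity intensity (IPAQ convention).
MET_WEIGHTS = {"light": 3.3, "moderate": 4.0, "vigorous": 8.0}


class CodingError(ValueError):
    """Raised when a raw value violates a coding contract."""


class DatasetError(ValueError):
    """Raised when a dataset is structurally unusable (e.g. missing column)."""


@dataclass(frozen=True)
class VariableScheme:
    """One study variable: its name, ordered (code, label) pairs, ordinality."""

    name: str
    codes: tuple[tuple[int, str], ...]
    ordinal: bool = False

    def __post_init__(self) -> None:
        values = [c for c, _ in self.codes]
        if len(set(values)) != len(values):
            raise CodingError(f"{self.name}: duplicate codes")
        if values != list(range(values[0], values[0] + len(values))):
            raise CodingError(f"{self.name}: codes must be consecutive integers")
        if not 2 <= len(values) <= 5:
            raise CodingError(f"{self.name}: expected 2-5 categories, got {len(values)}")

    @property
    def domain(self) -> tuple[int, ...]:
        return tuple(c for c, _ in self.codes)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for _, lab in self.codes)

    def label_of(self, code: int) -> str:
        for c, lab in self.codes:
            if c == code:
                return lab
        raise CodingError(f"{self.name}: code {code} outside domain {self.domain}")


@dataclass(frozen=True)
class ActivityRecord:
    """One intensity level of weekly physical activity."""

    intensity: str
    days_per_week: int
    minutes_per_day: float

    def __post_init__(self) -> None:
        if self.intensity not in MET_WEIGHTS:
            raise CodingError(f"unknown intensity {self.intensity!r}")
        if not 0 <= int(self.days_per_week) <= 7:
            raise CodingError("days_per_week must be in 0..7")
        if self.minutes_per_day < 0:
            raise CodingError("minutes_per_day must be non-negative")

    @property
    def met_minutes(self) -> float:
        return MET_WEIGHTS[self.intensity] * self.days_per_week * self.minutes_per_day


def load_codebook() -> dict[str, VariableScheme]:
    """Load the shipped machine-readable codebook (JSON mirror of the coding table)."""
    text = resources.files("mmdbn.data").joinpath("codebook.json").read_text()
    raw = json.loads(text)
    book: dict[str, VariableScheme] = {}
    for var in raw["variables"]:
        book[var["name"]] = VariableScheme(
            name=var["name"],
            codes=tuple((int(c), str(lab)) for c, lab in var["codes"]),
            ordinal=bool(var["ordinal"]),
        )
    return book


#: The canonical codebook, keyed by variable name in study order (x1..x10, y).
CODEBOOK: dict[str, VariableScheme] = load_codebook()

#: Canonical column order.
VARIABLES: tuple[str, ...] = tuple(CODEBOOK)


def derive_mmd(conditions: Sequence[int]) -> int:
    """Multimorbidity flag: 1 iff two or more chronic-condition indicators are set.

    Parameters
    ----------
    conditions
        Exactly 14 binary presence/absence flags, one per surveyed condition.
    """
    conditions = list(conditions)
    if len(conditions) != N_CONDITIONS:
        raise CodingError(f"expected {N_CONDITIONS} condition flags, got {len(conditions)}")
    if any(c not in (0, 1) for c in conditions):
        raise CodingError("condition flags must be 0 or 1")
    return 1 if sum(conditions) >= 2 else 0


def met_minutes(records: Iterable[ActivityRecord]) -> float:
    """Total weekly physical-activity energy expenditure in MET-min/week.

    Sums intensity weight x days/week x minutes/day over the supplied
    intensity levels (at most one record per level).
    """
    records = list(records)
    seen: set[str] = set()
    for rec in records:
        if rec.intensity in seen:
            raise CodingError(f"duplicate intensity {rec.intensity!r}")
        seen.add(rec.intensity)
    return float(sum(rec.met_minutes for rec in records))


def categorize_activity(met: float) -> int:
    """Band MET-min/week into light (<600) = 1, moderate [600, 3000) = 2, vigorous (>=3000) = 3."""
    if not math.isfinite(met) or met < 0:
        raise CodingError(f"MET-min/week must be finite and >= 0, got {met}")
    if met < 600:
        return 1
    if met < 3000:
        return 2
    return 3


# ---------------------------------------------------------------------------
# Raw-field encoders. Each maps a raw survey answer onto the Table-2 code;
# unrecognized values become MISSING with a warning (lenient contract).
# ---------------------------------------------------------------------------

_LABEL_ALIASES: dict[str, dict[str, int]] = {
    "sex": {"men": 1, "man": 1, "male": 1, "women": 2, "woman": 2, "female": 2},
    "residence": {
        "urban": 1, "town": 1,
        "boundary": 2, "combination": 2,
        "rural": 3, "village": 3,
        "special": 4, "special area": 4,
    },
    "marital_status": {
        "married": 1, "divorced": 2, "widowed": 3,
        "never married": 4, "single": 4,
    },
    "education": {
        "<=primary school": 1, "primary": 1, "<=primary": 1,
        "<=high school": 2, "<=middle school": 2, "high school": 2,
        "<=college": 3, "<college": 3, "college": 3,
        ">college": 4, ">=college": 4, "undergraduate and above": 4,
    },
    "physical_activity": {"light": 1, "moderate": 2, "vigorous": 3, "heavy": 3},
    "smoking": {"no": 0, "yes": 1},
    "alcohol": {"no": 0, "yes": 1},
    "mmd": {"no": 0, "yes": 1},
}


def _encode_label(name: str, value: object) -> int:
    table = _LABEL_ALIASES[name]
    key = str(value).strip().lower()
    if key in table:
        return table[key]
    warnings.warn(f"{name}: unrecognized label {value!r}; coded as missing", stacklevel=3)
    return MISSING


def _band_age(years: float) -> int:
    # Codes: <=55 -> 1; <=65 -> 2; <=75 -> 3; >75 -> 4.
    if years <= 55:
        return 1
    if years <= 65:
        return 2
    if years <= 75:
        return 3
    return 4


def _band_sleep(hours: float) -> int:
    # Codes: <=5 h -> 1; <=6 -> 2; <=7 -> 3; <=8 -> 4; >8 -> 5.
    for code, upper in ((1, 5), (2, 6), (3, 7), (4, 8)):
        if hours <= upper:
            return code
    return 5


def _band_nap(minutes: float) -> int:
    # Codes: 0 min -> 1; <=30 min -> 2; >30 min -> 3.
    if minutes <= 0:
        return 1
    if minutes <= 30:
        return 2
    return 3


def encode_record(raw: Mapping[str, object]) -> dict[str, int]:
    """Encode one raw survey record into integer study codes.

    Accepted raw fields (all optional; absent fields code as missing):

    - ``sex``, ``education``, ``residence``, ``marital_status``, ``smoking``,
      ``alcohol``: textual labels.
    - ``age_years``, ``sleep_hours``, ``nap_minutes``: numeric values, banded.
    - ``activity``: iterable of :class:`ActivityRecord` (or a precomputed
      ``met_min_week`` number), banded into the three activity levels.
    - ``conditions``: 14 binary chronic-condition flags, reduced to ``mmd``;
      or ``mmd`` directly as a label/code.

    Unrecognized labels code as :data:`MISSING` and emit a warning rather
    than raising, so one bad cell never drops a whole record.
    """
    out: dict[str, int] = {name: MISSING for name in VARIABLES}

    for name in ("sex", "education", "residence", "marital_status", "smoking", "alcohol"):
        if raw.get(name) is not None:
            out[name] = _encode_label(name, raw[name])
    if raw.get("age_years") is not None:
        out["age"] = _band_age(float(raw["age_years"]))
    if raw.get("sleep_hours") is not None:
        out["sleep"] = _band_sleep(float(raw["sleep_hours"]))
    if raw.get("nap_minutes") is not None:
        out["nap"] = _band_nap(float(raw["nap_minutes"]))

    if raw.get("activity") is not None:
        act = raw["activity"]
        met = float(act) if isinstance(act, (int, float)) else met_minutes(act)
        out["physical_activity"] = categorize_activity(met)
    elif raw.get("physical_activity") is not None:
        out["physical_activity"] = _encode_label("physical_activity", raw["physical_activity"])

    if raw.get("conditions") is not None:
        out["mmd"] = derive_mmd(raw["conditions"])  # type: ignore[arg-type]
    elif raw.get("mmd") is not None:
        out["mmd"] = _encode_label("mmd", raw["mmd"])
    return out


def decode_value(name: str, code: int) -> str:
    """Inverse of encoding for a single cell: code -> label."""
    if code == MISSING:
        return "missing"
    return CODEBOOK[name].label_of(code)


@dataclass(frozen=True)
class ValidationIssue:
    column: str
    kind: str  # "out_of_domain"
    count: int


@dataclass
class ValidationReport:
    n_rows: int
    issues: list[ValidationIssue] = field(default_factory=list)
    missing_fraction: dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.issues


def validate_dataset(
    data: pd.DataFrame, columns: Sequence[str] = VARIABLES
) -> ValidationReport:
    """Check a coded table against the codebook without mutating it.

    Reports per-column out-of-domain counts (excluding the missing sentinel
    and NaN, which count toward the missingness fraction instead). A missing
    required column is a structural :class:`DatasetError`.
    """
    absent = [c for c in columns if c not in data.columns]
    if absent:
        raise DatasetError(f"missing required column(s): {', '.join(absent)}")
    report = ValidationReport(n_rows=len(data))
    for col in columns:
        series = data[col]
        is_missing = series.isna() | (series == MISSING)
        report.missing_fraction[col] = float(is_missing.mean()) if len(series) else 0.0
        observed = series[~is_missing]
        bad = int((~observed.isin(CODEBOOK[col].domain)).sum())
        if bad:
            report.issues.append(ValidationIssue(col, "out_of_domain", bad))
    return report
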