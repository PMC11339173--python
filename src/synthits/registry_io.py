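"""Data model and I/O for health-event registries.

Event-level hospitalization/death records (date, ICD-10 code, age, sex),
annual population tables by 5-year age group, standard-population weight
tables for direct age standardization, and the study configuration that
ties them together (study window, policy month, smoothing window, analysis
age bands, cause definitions, donor-pool exclusions).

All tables are thin, validated wrappers around pandas DataFrames; reading
and writing goes through plain CSV / YAML.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: 5-year age groups used for standardization, 20 up to the open-ended 80+.
FIVE_YEAR_GROUPS: tuple[str, ...] = (
    "20-24", "25-29", "30-34", "35-39", "40-44", "45-49", "50-54",
    "55-59", "60-64", "65-69", "70-74", "75-79", "80+",
)

#: Analysis bands of the study design: three age strata plus everyone >= 20.
DEFAULT_ANALYSIS_BANDS: tuple[str, ...] = ("20-44", "45-64", "65+", "20+")

# ---------------------------------------------------------------------------
# age-band helpers


def parse_band(band: str) -> tuple[int, int | None]:
    """Parse an age-band label like ``"20-44"`` or ``"65+"`` into bounds.

    Returns ``(low, high)`` with ``high=None`` for an open-ended band.
    Both bounds are inclusive.
    """
    band = band.strip()
    if band.endswith("+"):
        return int(band[:-1]), None
    low, high = band.split("-")
    return int(low), int(high)


def age_to_group(age: int) -> str:
    """Map an age in years to its 5-year group label (ages >= 80 -> "80+")."""
    if age < 0:
        raise ValueError(f"negative age: {age}")
    for group in FIVE_YEAR_GROUPS:
        low, high = parse_band(group)
        if age >= low and (high is None or age <= high):
            return group
    raise ValueError(f"age {age} below the first group {FIVE_YEAR_GROUPS[0]}")


def groups_in_band(band: str) -> list[str]:
    """5-year groups whose full range lies inside the analysis band.

    The open-ended top group belongs to any band whose upper bound is open.
    """
    blow, bhigh = parse_band(band)
    out = []
    for group in FIVE_YEAR_GROUPS:
        glow, ghigh = parse_band(group)
        if glow < blow:
            continue
        if bhigh is None:
            out.append(group)
        elif ghigh is not None and ghigh <= bhigh:
            out.append(group)
    if not out:
        raise ValueError(f"band {band!r} contains no 5-year groups")
    return out


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class CauseDefinition:
    """A cause of hospitalization/death as a set of ICD-10 code ranges.

    ``icd10_ranges`` holds inclusive ranges such as ``"I20-I25"`` or single
    codes such as ``"I21"``; matching operates on the 3-character code root
    unless a range endpoint is given at 4 characters, in which case that
    range is compared at 4-character resolution. ``composite_of`` names
    member causes whose counts are summed (e.g. ischemic heart disease plus
    stroke as a combined cardiovascular outcome).
    """

    name: str
    icd10_ranges: tuple[str, ...] = ()
    composite_of: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "icd10_ranges", tuple(self.icd10_ranges))
        object.__setattr__(self, "composite_of", tuple(self.composite_of))
        if not self.icd10_ranges and not self.composite_of:
            raise ValueError(f"cause {self.name!r}: no ranges and no members")
        for rng in self.icd10_ranges:
            _parse_range(rng)


def _normalize_code(code: str) -> str:
    if not isinstance(code, str):
        raise ValueError(f"malformed ICD-10 code: {code!r}")
    code = code.strip().upper().replace(".", "")
    if not re.match(r"^[A-Z][0-9]{2}[0-9A-Z]{0,4}$", code):
        raise ValueError(f"malformed ICD-10 code: {code!r}")
    return code


def _parse_range(rng: str) -> tuple[str, str]:
    """Split ``"I20-I25"`` / ``"I21"`` into normalized (start, end) codes."""
    parts = [p.strip() for p in rng.split("-")]
    if len(parts) == 1:
        start = end = _normalize_code(parts[0])
    elif len(parts) == 2:
        start, end = _normalize_code(parts[0]), _normalize_code(parts[1])
    else:
        raise ValueError(f"malformed ICD-10 range: {rng!r}")
    if len(start) != len(end):
        raise ValueError(f"range endpoints differ in resolution: {rng!r}")
    if start > end:
        raise ValueError(f"descending ICD-10 range: {rng!r}")
    return start, end


def match_cause(icd10: str, cause: CauseDefinition,
                causes: Mapping[str, CauseDefinition] | None = None) -> bool:
    """True iff the code falls in any of the cause's ICD-10 ranges.

    A subcode (I21.4) inherits membership of its 3-character root (I21);
    ranges written at 4 characters are compared at that finer resolution.
    For a composite cause, ``causes`` must supply the member definitions.
    """
    code = _normalize_code(icd10)
    if cause.composite_of:
        if causes is None:
            raise ValueError(f"composite cause {cause.name!r} needs the cause registry")
        return any(match_cause(code, causes[m], causes) for m in cause.composite_of)
    for rng in cause.icd10_ranges:
        start, end = _parse_range(rng)
        key = code[: len(start)]
        if len(key) < len(start):  # e.g. 3-char code against a 4-char range
            continue
        if start <= key <= end:
            return True
    return False


@dataclass
class EventTable:
    """Individual or pre-counted health events.

    Columns: ``event_date`` (Timestamp), ``icd10`` (normalized code),
    ``age_years`` (int >= 0), ``sex`` ('M'/'F'), ``count`` (int >= 1).
    """

    df: pd.DataFrame

    REQUIRED = ("event_date", "icd10", "age_years", "sex", "count")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"EventTable missing columns: {missing}")
        if len(self.df) and (self.df["count"] < 1).any():
            raise ValueError("EventTable counts must be >= 1")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def total_events(self) -> int:
        return int(self.df["count"].sum())

    def to_csv(self, path: str | Path) -> None:
        out = self.df.rename(columns={"event_date": "date", "age_years": "age"})
        out.to_csv(path, index=False, date_format="%Y-%m-%d")


@dataclass
class PopulationTable:
    """Annual population by (year, 5-year age group, sex)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("year", "age_group", "sex", "population")
                   if c not in self.df.columns]
        if missing:
            raise ValueError(f"PopulationTable missing columns: {missing}")
        if (self.df["population"] <= 0).any():
            raise ValueError("populations must be positive")
        dup = self.df.duplicated(["year", "age_group", "sex"])
        if dup.any():
            raise ValueError("duplicate (year, age_group, sex) rows")

    @classmethod
    def from_csv(cls, path: str | Path) -> "PopulationTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    def get(self, year: int, age_group: str, sex: str = "all") -> float:
        """Population of one cell; sex='all' sums males and females."""
        sub = self.df[(self.df["year"] == year) & (self.df["age_group"] == age_group)]
        if sex != "all":
            sub = sub[sub["sex"] == sex]
        if sub.empty:
            raise KeyError(f"no population for ({year}, {age_group}, {sex})")
        return float(sub["population"].sum())


@dataclass
class StandardPopulation:
    """Standard-population weights by 5-year age group.

    Weights over any selected subset of groups are renormalized to sum to 1
    before use, so only their ratios matter.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("age_group", "weight") if c not in self.df.columns]
        if missing:
            raise ValueError(f"StandardPopulation missing columns: {missing}")
        if (self.df["weight"] < 0).any():
            raise ValueError("weights must be non-negative")

    @classmethod
    def from_csv(cls, path: str | Path) -> "StandardPopulation":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    def renormalized(self, groups: Sequence[str]) -> pd.Series:
        """Weights for the given groups, rescaled to sum to 1."""
        w = self.df.set_index("age_group")["weight"]
        missing = [g for g in groups if g not in w.index]
        if missing:
            raise KeyError(f"standard population lacks groups: {missing}")
        sub = w.loc[list(groups)].astype(float)
        total = sub.sum()
        if total <= 0:
            raise ValueError("selected standard weights sum to zero")
        return sub / total


def who_standard_population() -> StandardPopulation:
    """WHO World Standard population weights (2000-2025 vintage).

    Shipped with the package; the 80-84 and 85+ bands are collapsed to 80+
    to match the registry grid. Override by loading any other weight CSV.
    """
    with resources.files("synthits.data").joinpath("who_world_standard.csv").open() as fh:
        return StandardPopulation(pd.read_csv(fh))


@dataclass
class StudyConfig:
    """Study window, intervention timing, and analysis settings."""

    study_start: pd.Period
    study_end: pd.Period
    policy_month: pd.Period
    smoothing_window: int = 12
    min_age: int = 20
    age_bands: tuple[str, ...] = DEFAULT_ANALYSIS_BANDS
    causes: dict[str, CauseDefinition] = field(default_factory=dict)
    donor_exclusions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.study_start = pd.Period(self.study_start, freq="M")
        self.study_end = pd.Period(self.study_end, freq="M")
        self.policy_month = pd.Period(self.policy_month, freq="M")
        if not self.study_start < self.policy_month < self.study_end:
            raise ValueError("policy_month must lie strictly inside the study window")
        if self.smoothing_window < 1:
            raise ValueError("smoothing_window must be >= 1")
        self.age_bands = tuple(self.age_bands)
        for band in self.age_bands:
            groups_in_band(band)
        for cause in self.causes.values():
            for member in cause.composite_of:
                if member not in self.causes:
                    raise ValueError(
                        f"composite {cause.name!r} references undefined cause {member!r}")

    @property
    def months(self) -> pd.PeriodIndex:
        return pd.period_range(self.study_start, self.study_end, freq="M")


_CONFIG_DEFAULTS = {
    "smoothing_window": 12,
    "min_age": 20,
    "age_bands": list(DEFAULT_ANALYSIS_BANDS),
    "causes": {},
    "donor_exclusions": [],
}


def load_config(path: str | Path) -> StudyConfig:
    """Load a YAML study configuration, applying documented defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key, default in _CONFIG_DEFAULTS.items():
        raw.setdefault(key, default)
    causes = {
        name: CauseDefinition(
            name=name,
            icd10_ranges=tuple(spec.get("icd10_ranges", ())),
            composite_of=tuple(spec.get("composite_of", ())),
        )
        for name, spec in raw["causes"].items()
    }
    cfg = StudyConfig(
        study_start=raw["study_start"],
        study_end=raw["study_end"],
        policy_month=raw["policy_month"],
        smoothing_window=int(raw["smoothing_window"]),
        min_age=int(raw["min_age"]),
        age_bands=tuple(raw["age_bands"]),
        causes=causes,
        donor_exclusions=tuple(raw["donor_exclusions"]),
    )
    logger.info("resolved config: %s", cfg)
    return cfg


def save_config(cfg: StudyConfig, path: str | Path) -> None:
    raw = {
        "study_start": str(cfg.study_start),
        "study_end": str(cfg.study_end),
        "policy_month": str(cfg.policy_month),
        "smoothing_window": cfg.smoothing_window,
        "min_age": cfg.min_age,
        "age_bands": list(cfg.age_bands),
        "causes": {
            c.name: {
                "icd10_ranges": list(c.icd10_ranges),
                "composite_of": list(c.composite_of),
            }
            for c in cfg.causes.values()
        },
        "donor_exclusions": list(cfg.donor_exclusions),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# event reading

_DEFAULT_SCHEMA = {"date": "date", "icd10": "icd10", "age": "age", "sex": "sex",
                   "count": "count"}


def read_events(path: str | Path, schema: Mapping[str, str] | None = None,
                min_age: int = 20,
                study_start: pd.Period | None = None,
                study_end: pd.Period | None = None) -> EventTable:
    """Read an events CSV into a validated :class:`EventTable`.

    ``schema`` maps logical names {date, icd10, age, sex, count} to the
    file's column names; the count column is optional and defaults to 1.
    Rows below ``min_age`` are dropped with a logged count, as are rows
    outside the study window when one is given. Unparseable dates or codes
    raise with the offending line number.
    """
    colmap = dict(_DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    raw = pd.read_csv(path, dtype=str)
    required = ["date", "icd10", "age", "sex"]
    missing = [colmap[k] for k in required if colmap[k] not in raw.columns]
    if missing:
        raise ValueError(f"events file {path}: missing columns {missing}")

    if raw.empty:
        empty = pd.DataFrame(columns=list(EventTable.REQUIRED))
        empty["count"] = empty["count"].astype(int)
        return EventTable(empty)

    dates = pd.to_datetime(raw[colmap["date"]], format="ISO8601", errors="coerce")
    bad = dates.isna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header + 1-based
        raise ValueError(f"{path}: unparseable date on line {line}")

    codes = []
    for i, code in enumerate(raw[colmap["icd10"]]):
        try:
            codes.append(_normalize_code(code))
        except ValueError as exc:
            raise ValueError(f"{path}: line {i + 2}: {exc}") from exc

    ages = pd.to_numeric(raw[colmap["age"]], errors="coerce")
    if ages.isna().any():
        line = int(ages.isna().idxmax()) + 2
        raise ValueError(f"{path}: unparseable age on line {line}")

    sex = raw[colmap["sex"]].str.strip().str.upper().str[0]
    if not sex.isin(["M", "F"]).all():
        line = int((~sex.isin(["M", "F"])).idxmax()) + 2
        raise ValueError(f"{path}: unrecognized sex on line {line}")

    if colmap["count"] in raw.columns:
        counts = pd.to_numeric(raw[colmap["count"]]).astype(int)
    else:
        counts = pd.Series(1, index=raw.index)

    df = pd.DataFrame({
        "event_date": dates,
        "icd10": codes,
        "age_years": ages.astype(int),
        "sex": sex,
        "count": counts,
    })

    under = df["age_years"] < min_age
    if under.any():
        logger.info("dropping %d rows below age %d", int(under.sum()), min_age)
        df = df[~under]
    if study_start is not None and study_end is not None:
        months = df["event_date"].dt.to_period("M")
        outside = (months < study_start) | (months > study_end)
        if outside.any():
            logger.info("dropping %d rows outside the study window", int(outside.sum()))
            df = df[~outside]
    return EventTable(df.reset_index(drop=True))
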