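"""Core domain types for OAT episode construction.

Dispensation coverage is modelled as half-open integer-day intervals
``[start, end)``: a 7-day supply picked up on day *d* covers days
``d .. d+6`` and ends (exclusively) on day ``d + 7``.  Under this
convention two records where one ends exactly where the next starts share
no covered day and leave no gap -- the natural reading of back-to-back
days-supply -- and every ordered pair of records falls into exactly one
temporal relation at day granularity.

Day indices count days since 1970-01-01 (the Unix epoch date); the
conversion is exact and invertible for any calendar date, so calendar
dates are only touched at the I/O boundary.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

__all__ = [
    "DRUG_CLASSES",
    "DEFAULT_PERMISSIBLE_GAPS",
    "MONOTHERAPY",
    "TRANSITION",
    "MULTITHERAPY",
    "TRANSITION_MULTITHERAPY",
    "EPISODE_TYPES",
    "day_index",
    "day_to_date",
    "Interval",
    "Dispensation",
    "DoseSegment",
    "DrugPolicy",
    "EpisodeConfig",
    "Episode",
    "HospitalStay",
    "default_config",
]

_EPOCH_ORDINAL = _dt.date(1970, 1, 1).toordinal()

#: The four OAT drug classes handled by the framework.
DRUG_CLASSES = ("methadone", "bup_nal", "srom", "ioat")

#: Maximum uncovered interruption (whole days) tolerated within a continuous
#: episode, per drug class.  Informed by BC OAT clinical guidance and the
#: medications' half-lives: 5 days for the full agonists methadone and
#: slow-release oral morphine, 6 days for buprenorphine/naloxone, and
#: 3 days for injectable OAT.
DEFAULT_PERMISSIBLE_GAPS = {"methadone": 5, "bup_nal": 6, "srom": 5, "ioat": 3}

MONOTHERAPY = "monotherapy"
TRANSITION = "transition"
MULTITHERAPY = "multitherapy"
TRANSITION_MULTITHERAPY = "transition_multitherapy"
EPISODE_TYPES = (MONOTHERAPY, TRANSITION, MULTITHERAPY, TRANSITION_MULTITHERAPY)


def day_index(date: _dt.date) -> int:
    """Convert a calendar date to an integer day index (days since 1970-01-01)."""
    return date.toordinal() - _EPOCH_ORDINAL


def day_to_date(day: int) -> _dt.date:
    """Inverse of :func:`day_index`."""
    return _dt.date.fromordinal(day + _EPOCH_ORDINAL)


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open integer-day coverage window ``[start, end)``.

    ``end > start`` is required: a dispensation covers at least one day.
    """

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"degenerate interval [{self.start}, {self.end}): end must exceed start"
            )

    @property
    def duration(self) -> int:
        return self.end - self.start

    def shift(self, days: int) -> "Interval":
        return Interval(self.start + days, self.end + days)

    def overlap_days(self, other: "Interval") -> int:
        """Number of days covered by both intervals (0 if disjoint)."""
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def covers(self, day: int) -> bool:
        return self.start <= day < self.end

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"[{self.start}, {self.end})"


@dataclass
class Dispensation:
    """One pharmacy fill of an OAT medication.

    The coverage interval is derived from the date of service and the days
    supply; the daily dose is quantity x strength / days supply (mg/day),
    and QPD (quantity per day) is quantity / days supply.  ``shift_days``
    records any forward shift applied by overlap recoding, so the original
    service day is always recoverable as ``service_day - shift_days``.
    """

    person_id: str
    drug: str
    service_day: int
    days_supply: int
    quantity: float
    strength: float
    din: str = ""
    flags: set = field(default_factory=set)
    shift_days: int = 0

    def __post_init__(self) -> None:
        if self.days_supply < 1:
            raise ValueError(f"days_supply must be >= 1, got {self.days_supply}")
        if self.quantity <= 0:
            raise ValueError(f"quantity must be positive, got {self.quantity}")
        if self.strength <= 0:
            raise ValueError(f"strength must be positive, got {self.strength}")

    @property
    def interval(self) -> Interval:
        return Interval(self.service_day, self.service_day + self.days_supply)

    @property
    def daily_dose(self) -> float:
        """Dispensed dose in mg/day."""
        return self.quantity * self.strength / self.days_supply

    @property
    def qpd(self) -> float:
        """Quantity per day -- the cleaning module's plausibility signal."""
        return self.quantity / self.days_supply

    @property
    def total_mg(self) -> float:
        return self.quantity * self.strength

    def shifted(self, days: int) -> "Dispensation":
        """Copy of this record with the service day moved forward ``days`` days."""
        out = replace(
            self,
            service_day=self.service_day + days,
            flags=set(self.flags) | ({"shifted"} if days else set()),
            shift_days=self.shift_days + days,
        )
        return out


@dataclass(frozen=True)
class DoseSegment:
    """A constant-dose piece of an episode: one drug at ``mg_per_day`` over ``interval``."""

    interval: Interval
    drug: str
    mg_per_day: float


@dataclass(frozen=True)
class DrugPolicy:
    """Per-drug configuration: the permissible gap and the catalog codes mapping to it."""

    drug: str
    permissible_gap: int
    catalog_codes: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.permissible_gap < 0:
            raise ValueError("permissible_gap must be >= 0")


@dataclass
class EpisodeConfig:
    """Tunable parameters of the episode-construction framework.

    ``epsilon_same`` (default 7 days) bounds the same-drug overlaps that are
    recoded to *meets*; ``epsilon_cross`` (default 14 days) separates
    transition from multitherapy when different drugs' coverage overlaps.
    """

    epsilon_same: int = 7
    epsilon_cross: int = 14
    policies: dict = field(default_factory=dict)
    bridge_hospitalizations: bool = True

    def __post_init__(self) -> None:
        if self.epsilon_same < 0 or self.epsilon_cross < 0:
            raise ValueError("temporal margins must be >= 0")
        if not self.policies:
            self.policies = {
                d: DrugPolicy(d, g) for d, g in DEFAULT_PERMISSIBLE_GAPS.items()
            }

    def gap(self, drug: str) -> int:
        """Permissible gap for ``drug``; unknown drugs get the strictest default."""
        try:
            return self.policies[drug].permissible_gap
        except KeyError:
            return min(p.permissible_gap for p in self.policies.values())


def default_config() -> EpisodeConfig:
    """The framework's default configuration (epsilon 7/14, printed permissible gaps)."""
    return EpisodeConfig()


@dataclass
class Episode:
    """A contiguous treatment span for one person.

    ``end`` is exclusive (last covered day + 1).  ``drug_sequence`` lists
    drug classes in first-appearance order after absorption of short nested
    cross-drug records; an episode is monotherapy iff it contains exactly
    one drug class.
    """

    person_id: str
    episode_id: str
    start: int
    end: int
    type: str
    drug_sequence: tuple
    n_dispensations: int
    max_co_dispensation_days: int = 0
    n_switches: int = 0
    dose_segments: tuple = ()
    bridged_hospital_days: int = 0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("episode end must exceed start")
        if self.type not in EPISODE_TYPES:
            raise ValueError(f"unknown episode type {self.type!r}")

    @property
    def duration_days(self) -> int:
        return self.end - self.start

    @property
    def span(self) -> Interval:
        return Interval(self.start, self.end)


@dataclass(frozen=True)
class HospitalStay:
    """An inpatient interval ``[admit, discharge)`` in day indices."""

    person_id: str
    admit: int
    discharge: int

    def __post_init__(self) -> None:
        if self.discharge <= self.admit:
            raise ValueError("discharge must be after admission")

    @property
    def length(self) -> int:
        return self.discharge - self.admit
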