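"""Logic-based pre-episode corrections of raw dispensation rows.

Raw pharmacy claims contain split-dose rows, quantity-per-day (QPD)
outliers from data-entry slips, and days-supply values that overshoot the
next fill of the same product.  The pipeline applies three deterministic
rules, in a fixed order, and records everything it touches in an audit
report:

1. ``consolidate_split_doses`` -- same-person, same-product, same-day rows
   are merged (quantities summed, days supply = group maximum), provided
   their strengths agree; discordant strengths are flagged and left alone.
2. ``repair_qpd_outliers`` -- a row whose QPD deviates from the median QPD
   of its adjacent same-product records by more than a configurable factor
   is repaired: first by recalculating the days supply when that lands in
   a plausible range, otherwise by resetting the quantity to match the
   neighbourhood's QPD.
3. ``cap_days_supply`` -- a days supply that extends past the next fill of
   the same product is reset to the inter-fill interval.

All three rules compare records within the same (person, product-code)
stream.  Same-day or overlapping records of *different* products of one
drug class are legitimate dispensing patterns (witnessed ingestion, split
dosing, early refills) and are deliberately left for the episode builder's
temporal-relation machinery, not treated as errors.

The full pipeline is idempotent: cleaning a cleaned table changes nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

from .core import Dispensation

__all__ = [
    "CleaningConfig",
    "CleaningReport",
    "consolidate_split_doses",
    "repair_qpd_outliers",
    "cap_days_supply",
    "clean",
]


@dataclass(frozen=True)
class CleaningConfig:
    """Thresholds of the cleaning rules.

    ``qpd_deviation_factor`` (default 2.0): multiplicative deviation from
    the adjacent-record median QPD (either direction) that flags a row.
    ``adjacency_window`` (default 2): records examined on each side, same
    person and product.  ``plausible_supply_range`` (default 1..28 days):
    OAT is dispensed daily to roughly monthly (the monthly depot
    buprenorphine injection sets the 28-day ceiling), so a recalculated
    days supply outside this range is rejected in favour of a quantity
    correction.
    """

    qpd_deviation_factor: float = 2.0
    adjacency_window: int = 2
    plausible_supply_min: int = 1
    plausible_supply_max: int = 28

    def __post_init__(self) -> None:
        if self.qpd_deviation_factor <= 1:
            raise ValueError("qpd_deviation_factor must exceed 1")
        if self.adjacency_window < 1:
            raise ValueError("adjacency_window must be >= 1")
        if not (1 <= self.plausible_supply_min <= self.plausible_supply_max):
            raise ValueError("implausible plausible_supply_range")


@dataclass
class CleaningReport:
    """Bookkeeping for one cleaning pass: per-rule counts and a row-level audit trail."""

    n_input: int = 0
    rule_flagged: dict = field(default_factory=dict)
    rule_corrected: dict = field(default_factory=dict)
    audit: list = field(default_factory=list)

    @property
    def n_flagged(self) -> int:
        return sum(self.rule_flagged.values())

    @property
    def n_corrected(self) -> int:
        return sum(self.rule_corrected.values())

    def log(self, rule: str, disp: Dispensation, field_name: str, before, after) -> None:
        self.rule_flagged[rule] = self.rule_flagged.get(rule, 0) + 1
        corrected = before != after
        if corrected:
            self.rule_corrected[rule] = self.rule_corrected.get(rule, 0) + 1
        self.audit.append(
            {
                "rule": rule,
                "person_id": disp.person_id,
                "drug": disp.drug,
                "din": disp.din,
                "service_day": disp.service_day,
                "field": field_name,
                "before": before,
                "after": after,
            }
        )

    def merge(self, other: "CleaningReport") -> None:
        for rule, n in other.rule_flagged.items():
            self.rule_flagged[rule] = self.rule_flagged.get(rule, 0) + n
        for rule, n in other.rule_corrected.items():
            self.rule_corrected[rule] = self.rule_corrected.get(rule, 0) + n
        self.audit.extend(other.audit)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_flagged": self.n_flagged,
            "n_corrected": self.n_corrected,
            "rule_flagged": dict(self.rule_flagged),
            "rule_corrected": dict(self.rule_corrected),
            "audit": list(self.audit),
        }


def _sort_key(d: Dispensation):
    return (d.person_id, d.drug, d.din, d.service_day, d.interval.end)


def _stream_key(d: Dispensation):
    return (d.person_id, d.drug, d.din)


def consolidate_split_doses(
    rows: Sequence[Dispensation], report: CleaningReport | None = None
) -> list[Dispensation]:
    """Merge same-person, same-product, same-day rows by summing quantities.

    Days supply of the merged row is the group's maximum; total quantity is
    conserved.  Groups whose strengths disagree cannot be summed safely and
    are flagged but left unmerged.
    """
    report = report if report is not None else CleaningReport()
    rows = sorted(rows, key=_sort_key)
    out: list[Dispensation] = []
    i = 0
    while i < len(rows):
        j = i
        while (
            j + 1 < len(rows)
            and _stream_key(rows[j + 1]) == _stream_key(rows[i])
            and rows[j + 1].service_day == rows[i].service_day
        ):
            j += 1
        group = rows[i : j + 1]
        if len(group) == 1:
            out.append(group[0])
        elif len({g.strength for g in group}) > 1:
            for g in group:
                g.flags.add("split_dose_strength_mismatch")
                report.log(
                    "split_dose_strength_mismatch", g, "quantity", g.quantity, g.quantity
                )
            out.extend(group)
        else:
            total_q = sum(g.quantity for g in group)
            merged = replace(
                group[0],
                quantity=total_q,
                days_supply=max(g.days_supply for g in group),
                flags=set.union(*(set(g.flags) for g in group)) | {"consolidated"},
            )
            report.log(
                "split_dose_consolidated",
                merged,
                "quantity",
                [g.quantity for g in group],
                total_q,
            )
            out.append(merged)
        i = j + 1
    return out


def _lower_median(values: Sequence[float]) -> float:
    """Median taking the lower of the two middle values for even counts.

    Conservative tie-break: avoids inflating the reference dose when the
    neighbourhood is split between two levels.
    """
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def repair_qpd_outliers(
    rows: Sequence[Dispensation],
    cfg: CleaningConfig | None = None,
    report: CleaningReport | None = None,
) -> tuple[list[Dispensation], CleaningReport]:
    """Repair rows whose QPD deviates from the adjacent-record median.

    For each row the reference is the median QPD of up to
    ``adjacency_window`` records on each side in the same (person, product)
    stream, computed from the values as they stood at the start of the pass
    (so corrections do not feed into later references within one pass).
    A row deviating by more than ``qpd_deviation_factor`` (ratio or its
    inverse) is repaired: recalculate the days supply as
    ``round(quantity / median_QPD)`` when that is plausible -- inside the
    configured supply range and not overshooting the next fill of the
    same product -- otherwise reset the quantity to
    ``median_QPD * days_supply``.  Rows with fewer than two neighbours
    are never altered.
    """
    cfg = cfg or CleaningConfig()
    report = report if report is not None else CleaningReport()
    rows = sorted(rows, key=_sort_key)
    # Snapshot of QPDs per stream, taken before any repair in this pass.
    streams: dict = {}
    for idx, d in enumerate(rows):
        streams.setdefault(_stream_key(d), []).append(idx)
    snapshot_qpd = [d.qpd for d in rows]
    out = list(rows)
    for key, idxs in streams.items():
        for pos, idx in enumerate(idxs):
            lo = max(0, pos - cfg.adjacency_window)
            neighbours = idxs[lo:pos] + idxs[pos + 1 : pos + 1 + cfg.adjacency_window]
            if len(neighbours) < 2:
                continue
            med = _lower_median([snapshot_qpd[n] for n in neighbours])
            qpd = snapshot_qpd[idx]
            ratio = qpd / med
            if ratio <= cfg.qpd_deviation_factor and 1 / ratio <= cfg.qpd_deviation_factor:
                continue
            d = out[idx]
            new_ds = int(d.quantity / med + 0.5)
            next_gap = None
            if pos + 1 < len(idxs):
                next_gap = rows[idxs[pos + 1]].service_day - d.service_day
            plausible = (
                cfg.plausible_supply_min <= new_ds <= cfg.plausible_supply_max
                and (next_gap is None or new_ds <= next_gap)
            )
            if plausible:
                repaired = replace(
                    d, days_supply=new_ds, flags=set(d.flags) | {"qpd_days_supply_recalc"}
                )
                report.log("qpd_days_supply_recalc", d, "days_supply", d.days_supply, new_ds)
            else:
                new_q = med * d.days_supply
                repaired = replace(
                    d, quantity=new_q, flags=set(d.flags) | {"qpd_quantity_reset"}
                )
                report.log("qpd_quantity_reset", d, "quantity", d.quantity, new_q)
            out[idx] = repaired
    return out, report


def cap_days_supply(
    rows: Sequence[Dispensation], report: CleaningReport | None = None
) -> tuple[list[Dispensation], CleaningReport]:
    """Reset days-supply values that overshoot the next fill of the same product.

    For consecutive records x, y in one (person, product) stream, if
    ``x.days_supply > y.service_day - x.service_day`` then x's days supply
    is reset to that inter-fill interval (minimum 1 day).  The last record
    of each stream is never capped; quantities are unchanged, so the
    implied daily dose is recomputed through the derived field.
    """
    report = report if report is not None else CleaningReport()
    rows = sorted(rows, key=_sort_key)
    out = list(rows)
    for idx in range(len(rows) - 1):
        x, y = out[idx], out[idx + 1]
        if _stream_key(x) != _stream_key(y):
            continue
        interval = y.service_day - x.service_day
        if interval == 0:
            raise ValueError(
                f"duplicate same-day rows for {x.person_id!r}/{x.din!r} on day "
                f"{x.service_day}; run consolidate_split_doses first"
            )
        if x.days_supply > interval:
            new_ds = max(1, interval)
            out[idx] = replace(
                x, days_supply=new_ds, flags=set(x.flags) | {"days_supply_capped"}
            )
            report.log("days_supply_capped", x, "days_supply", x.days_supply, new_ds)
    return out, report


def clean(
    rows: Sequence[Dispensation], cfg: CleaningConfig | None = None
) -> tuple[list[Dispensation], CleaningReport]:
    """Full cleaning pipeline: consolidate -> QPD repair -> days-supply cap.

    The order is fixed: capping depends on consolidated dates, and QPD
    repair should see original supplies.  The pipeline is idempotent.
    """
    cfg = cfg or CleaningConfig()
    report = CleaningReport(n_input=len(rows))
    out = consolidate_split_doses(rows, report)
    out, _ = repair_qpd_outliers(out, cfg, report)
    out, _ = cap_days_supply(out, report)
    # Corrections can interact when one record carries several errors
    # (e.g. a capped supply exposing a quantity inconsistency); iterate to
    # a fixed point so cleaning a cleaned table changes nothing.
    for _ in range(5):
        again = CleaningReport(n_input=len(out))
        out2 = consolidate_split_doses(out, again)
        out2, _ = repair_qpd_outliers(out2, cfg, again)
        out2, _ = cap_days_supply(out2, again)
        if again.n_corrected == 0:
            break
        report.merge(again)
        out = out2
    return out, report
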