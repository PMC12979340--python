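"""The episode state machine.

A chronological sweep over one person's cleaned dispensations maintains a
set of *active drug threads* (one per drug class currently contributing
coverage).  Consecutive records of one drug are linked by concatenation
(*meets*), short interruptions (*before* within the drug's permissible
gap), short-overlap recoding (*overlaps* <= epsilon recoded to *meets* by
shifting the later record forward), or aggregation of nested records
(dose summed over the shared period).  When a different drug appears, the
cross-drug margin (default 14 days) separates switches with continuity of
care (transition) from genuine concurrency (multitherapy): short
cross-drug overlaps are recoded to *meets* and logged as switches, short
nested records are absorbed into the encompassing drug, short *equals*
pairs are excluded outright, and anything longer opens a concurrent
thread.  An episode closes when every active thread's coverage end has
been exceeded by more than its drug's permissible gap.

Episode typing: monotherapy iff one drug class remains after absorption;
otherwise the episode is a transition if it contains at least one switch
and no co-dispensation longer than the cross-drug margin, a multitherapy
if the reverse, and a transition-multitherapy if both occurred.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from . import allen
from .core import (
    MONOTHERAPY,
    MULTITHERAPY,
    TRANSITION,
    TRANSITION_MULTITHERAPY,
    Dispensation,
    DoseSegment,
    DrugPolicy,
    Episode,
    EpisodeConfig,
    Interval,
    default_config,
)
from .summaries import five_number_row

__all__ = [
    "SwitchEvent",
    "ConcurrencySegment",
    "recode_same_drug_overlap",
    "aggregate_nested",
    "link_same_drug",
    "link_cross_drug",
    "build_episodes",
    "co_dispensation_patterns",
    "CONTINUE",
    "DISCONTINUE",
    "TRANSITION_LINK",
    "MULTITHERAPY_OPEN",
    "ABSORB",
    "EXCLUDE",
    "NEW_EPISODE",
]

# link decisions
CONTINUE = "continue"
DISCONTINUE = "discontinue"
TRANSITION_LINK = "transition"
MULTITHERAPY_OPEN = "multitherapy_open"
ABSORB = "absorb"
EXCLUDE = "exclude"
NEW_EPISODE = "new_episode"

#: same-drug nested relations handled by aggregation (sorted input cannot
#: produce ``during``/``started_by``/``finishes``, but they are accepted
#: for completeness of the standalone operation).
_NESTED = {
    "starts",
    "started_by",
    "finishes",
    "finished_by",
    "contains",
    "during",
    "equals",
}

#: cross-drug relations where the earlier record encompasses the later.
_X_ENCLOSES_Y = {"contains", "finished_by", "started_by"}
#: cross-drug relations where the later record encompasses the earlier.
_Y_ENCLOSES_X = {"starts", "during"}


@dataclass(frozen=True)
class SwitchEvent:
    """A change of drug with continuity of care."""

    day: int
    from_drug: str
    to_drug: str
    mechanism: str  # meets | within_gap_before | short_overlap_recode

    def __post_init__(self) -> None:
        if self.from_drug == self.to_drug:
            raise ValueError("a switch needs two distinct drugs")


@dataclass(frozen=True)
class ConcurrencySegment:
    """A maximal span over which two or more drugs' coverage overlaps."""

    interval: Interval
    drugs: frozenset


def recode_same_drug_overlap(
    x: Dispensation, y: Dispensation, epsilon_same: int
) -> tuple[Dispensation, allen.Relation]:
    """Recode a short same-drug overlap to *meets* by shifting the later record.

    If the overlap is <= ``epsilon_same`` days the subsequent dispensation
    is shifted forward (start and end both move; days supply is preserved)
    until it abuts the first, and the relation becomes *meets*.  Longer
    overlaps are left untouched.  The shift is recorded on the returned
    record, so subsequent relations cascade against the shifted position.
    """
    rel = allen.classify(x.interval, y.interval)
    if rel.label != "overlaps":
        raise ValueError(f"recode requires an overlaps pair, got {rel.label!r}")
    if rel.overlap_days <= epsilon_same:
        y2 = y.shifted(rel.overlap_days)
        return y2, allen.Relation("meets")
    return y, rel


def aggregate_nested(x: Dispensation, y: Dispensation) -> list[tuple[Interval, float]]:
    """Merge two nested same-drug records into piecewise dose segments.

    The merged span is the union of the two intervals (for *contains*,
    the endpoints of the record with the larger days supply); the daily
    dose is the sum of both records over the nested (shared) period and
    the outer record's dose elsewhere.  Total dispensed mg is conserved.
    """
    rel = allen.classify(x.interval, y.interval)
    if rel.label not in _NESTED:
        raise ValueError(f"aggregation requires a nested relation, got {rel.label!r}")
    points = sorted(
        {x.interval.start, x.interval.end, y.interval.start, y.interval.end}
    )
    segments: list[tuple[Interval, float]] = []
    for a, b in zip(points, points[1:]):
        seg = Interval(a, b)
        dose = 0.0
        for d in (x, y):
            if d.interval.overlap_days(seg) == seg.duration:
                dose += d.daily_dose
        if dose > 0:
            segments.append((seg, dose))
    return segments


def link_same_drug(
    x: Dispensation,
    y: Dispensation,
    policy: DrugPolicy,
    epsilon_same: int,
) -> tuple[str, Dispensation, allen.Relation]:
    """Decide whether record y continues x's same-drug thread.

    *meets* and *before* within the permissible gap continue the episode;
    *before* beyond the gap discontinues it; overlaps are recoded against
    the margin and then continue; nested relations aggregate and continue.
    Returns (decision, effective y, effective relation).
    """
    if x.drug != y.drug:
        raise ValueError("link_same_drug requires records of one drug class")
    rel = allen.classify(x.interval, y.interval)
    if rel.label == "meets":
        return CONTINUE, y, rel
    if rel.label == "before":
        if rel.gap_days <= policy.permissible_gap:
            return CONTINUE, y, rel
        return DISCONTINUE, y, rel
    if rel.label == "overlaps":
        y2, rel2 = recode_same_drug_overlap(x, y, epsilon_same)
        return CONTINUE, y2, rel2
    if rel.label in _NESTED:
        return CONTINUE, y, rel
    raise ValueError(f"unexpected same-drug relation {rel.label!r} for sorted input")


def link_cross_drug(
    x: Dispensation,
    y: Dispensation,
    cfg: EpisodeConfig,
    coverage_end: int | None = None,
) -> tuple[str, Dispensation, allen.Relation, SwitchEvent | None]:
    """Decide how record y of a new drug relates to the active thread ending with x.

    ``coverage_end`` lets the episode builder pass the thread's full
    coverage end when nested records have extended it past ``x``; for a
    plain two-record comparison it defaults to x's own end.  Returns
    (decision, effective y, relation, switch event or None).
    """
    if x.drug == y.drug:
        raise ValueError("link_cross_drug requires records of different drug classes")
    cov_end = x.interval.end if coverage_end is None else coverage_end
    rel = allen.classify(x.interval, y.interval)
    eff_gap = y.interval.start - cov_end

    if eff_gap == 0:
        switch = SwitchEvent(y.interval.start, x.drug, y.drug, "meets")
        return TRANSITION_LINK, y, rel, switch
    if eff_gap > 0:
        # A positive gap: the grace period of the *previous* drug applies.
        if eff_gap <= cfg.gap(x.drug):
            switch = SwitchEvent(y.interval.start, x.drug, y.drug, "within_gap_before")
            return TRANSITION_LINK, y, rel, switch
        return NEW_EPISODE, y, rel, None

    # Coverage overlap exists.
    if rel.label == "equals":
        if rel.overlap_days <= cfg.epsilon_cross:
            return EXCLUDE, y, rel, None
        return MULTITHERAPY_OPEN, y, rel, None
    if rel.label in _X_ENCLOSES_Y or rel.label in _Y_ENCLOSES_X:
        if rel.overlap_days <= cfg.epsilon_cross:
            return ABSORB, y, rel, None
        return MULTITHERAPY_OPEN, y, rel, None
    # overlaps (possibly only against the extended coverage end)
    co_disp = cov_end - y.interval.start
    if co_disp <= cfg.epsilon_cross:
        y2 = y.shifted(co_disp)
        switch = SwitchEvent(y2.interval.start, x.drug, y.drug, "short_overlap_recode")
        return TRANSITION_LINK, y2, rel, switch
    return MULTITHERAPY_OPEN, y, rel, None


# ---------------------------------------------------------------------------
# the sweep


@dataclass
class _Member:
    disp: Dispensation
    eff_drug: str


@dataclass
class _Thread:
    drug: str
    records: list  # of _Member
    cov_end: int

    @property
    def last(self) -> Dispensation:
        return self.records[-1].disp


def _coverage_union(intervals: Iterable[Interval]) -> list[Interval]:
    """Merge possibly-overlapping intervals into disjoint coverage."""
    ivs = sorted(intervals, key=lambda i: (i.start, i.end))
    out: list[Interval] = []
    for iv in ivs:
        if out and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = Interval(out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


def _concurrency_segments(records: Sequence[_Member]) -> list[ConcurrencySegment]:
    by_drug: dict[str, list[Interval]] = {}
    for m in records:
        by_drug.setdefault(m.eff_drug, []).append(m.disp.interval)
    coverage = {d: _coverage_union(ivs) for d, ivs in by_drug.items()}
    points = sorted({p for ivs in coverage.values() for iv in ivs for p in (iv.start, iv.end)})
    raw: list[tuple[Interval, frozenset]] = []
    for a, b in zip(points, points[1:]):
        drugs = frozenset(
            d for d, ivs in coverage.items() if any(iv.start <= a and b <= iv.end for iv in ivs)
        )
        if len(drugs) >= 2:
            raw.append((Interval(a, b), drugs))
    # merge adjacent segments with identical drug sets
    merged: list[ConcurrencySegment] = []
    for iv, drugs in raw:
        if merged and merged[-1].drugs == drugs and merged[-1].interval.end == iv.start:
            merged[-1] = ConcurrencySegment(
                Interval(merged[-1].interval.start, iv.end), drugs
            )
        else:
            merged.append(ConcurrencySegment(iv, drugs))
    return merged


def _dose_segments(records: Sequence[_Member]) -> tuple[DoseSegment, ...]:
    by_drug: dict[str, list[Dispensation]] = {}
    for m in records:
        by_drug.setdefault(m.eff_drug, []).append(m.disp)
    out: list[DoseSegment] = []
    for drug in sorted(by_drug):
        disps = by_drug[drug]
        points = sorted({p for d in disps for p in (d.interval.start, d.interval.end)})
        pending: DoseSegment | None = None
        for a, b in zip(points, points[1:]):
            dose = sum(
                d.daily_dose for d in disps if d.interval.start <= a and b <= d.interval.end
            )
            if dose <= 0:
                if pending:
                    out.append(pending)
                    pending = None
                continue
            if pending and pending.mg_per_day == dose and pending.interval.end == a:
                pending = DoseSegment(Interval(pending.interval.start, b), drug, dose)
            else:
                if pending:
                    out.append(pending)
                pending = DoseSegment(Interval(a, b), drug, dose)
        if pending:
            out.append(pending)
    out.sort(key=lambda s: (s.interval.start, s.drug))
    return tuple(out)


class _EpisodeAccumulator:
    """State of one in-progress episode during the sweep."""

    def __init__(self, person_id: str):
        self.person_id = person_id
        self.members: list[_Member] = []
        self.threads: dict[str, _Thread] = {}
        self.switches: list[SwitchEvent] = []

    @property
    def empty(self) -> bool:
        return not self.members

    def open_thread(self, disp: Dispensation, eff_drug: str | None = None) -> None:
        m = _Member(disp, eff_drug or disp.drug)
        self.members.append(m)
        t = self.threads.get(m.eff_drug)
        if t is None:
            self.threads[m.eff_drug] = _Thread(m.eff_drug, [m], disp.interval.end)
        else:
            t.records.append(m)
            t.cov_end = max(t.cov_end, disp.interval.end)

    def absorb(self, disp: Dispensation, into_drug: str) -> None:
        disp.flags.add("absorbed")
        m = _Member(disp, into_drug)
        self.members.append(m)
        t = self.threads[into_drug]
        t.records.append(m)
        t.cov_end = max(t.cov_end, disp.interval.end)

    def reassign_last(self, thread: _Thread, new_drug: str) -> None:
        """Move a thread's last record into another drug (the encompassing one)."""
        m = thread.records.pop()
        m.disp.flags.add("absorbed")
        m.eff_drug = new_drug
        if not thread.records:
            del self.threads[thread.drug]
        else:
            thread.cov_end = max(r.disp.interval.end for r in thread.records)
        t = self.threads.get(new_drug)
        if t is None:
            self.threads[new_drug] = _Thread(new_drug, [m], m.disp.interval.end)
        else:
            t.records.append(m)
            t.cov_end = max(t.cov_end, m.disp.interval.end)

    def drop_last_of(self, thread: _Thread) -> None:
        m = thread.records.pop()
        m.disp.flags.add("excluded_equals")
        self.members.remove(m)
        if not thread.records:
            del self.threads[thread.drug]
        else:
            thread.cov_end = max(r.disp.interval.end for r in thread.records)

    def close(self, episode_id: str, cfg: EpisodeConfig) -> Episode | None:
        if not self.members:
            return None
        start = min(m.disp.interval.start for m in self.members)
        end = max(m.disp.interval.end for m in self.members)
        seq: list[str] = []
        for m in self.members:
            if m.eff_drug not in seq:
                seq.append(m.eff_drug)
        segments = _concurrency_segments(self.members)
        max_co = max((s.interval.duration for s in segments), default=0)
        has_multi = max_co > cfg.epsilon_cross
        has_switch = bool(self.switches)
        if len(seq) == 1:
            etype = MONOTHERAPY
        elif has_switch and has_multi:
            etype = TRANSITION_MULTITHERAPY
        elif has_multi:
            etype = MULTITHERAPY
        else:
            etype = TRANSITION
        return Episode(
            person_id=self.person_id,
            episode_id=episode_id,
            start=start,
            end=end,
            type=etype,
            drug_sequence=tuple(seq),
            n_dispensations=len(self.members),
            max_co_dispensation_days=max_co,
            n_switches=len(self.switches),
            dose_segments=_dose_segments(self.members),
        )


def _build_person(
    person_id: str, disps: list[Dispensation], cfg: EpisodeConfig
) -> list[Episode]:
    disps = sorted(disps, key=lambda d: (d.interval.start, d.drug, d.interval.end))
    episodes: list[Episode] = []
    acc = _EpisodeAccumulator(person_id)

    def close_current() -> None:
        nonlocal acc
        ep = acc.close(f"{person_id}-{len(episodes) + 1}", cfg)
        if ep is not None:
            episodes.append(ep)
        acc = _EpisodeAccumulator(person_id)

    for y in disps:
        if acc.threads:
            # expire threads whose coverage end is exceeded by more than their gap
            dead = [
                d
                for d, t in acc.threads.items()
                if y.interval.start - t.cov_end > cfg.gap(d)
            ]
            if len(dead) == len(acc.threads):
                close_current()
            else:
                for d in dead:
                    del acc.threads[d]
        if not acc.threads:
            acc.open_thread(y)
            continue

        if y.drug in acc.threads:
            t = acc.threads[y.drug]
            rel = allen.classify(t.last.interval, y.interval)
            if rel.label in ("overlaps", "overlapped_by", "during"):
                # recode against the thread's full coverage end so a shift
                # never re-overlaps earlier records; cascading shifts can
                # leave the next raw record behind the shifted predecessor
                # (overlapped_by/during), which is the same early-refill
                # pattern and is recoded the same way
                co = t.cov_end - y.interval.start
                if 0 < co <= cfg.epsilon_same:
                    y = y.shifted(co)
            acc.open_thread(y)
        else:
            ref = max(acc.threads.values(), key=lambda t: (t.cov_end, t.drug))
            decision, y_eff, rel, switch = link_cross_drug(
                ref.last, y, cfg, coverage_end=ref.cov_end
            )
            if decision == TRANSITION_LINK:
                acc.switches.append(switch)
                acc.open_thread(y_eff)
            elif decision == MULTITHERAPY_OPEN:
                acc.open_thread(y)
            elif decision == ABSORB:
                if rel.label in _Y_ENCLOSES_X:
                    acc.reassign_last(ref, y.drug)
                    acc.open_thread(y, eff_drug=y.drug)
                else:
                    acc.absorb(y, ref.drug)
            elif decision == EXCLUDE:
                y.flags.add("excluded_equals")
                acc.drop_last_of(ref)
            else:  # NEW_EPISODE -- defensive; expiry normally handles this
                close_current()
                acc.open_thread(y)
    close_current()
    return episodes


def build_episodes(
    disps: Sequence[Dispensation], cfg: EpisodeConfig | None = None
) -> list[Episode]:
    """Build typed episodes from cleaned dispensations (any number of persons).

    Records are grouped per person and swept chronologically; every
    retained record lands in exactly one episode, and one person's
    episodes are pairwise disjoint and ordered.
    """
    cfg = cfg or default_config()
    by_person: dict[str, list[Dispensation]] = {}
    for d in disps:
        by_person.setdefault(d.person_id, []).append(d)
    episodes: list[Episode] = []
    for pid in sorted(by_person):
        episodes.extend(_build_person(pid, by_person[pid], cfg))
    return episodes


# ---------------------------------------------------------------------------
# co-dispensation patterns


def co_dispensation_patterns(disps: Sequence[Dispensation]) -> pd.DataFrame:
    """Identify cross-drug co-dispensation periods and label their sequences.

    A co-dispensation period is a maximal span during which at least two
    drugs' raw coverage overlaps.  Each period between exactly two drugs
    is labelled by which drug's coverage continues afterwards:
    ``A->(A+B)->A`` (return to the initial therapy), ``A->(A+B)->B``
    (switch to the added therapy), or ``other``.  Durations are summarised
    per labelled sequence (n, median, Q1, Q3, mean, SD, min, max).
    """
    rows: list[tuple[str, str, int]] = []
    by_person: dict[str, list[Dispensation]] = {}
    for d in disps:
        by_person.setdefault(d.person_id, []).append(d)
    for pid, pdisps in by_person.items():
        by_drug: dict[str, list[Interval]] = {}
        for d in pdisps:
            by_drug.setdefault(d.drug, []).append(d.interval)
        coverage = {drug: _coverage_union(ivs) for drug, ivs in by_drug.items()}
        if len(coverage) < 2:
            continue

        def covering(day: int) -> frozenset:
            return frozenset(
                drug
                for drug, ivs in coverage.items()
                if any(iv.covers(day) for iv in ivs)
            )

        points = sorted(
            {p for ivs in coverage.values() for iv in ivs for p in (iv.start, iv.end)}
        )
        segs: list[tuple[int, int, frozenset]] = []
        for a, b in zip(points, points[1:]):
            # a segment between adjacent breakpoints is homogeneous
            drugs = frozenset(
                drug
                for drug, ivs in coverage.items()
                if any(iv.start <= a and b <= iv.end for iv in ivs)
            )
            if len(drugs) >= 2:
                if segs and segs[-1][1] == a and segs[-1][2] == drugs:
                    segs[-1] = (segs[-1][0], b, drugs)
                else:
                    segs.append((a, b, drugs))
        for a, b, drugs in segs:
            prior = covering(a - 1)
            after = covering(b)
            if len(drugs) == 2 and len(prior) == 1 and prior <= drugs:
                oat1 = next(iter(prior))
                oat2 = next(iter(drugs - prior))
                if after == prior:
                    label = f"{oat1}->({oat1}+{oat2})->{oat1}"
                    pattern = "return"
                elif after == frozenset({oat2}):
                    label = f"{oat1}->({oat1}+{oat2})->{oat2}"
                    pattern = "switch"
                else:
                    label, pattern = "other", "other"
            else:
                label, pattern = "other", "other"
            rows.append((label, pattern, b - a))

    columns = ["sequence", "pattern", "n", "median", "q1", "q3", "mean", "sd", "min", "max"]
    if not rows:
        return pd.DataFrame(columns=columns)
    df = pd.DataFrame(rows, columns=["sequence", "pattern", "duration"])
    out = []
    for (seq, pattern), grp in df.groupby(["sequence", "pattern"]):
        out.append((seq, pattern, *five_number_row(grp["duration"].tolist())))
    result = pd.DataFrame(out, columns=columns)
    return result.sort_values("n", ascending=False).reset_index(drop=True)
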