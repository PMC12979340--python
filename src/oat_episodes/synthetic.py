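"""Seeded generator of dispensation cohorts with known ground truth.

The generator serves two purposes.  First, it samples per-record temporal
relation categories from configurable per-drug mixtures (defaults
calibrated to the relation mix characteristic of BC PharmaNet OAT
dispensing, where *before* dominates for methadone and *equals* -- from
witnessed/split same-day dosing -- is common for buprenorphine/naloxone
and SROM) and realizes coverage intervals satisfying each sampled
relation, so the relation classifier can be validated by round-trip:
``classify(prev, realize_relation(label, prev)) == label`` for all 13
labels.  Second, it builds whole cohorts with episode-level ground truth
(boundaries, type, switch count) derived from the drawn quantities by
simple arithmetic at generation time, plus optional cross-drug
co-dispensation sequences, hospital stays, and injected cleaning errors
(split doses, QPD outliers, days-supply overruns) recorded in a ledger.

Every source of randomness flows from a single seed; output is
reproducible byte for byte.

Records realized for whole-cohort generation intentionally keep their
days supply at three days or more so that every temporal relation is
constructible against any record (*contains* needs an enclosing interval
of at least three days); this trades a little realism for injectable OAT
(dispensed daily in practice) against full coverage of the relation
space.  Split/witnessed dosing is emulated by assigning overlapping
records distinct product codes of one drug class, which is also why a
clean generated table produces zero cleaning flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import allen
from .core import (
    DRUG_CLASSES,
    Dispensation,
    EpisodeConfig,
    HospitalStay,
    Interval,
    MONOTHERAPY,
    MULTITHERAPY,
    TRANSITION,
    default_config,
)
from .io import example_catalog

__all__ = [
    "InfeasibleRelation",
    "DEFAULT_RELATION_MIXTURES",
    "relation_mixture",
    "CoDispensationSpec",
    "SimConfig",
    "TrueEpisode",
    "SimResult",
    "realize_relation",
    "sample_relation_stream",
    "generate_cohort",
]


class InfeasibleRelation(ValueError):
    """The requested relation cannot be realized against the given interval."""


#: Per-drug relation-category counts (eight categories: not-applicable +
#: seven base relations) used as the default sampling mixture.
DEFAULT_RELATION_MIXTURES: dict[str, dict[str, int]] = {
    "methadone": {
        "not_applicable": 1331,
        "meets": 3752,
        "before": 1778136,
        "overlaps": 406,
        "starts": 26,
        "finishes": 113,
        "contains": 540,
        "equals": 4091,
    },
    "bup_nal": {
        "not_applicable": 529,
        "meets": 466,
        "before": 48452,
        "overlaps": 265,
        "starts": 57,
        "finishes": 27,
        "contains": 149,
        "equals": 13647,
    },
    "srom": {
        "not_applicable": 690,
        "meets": 1677,
        "before": 159516,
        "overlaps": 2069,
        "starts": 140,
        "finishes": 112,
        "contains": 355,
        "equals": 43401,
    },
    "ioat": {
        "not_applicable": 175,
        "meets": 80,
        "before": 33528,
        "overlaps": 72,
        "starts": 25,
        "finishes": 11,
        "contains": 34,
        "equals": 660,
    },
}

_CATEGORIES = ("not_applicable",) + allen.BASE_RELATIONS

#: In a chronologically sorted same-drug stream the later record can never
#: start first, so the *finishes* category is realized in its sorted-
#: feasible orientation (the later record finishes the earlier one).
_CHAIN_ORIENTATION = {
    "meets": "meets",
    "before": "before",
    "overlaps": "overlaps",
    "starts": "starts",
    "finishes": "finished_by",
    "contains": "contains",
    "equals": "equals",
}


def relation_mixture(drug: str, overrides: dict | None = None) -> dict[str, float]:
    """Normalized category probabilities for ``drug`` (8 categories summing to 1)."""
    counts = dict(overrides or DEFAULT_RELATION_MIXTURES[drug])
    total = float(sum(counts.values()))
    probs = {c: counts.get(c, 0) / total for c in _CATEGORIES}
    if abs(sum(probs.values()) - 1.0) > 1e-9:
        raise ValueError("relation mixture must sum to 1")
    return probs


@dataclass(frozen=True)
class CoDispensationSpec:
    """One cross-drug co-dispensation pattern to inject.

    ``kind`` is ``"return"`` (initial drug resumes after the overlap) or
    ``"switch"`` (the added drug continues); ``duration_range`` bounds the
    drawn co-dispensation length in days.  Defaults echo the short
    return overlaps (median ~3 days, iOAT+SROM) and the longer switch
    overlaps (median ~11.5 days, SROM to methadone) typical of OAT claims.
    """

    kind: str
    drugs: tuple[str, str]
    duration_range: tuple[int, int]
    weight: float = 1.0


_DEFAULT_CODISP_SPECS = (
    CoDispensationSpec("return", ("ioat", "srom"), (1, 7), weight=0.82),
    CoDispensationSpec("switch", ("srom", "methadone"), (3, 30), weight=0.18),
)


@dataclass
class SimConfig:
    """Generator configuration; every field has a study-realistic default."""

    n_persons: int = 100
    mean_records: float = 20.0
    seed: int = 0
    drug_mixture: dict = field(
        default_factory=lambda: {
            "methadone": 0.855,
            "bup_nal": 0.030,
            "srom": 0.100,
            "ioat": 0.015,
        }
    )
    relation_mixtures: dict = field(
        default_factory=lambda: {d: relation_mixture(d) for d in DRUG_CLASSES}
    )
    days_supply_range: dict = field(
        default_factory=lambda: {
            "methadone": (3, 7),
            "bup_nal": (7, 28),
            "srom": (3, 28),
            "ioat": (3, 5),
        }
    )
    dose_range_mg: dict = field(
        default_factory=lambda: {
            "methadone": (30, 120),
            "bup_nal": (4, 24),
            "srom": (200, 1000),
            "ioat": (100, 500),
        }
    )
    strength_mg: dict = field(
        default_factory=lambda: {
            "methadone": 10.0,
            "bup_nal": 2.0,
            "srom": 100.0,
            "ioat": 10.0,
        }
    )
    gap_geom_p: float = 0.25
    overlap_geom_p: float = 0.4
    codisp_rate: float = 0.3
    codisp_specs: tuple = _DEFAULT_CODISP_SPECS
    split_dose_rate: float = 0.0
    qpd_outlier_rate: float = 0.0
    supply_overrun_rate: float = 0.0
    hospital_rate: float = 0.1
    hospital_stay_range: tuple = (2, 21)

    def __post_init__(self) -> None:
        for name in (
            "codisp_rate",
            "split_dose_rate",
            "qpd_outlier_rate",
            "supply_overrun_rate",
            "hospital_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.drug_mixture.values()) - 1.0) > 1e-9:
            raise ValueError("drug_mixture must sum to 1")
        for drug, mix in self.relation_mixtures.items():
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"relation mixture for {drug} must sum to 1")


@dataclass(frozen=True)
class TrueEpisode:
    """Generation-time ground truth for one episode."""

    person_id: str
    start: int
    end: int
    type: str
    drugs: tuple
    n_switches: int


@dataclass
class SimResult:
    dispensations: list
    truth_episodes: list
    truth_relations: list  # (person_id, record index, drawn category)
    error_ledger: list  # dicts: person_id, din, service_day, rule
    hospital_stays: list
    catalog: dict


# ---------------------------------------------------------------------------
# relation realization


def _geom(rng: np.random.Generator, p: float) -> int:
    return int(rng.geometric(p))


def realize_relation(
    label: str,
    prev: Interval,
    rng: np.random.Generator,
    length_range: tuple[int, int] = (3, 10),
    gap: int | None = None,
    overlap: int | None = None,
) -> Interval:
    """Construct an interval ``y`` with ``classify(prev, y).label == label``.

    Free lengths are drawn from ``length_range``; ``gap``/``overlap`` pin
    the respective free quantity when provided.  Raises
    :class:`InfeasibleRelation` when ``prev`` is too short to admit the
    pattern (e.g. *contains* needs a duration of at least 3 days).
    """
    s, e, dur = prev.start, prev.end, prev.duration
    lo, hi = length_range

    def length(minimum: int = 1) -> int:
        m = max(lo, minimum)
        h = max(hi, m)
        return int(rng.integers(m, h + 1))

    if label == "equals":
        return prev
    if label == "meets":
        return Interval(e, e + length())
    if label == "met_by":
        ln = length()
        return Interval(s - ln, s)
    if label == "before":
        g = gap if gap is not None else _geom(rng, 0.25)
        return Interval(e + g, e + g + length())
    if label == "after":
        g = gap if gap is not None else _geom(rng, 0.25)
        ln = length()
        return Interval(s - g - ln, s - g)
    if label == "overlaps":
        if dur < 2:
            raise InfeasibleRelation("overlaps needs the first interval >= 2 days")
        o = overlap if overlap is not None else min(_geom(rng, 0.4), dur - 1)
        if not 1 <= o <= dur - 1:
            raise InfeasibleRelation(f"overlap {o} infeasible for duration {dur}")
        return Interval(e - o, e - o + length(minimum=o + 1))
    if label == "overlapped_by":
        if dur < 2:
            raise InfeasibleRelation("overlapped_by needs the second interval >= 2 days")
        o = overlap if overlap is not None else min(_geom(rng, 0.4), dur - 1)
        if not 1 <= o <= dur - 1:
            raise InfeasibleRelation(f"overlap {o} infeasible for duration {dur}")
        ln = length(minimum=o + 1)
        return Interval(s + o - ln, s + o)
    if label == "starts":
        return Interval(s, s + length(minimum=dur + 1))
    if label == "started_by":
        if dur < 2:
            raise InfeasibleRelation("started_by needs a strictly shorter interval")
        return Interval(s, s + int(rng.integers(1, dur)))
    if label == "finishes":
        return Interval(s - length(), e)
    if label == "finished_by":
        if dur < 2:
            raise InfeasibleRelation("finished_by needs a strictly shorter interval")
        # keep the realized record as long as possible so later relations
        # in a chain stay constructible
        k = 1 if dur >= 4 else int(rng.integers(1, dur))
        k = min(k, dur - 1)
        return Interval(s + k, e)
    if label == "contains":
        if dur < 3:
            raise InfeasibleRelation("contains needs an enclosing interval >= 3 days")
        a = 1
        b = int(rng.integers(a + 1, dur))  # nested end offset in (a, dur)
        return Interval(s + a, s + b)
    if label == "during":
        return Interval(s - length(), e + length())
    raise ValueError(f"unknown relation label {label!r}")


# ---------------------------------------------------------------------------
# record streams for mixture recovery


def sample_relation_stream(
    mixture: dict[str, float],
    n_records: int,
    rng: np.random.Generator,
    drug: str = "methadone",
    length_range: tuple[int, int] = (3, 10),
) -> tuple[list[Dispensation], list[str]]:
    """Draw ``n_records`` relation categories i.i.d. and realize them as records.

    A drawn ``not_applicable`` starts a new person (the sentinel marks
    sequence-initial records); every other category is realized against
    the previous record of the current person, in its sorted-feasible
    orientation.  Classifying the resulting records recovers the drawn
    categories, so empirical frequencies converge to the mixture.
    """
    cats = list(_CATEGORIES)
    probs = np.array([mixture.get(c, 0.0) for c in cats])
    probs = probs / probs.sum()
    draws = rng.choice(len(cats), size=n_records, p=probs)
    disps: list[Dispensation] = []
    labels: list[str] = []
    person = 0
    prev: Interval | None = None
    for k in draws:
        cat = cats[int(k)]
        if cat == "not_applicable" or prev is None:
            person += 1
            iv = Interval(0, int(rng.integers(*length_range)) + 1)
            cat_eff = "not_applicable"
        else:
            oriented = _CHAIN_ORIENTATION[cat]
            try:
                iv = realize_relation(oriented, prev, rng, length_range)
            except InfeasibleRelation:
                # the previous interval is too short for this pattern;
                # re-anchor with a fresh sequence-initial record
                person += 1
                iv = Interval(0, int(rng.integers(*length_range)) + 1)
                cat_eff = "not_applicable"
            else:
                cat_eff = cat
        disps.append(
            Dispensation(
                person_id=f"S{person:06d}",
                drug=drug,
                service_day=iv.start,
                days_supply=iv.duration,
                quantity=float(iv.duration),
                strength=1.0,
            )
        )
        labels.append(cat_eff)
        prev = iv
    return disps, labels


# ---------------------------------------------------------------------------
# whole-cohort generation with ground truth


class _DinPool:
    """Assign product codes within one drug class so that records of one
    code never overlap or collide on a day -- same-day and overlapping
    dispensing is carried by distinct products, as in real claims."""

    def __init__(self, codes: Sequence[str]):
        self.codes = list(codes)
        self.last_end: dict[str, int] = {}

    def pick(self, iv: Interval) -> str:
        for code in self.codes:
            if self.last_end.get(code, -(10**9)) <= iv.start:
                self.last_end[code] = iv.end
                return code
        # essentially unreachable with a 16-code pool; fall back gracefully
        code = min(self.codes, key=lambda c: self.last_end.get(c, 0))
        self.last_end[code] = iv.end
        return code


def _person_chain(
    pid: str,
    drug: str,
    cfg: SimConfig,
    rng: np.random.Generator,
    cfg_ep: EpisodeConfig,
    dins: dict[str, "_DinPool"],
):
    """Generate one person's same-drug chain plus optional cross-drug tail.

    Returns (records, truth episodes, drawn categories).  Truth episode
    boundaries are tracked with the same coverage-end arithmetic the
    episode builder applies, driven directly by the drawn quantities.
    """
    gap_limit = cfg_ep.gap(drug)
    eps_same = cfg_ep.epsilon_same
    eps_cross = cfg_ep.epsilon_cross
    ds_lo, ds_hi = cfg.days_supply_range[drug]
    ds_lo = max(3, ds_lo)
    ds_hi = max(ds_lo, ds_hi)
    dose = float(rng.integers(*cfg.dose_range_mg[drug]))
    strength = cfg.strength_mg[drug]

    def make(drug_: str, iv: Interval, dose_: float) -> Dispensation:
        q = round(dose_ * iv.duration / cfg.strength_mg[drug_], 3)
        return Dispensation(
            person_id=pid,
            drug=drug_,
            service_day=iv.start,
            days_supply=iv.duration,
            quantity=q,
            strength=cfg.strength_mg[drug_],
            din=dins[drug_].pick(iv),
        )

    n_rec = max(2, int(rng.poisson(cfg.mean_records)))
    mixture = cfg.relation_mixtures[drug]
    cats = [c for c in _CATEGORIES if c != "not_applicable"]
    probs = np.array([mixture[c] for c in cats])
    probs = probs / probs.sum()

    records: list[Dispensation] = []
    drawn: list[str] = []
    day0 = int(rng.integers(0, 3650))
    prev_eff = Interval(day0, day0 + int(rng.integers(ds_lo, ds_hi + 1)))
    records.append(make(drug, prev_eff, dose))
    drawn.append("not_applicable")

    episodes: list[TrueEpisode] = []
    ep_start = prev_eff.start
    cov_end = prev_eff.end
    for _ in range(n_rec - 1):
        for _attempt in range(20):
            cat = cats[int(rng.choice(len(cats), p=probs))]
            oriented = _CHAIN_ORIENTATION[cat]
            try:
                iv = realize_relation(oriented, prev_eff, rng, (ds_lo, ds_hi))
            except InfeasibleRelation:
                continue
            break
        else:  # pragma: no cover - defensive
            break
        drawn.append(cat)
        if cat == "before":
            if iv.start - cov_end > gap_limit:
                episodes.append(
                    TrueEpisode(pid, ep_start, cov_end, MONOTHERAPY, (drug,), 0)
                )
                ep_start = iv.start
                cov_end = iv.end
            else:
                cov_end = max(cov_end, iv.end)
            records.append(make(drug, iv, dose))
            prev_eff = iv
        elif cat == "overlaps":
            co = cov_end - iv.start
            records.append(make(drug, iv, dose))
            if 0 < co <= eps_same:
                iv = iv.shift(co)  # mirrors the builder's recode-to-meets
            cov_end = max(cov_end, iv.end)
            prev_eff = iv
        else:  # meets and the nested categories extend coverage in place
            records.append(make(drug, iv, dose))
            cov_end = max(cov_end, iv.end)
            prev_eff = iv

    # optional cross-drug co-dispensation tail
    did_codisp = False
    if cfg.codisp_specs and rng.random() < cfg.codisp_rate:
        weights = np.array([s.weight for s in cfg.codisp_specs])
        spec = cfg.codisp_specs[int(rng.choice(len(cfg.codisp_specs), p=weights / weights.sum()))]
        other = spec.drugs[1] if spec.drugs[0] == drug else spec.drugs[0]
        if other == drug:
            other = next(d for d in DRUG_CLASSES if d != drug)
        d_target = int(rng.integers(spec.duration_range[0], spec.duration_range[1] + 1))
        b_start = max(prev_eff.start + 1, cov_end - d_target)
        co = cov_end - b_start
        lb = max(co, 1) + int(rng.integers(7, 15))
        b_iv = Interval(b_start, b_start + lb)
        dose_b = float(rng.integers(*cfg.dose_range_mg[other]))
        records.append(make(other, b_iv, dose_b))
        drawn.append("cross_drug")
        did_codisp = True
        if co <= eps_cross:
            b_eff = b_iv.shift(co)
            if spec.kind == "return":
                la = int(rng.integers(ds_lo, ds_hi + 1))
                a_iv = Interval(b_eff.end, b_eff.end + la)
                records.append(make(drug, a_iv, dose))
                drawn.append("cross_drug")
                episodes.append(
                    TrueEpisode(pid, ep_start, a_iv.end, TRANSITION, (drug, other), 2)
                )
            else:
                episodes.append(
                    TrueEpisode(pid, ep_start, b_eff.end, TRANSITION, (drug, other), 1)
                )
        else:
            end = max(cov_end, b_iv.end)
            if spec.kind == "return":
                g = int(rng.integers(1, gap_limit + 1)) if gap_limit >= 1 else 0
                la = int(rng.integers(ds_lo, ds_hi + 1))
                a_iv = Interval(cov_end + g, cov_end + g + la)
                records.append(make(drug, a_iv, dose))
                drawn.append("cross_drug")
                end = max(end, a_iv.end)
            episodes.append(
                TrueEpisode(pid, ep_start, end, MULTITHERAPY, (drug, other), 0)
            )
    if not did_codisp:
        episodes.append(TrueEpisode(pid, ep_start, cov_end, MONOTHERAPY, (drug,), 0))
    return records, episodes, drawn


def _inject_errors(
    records: list[Dispensation], cfg: SimConfig, rng: np.random.Generator
) -> tuple[list[Dispensation], list[dict]]:
    ledger: list[dict] = []
    out = list(records)

    def entry(d: Dispensation, rule: str) -> dict:
        return {
            "person_id": d.person_id,
            "din": d.din,
            "service_day": d.service_day,
            "rule": rule,
        }

    # group indices per (person, din) stream in chronological order
    streams: dict = {}
    for i, d in enumerate(out):
        streams.setdefault((d.person_id, d.din), []).append(i)
    touched: set[int] = set()

    if cfg.supply_overrun_rate > 0:
        for idxs in streams.values():
            for pos in range(len(idxs) - 1):
                i, j = idxs[pos], idxs[pos + 1]
                if i in touched or rng.random() >= cfg.supply_overrun_rate:
                    continue
                d = out[i]
                interval = out[j].service_day - d.service_day
                if interval < 2:
                    continue
                # overshoot by strictly less than the inter-fill interval,
                # so that capping the supply leaves the implied dose
                # consistent with adjacent records
                new_ds = interval + int(rng.integers(1, interval))
                # scale quantity with the inflated supply so QPD stays
                # consistent and only the cap rule can catch it
                out[i] = replace(
                    d,
                    days_supply=new_ds,
                    quantity=round(d.quantity * new_ds / d.days_supply, 3),
                )
                ledger.append(entry(d, "supply_overrun"))
                touched.add(i)

    if cfg.qpd_outlier_rate > 0:
        for idxs in streams.values():
            if len(idxs) < 5:
                continue
            for pos in range(2, len(idxs) - 2):
                i = idxs[pos]
                window = idxs[pos - 2 : pos] + idxs[pos + 1 : pos + 3]
                if i in touched or any(w in touched for w in window):
                    continue
                if rng.random() >= cfg.qpd_outlier_rate:
                    continue
                d = out[i]
                out[i] = replace(d, quantity=round(d.quantity * 8, 3))
                ledger.append(entry(d, "qpd_outlier"))
                touched.add(i)

    if cfg.split_dose_rate > 0:
        extra: list[Dispensation] = []
        for i, d in enumerate(out):
            if i in touched or rng.random() >= cfg.split_dose_rate:
                continue
            half = round(d.quantity / 2, 3)
            if half <= 0 or d.quantity - half <= 0:
                continue
            out[i] = replace(d, quantity=half)
            extra.append(replace(d, quantity=round(d.quantity - half, 3), flags=set()))
            ledger.append(entry(d, "split_dose"))
            touched.add(i)
        out.extend(extra)

    return out, ledger


def generate_cohort(cfg: SimConfig | None = None, episode_config: EpisodeConfig | None = None) -> SimResult:
    """Generate a dispensation cohort plus ground truth, reproducibly from the seed."""
    cfg = cfg or SimConfig()
    cfg_ep = episode_config or default_config()
    rng = np.random.default_rng(cfg.seed)
    catalog = example_catalog()
    codes_by_class: dict[str, list[str]] = {}
    for code, cls in sorted(catalog.items()):
        codes_by_class.setdefault(cls, []).append(code)

    drugs = list(cfg.drug_mixture)
    drug_p = np.array([cfg.drug_mixture[d] for d in drugs])
    drug_p = drug_p / drug_p.sum()

    all_records: list[Dispensation] = []
    truth_eps: list[TrueEpisode] = []
    truth_rel: list[tuple[str, int, str]] = []
    stays: list[HospitalStay] = []
    for p in range(cfg.n_persons):
        pid = f"P{p:05d}"
        drug = drugs[int(rng.choice(len(drugs), p=drug_p))]
        dins = {d: _DinPool(codes_by_class[d]) for d in DRUG_CLASSES}
        records, eps, drawn = _person_chain(pid, drug, cfg, rng, cfg_ep, dins)
        all_records.extend(records)
        truth_eps.extend(eps)
        truth_rel.extend((pid, i, c) for i, c in enumerate(drawn))
        if rng.random() < cfg.hospital_rate and eps:
            lo = min(e.start for e in eps) + 1
            hi = max(e.end for e in eps)
            if hi > lo:
                admit = int(rng.integers(lo, hi))
                stay_len = int(rng.integers(*cfg.hospital_stay_range))
                stays.append(HospitalStay(pid, admit, admit + stay_len))

    all_records, ledger = _inject_errors(all_records, cfg, rng)
    all_records.sort(key=lambda d: (d.person_id, d.interval.start, d.drug, d.interval.end))
    return SimResult(
        dispensations=all_records,
        truth_episodes=sorted(truth_eps, key=lambda e: (e.person_id, e.start)),
        truth_relations=truth_rel,
        error_ledger=ledger,
        hospital_stays=stays,
        catalog=catalog,
    )
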