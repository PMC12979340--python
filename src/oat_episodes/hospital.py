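"""Bridging episodes across hospitalizations.

Community-pharmacy claims exclude inpatient dispensations, so an episode
that runs into a hospital admission appears to stop even when therapy
continues on the ward.  When an admission falls inside an episode's span
-- or inside the closing drug's permissible gap just after its coverage
ends -- the episode is assumed to continue through the stay: the gap
clock restarts at discharge, and a dispensation of any OAT drug within
the permissible gap after discharge merges the would-be-separate
episodes into one (a drug change at discharge counts as a switch).
Stays with no adjacent episode have no effect.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

from .core import (
    Episode,
    EpisodeConfig,
    HospitalStay,
    MONOTHERAPY,
    MULTITHERAPY,
    TRANSITION,
    TRANSITION_MULTITHERAPY,
    default_config,
)

__all__ = ["bridge", "merge_stays", "closing_drug"]


def merge_stays(stays: Sequence[HospitalStay]) -> list[HospitalStay]:
    """Merge overlapping or abutting stays of one person."""
    out: list[HospitalStay] = []
    for s in sorted(stays, key=lambda s: (s.person_id, s.admit, s.discharge)):
        if out and out[-1].person_id == s.person_id and s.admit <= out[-1].discharge:
            if s.discharge > out[-1].discharge:
                out[-1] = HospitalStay(s.person_id, out[-1].admit, s.discharge)
        else:
            out.append(s)
    return out


def closing_drug(episode: Episode) -> str:
    """The drug dispensed last in the episode (drug of the final dose segment)."""
    if episode.dose_segments:
        return episode.dose_segments[-1].drug
    return episode.drug_sequence[-1]


def _merge(a: Episode, b: Episode, stay: HospitalStay, cfg: EpisodeConfig) -> Episode:
    drugs = list(a.drug_sequence)
    for d in b.drug_sequence:
        if d not in drugs:
            drugs.append(d)
    n_switches = a.n_switches + b.n_switches
    if closing_drug(a) != b.drug_sequence[0]:
        n_switches += 1  # regimen change across the hospitalization
    max_co = max(a.max_co_dispensation_days, b.max_co_dispensation_days)
    if len(drugs) == 1:
        etype = MONOTHERAPY
    else:
        has_multi = max_co > cfg.epsilon_cross
        has_switch = n_switches >= 1
        if has_multi and has_switch:
            etype = TRANSITION_MULTITHERAPY
        elif has_multi:
            etype = MULTITHERAPY
        else:
            etype = TRANSITION
    return replace(
        a,
        end=b.end,
        type=etype,
        drug_sequence=tuple(drugs),
        n_dispensations=a.n_dispensations + b.n_dispensations,
        max_co_dispensation_days=max_co,
        n_switches=n_switches,
        dose_segments=tuple(a.dose_segments) + tuple(b.dose_segments),
        bridged_hospital_days=a.bridged_hospital_days
        + b.bridged_hospital_days
        + stay.length,
    )


def bridge(
    episodes: Sequence[Episode],
    stays: Sequence[HospitalStay],
    cfg: EpisodeConfig | None = None,
) -> list[Episode]:
    """Merge episodes separated only by a hospitalization.

    A stay bridges when its admission falls within an episode's span or
    within the closing drug's permissible gap after the episode's
    coverage end, and the next episode starts no later than that gap
    after discharge.  Bridging never splits an episode; with
    ``bridge_hospitalizations`` disabled the input is returned unchanged.
    """
    cfg = cfg or default_config()
    if not cfg.bridge_hospitalizations or not stays:
        return list(episodes)
    stays = merge_stays(stays)
    by_person: dict[str, list] = {}
    for e in episodes:
        by_person.setdefault(e.person_id, []).append(e)
    stays_by_person: dict[str, list] = {}
    for s in stays:
        stays_by_person.setdefault(s.person_id, []).append(s)

    out: list[Episode] = []
    for pid, eps in by_person.items():
        eps = sorted(eps, key=lambda e: e.start)
        for stay in stays_by_person.get(pid, []):
            merged: list[Episode] = []
            i = 0
            while i < len(eps):
                cur = eps[i]
                grace = cfg.gap(closing_drug(cur))
                admits_inside = cur.start <= stay.admit < cur.end + grace
                if admits_inside and i + 1 < len(eps):
                    nxt = eps[i + 1]
                    if (
                        nxt.start >= stay.admit
                        and nxt.start - stay.discharge <= grace
                    ):
                        cur = _merge(cur, nxt, stay, cfg)
                        i += 1  # consume the merged successor
                merged.append(cur)
                i += 1
            eps = merged
        out.extend(eps)
    out.sort(key=lambda e: (e.person_id, e.start))
    return out
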