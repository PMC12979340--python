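"""Allen's interval algebra over dispensation coverage windows.

Any ordered pair of non-degenerate half-open integer-day intervals stands
in exactly one of thirteen temporal relations: seven base relations --
*meets*, *before*, *overlaps*, *starts*, *finishes*, *contains*, *equals*
-- and the six inverses of the non-symmetric ones (*equals* is its own
inverse).  On day-granular data under the half-open convention the
thirteen patterns partition the pair space with no residual cases.

A person's first record in a scope carries the ``not_applicable``
sentinel instead of a relation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .core import Dispensation, Interval

__all__ = [
    "BASE_RELATIONS",
    "ALL_LABELS",
    "NOT_APPLICABLE",
    "Relation",
    "classify",
    "inverse_label",
    "base_label",
    "annotate_sequence",
    "relation_frequencies",
]

#: Base relation names, in conventional reporting order.
BASE_RELATIONS = (
    "meets",
    "before",
    "overlaps",
    "starts",
    "finishes",
    "contains",
    "equals",
)

_INVERSE = {
    "meets": "met_by",
    "before": "after",
    "overlaps": "overlapped_by",
    "starts": "started_by",
    "finishes": "finished_by",
    "contains": "during",
    "equals": "equals",
}
_INVERSE.update({v: k for k, v in _INVERSE.items() if k != "equals"})

NOT_APPLICABLE = "not_applicable"
_INVERSE[NOT_APPLICABLE] = NOT_APPLICABLE

#: All thirteen relation labels.
ALL_LABELS = tuple(BASE_RELATIONS) + tuple(
    _INVERSE[b] for b in BASE_RELATIONS if b != "equals"
)

_BASE_OF = {lab: lab for lab in BASE_RELATIONS}
_BASE_OF.update({_INVERSE[b]: b for b in BASE_RELATIONS})
_BASE_OF[NOT_APPLICABLE] = NOT_APPLICABLE

#: Category order used in frequency reports.
REPORT_CATEGORIES = (NOT_APPLICABLE,) + BASE_RELATIONS


def inverse_label(label: str) -> str:
    """The label of the reversed pair: ``label(x, y) == inverse(label(y, x))``."""
    return _INVERSE[label]


def base_label(label: str) -> str:
    """Collapse an inverse label onto its base name (``met_by`` -> ``meets``)."""
    return _BASE_OF[label]


@dataclass(frozen=True)
class Relation:
    """The temporal relation between an ordered pair of coverage intervals.

    ``gap_days`` (>= 1) is set for *before*/*after*; ``overlap_days`` (>= 1)
    is set whenever the two intervals share at least one covered day.
    """

    label: str
    gap_days: int | None = None
    overlap_days: int | None = None

    @property
    def base(self) -> str:
        return base_label(self.label)

    def inverse(self) -> "Relation":
        return Relation(inverse_label(self.label), self.gap_days, self.overlap_days)


def classify(x: Interval, y: Interval) -> Relation:
    """Classify the ordered pair ``(x, y)`` into exactly one of the 13 relations.

    Endpoint patterns (half-open day intervals):

    ========== =============================================
    meets       x.start < x.end == y.start < y.end
    before      x.end < y.start          (gap = y.start - x.end)
    overlaps    x.start < y.start < x.end < y.end
    starts      x.start == y.start < x.end < y.end
    finishes    y.start < x.start < x.end == y.end
    contains    x.start < y.start  and  y.end < x.end
    equals      identical endpoints
    ========== =============================================

    with the six inverse labels returned when ``y`` precedes ``x`` in the
    corresponding pattern.
    """
    if x.end < y.start:
        return Relation("before", gap_days=y.start - x.end)
    if y.end < x.start:
        return Relation("after", gap_days=x.start - y.end)
    if x.end == y.start:
        return Relation("meets")
    if y.end == x.start:
        return Relation("met_by")

    # From here the intervals share at least one covered day.
    ov = min(x.end, y.end) - max(x.start, y.start)
    if x.start == y.start and x.end == y.end:
        return Relation("equals", overlap_days=ov)
    if x.start == y.start:
        label = "starts" if x.end < y.end else "started_by"
        return Relation(label, overlap_days=ov)
    if x.end == y.end:
        label = "finishes" if x.start > y.start else "finished_by"
        return Relation(label, overlap_days=ov)
    if x.start < y.start and y.end < x.end:
        return Relation("contains", overlap_days=ov)
    if y.start < x.start and x.end < y.end:
        return Relation("during", overlap_days=ov)
    if x.start < y.start:
        return Relation("overlaps", overlap_days=ov)
    return Relation("overlapped_by", overlap_days=ov)


_SORT_KEY = lambda d: (d.interval.start, d.drug, d.interval.end)  # noqa: E731


def _check_sorted(disps: Sequence[Dispensation]) -> None:
    for a, b in zip(disps, disps[1:]):
        if _SORT_KEY(a) > _SORT_KEY(b):
            raise ValueError(
                "dispensations must be sorted by (start day, drug, end day); "
                f"records {a} and {b} are out of order"
            )


def annotate_sequence(
    disps: Sequence[Dispensation], scope: str = "same_drug"
) -> list[tuple[Dispensation, Relation]]:
    """Annotate one person's sorted records with consecutive-pair relations.

    Each record is related to the immediately preceding record in scope:
    the previous record of the same drug class for ``scope="same_drug"``,
    or of any drug for ``scope="cross_drug"``.  The first record in a scope
    gets the ``not_applicable`` sentinel.
    """
    if scope not in ("same_drug", "cross_drug"):
        raise ValueError(f"unknown scope {scope!r}")
    _check_sorted(disps)
    last: dict[str, Dispensation] = {}
    out: list[tuple[Dispensation, Relation]] = []
    for d in disps:
        key = d.drug if scope == "same_drug" else "__any__"
        prev = last.get(key)
        if prev is None:
            rel = Relation(NOT_APPLICABLE)
        else:
            rel = classify(prev.interval, d.interval)
        out.append((d, rel))
        last[key] = d
    return out


def relation_frequencies(
    annotated: Iterable[tuple[Dispensation, Relation]],
    base_names: bool = True,
) -> pd.DataFrame:
    """Tabulate relation counts and percentages per drug class.

    With ``base_names=True`` (the reporting convention) inverse labels are
    collapsed onto their base relation, giving the eight categories
    not-applicable + seven base relations; percentages sum to 100 within
    each drug up to rounding.
    """
    rows = []
    for d, rel in annotated:
        lab = rel.base if base_names else rel.label
        rows.append((d.drug, lab))
    if not rows:
        return pd.DataFrame(columns=["drug", "relation", "n", "pct"])
    df = pd.DataFrame(rows, columns=["drug", "relation"])
    counts = df.groupby(["drug", "relation"]).size().rename("n").reset_index()
    counts["pct"] = counts.groupby("drug")["n"].transform(lambda s: 100.0 * s / s.sum())
    if base_names:
        order = {c: i for i, c in enumerate(REPORT_CATEGORIES)}
        counts["__o"] = counts["relation"].map(order)
        counts = counts.sort_values(["drug", "__o"]).drop(columns="__o")
    return counts.reset_index(drop=True)
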