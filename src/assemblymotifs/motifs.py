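"""Classification of detected assemblies relative to a focal area.

Pairs split into synchronous (all lags zero) vs directional, and by where
their units sit: crossing the focal/partner boundary ("external"), both
inside the focal area, or both inside one other area.  Triplets spanning two
areas are "loop-like" when they form a strictly sequential A -> B -> A chain
whose first and last units are *distinct* neurons of the same area with the
middle unit in the other area; everything else (synchronous sub-activations,
chains like X -> X -> ZI, triplets not spanning exactly two areas) is
non-loop-like.

Coverage categories summarize, per focal unit, with how many of the external
areas it forms at least one pair: none (with or without internal pairs),
fewer than half, at least half but not all, or all.  "At least half" uses
``2k >= N`` (a tie counts as at least half).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .detection import AssemblyPattern
from .io_spikes import Session

PAIR_CLASSES = (
    "pair_synchronous",
    "pair_from_focal",
    "pair_to_focal",
    "pair_external_other",
    "pair_internal_focal",
    "pair_internal_other",
)
TRIPLET_CLASSES = ("triplet_loop_focal", "triplet_loop_external", "triplet_non_loop")

COVERAGE_CATEGORIES = (
    "no_int_no_ext",
    "only_int",
    "lt_half_ext_at_least_1",
    "ge_half_not_all",
    "all_ext",
)


@dataclass(frozen=True)
class MotifRecord:
    """A classified assembly: its class, partner area (when meaningful),
    whether its chain pairs are independently significant (triplets only),
    and whether it is fully synchronous."""

    assembly: AssemblyPattern
    klass: str
    partner_area: str | None = None
    pairwise_supported: bool | None = None
    synchronous: bool = False


@dataclass(frozen=True)
class CoverageCategory:
    unit_id: str
    category: str
    n_partner_areas: int
    n_areas_available: int


def classify_pair(a: AssemblyPattern, focal: str) -> MotifRecord:
    """Classify an order-2 assembly relative to the focal area.

    Direction comes from the (canonical) lag sign and area membership: the
    leading unit is the one with lag 0.  Internal pairs keep the
    directional/synchronous distinction in ``synchronous``.
    """
    if a.order != 2:
        raise ValueError("classify_pair requires an order-2 assembly")
    (area1, area2) = a.areas
    sync = a.synchronous
    if area1 == focal and area2 == focal:
        return MotifRecord(a, "pair_internal_focal", None, None, sync)
    if area1 == area2:
        return MotifRecord(a, "pair_internal_other", area1, None, sync)
    if focal not in (area1, area2):
        partner = "+".join(sorted((area1, area2)))
        return MotifRecord(a, "pair_external_other", partner, None, sync)
    partner = area2 if area1 == focal else area1
    if sync:
        return MotifRecord(a, "pair_synchronous", partner, None, True)
    if area1 == focal:  # focal unit leads
        return MotifRecord(a, "pair_from_focal", partner, None, False)
    return MotifRecord(a, "pair_to_focal", partner, None, False)


def classify_triplet(a: AssemblyPattern, focal: str) -> MotifRecord:
    """Classify an order-3 assembly as loop-like (focal or external) or not.

    Loop-like requires: units spanning exactly two areas, strictly sequential
    activation (no two equal lags), distinct first and last units sharing an
    area, and the middle unit in the other area.
    """
    if a.order != 3:
        raise ValueError("classify_triplet requires an order-3 assembly")
    areas = set(a.areas)
    strictly_sequential = len(set(a.lags_bins)) == 3
    if len(areas) == 2 and strictly_sequential:
        first, mid, last = a.areas  # canonical activation order
        if first == last and mid != first:
            partner = mid if first == focal else first
            if first == focal:
                return MotifRecord(a, "triplet_loop_focal", partner, None, False)
            if mid == focal:
                return MotifRecord(a, "triplet_loop_external", partner, None, False)
            # A -> B -> A between two non-focal areas: not a focal loop
            return MotifRecord(a, "triplet_non_loop", None, None, a.synchronous)
    partner = None
    if len(areas) == 2 and focal in areas:
        partner = next(x for x in areas if x != focal)
    return MotifRecord(a, "triplet_non_loop", partner, None, a.synchronous)


def pairwise_support(a: AssemblyPattern, pairs: Sequence[AssemblyPattern]) -> bool:
    """True iff both chain-adjacent pairs of a triplet (first-second and
    second-third in activation order) appear, as unit sets, among the
    significant pair assemblies."""
    if a.order != 3:
        raise ValueError("pairwise_support requires an order-3 assembly")
    pair_sets = {frozenset(p.unit_ids) for p in pairs if p.order == 2}
    chain1 = frozenset(a.unit_ids[:2])
    chain2 = frozenset(a.unit_ids[1:])
    return chain1 in pair_sets and chain2 in pair_sets


def classify_assemblies(
    assemblies: Sequence[AssemblyPattern], focal: str
) -> list[MotifRecord]:
    """Classify every order-2/3 assembly; triplets get their pairwise-support
    flag computed against the detected pairs of the same run."""
    pairs = [a for a in assemblies if a.order == 2]
    out: list[MotifRecord] = []
    for a in assemblies:
        if a.order == 2:
            out.append(classify_pair(a, focal))
        elif a.order == 3:
            rec = classify_triplet(a, focal)
            out.append(
                MotifRecord(
                    rec.assembly, rec.klass, rec.partner_area,
                    pairwise_support(a, pairs), rec.synchronous,
                )
            )
        else:
            raise ValueError(f"cannot classify order-{a.order} assembly")
    return out


def _unit_pair_links(records: Iterable[MotifRecord], unit_id: str, focal: str):
    """Partner areas (external) and internal-pair flag for one focal unit,
    from pair records."""
    ext_areas: set[str] = set()
    internal = False
    int_partners: set[str] = set()
    for rec in records:
        a = rec.assembly
        if a.order != 2 or unit_id not in a.unit_ids:
            continue
        if rec.klass in ("pair_synchronous", "pair_from_focal", "pair_to_focal"):
            ext_areas.add(rec.partner_area)
        elif rec.klass == "pair_internal_focal":
            internal = True
            other = next(u for u in a.unit_ids if u != unit_id)
            int_partners.add(other)
    return ext_areas, internal, int_partners


def coverage(
    unit_id: str, records: Sequence[MotifRecord], session: Session
) -> CoverageCategory:
    """Coverage category of one focal unit.

    ``k`` = external areas linked by at least one pair; ``N`` = external
    areas in the session.  Categories are mutually exclusive and exhaustive:
    no pairs at all; internal pairs only; fewer than half the areas
    (``2k < N``) with at least one; at least half but not all (``2k >= N``,
    ``k < N``); all areas.
    """
    if session.unit_area(unit_id) != session.focal_area:
        raise ValueError(f"unit {unit_id!r} is not in the focal area")
    n_ext = len(session.areas) - 1
    ext_areas, internal, _ = _unit_pair_links(records, unit_id, session.focal_area)
    k = len(ext_areas)
    if k == 0:
        cat = "only_int" if internal else "no_int_no_ext"
    elif k == n_ext:
        cat = "all_ext"
    elif 2 * k >= n_ext:
        cat = "ge_half_not_all"
    else:
        cat = "lt_half_ext_at_least_1"
    return CoverageCategory(unit_id, cat, k, n_ext)


def loop_membership_crosstab(
    records: Sequence[MotifRecord], session: Session
) -> dict:
    """Cross-tabulate focal units by loop membership and coverage.

    Focal units split into a "loop" branch (member of at least one loop-like
    triplet) and a "non_loop" branch (everything else, including units in no
    triplet).  Within each branch, counts and fractions over the coverage
    categories (fractions sum to 1 for non-empty branches).  Also reports,
    per branch, the share of units forming internal pairs with at least half
    of the *other* focal units.
    """
    focal = session.focal_area
    focal_units = [tr.unit_id for tr in session.trains if tr.area == focal]
    loop_units: set[str] = set()
    for rec in records:
        if rec.klass in ("triplet_loop_focal", "triplet_loop_external"):
            for u in rec.assembly.unit_ids:
                if u in focal_units:
                    loop_units.add(u)

    n_other_focal = len(focal_units) - 1
    out: dict = {"branches": {}, "internal_coordination": {}}
    for branch, members in (
        ("loop", [u for u in focal_units if u in loop_units]),
        ("non_loop", [u for u in focal_units if u not in loop_units]),
    ):
        counts = {c: 0 for c in COVERAGE_CATEGORIES}
        n_broad_internal = 0
        for u in members:
            counts[coverage(u, records, session).category] += 1
            _, _, int_partners = _unit_pair_links(records, u, focal)
            if n_other_focal > 0 and 2 * len(int_partners) >= n_other_focal:
                n_broad_internal += 1
        total = len(members)
        fractions = {
            c: (counts[c] / total if total else 0.0) for c in COVERAGE_CATEGORIES
        }
        out["branches"][branch] = {
            "n_units": total,
            "counts": counts,
            "fractions": fractions,
        }
        out["internal_coordination"][branch] = (
            n_broad_internal / total if total else 0.0
        )
    return out
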