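"""Collapse redundant observations of one historical conversion event.

A single conversion is commonly observed several times:

* **Type a** — speciations between the duplication and the conversion let the
  same (primary, pair) observation recur with several outgroups.
* **Type b** — speciations after the conversion let it recur in several
  primary species, between orthologous paralog pairs, with the same outgroup.
* **Type c** — duplications after (or just before) the conversion let it
  recur across paralog pairs sharing one converted copy; percent identities
  among the three copies in the converted region decide whether the
  conversion predates the duplication or which pairwise observation is real.

Collapsing runs in the order a, b, c.  Every observation gets exactly one
event id; the representative of an event is the lowest-P observation (types
a/b, and type c before-duplication) or the observation the similarity rule
singles out (type c pairwise cases).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .detect import ConversionObservation, observations_to_table
from .io import (
    GenomicInterval,
    OrthologyMap,
    PairwiseAlignment,
    UndefinedIdentityError,
    percent_identity,
    reciprocal_overlap,
)

__all__ = [
    "ConversionEvent",
    "TripleSimilarity",
    "boundaries_similar",
    "collapse_type_a",
    "collapse_type_b",
    "classify_type_c",
    "deduplicate",
    "events_to_tables",
]

logger = logging.getLogger(__name__)


@dataclass
class ConversionEvent:
    """A group of observations attributed to one historical conversion."""

    event_id: int
    observations: list[ConversionObservation]
    representative: ConversionObservation
    inferred_case: Optional[str] = None
    branch: Optional[str] = None

    @property
    def primaries(self) -> set[str]:
        return {o.primary_species for o in self.observations}

    @property
    def outgroups_by_primary(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for o in self.observations:
            out.setdefault(o.primary_species, set()).add(o.outgroup_species)
        return out


@dataclass(frozen=True)
class TripleSimilarity:
    """Percent identities among three copies within a conversion region.

    s1 = Sim(A1, A2), s2 = Sim(A1, A3), s3 = Sim(A2, A3), where A3 is the
    copy shared by the two observations.
    """

    s1: float
    s2: float
    s3: float

    def __post_init__(self) -> None:
        for s in (self.s1, self.s2, self.s3):
            if not (0.0 <= s <= 1.0):
                raise ValueError("similarities must be fractions in [0, 1]")


def boundaries_similar(
    obs1: ConversionObservation,
    obs2: ConversionObservation,
    tolerance: float = 0.5,
    interval1: Optional[tuple[int, int]] = None,
    interval2: Optional[tuple[int, int]] = None,
) -> bool:
    """'Equal or quite similar' boundaries = reciprocal overlap >= tolerance.

    ``interval1``/``interval2`` override the compared intervals when the
    observations must first be mapped to comparable coordinates (type b/c).
    """
    a = interval1 if interval1 is not None else obs1.conv1
    b = interval2 if interval2 is not None else obs2.conv1
    return reciprocal_overlap(a, b) >= tolerance


def _cluster_by_similarity(items: list, similar) -> list[list]:
    """Single-linkage clustering under a pairwise boolean predicate."""
    parent = list(range(len(items)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            if similar(items[i], items[j]):
                ri, rj = find(i), find(j)
                parent[ri] = rj
    groups: dict[int, list] = {}
    for i, item in enumerate(items):
        groups.setdefault(find(i), []).append(item)
    return list(groups.values())


def _make_event(observations: list[ConversionObservation]) -> ConversionEvent:
    rep = min(observations, key=lambda o: o.p_value)
    return ConversionEvent(-1, list(observations), rep)


def collapse_type_a(
    observations: Sequence[ConversionObservation], tolerance: float = 0.5
) -> list[ConversionEvent]:
    """Merge boundary-similar observations of one pair across outgroups.

    Dissimilar boundaries within a pair remain separate (repeated
    conversions); the representative is the lowest-P observation.
    """
    by_pair: dict[tuple, list[ConversionObservation]] = {}
    for obs in observations:
        by_pair.setdefault(obs.pair_key, []).append(obs)
    events = []
    for group in by_pair.values():
        for cluster in _cluster_by_similarity(
            group, lambda a, b: boundaries_similar(a, b, tolerance)
        ):
            events.append(_make_event(cluster))
    return events


def _map_interval(
    aln: PairwiseAlignment, query_row: int, interval: tuple[int, int]
) -> Optional[tuple[int, int]]:
    """Map a half-open genomic interval through a pairwise alignment."""
    qpos = aln.col_positions(query_row)
    tpos = aln.col_positions(2 if query_row == 1 else 1)
    sel = (qpos >= interval[0]) & (qpos < interval[1]) & (tpos >= 0)
    hits = tpos[sel]
    if hits.size == 0:
        return None
    return int(hits.min()), int(hits.max()) + 1


def _orthologous_interval(
    orthology: OrthologyMap,
    interval: GenomicInterval,
    other_species: str,
    region: tuple[int, int],
) -> Optional[tuple[int, int]]:
    found = orthology.best_alignment(interval, other_species)
    if found is None:
        return None
    aln, qrow = found
    return _map_interval(aln, qrow, region)


def _paralogs_orthologous(
    orthology: OrthologyMap,
    a: GenomicInterval,
    b: GenomicInterval,
) -> bool:
    """True iff some orthology entry joins intervals overlapping a and b."""
    for piv, _, _ in orthology.partners(a, b.species):
        if piv.overlaps(b):
            return True
    return False


def collapse_type_b(
    events: list[ConversionEvent],
    orthology: Optional[OrthologyMap],
    tolerance: float = 0.5,
) -> list[ConversionEvent]:
    """Merge events seen in different primaries with the same outgroup.

    Two events merge when their paralog pairs are orthologous (directly or
    swapped), they share a detecting outgroup, and the converted interval of
    one maps (through the primary-primary orthology alignment) onto a
    boundary-similar interval of the other.
    """
    if orthology is None or not events:
        return events

    def mergeable(e1: ConversionEvent, e2: ConversionEvent) -> bool:
        r1, r2 = e1.representative, e2.representative
        if r1.primary_species == r2.primary_species:
            return False
        og1 = {o.outgroup_species for o in e1.observations}
        og2 = {o.outgroup_species for o in e2.observations}
        if not (og1 & og2):
            return False
        direct = _paralogs_orthologous(
            orthology, r1.paralog1, r2.paralog1
        ) and _paralogs_orthologous(orthology, r1.paralog2, r2.paralog2)
        swapped = _paralogs_orthologous(
            orthology, r1.paralog1, r2.paralog2
        ) and _paralogs_orthologous(orthology, r1.paralog2, r2.paralog1)
        if not (direct or swapped):
            return False
        mapped = _orthologous_interval(
            orthology,
            r1.paralog1,
            r2.primary_species,
            r1.conv1,
        )
        if mapped is None:
            return False
        target = r2.conv1 if direct else r2.conv2
        return reciprocal_overlap(mapped, target) >= tolerance

    clusters = _cluster_by_similarity(events, mergeable)
    merged = []
    for cluster in clusters:
        if len(cluster) == 1:
            merged.append(cluster[0])
            continue
        obs = [o for e in cluster for o in e.observations]
        merged.append(_make_event(obs))
    return merged


def classify_type_c(
    obsA: ConversionObservation,
    obsB: ConversionObservation,
    similarities: TripleSimilarity,
) -> str:
    """Arbitrate two observations sharing a converted copy.

    With observations A1->A3 and A2->A3 (A3 shared) and percent identities
    s1 = Sim(A1,A2), s2 = Sim(A1,A3), s3 = Sim(A2,A3) inside the conversion
    region:

    * max = s1: the conversion predates the A1/A2 duplication
      ('before-duplication'; both observations are the same event, keep the
      lowest P-value);
    * max = s2: the real conversion is A1<->A3 ('pairwise-1'; the A2->A3
      observation is the incorrect one);
    * max = s3: the real conversion is A2<->A3 ('pairwise-2').

    Exact ties resolve toward 'before-duplication' (fewest distinct events)
    with a log warning.
    """
    s = similarities
    top = max(s.s1, s.s2, s.s3)
    winners = [name for name, val in (("s1", s.s1), ("s2", s.s2), ("s3", s.s3)) if val == top]
    if len(winners) > 1:
        logger.warning(
            "type-c similarity tie (%s); resolving toward before-duplication", winners
        )
        if "s1" in winners:
            return "before-duplication"
        return "pairwise-1" if "s2" in winners else "pairwise-2"
    return {"s1": "before-duplication", "s2": "pairwise-1", "s3": "pairwise-2"}[
        winners[0]
    ]


def _find_paralog_alignment(
    alignments: Sequence[PairwiseAlignment],
    a: GenomicInterval,
    b: GenomicInterval,
) -> Optional[tuple[PairwiseAlignment, int]]:
    """An intra-species alignment joining intervals a and b (a's row first)."""
    best, best_ov = None, 0
    for aln in alignments:
        if aln.kind != "paralog":
            continue
        for ra, rb in ((1, 2), (2, 1)):
            iva, _ = aln.row(ra)
            ivb, _ = aln.row(rb)
            if iva.overlaps(a) and ivb.overlaps(b):
                ov = iva.overlap_len(a) + ivb.overlap_len(b)
                if ov > best_ov:
                    best, best_ov = (aln, ra), ov
    return best


def _identity_in_region(
    alignments: Sequence[PairwiseAlignment],
    a: GenomicInterval,
    b: GenomicInterval,
    region_on_a: tuple[int, int],
) -> Optional[float]:
    found = _find_paralog_alignment(alignments, a, b)
    if found is None:
        return None
    aln, arow = found
    pos = aln.col_positions(arow)
    cols = np.flatnonzero((pos >= region_on_a[0]) & (pos < region_on_a[1]))
    if cols.size == 0:
        return None
    try:
        return percent_identity(aln, (int(cols.min()), int(cols.max()) + 1))
    except UndefinedIdentityError:
        return None


def _shared_paralog(
    e1: ConversionEvent, e2: ConversionEvent, tolerance: float
) -> Optional[tuple]:
    """Detect the type-c configuration between two events of one primary.

    Returns ``(A1, A2, A3, conv_on_A3_1, conv_on_A3_2)`` when the two events'
    pairs share one copy (A3) with boundary-similar converted intervals on
    it, or None.
    """
    r1, r2 = e1.representative, e2.representative
    if r1.primary_species != r2.primary_species:
        return None
    combos = []
    for p1a, p1b, c1a, c1b in (
        (r1.paralog1, r1.paralog2, r1.conv1, r1.conv2),
        (r1.paralog2, r1.paralog1, r1.conv2, r1.conv1),
    ):
        for p2a, p2b, c2a, c2b in (
            (r2.paralog1, r2.paralog2, r2.conv1, r2.conv2),
            (r2.paralog2, r2.paralog1, r2.conv2, r2.conv1),
        ):
            # shared copy = p1b ~ p2b; distinct partners p1a vs p2a
            if not p1b.overlaps(p2b):
                continue
            if reciprocal_overlap((p1b.start, p1b.end), (p2b.start, p2b.end)) < tolerance:
                continue
            if p1a.overlaps(p2a):
                continue
            if reciprocal_overlap(c1b, c2b) < tolerance:
                continue
            combos.append((p1a, p2a, p1b, c1a, c1b, c2a, c2b))
    return combos[0] if combos else None


def collapse_type_c(
    events: list[ConversionEvent],
    alignments: Optional[Sequence[PairwiseAlignment]],
    tolerance: float = 0.5,
) -> list[ConversionEvent]:
    """Arbitrate events sharing a converted copy via the similarity rule."""
    if not alignments:
        return events
    events = list(events)
    merged_away: set[int] = set()
    for i in range(len(events)):
        if i in merged_away:
            continue
        for j in range(i + 1, len(events)):
            if j in merged_away or i in merged_away:
                continue
            found = _shared_paralog(events[i], events[j], tolerance)
            if found is None:
                continue
            a1, a2, a3, conv_a1, conv_on_a3_1, conv_a2, conv_on_a3_2 = found
            s1 = _identity_in_region(alignments, a1, a2, conv_a1)
            s2 = _identity_in_region(alignments, a1, a3, conv_a1)
            s3 = _identity_in_region(alignments, a2, a3, conv_a2)
            if s1 is None or s2 is None or s3 is None:
                logger.warning(
                    "type-c candidate lacks alignments for similarity; left separate"
                )
                continue
            case = classify_type_c(
                events[i].representative,
                events[j].representative,
                TripleSimilarity(s1, s2, s3),
            )
            obs = events[i].observations + events[j].observations
            if case == "before-duplication":
                new = _make_event(obs)
            elif case == "pairwise-1":
                new = ConversionEvent(-1, obs, events[i].representative)
            else:
                new = ConversionEvent(-1, obs, events[j].representative)
            new.inferred_case = case
            events[i] = new
            merged_away.add(j)
    return [e for idx, e in enumerate(events) if idx not in merged_away]


def deduplicate(
    observations: Sequence[ConversionObservation],
    orthology: Optional[OrthologyMap] = None,
    alignments: Optional[Sequence[PairwiseAlignment]] = None,
    tolerance: float = 0.5,
) -> list[ConversionEvent]:
    """Full redundancy collapse: type a, then b, then c.

    Event ids are assigned in ascending (primary species, genomic start)
    order of the representatives, and stamped onto every observation.
    """
    events = collapse_type_a(observations, tolerance)
    events = collapse_type_b(events, orthology, tolerance)
    events = collapse_type_c(events, alignments, tolerance)
    events.sort(
        key=lambda e: (
            e.representative.primary_species,
            e.representative.converted_interval[0],
            e.representative.paralog1.start,
        )
    )
    for idx, event in enumerate(events, start=1):
        event.event_id = idx
        for obs in event.observations:
            obs.event_id = idx
    return events


def events_to_bed(events: Sequence[ConversionEvent]) -> str:
    """BED6 text of the representatives' converted intervals."""
    lines = []
    for e in events:
        rep = e.representative
        lo, hi = rep.converted_interval
        lines.append(
            f"{rep.paralog1.seq_id}\t{lo}\t{hi}\t"
            f"event_{e.event_id}_{rep.primary_species}\t0\t+"
        )
    return "\n".join(lines) + ("\n" if lines else "")


def events_to_tables(
    events: Sequence[ConversionEvent],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(full annotated table, non-redundant representative table)."""
    all_obs = [o for e in events for o in e.observations]
    all_obs.sort(key=lambda o: (o.event_id, o.p_value))
    full = observations_to_table(all_obs, with_event_id=True)
    reps = [e.representative for e in events]
    nr = observations_to_table(reps, with_event_id=True)
    for frame, evs in ((nr, events),):
        frame["branch"] = [e.branch if e.branch is not None else "" for e in evs]
    if events:
        branch_by_id = {e.event_id: (e.branch or "") for e in events}
        full["branch"] = [branch_by_id[i] for i in full["event_id"]]
    else:
        full["branch"] = pd.Series(dtype=str)
    return full, nr
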