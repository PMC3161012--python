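"""Conversion detection over all (primary species, paralog pair, outgroup) tests.

For every intra-species paralog alignment and every other species in the
tree, a triplet test is run when one ortholog projection is available and a
quadruplet test when both are.  The maximum descent routes each test to
criterion 1 (descent P-value) or, when the descent spans more than the
coverage threshold of the paralog alignment, to criterion 2 (binomial
whole-paralog test, gated on the paralogs mapping to distinct ortholog
regions).  Significance is Bonferroni-corrected over all tests executed in
the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import (
    GenomicInterval,
    OrthologyMap,
    PairwiseAlignment,
    project_onto_paralog_columns,
)
from .tree import SpeciesTree
from .walk import (
    MaxDescent,
    StepSeries,
    binomial_coverage_pvalue,
    build_triplet_walk,
    collapse_magnitudes,
    combine_quadruplet,
    infer_direction,
    max_descent_pvalue,
    maximum_descent,
)

__all__ = [
    "DetectionConfig",
    "ConversionObservation",
    "select_criterion",
    "distinct_orthologs",
    "significance_cutoff",
    "detect_pair",
    "scan_cluster",
    "observations_to_table",
    "OBSERVATION_COLUMNS",
]

logger = logging.getLogger(__name__)


@dataclass
class DetectionConfig:
    """Tunable thresholds of the detector.

    coverage_threshold
        Descent-span fraction above which the whole-paralog criterion 2
        replaces the descent test (strictly greater than; default 0.80).
    alpha
        Family-wise significance level, Bonferroni-corrected over all tests
        executed in a run.
    min_informative_sites
        Tests with fewer informative sites are reported as untested.
    boundary_tolerance
        Reciprocal-overlap threshold for "equal or quite similar" boundaries
        during redundancy collapsing.
    direction_alpha
        Significance level of the donor/recipient call.
    """

    coverage_threshold: float = 0.80
    alpha: float = 0.05
    min_informative_sites: int = 10
    boundary_tolerance: float = 0.5
    direction_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.coverage_threshold < 1.0):
            raise ValueError("coverage_threshold must be in (0, 1)")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class ConversionObservation:
    """One detected converted interval for a (primary, pair, outgroup) test.

    ``conv1``/``conv2`` are the half-open genomic intervals of the descent
    region on the two paralog rows.  ``direction`` is donor->recipient in
    terms of rows ("p1->p2", "p2->p1", or "unknown").
    """

    primary_species: str
    paralog1: GenomicInterval
    paralog2: GenomicInterval
    outgroup_species: str
    conv1: tuple[int, int]
    conv2: tuple[int, int]
    p_value: float
    criterion: int
    direction: str
    m: int
    n: int
    k: int
    direction_p: Optional[float] = None
    p_binom_param: Optional[float] = None
    event_id: Optional[int] = None

    @property
    def pair_key(self) -> tuple:
        return (
            self.primary_species,
            self.paralog1.seq_id,
            self.paralog1.start,
            self.paralog1.end,
            self.paralog2.start,
            self.paralog2.end,
        )

    @property
    def converted_interval(self) -> tuple[int, int]:
        """Interval on the inferred recipient (row 1 when direction unknown)."""
        return self.conv2 if self.direction == "p1->p2" else self.conv1


def select_criterion(
    walk: StepSeries,
    descent: MaxDescent,
    paralog_len_cols: int,
    config: Optional[DetectionConfig] = None,
) -> str:
    """Route a test: 'criterion1', 'criterion2_candidate', or 'rejected'.

    A descent spanning strictly more than ``coverage_threshold`` of the
    paralog-alignment columns skips the descent test (its P-value degenerates
    without flanking regions) in favour of the whole-paralog criterion.
    Walks below the informative-site minimum are rejected as untested.
    """
    config = config or DetectionConfig()
    if walk.m + walk.n < config.min_informative_sites:
        return "rejected"
    if descent.empty or descent.start_col is None:
        return "criterion1"
    span = descent.end_col - descent.start_col + 1
    if span > config.coverage_threshold * paralog_len_cols:
        return "criterion2_candidate"
    return "criterion1"


def distinct_orthologs(
    paralog1: GenomicInterval,
    paralog2: GenomicInterval,
    orthology: OrthologyMap,
    outgroup: str,
) -> bool:
    """True iff both paralogs map to non-empty, non-overlapping ortholog sets.

    Distinct ortholog regions witness a duplication predating the speciation,
    so whole-length similarity between the paralogs is evidence of conversion
    rather than of a recent duplication.
    """
    orth1 = [iv for iv, _, _ in orthology.partners(paralog1, outgroup)]
    orth2 = [iv for iv, _, _ in orthology.partners(paralog2, outgroup)]
    if not orth1 or not orth2:
        return False
    return not any(a.overlaps(b) for a in orth1 for b in orth2)


def significance_cutoff(num_tests: int, alpha: float) -> float:
    """Bonferroni per-test threshold over all tests executed in the run."""
    if num_tests < 1:
        raise ValueError("num_tests must be >= 1")
    return alpha / num_tests


def _descent_to_genomic(
    paralog: PairwiseAlignment, descent: MaxDescent
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Half-open genomic intervals spanned by the descent on both rows."""
    out = []
    for which in (1, 2):
        pos = paralog.col_positions(which)
        lo, hi = descent.start_col, descent.end_col
        span = pos[lo : hi + 1]
        span = span[span >= 0]
        out.append((int(span.min()), int(span.max()) + 1))
    return out[0], out[1]


def _run_pair_test(
    paralog: PairwiseAlignment,
    outgroup: str,
    orthology: OrthologyMap,
    config: DetectionConfig,
) -> tuple[Optional[ConversionObservation], bool]:
    """One (pair, outgroup) test with an *uncorrected* P-value.

    Returns ``(candidate, executed)``; the candidate still has to clear the
    run-level corrected cutoff.  ``executed`` is False when no ortholog
    projection exists or too few informative sites were found.
    """
    walks: dict[int, StepSeries] = {}
    for row in (1, 2):
        found = orthology.best_alignment(paralog.row(row)[0], outgroup)
        if found is None:
            continue
        ortho_aln, qrow = found
        proj = project_onto_paralog_columns(paralog, ortho_aln, row, qrow)
        walk = build_triplet_walk(paralog, proj, row)
        if len(walk):
            walks[row] = walk
    if not walks:
        return None, False

    if len(walks) == 2:
        # magnitudes mark doubly-supported columns; the exchangeable null of
        # the P-value counts columns, so the test walk collapses them.
        operative = collapse_magnitudes(combine_quadruplet(walks[1], walks[2]))
    else:
        operative = next(iter(walks.values()))

    descent = maximum_descent(operative)
    route = select_criterion(operative, descent, len(paralog), config)
    if route == "rejected":
        return None, False

    m, n, k = operative.m, operative.n, descent.k
    p_binom_param: Optional[float] = None
    if route == "criterion2_candidate":
        if not distinct_orthologs(
            paralog.interval1, paralog.interval2, orthology, outgroup
        ):
            # duplication may postdate the speciation: whole-length similarity
            # is expected, not conversion.  The test was still executed.
            return None, True
        p_value, p_binom_param = binomial_coverage_pvalue(m, n)
        criterion = 2
    else:
        p_value = max_descent_pvalue(m, n, k) if k > 0 else 1.0
        criterion = 1

    direction, direction_p = "unknown", None
    if len(walks) == 2 and not descent.empty:
        d1, d2 = maximum_descent(walks[1]), maximum_descent(walks[2])
        if not d1.empty and not d2.empty:
            lo = max(d1.start_col, d2.start_col)
            hi = min(d1.end_col, d2.end_col)
            if lo <= hi:
                shared = MaxDescent(1, lo, hi)
                rdir, direction_p = infer_direction(
                    walks[1], walks[2], shared, config.direction_alpha
                )
                direction = {
                    "row1->row2": "p1->p2",
                    "row2->row1": "p2->p1",
                    "unknown": "unknown",
                }[rdir]

    if descent.empty:
        return None, True
    conv1, conv2 = _descent_to_genomic(paralog, descent)
    obs = ConversionObservation(
        primary_species=paralog.interval1.species,
        paralog1=paralog.interval1,
        paralog2=paralog.interval2,
        outgroup_species=outgroup,
        conv1=conv1,
        conv2=conv2,
        p_value=p_value,
        criterion=criterion,
        direction=direction,
        m=m,
        n=n,
        k=k,
        direction_p=direction_p,
        p_binom_param=p_binom_param,
    )
    return obs, True


def detect_pair(
    paralog: PairwiseAlignment,
    outgroup: str,
    orthology: OrthologyMap,
    config: Optional[DetectionConfig] = None,
    cutoff: Optional[float] = None,
) -> list[ConversionObservation]:
    """Run one paralog pair against one outgroup and filter by ``cutoff``.

    ``cutoff`` defaults to the uncorrected ``config.alpha``; within a full
    cluster scan the Bonferroni-corrected run-level cutoff is applied
    instead (see :func:`scan_cluster`).
    """
    config = config or DetectionConfig()
    cutoff = config.alpha if cutoff is None else cutoff
    candidate, _ = _run_pair_test(paralog, outgroup, orthology, config)
    if candidate is not None and candidate.p_value <= cutoff:
        return [candidate]
    return []


def _is_self_diagonal(aln: PairwiseAlignment) -> bool:
    return (
        aln.interval1.seq_id == aln.interval2.seq_id
        and aln.interval1.start == aln.interval2.start
        and aln.interval1.end == aln.interval2.end
    )


def scan_cluster(
    alignments: Sequence[PairwiseAlignment],
    orthology: OrthologyMap,
    tree: SpeciesTree,
    config: Optional[DetectionConfig] = None,
) -> tuple[list[ConversionObservation], int]:
    """Test every (primary, paralog pair, outgroup) combination.

    Returns the significant observations (sorted by primary species,
    coordinates, outgroup) and the number of tests executed; the per-test
    cutoff is ``alpha / num_tests``.  Species present in alignments but
    absent from the tree raise.
    """
    config = config or DetectionConfig()
    species = set(tree.species)
    paralogs = [a for a in alignments if a.kind == "paralog"]
    for aln in paralogs:
        if aln.interval1.species not in species:
            raise ValueError(
                f"species {aln.interval1.species!r} in alignments but not in tree"
            )
    if len(species) < 2:
        logger.warning("single-species tree: no outgroups, nothing to test")

    candidates: list[ConversionObservation] = []
    num_tests = 0
    for aln in paralogs:
        if _is_self_diagonal(aln):
            continue
        primary = aln.interval1.species
        for outgroup in sorted(species - {primary}):
            candidate, executed = _run_pair_test(aln, outgroup, orthology, config)
            num_tests += executed
            if candidate is not None:
                candidates.append(candidate)

    observations: list[ConversionObservation] = []
    if num_tests:
        cutoff = significance_cutoff(num_tests, config.alpha)
        observations = [c for c in candidates if c.p_value <= cutoff]
    observations.sort(
        key=lambda o: (
            o.primary_species,
            o.paralog1.start,
            o.paralog2.start,
            o.outgroup_species,
        )
    )
    return observations, num_tests


OBSERVATION_COLUMNS = [
    "primary_species",
    "chrom",
    "par1_start",
    "par1_end",
    "par2_start",
    "par2_end",
    "outgroup",
    "conv_start",
    "conv_end",
    "direction",
    "p_value",
    "criterion",
    "m",
    "n",
    "k",
]


def observations_to_table(
    observations: Sequence[ConversionObservation], with_event_id: bool = False
) -> pd.DataFrame:
    """Tab-separated observation schema (1-based, inclusive coordinates)."""
    rows = []
    for o in observations:
        conv = o.converted_interval
        row = {
            "primary_species": o.primary_species,
            "chrom": o.paralog1.seq_id,
            "par1_start": o.paralog1.start + 1,
            "par1_end": o.paralog1.end,
            "par2_start": o.paralog2.start + 1,
            "par2_end": o.paralog2.end,
            "outgroup": o.outgroup_species,
            "conv_start": conv[0] + 1,
            "conv_end": conv[1],
            "direction": o.direction,
            "p_value": o.p_value,
            "criterion": o.criterion,
            "m": o.m,
            "n": o.n,
            "k": o.k,
        }
        if with_event_id:
            row["event_id"] = o.event_id
        rows.append(row)
    cols = OBSERVATION_COLUMNS + (["event_id"] if with_event_id else [])
    return pd.DataFrame(rows, columns=cols)
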