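"""Single-command end-to-end run: inputs -> observation and event tables.

``run_all`` chains the cluster scan, redundancy collapse, and branch
assignment, then writes the observation table, the full event-annotated
table, the non-redundant table, and a JSON run manifest.  ``summarize``
reports cluster-level conversion frequencies and the per-feature hot-spot
table.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .detect import (
    ConversionObservation,
    DetectionConfig,
    observations_to_table,
    scan_cluster,
)
from .grouping import ConversionEvent, deduplicate, events_to_bed, events_to_tables
from .io import OrthologyMap, PairwiseAlignment, read_bed, read_fasta, read_maf
from .timing import assign_branches
from .tree import SpeciesTree, read_newick_tree

__all__ = ["RunManifest", "run_all", "summarize", "load_inputs"]

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Provenance and per-stage counts of one pipeline run."""

    inputs: dict
    config: dict
    version: str
    seed: int
    num_pairs: int = 0
    num_tests: int = 0
    num_observations: int = 0
    num_events: int = 0
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _atomic_write(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name)
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        os.unlink(tmp)
        raise


def _write_table(path: Path, frame: pd.DataFrame) -> None:
    _atomic_write(path, frame.to_csv(sep="\t", index=False))


def load_inputs(
    fasta_dir, maf_dir, tree_path
) -> tuple[dict, list[PairwiseAlignment], OrthologyMap, SpeciesTree]:
    """Read cluster FASTAs, MAF alignments, and the species tree.

    Every MAF block is classified by its row species: same species =>
    paralog pair, different species => orthology entry.
    """
    tree = read_newick_tree(tree_path)
    sequences: dict[str, str] = {}
    fasta_dir = Path(fasta_dir)
    for path in sorted(fasta_dir.glob("*.fa")) + sorted(fasta_dir.glob("*.fasta")):
        for name, seq in read_fasta(path):
            sequences[name] = seq
    paralogs: list[PairwiseAlignment] = []
    orthology = OrthologyMap()
    for path in sorted(Path(maf_dir).glob("*.maf")):
        for aln in read_maf(path):
            if aln.kind == "paralog":
                paralogs.append(aln)
            else:
                orthology.add(aln)
    species_seen = {a.interval1.species for a in paralogs} | {
        s for a in orthology.alignments for s in
        (a.interval1.species, a.interval2.species)
    }
    missing = sorted(species_seen - set(tree.species))
    if missing:
        raise ValueError(
            f"species in alignments but not in tree: {', '.join(missing)}"
        )
    return sequences, paralogs, orthology, tree


def run_all(
    fasta_dir,
    maf_dir,
    tree_path,
    out_dir,
    config: Optional[DetectionConfig] = None,
) -> RunManifest:
    """Detect, deduplicate, date, and write all output tables."""
    config = config or DetectionConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sequences, paralogs, orthology, tree = load_inputs(fasta_dir, maf_dir, tree_path)

    manifest = RunManifest(
        inputs={
            "fasta_dir": str(fasta_dir),
            "maf_dir": str(maf_dir),
            "tree": str(tree_path),
        },
        config=dataclasses.asdict(config),
        version=__version__,
        seed=config.seed,
        num_pairs=len(paralogs),
    )
    if not paralogs:
        manifest.warnings.append("no paralog alignments found; tables are empty")
        logger.warning("no paralog alignments found")

    observations, num_tests = scan_cluster(paralogs, orthology, tree, config)
    events = deduplicate(
        observations, orthology, paralogs, config.boundary_tolerance
    )
    assign_branches(events, tree)

    manifest.num_tests = num_tests
    manifest.num_observations = len(observations)
    manifest.num_events = len(events)

    _write_table(out / "observations.tsv", observations_to_table(observations))
    full, nonredundant = events_to_tables(events)
    _write_table(out / "events.tsv", full)
    _write_table(out / "events_nr.tsv", nonredundant)
    _atomic_write(out / "events_nr.bed", events_to_bed(events))
    _atomic_write(out / "tree_edges.nwk", tree.annotated_newick() + "\n")
    _atomic_write(out / "manifest.json", manifest.to_json() + "\n")
    return manifest


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total, cur_lo, cur_hi = 0, None, None
    for lo, hi in sorted(intervals):
        if cur_hi is None or lo > cur_hi:
            if cur_hi is not None:
                total += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    if cur_hi is not None:
        total += cur_hi - cur_lo
    return total


def _coverage_tiers(
    intervals: list[tuple[int, int]], tiers: Sequence[int]
) -> dict[int, int]:
    """Bases covered by at least `tier` of the given (possibly nested) intervals."""
    if not intervals:
        return {t: 0 for t in tiers}
    edges = sorted({x for iv in intervals for x in iv})
    counts = {t: 0 for t in tiers}
    for lo, hi in zip(edges, edges[1:]):
        depth = sum(1 for a, b in intervals if a <= lo and hi <= b)
        for t in tiers:
            if depth >= t:
                counts[t] += hi - lo
    return counts


def summarize(
    events: Sequence[ConversionEvent],
    paralogs: Sequence[PairwiseAlignment],
    bed_path=None,
) -> dict:
    """Cluster-level conversion frequencies and hot-spot features.

    Reports the fraction of paralog pairs with at least one event, the
    fraction of duplicated bases (bases covered by >= 1 paralog alignment)
    involved in >= 1/2/4 conversions as donor or recipient, and per-feature
    event counts when a BED annotation is given.
    """
    pair_keys = set()
    for aln in paralogs:
        pair_keys.add((
            aln.interval1.species, aln.interval1.seq_id,
            aln.interval1.start, aln.interval1.end,
            aln.interval2.start, aln.interval2.end,
        ))
    pairs_with_event = set()
    for event in events:
        for obs in event.observations:
            pairs_with_event.add(obs.pair_key)
    pair_fraction = len(pairs_with_event) / len(pair_keys) if pair_keys else 0.0

    # duplicated bases, per species: union of paralog-alignment rows
    dup_by_species: dict[str, list[tuple[int, int]]] = {}
    for aln in paralogs:
        for which in (1, 2):
            iv, _ = aln.row(which)
            dup_by_species.setdefault(iv.species, []).append((iv.start, iv.end))
    dup_total = sum(_union_length(v) for v in dup_by_species.values())

    conv_by_species: dict[str, list[tuple[int, int]]] = {}
    for event in events:
        rep = event.representative
        # donor and recipient intervals both count as "involved"
        conv_by_species.setdefault(rep.primary_species, []).extend(
            [rep.conv1, rep.conv2]
        )
    tiers = (1, 2, 4)
    tier_totals = {t: 0 for t in tiers}
    for sp, intervals in conv_by_species.items():
        got = _coverage_tiers(intervals, tiers)
        for t in tiers:
            tier_totals[t] += got[t]
    base_fractions = {
        f"bases_converted_ge{t}": (tier_totals[t] / dup_total if dup_total else 0.0)
        for t in tiers
    }

    hotspots = []
    if bed_path is not None:
        features = read_bed(bed_path)
        chroms = {o.paralog1.seq_id for e in events for o in e.observations}
        for chrom, start, end, name in features:
            if chroms and chrom not in chroms:
                logger.warning("BED feature %s on unknown chrom %s; skipped", name, chrom)
                continue
            count = 0
            for event in events:
                rep = event.representative
                if any(lo < end and start < hi for lo, hi in (rep.conv1, rep.conv2)):
                    count += 1
            hotspots.append({"feature": name, "chrom": chrom, "events": count})
        hotspots.sort(key=lambda h: (-h["events"], h["feature"]))

    return {
        "num_pairs": len(pair_keys),
        "num_events": len(events),
        "pair_fraction_converted": pair_fraction,
        "duplicated_bases": dup_total,
        **base_fractions,
        "hotspots": hotspots,
    }
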