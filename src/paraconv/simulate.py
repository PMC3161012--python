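"""Gene-cluster evolution simulator and detection-evaluation harness.

The simulator evolves a cluster of paralogous *units* down a species tree
with branch lengths in expected substitutions/site.  Units are contiguous
copies of intervals of the ancestral (root) coordinate system:

* substitutions follow a single-rate symmetric (Jukes-Cantor-style) model,
  applied independently per site;
* duplications copy a unit (or a sub-interval) and insert it adjacent to
  its source, creating a new unit id;
* conversions overwrite a tract of a recipient unit with the homologous
  (same root coordinates) tract of a donor unit in the same genome.

Because units never acquire indels, the true paralog and ortholog alignments
are gap-free and derived exactly from the recorded coordinate history — no
aligner is involved.  Orthology is positional: the same unit id in two
species.  Events can be drawn from per-branch Poisson rates, scripted
explicitly, or both; a single integer seed fixes every output byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .detect import ConversionObservation, DetectionConfig, scan_cluster
from .io import (
    GenomicInterval,
    OrthologyMap,
    PairwiseAlignment,
    reciprocal_overlap,
    write_fasta,
    write_maf,
)
from .tree import SpeciesTree

__all__ = [
    "SimConfig",
    "ScriptedDuplication",
    "ScriptedConversion",
    "GroundTruthEvent",
    "SimResult",
    "simulate_cluster",
    "evaluate_detection",
    "run_detector",
    "null_calibration",
    "recovery_study",
    "threshold_sweep",
    "DEFAULT_TREE",
]

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Four-taxon study tree; depths in expected substitutions/site.  The stem
#: branch above the clade lets an ancestral duplication strictly predate the
#: first speciation, the canonical condition for outgroup-based detection.
DEFAULT_TREE = "((((S1:0.04,S2:0.04):0.03,S3:0.07):0.03,S4:0.10):0.05);"

ROOT_BRANCH = "root"

_MAX_UNITS = 10_000


@dataclass(frozen=True)
class ScriptedDuplication:
    """A deterministic duplication on a named branch.

    ``branch`` is the clade key of the edge's child node ('+'-joined sorted
    leaf names; the string 'root' places the event in the ancestral cluster
    before any speciation).  ``time`` is the fractional position along the
    branch.  ``length`` of None copies the whole source unit.
    """

    branch: str
    time: float = 0.5
    source_index: int = 0
    length: Optional[int] = None


@dataclass(frozen=True)
class ScriptedConversion:
    """A deterministic conversion on a named branch.

    ``start`` is a root coordinate for the tract start (None: placed
    uniformly); ``length`` of None draws from the tract-length distribution,
    and a length covering the full donor/recipient overlap converts the
    entire unit.
    """

    branch: str
    time: float = 0.5
    donor_index: int = 0
    recipient_index: int = 1
    start: Optional[int] = None
    length: Optional[int] = None


@dataclass
class SimConfig:
    """Study conditions for one simulated cluster.

    Rates are expected events per unit branch length (substitutions/site),
    per genome.  Defaults emulate a small primate-like cluster: one ancestral
    whole-cluster duplication, 3 kb units, and no stochastic rearrangements
    (conversions are scripted per study).
    """

    tree_newick: str = DEFAULT_TREE
    root_length: int = 3000
    duplication_rate: float = 0.0
    conversion_rate: float = 0.0
    conversion_tract_mean: float = 500.0
    duplication_length: Optional[int] = None
    min_homology: int = 200
    scripted_duplications: tuple[ScriptedDuplication, ...] = (
        ScriptedDuplication(branch=ROOT_BRANCH, source_index=0),
    )
    scripted_conversions: tuple[ScriptedConversion, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duplication_rate < 0 or self.conversion_rate < 0:
            raise ValueError("rates must be non-negative")


@dataclass(frozen=True)
class GroundTruthEvent:
    """One entry of the simulation's event log.

    ``branch`` is the clade key of the branch the event occurred on;
    ``root_start``/``root_end`` delimit the affected tract in ancestral
    coordinates (the copied interval for duplications).
    """

    kind: str  # duplication | conversion | speciation
    branch: str
    time: float
    donor_unit: int
    recipient_unit: int
    root_start: int
    root_end: int


@dataclass
class _Unit:
    uid: int
    root_start: int
    root_end: int
    seq: np.ndarray

    def copy(self) -> "_Unit":
        return _Unit(self.uid, self.root_start, self.root_end, self.seq.copy())

    def __len__(self) -> int:
        return self.root_end - self.root_start


@dataclass
class SimResult:
    """Sequences, true alignments, orthology, and ground truth of one run."""

    config: SimConfig
    tree: SpeciesTree
    sequences: dict[str, str]
    paralog_alignments: list[PairwiseAlignment]
    orthology: OrthologyMap
    truth: list[GroundTruthEvent]
    unit_layout: dict[str, list[tuple[int, int, int, int]]]
    #: unit creation branch, by unit id
    unit_branch: dict[int, str]

    def truth_conversions(self) -> list[GroundTruthEvent]:
        return [e for e in self.truth if e.kind == "conversion"]

    def leaf_interval(self, species: str, unit_id: int,
                      root_interval: tuple[int, int]) -> Optional[tuple[int, int]]:
        """Genome coordinates of a root-coordinate tract of a unit in a leaf."""
        for uid, gstart, rstart, rend in self.unit_layout[species]:
            if uid != unit_id:
                continue
            lo = max(root_interval[0], rstart)
            hi = min(root_interval[1], rend)
            if lo >= hi:
                return None
            return gstart + lo - rstart, gstart + hi - rstart
        return None


def _substitute(units: list[_Unit], t: float, rng: np.random.Generator) -> None:
    if t <= 0:
        return
    p = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
    for unit in units:
        mask = rng.random(len(unit.seq)) < p
        hits = int(mask.sum())
        if hits:
            unit.seq[mask] = (unit.seq[mask] + rng.integers(1, 4, hits)) % 4


def _apply_duplication(
    units: list[_Unit],
    src_idx: int,
    length: Optional[int],
    next_uid: int,
    rng: np.random.Generator,
) -> tuple[_Unit, int, int]:
    src = units[src_idx]
    if length is None or length >= len(src):
        lo, hi = src.root_start, src.root_end
    else:
        off = int(rng.integers(0, len(src) - length + 1))
        lo, hi = src.root_start + off, src.root_start + off + length
    new = _Unit(next_uid, lo, hi, src.seq[lo - src.root_start : hi - src.root_start].copy())
    units.insert(src_idx + 1, new)
    return new, lo, hi


def _apply_conversion(
    units: list[_Unit],
    donor_idx: int,
    recip_idx: int,
    start: Optional[int],
    length: Optional[int],
    tract_mean: float,
    rng: np.random.Generator,
) -> Optional[tuple[int, int]]:
    donor, recip = units[donor_idx], units[recip_idx]
    lo = max(donor.root_start, recip.root_start)
    hi = min(donor.root_end, recip.root_end)
    if hi - lo <= 0:
        return None
    span = hi - lo
    if length is None:
        length = int(rng.geometric(1.0 / tract_mean))
    length = max(1, min(length, span))
    if start is None:
        start = lo + int(rng.integers(0, span - length + 1))
    start = max(lo, min(start, hi - length))
    end = start + length
    recip.seq[start - recip.root_start : end - recip.root_start] = donor.seq[
        start - donor.root_start : end - donor.root_start
    ]
    return start, end


def _branch_events(
    node_key: str,
    branch_len: float,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[tuple[float, str, object]]:
    """Time-sorted (time, kind, payload) events for one branch."""
    events: list[tuple[float, str, object]] = []
    for sd in config.scripted_duplications:
        if sd.branch == node_key:
            events.append((sd.time, "duplication", sd))
    for sc in config.scripted_conversions:
        if sc.branch == node_key:
            events.append((sc.time, "conversion", sc))
    if branch_len > 0:
        for _ in range(rng.poisson(config.duplication_rate * branch_len)):
            events.append((float(rng.random()), "duplication", None))
        for _ in range(rng.poisson(config.conversion_rate * branch_len)):
            events.append((float(rng.random()), "conversion", None))
    events.sort(key=lambda e: e[0])
    return events


def simulate_cluster(config: SimConfig, seed: Optional[int] = None) -> SimResult:
    """Evolve a cluster down the species tree; deterministic given the seed."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    tree = SpeciesTree(config.tree_newick)
    truth: list[GroundTruthEvent] = []
    unit_branch: dict[int, str] = {0: ROOT_BRANCH}
    next_uid = 1

    root_units = [_Unit(0, 0, config.root_length,
                        rng.integers(0, 4, config.root_length, dtype=np.uint8))]

    def run_branch(units: list[_Unit], node_key: str, branch_len: float) -> None:
        nonlocal next_uid
        clock = 0.0
        events = _branch_events(node_key, branch_len, config, rng)
        n_dups = sum(1 for _, kind, _ in events if kind == "duplication")
        if len(units) + n_dups > _MAX_UNITS:
            raise RuntimeError(
                "duplication rate produced too many segments; lower the rate"
            )
        for time, kind, payload in events:
            _substitute(units, (time - clock) * branch_len, rng)
            clock = time
            if kind == "duplication":
                if payload is not None:
                    src = payload.source_index
                    length = payload.length
                else:
                    src = int(rng.integers(0, len(units)))
                    length = config.duplication_length
                new, lo, hi = _apply_duplication(units, src, length, next_uid, rng)
                unit_branch[new.uid] = node_key
                truth.append(GroundTruthEvent(
                    "duplication", node_key, time, units[src].uid, new.uid, lo, hi))
                next_uid += 1
            else:
                if payload is not None:
                    d, r = payload.donor_index, payload.recipient_index
                    start, length = payload.start, payload.length
                else:
                    pairs = [
                        (i, j)
                        for i in range(len(units))
                        for j in range(len(units))
                        if i != j
                        and min(units[i].root_end, units[j].root_end)
                        - max(units[i].root_start, units[j].root_start)
                        >= config.min_homology
                    ]
                    if not pairs:
                        continue
                    d, r = pairs[int(rng.integers(0, len(pairs)))]
                    start, length = None, None
                if d >= len(units) or r >= len(units) or d == r:
                    raise ValueError(f"scripted conversion indexes invalid on {node_key}")
                tract = _apply_conversion(
                    units, d, r, start, length, config.conversion_tract_mean, rng)
                if tract is not None:
                    truth.append(GroundTruthEvent(
                        "conversion", node_key, time,
                        units[d].uid, units[r].uid, tract[0], tract[1]))
        _substitute(units, (1.0 - clock) * branch_len, rng)

    leaf_genomes: dict[str, list[_Unit]] = {}

    def descend(units: list[_Unit], node) -> None:
        if node.is_leaf():
            leaf_genomes[node.label] = units
            return
        truth.append(GroundTruthEvent(
            "speciation", node.clade_key(), 1.0, -1, -1, 0, 0))
        for child in node.children:
            child_units = [u.copy() for u in units]
            run_branch(child_units, child.clade_key(), child.length)
            descend(child_units, child)

    run_branch(root_units, ROOT_BRANCH, 0.0)
    descend(root_units, tree.root)

    sequences: dict[str, str] = {}
    unit_layout: dict[str, list[tuple[int, int, int, int]]] = {}
    for species in tree.species:
        units = leaf_genomes[species]
        layout, chunks, offset = [], [], 0
        for u in units:
            layout.append((u.uid, offset, u.root_start, u.root_end))
            chunks.append(u.seq)
            offset += len(u)
        unit_layout[species] = layout
        sequences[species] = (
            _ALPHABET[np.concatenate(chunks)].tobytes().decode()
        )

    paralogs = _true_paralog_alignments(tree, leaf_genomes, unit_layout)
    orthology = _true_ortholog_alignments(tree, leaf_genomes, unit_layout)
    return SimResult(
        config=config,
        tree=tree,
        sequences=sequences,
        paralog_alignments=paralogs,
        orthology=orthology,
        truth=truth,
        unit_layout=unit_layout,
        unit_branch=unit_branch,
    )


def _unit_text(unit: _Unit, lo: int, hi: int) -> str:
    seg = unit.seq[lo - unit.root_start : hi - unit.root_start]
    return _ALPHABET[seg].tobytes().decode()


def _genome_interval(layout, species: str, uid: int, lo: int, hi: int) -> GenomicInterval:
    for u, gstart, rstart, rend in layout[species]:
        if u == uid:
            return GenomicInterval(
                species, "cluster", gstart + lo - rstart, gstart + hi - rstart)
    raise KeyError(uid)


def _true_paralog_alignments(tree, genomes, layout, min_len: int = 100):
    out = []
    for species in tree.species:
        units = genomes[species]
        for i in range(len(units)):
            for j in range(i + 1, len(units)):
                a, b = units[i], units[j]
                lo = max(a.root_start, b.root_start)
                hi = min(a.root_end, b.root_end)
                if hi - lo < min_len:
                    continue
                out.append(PairwiseAlignment(
                    _genome_interval(layout, species, a.uid, lo, hi),
                    _unit_text(a, lo, hi),
                    _genome_interval(layout, species, b.uid, lo, hi),
                    _unit_text(b, lo, hi),
                    kind="paralog",
                ))
    return out


def _true_ortholog_alignments(tree, genomes, layout, min_len: int = 100):
    omap = OrthologyMap()
    species = tree.species
    for si in range(len(species)):
        for sj in range(si + 1, len(species)):
            sa, sb = species[si], species[sj]
            units_b = {u.uid: u for u in genomes[sb]}
            for ua in genomes[sa]:
                ub = units_b.get(ua.uid)
                if ub is None:
                    continue
                lo = max(ua.root_start, ub.root_start)
                hi = min(ua.root_end, ub.root_end)
                if hi - lo < min_len:
                    continue
                omap.add(PairwiseAlignment(
                    _genome_interval(layout, sa, ua.uid, lo, hi),
                    _unit_text(ua, lo, hi),
                    _genome_interval(layout, sb, ub.uid, lo, hi),
                    _unit_text(ub, lo, hi),
                    kind="ortholog",
                ))
    return omap


# ---------------------------------------------------------------------------
# Evaluation harness
# ---------------------------------------------------------------------------

def _node_by_key(tree: SpeciesTree, key: str):
    if key == ROOT_BRANCH:
        return tree.root
    for node in tree.postorder():
        if node.clade_key() == key:
            return node
    raise KeyError(key)


def _leaves_under(tree: SpeciesTree, node) -> set[str]:
    return set(node.leaf_labels())


def evaluate_detection(
    observations: Sequence[ConversionObservation],
    sim: SimResult,
    match_rule: float = 0.5,
) -> dict:
    """Sensitivity, FDR, and boundary-error statistics against ground truth.

    A detected observation matches a true conversion when one of its two
    converted intervals reciprocally overlaps the true tract (projected onto
    the recipient or donor unit of the observation's primary species) by at
    least ``match_rule``.  A truth counts as detectable in principle when
    some carrying leaf has an outgroup that split after the pair's
    duplication but is not itself a carrier.  FDR is 0 by convention when
    there are no detections.
    """
    tree = sim.tree
    truths = sim.truth_conversions()
    all_leaves = set(tree.species)

    matched = set()
    obs_matched = [False] * len(observations)
    boundary_errors: list[float] = []

    detectable = []
    for t_idx, ev in enumerate(truths):
        carriers = _leaves_under(tree, _node_by_key(tree, ev.branch))
        dup_key = sim.unit_branch[max(ev.donor_unit, ev.recipient_unit)]
        have_pair = _leaves_under(tree, _node_by_key(tree, dup_key))
        outgroup_pool = (have_pair - carriers) & all_leaves
        if carriers and outgroup_pool:
            detectable.append(t_idx)

        errs = []
        for o_idx, obs in enumerate(observations):
            sp = obs.primary_species
            if sp not in carriers:
                continue
            for uid in (ev.recipient_unit, ev.donor_unit):
                true_iv = sim.leaf_interval(sp, uid, (ev.root_start, ev.root_end))
                if true_iv is None:
                    continue
                for det_iv in (obs.conv1, obs.conv2):
                    if reciprocal_overlap(det_iv, true_iv) >= match_rule:
                        matched.add(t_idx)
                        obs_matched[o_idx] = True
                        errs.append(
                            0.5 * (abs(det_iv[0] - true_iv[0]) + abs(det_iv[1] - true_iv[1]))
                        )
        if errs:
            boundary_errors.append(min(errs))

    n_det = len(detectable)
    sensitivity = (
        len([t for t in detectable if t in matched]) / n_det if n_det else 0.0
    )
    if observations:
        fdr = sum(1 for hit in obs_matched if not hit) / len(observations)
    else:
        fdr = 0.0
    return {
        "sensitivity": sensitivity,
        "fdr": fdr,
        "n_truths": len(truths),
        "n_detectable": n_det,
        "n_observations": len(observations),
        "boundary_errors": boundary_errors,
        "median_boundary_error": float(np.median(boundary_errors))
        if boundary_errors
        else float("nan"),
    }


def run_detector(
    sim: SimResult, config: Optional[DetectionConfig] = None
) -> list[ConversionObservation]:
    """Scan one simulated cluster with the full detector."""
    observations, _ = scan_cluster(
        sim.paralog_alignments, sim.orthology, sim.tree, config
    )
    return observations


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def null_calibration(
    n_reps: int = 500,
    seed: int = 0,
    config: Optional[DetectionConfig] = None,
    sim_config: Optional[SimConfig] = None,
) -> dict:
    """Fraction of no-conversion clusters with any call at corrected alpha.

    Clusters carry one duplication predating all speciations and evolve
    clock-free of conversion; with a valid test and Bonferroni correction the
    per-cluster false-call rate should not exceed alpha.
    """
    base = sim_config or SimConfig()
    hits = 0
    for s in _spawn_seeds(seed, n_reps):
        sim = simulate_cluster(replace(base, scripted_conversions=()), seed=s)
        if run_detector(sim, config):
            hits += 1
    return {"false_call_rate": hits / n_reps, "n_reps": n_reps}


def recovery_study(
    n_reps: int = 100,
    seed: int = 0,
    tract_length: Optional[int] = 500,
    conversion_branch: str = "S1",
    config: Optional[DetectionConfig] = None,
    sim_config: Optional[SimConfig] = None,
    match_rule: float = 0.5,
) -> dict:
    """Implant one conversion per cluster and measure recovery.

    ``tract_length`` of None converts the entire unit (the whole-paralog
    regime that only criterion 2 can call).  Returns pooled sensitivity, FDR,
    the median boundary error over recovered events, and the fraction of
    matched events called via each criterion.
    """
    base = sim_config or SimConfig()
    length = base.root_length if tract_length is None else tract_length
    start = 0 if tract_length is None else None
    conv = ScriptedConversion(
        branch=conversion_branch, time=0.5, donor_index=0, recipient_index=1,
        start=start, length=length,
    )
    n_detected = n_detectable = n_obs = n_false = 0
    errors: list[float] = []
    criterion_counts = {1: 0, 2: 0}
    for s in _spawn_seeds(seed, n_reps):
        sim = simulate_cluster(
            replace(base, scripted_conversions=(conv,)), seed=s)
        obs = run_detector(sim, config)
        res = evaluate_detection(obs, sim, match_rule)
        n_detectable += res["n_detectable"]
        n_detected += round(res["sensitivity"] * res["n_detectable"])
        n_obs += res["n_observations"]
        n_false += round(res["fdr"] * res["n_observations"])
        errors.extend(res["boundary_errors"])
        for o in obs:
            criterion_counts[o.criterion] += 1
    return {
        "sensitivity": n_detected / n_detectable if n_detectable else 0.0,
        "fdr": n_false / n_obs if n_obs else 0.0,
        "median_boundary_error": float(np.median(errors)) if errors else float("nan"),
        "n_reps": n_reps,
        "n_observations": n_obs,
        "criterion_counts": criterion_counts,
    }


def threshold_sweep(
    thresholds: Sequence[float] = (0.6, 0.65, 0.7, 0.75, 0.8, 0.85, 0.9, 0.95),
    n_reps: int = 40,
    seed: int = 0,
    tract_lengths: Sequence[int] = (400, 800, 1600, 3000),
    sim_config: Optional[SimConfig] = None,
) -> pd.DataFrame:
    """Sensitivity/FDR as a function of the coverage threshold.

    Implanted tract lengths cycle through short, medium, and whole-unit
    conversions so that criterion routing actually varies with the
    threshold.  Simulations are reused across thresholds; only detection is
    re-run.
    """
    base = sim_config or SimConfig()
    sims = []
    for i, s in enumerate(_spawn_seeds(seed, n_reps)):
        length = tract_lengths[i % len(tract_lengths)]
        whole = length >= base.root_length
        conv = ScriptedConversion(
            branch="S1", time=0.5, donor_index=0, recipient_index=1,
            start=0 if whole else None, length=length,
        )
        sims.append(simulate_cluster(
            replace(base, scripted_conversions=(conv,)), seed=s))

    rows = []
    for thr in thresholds:
        config = DetectionConfig(coverage_threshold=thr)
        n_det = n_detectable = n_obs = n_false = 0
        for sim in sims:
            obs = run_detector(sim, config)
            res = evaluate_detection(obs, sim)
            n_detectable += res["n_detectable"]
            n_det += round(res["sensitivity"] * res["n_detectable"])
            n_obs += res["n_observations"]
            n_false += round(res["fdr"] * res["n_observations"])
        rows.append({
            "coverage_threshold": thr,
            "sensitivity": n_det / n_detectable if n_detectable else 0.0,
            "fdr": n_false / n_obs if n_obs else 0.0,
            "n_observations": n_obs,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# File export
# ---------------------------------------------------------------------------

def config_to_json(config: SimConfig) -> str:
    import dataclasses
    import json

    return json.dumps(dataclasses.asdict(config), indent=2, sort_keys=True)


def config_from_json(text: str) -> SimConfig:
    import json

    raw = json.loads(text)
    raw["scripted_duplications"] = tuple(
        ScriptedDuplication(**d) for d in raw.get("scripted_duplications", ())
    )
    raw["scripted_conversions"] = tuple(
        ScriptedConversion(**d) for d in raw.get("scripted_conversions", ())
    )
    return SimConfig(**raw)


def sim_to_files(sim: SimResult, out_dir) -> None:
    """Write FASTA/MAF/Newick plus the tab-separated truth log."""
    out = Path(out_dir)
    (out / "fasta").mkdir(parents=True, exist_ok=True)
    (out / "maf").mkdir(parents=True, exist_ok=True)
    for species, seq in sim.sequences.items():
        write_fasta(out / "fasta" / f"{species}.fa", [(f"{species}.cluster", seq)])
    src_sizes = {
        (sp, "cluster"): len(seq) for sp, seq in sim.sequences.items()
    }
    write_maf(out / "maf" / "paralogs.maf", sim.paralog_alignments, src_sizes)
    write_maf(out / "maf" / "orthologs.maf", sim.orthology.alignments, src_sizes)
    (out / "tree.nwk").write_text(sim.config.tree_newick + "\n")
    (out / "config.json").write_text(config_to_json(sim.config) + "\n")
    rows = [
        {
            "kind": e.kind,
            "branch": e.branch,
            "time": e.time,
            "donor_unit": e.donor_unit,
            "recipient_unit": e.recipient_unit,
            "root_start": e.root_start,
            "root_end": e.root_end,
        }
        for e in sim.truth
    ]
    pd.DataFrame(rows).to_csv(out / "truth.tsv", sep="\t", index=False)
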