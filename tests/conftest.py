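"""Shared fixtures: tiny hand-built alignments and reusable simulations."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("stable", derandomize=True, deadline=None)
settings.load_profile("stable")

from paraconv.detect import ConversionObservation
from paraconv.io import GenomicInterval, OrthologyMap, PairwiseAlignment
from paraconv.simulate import ScriptedConversion, SimConfig, simulate_cluster
from paraconv.tree import SpeciesTree


def make_alignment(
    text1: str,
    text2: str,
    species1: str = "A",
    species2: str = "A",
    start1: int = 0,
    start2: int = 1000,
    seq_id: str = "cluster",
    strand2: str = "+",
    kind: str | None = None,
) -> PairwiseAlignment:
    """Pairwise alignment from two gapped strings with auto intervals."""
    len1 = len(text1) - text1.count("-")
    len2 = len(text2) - text2.count("-")
    if kind is None:
        kind = "paralog" if species1 == species2 else "ortholog"
    return PairwiseAlignment(
        GenomicInterval(species1, seq_id, start1, start1 + len1),
        text1,
        GenomicInterval(species2, seq_id, start2, start2 + len2, strand2),
        text2,
        kind=kind,
    )


def make_observation(
    primary: str = "A",
    outgroup: str = "B",
    conv1: tuple[int, int] = (100, 200),
    conv2: tuple[int, int] = (1100, 1200),
    p_value: float = 1e-6,
    par1: tuple[int, int] = (0, 1000),
    par2: tuple[int, int] = (1000, 2000),
    criterion: int = 1,
    direction: str = "unknown",
    seq_id: str = "cluster",
) -> ConversionObservation:
    return ConversionObservation(
        primary_species=primary,
        paralog1=GenomicInterval(primary, seq_id, *par1),
        paralog2=GenomicInterval(primary, seq_id, *par2),
        outgroup_species=outgroup,
        conv1=conv1,
        conv2=conv2,
        p_value=p_value,
        criterion=criterion,
        direction=direction,
        m=50,
        n=20,
        k=15,
    )


@pytest.fixture(scope="session")
def four_taxon_tree() -> SpeciesTree:
    return SpeciesTree("(((H:1,C:1):1,G:2):1,O:3);")


@pytest.fixture(scope="session")
def sim_with_conversion():
    """One cluster with an ancestral duplication and a 500-bp conversion on S1."""
    conv = ScriptedConversion(
        branch="S1", time=0.5, donor_index=0, recipient_index=1, length=500
    )
    return simulate_cluster(SimConfig(scripted_conversions=(conv,)), seed=42)


@pytest.fixture(scope="session")
def null_sim():
    """Duplication before speciation, no conversion."""
    return simulate_cluster(SimConfig(), seed=7)
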