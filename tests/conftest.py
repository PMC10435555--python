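"""Shared fixtures: the toy reference panel and synthetic-world builders."""
from __future__ import annotations

import random

import dendropy.simulate.treesim as treesim
import numpy as np
import pytest

from ervi import ltr_scan, synthetic


@pytest.fixture(scope="session")
def panel():
    return synthetic.make_reference_panel(seed=0)


@pytest.fixture(scope="session")
def intact_world(panel):
    """50-kb background with one intact toyRV1 implant."""
    background = synthetic.make_background(50_000, seed=1)
    spec = synthetic.ImplantSpec(element_id="intact", source="toyRV1", position=25_000)
    genome, truth = synthetic.implant_provirus(background, spec, panel, seed=1)
    return background, genome, truth


@pytest.fixture(scope="session")
def decoy_world(panel):
    """One intact element plus the five decoy classes on one contig."""
    background = synthetic.make_background(60_000, seed=2)
    sites = [int((i + 1) * 60_000 / 7) for i in range(6)]
    specs = synthetic.decoy_specs(sites)
    genome, truths = synthetic.build_world(background, specs, panel, seed=2)
    return background, genome, truths


@pytest.fixture(scope="session")
def scanned_intact(intact_world):
    background, genome, truth = intact_world
    cands = ltr_scan.find_identical_ltr_pairs(genome)
    assert len(cands) == 1
    return ltr_scan.detect_tsd(genome, cands[0])


def random_trait_tree(n_tips: int, seed: int):
    """Random birth-death tree with strictly positive branch lengths."""
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips, rng=random.Random(seed)
    )
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None and (nd.edge.length is None or nd.edge.length <= 0):
            nd.edge.length = 1e-3
    return tree
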