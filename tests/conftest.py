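"""Shared fixtures: small synthetic registries, genome pools and trees.

Everything is generated programmatically at fixed seeds; heavyweight
objects are session-scoped so the pipeline pieces are built once.
"""

from __future__ import annotations

import random

import dendropy
import numpy as np
import pandas as pd
import pytest

from flagmet.io import ProteinEntry, ProteinRegistry, ROLE_FLAGELLAR, ROLE_MARKER
from flagmet.simulate import build_gradient, build_reference, generate_pool


@pytest.fixture(scope="session")
def small_registry() -> ProteinRegistry:
    """Compact registry (24 markers, 8 flagellar genes) with sequences."""
    return build_reference(n_marker=24, n_flagellar=8, seed=11,
                           gene_length_range_nt=(450, 900))


@pytest.fixture(scope="session")
def small_pool(small_registry):
    return generate_pool(5, 5, small_registry, seed=12)


@pytest.fixture(scope="session")
def small_gradient_quant(small_registry, small_pool):
    """Quantified 5-point gradient on the small pool: (proportion, result)."""
    from flagmet.quant import quantify_metagenome
    from flagmet.simulate import simulate_reads

    design = build_gradient(small_pool, n_points=5, seed=13)
    genomes = {g.genome_id: g for g in small_pool}
    out = []
    for mix in design.mixtures:
        reads = simulate_reads(mix, genomes)
        res = quantify_metagenome(reads=reads, registry=small_registry)
        out.append((mix.proportion_flagellated, res))
    return out


@pytest.fixture
def lengths_registry() -> ProteinRegistry:
    """Sequence-less registry with hand-set gene lengths for RPK checks.

    Marker genes of 900, 450 and 1800 nt (aa lengths 300, 150, 600) and
    one flagellar gene of 600 nt.
    """
    return ProteinRegistry([
        ProteinEntry("m1_v1", "m1", ROLE_MARKER, 300),
        ProteinEntry("m2_v1", "m2", ROLE_MARKER, 150),
        ProteinEntry("m3_v1", "m3", ROLE_MARKER, 600),
        ProteinEntry("f1_v1", "f1", ROLE_FLAGELLAR, 200),
    ])


def random_birth_death_tree(n_tips: int, seed: int) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n_tips)])
    return dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips,
        taxon_namespace=taxa, rng=random.Random(seed),
    )


def brownian_threshold_traits(tree: dendropy.Tree, k_ones: int, seed: int) -> dict:
    """Independent Brownian-threshold trait generator (recursive walk)."""
    rng = random.Random(seed)
    tip_values: dict[str, float] = {}

    def walk(node, val):
        for child in node.child_nodes():
            bl = child.edge.length if child.edge.length is not None else 1.0
            v = val + rng.gauss(0.0, max(bl, 0.0) ** 0.5)
            if child.is_leaf():
                tip_values[child.taxon.label] = v
            else:
                walk(child, v)

    walk(tree.seed_node, 0.0)
    ranked = sorted(tip_values, key=lambda t: -tip_values[t])
    ones = set(ranked[:k_ones])
    return {t: (1 if t in ones else 0) for t in tip_values}
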