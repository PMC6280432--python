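"""Shared fixtures: hand-built tiny reference sets and the seeded
simulation used by the recovery tests."""

import random

import pytest

from ampliref.refdb import RefSeqEntry, ReferenceSet, TaxonRecord
from ampliref.synthetic import (
    SimConfig,
    simulate_clone_library,
    simulate_reference_set,
)

LINEAGE = ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales",
           "Carnobacteriaceae", "Dolosigranulum")


def random_dna(n, seed=0):
    rng = random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(n))


def mutate(seq, positions):
    """Substitute at the given positions (to the 'next' base, cyclically)."""
    out = list(seq)
    for p in positions:
        out[p] = "ACGT"[("ACGT".index(out[p]) + 1) % 4]
    return "".join(out)


def make_refset(seq_by_hmt, genus="Dolosigranulum"):
    """Build a minimal valid ReferenceSet from {hmt: sequence or [seqs]}."""
    refset = ReferenceSet(version_tag="test")
    for hmt, seqs in seq_by_hmt.items():
        if isinstance(seqs, str):
            seqs = [seqs]
        refs = [
            RefSeqEntry(f"{hmt:03d}T{i:03d}", f"ACC{hmt}{i}", s)
            for i, s in enumerate(seqs)
        ]
        refset.add(
            TaxonRecord(
                hmt=hmt,
                lineage=LINEAGE[:-1] + (genus,),
                species_epithet=f"sp{hmt}",
                refs=refs,
            )
        )
    refset.validate()
    return refset


@pytest.fixture
def small_refset():
    """Three well-separated 400-nt taxa (exhaustive search path)."""
    base = random_dna(400, seed=11)
    return make_refset({
        100: base,
        101: mutate(base, range(0, 400, 10)),   # 10% diverged
        102: mutate(base, range(5, 400, 10)),   # 10% diverged, different sites
    })


# The study conditions used by the recovery tests: 40 taxa at 2.5%
# divergence, two planted region-identical same-genus pairs, one planted
# 99.2%-identity chain of three, and three planted novel lineages at 5%
# divergence with support {50, 12, 9} in a 1,000-read background library
# with 0.2% per-base error.
ACCEPTANCE_SIM = dict(
    seed=1,
    n_taxa=40,
    taxon_divergence=2.5,
    planted_supraspecies=((0, 10), (1, 11)),
    planted_region_identity=((2, 12, 99.2), (2, 22, 99.2)),
    planted_novel=((50, 5.0), (12, 5.0), (9, 5.0)),
    n_reads=1000,
    error_rate=0.002,
)


@pytest.fixture(scope="session")
def sim_refset():
    cfg = SimConfig(**ACCEPTANCE_SIM)
    refset, truth = simulate_reference_set(cfg)
    return cfg, refset, truth


@pytest.fixture(scope="session")
def sim_library(sim_refset):
    cfg, refset, truth = sim_refset
    reads, truth = simulate_clone_library(refset, truth, cfg)
    return cfg, refset, truth, reads


@pytest.fixture(scope="session")
def sim_assignments(sim_library):
    """Default-threshold classification of the simulated library."""
    from ampliref.assign import ClassifyConfig, classify_set

    cfg, refset, truth, reads = sim_library
    assignments, row = classify_set(reads, refset, ClassifyConfig(), database_label="sim")
    return cfg, refset, truth, reads, assignments, row
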