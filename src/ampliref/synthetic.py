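"""Seeded generators of 16S-like data with planted ground truth.

Everything downstream (classification, region resolvability, reference
expansion, habitat scoring) is testable without any download: the
generators emulate

* a reference set of taxa evolved from one backbone by substitutions
  confined to variable blocks, with conserved primer islands (27F, 338R,
  534R sites) copied verbatim into every taxon so region extraction is
  exact by construction;
* clone libraries of full-length reads with a per-base substitution
  error, optionally including reads from planted novel taxa absent from
  the reference set;
* taxon-by-body-site count tables with planted focal-site enrichment
  where the planted factor *is* the expected focal enrichment ratio.

The substitution-only model keeps identity expectations analytic: two
taxa at divergence p differ at a variable site with probability
2p(1-p) + (2/3)p^2.  All randomness flows from one integer seed through
a single numpy Generator; fixed seeds give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .alignment import reverse_complement
from .refdb import RefSeqEntry, ReferenceSet, TaxonRecord
from .regions import PRIMERS

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_reference_set",
    "simulate_clone_library",
    "simulate_count_table",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# One concrete realisation of the degenerate 27F primer (M -> A), used as
# the conserved forward-primer island.
_SITE_27F = "AGAGTTTGATCATGGCTCAG"
_SITE_338R = reverse_complement(PRIMERS["338R"])
_SITE_534R = reverse_complement(PRIMERS["534R"])
_PAD = "GTTTGACCTG"  # conserved 5' pad so the primer site is internal

GENERA = [
    "Staphylococcus", "Corynebacterium", "Streptococcus", "Moraxella",
    "Dolosigranulum", "Neisseria", "Cutibacterium", "Lawsonella",
    "Haemophilus", "Anaerococcus",
]
EPITHETS = [
    "aurantiaca", "brevis", "caprina", "dolosa", "elongata", "flava",
    "gracilis", "hominis", "insolita", "jejuni", "kansasii", "lenta",
    "mirabilis", "nasalis", "otitidis", "parva", "quieta", "rostrata",
    "subtilis", "tenuis", "umbrina", "varia", "wadei", "xylosa",
]


def _default_layout(backbone_length: int):
    """Alternating (conserved island, variable block length) pairs."""
    head = _PAD + _SITE_27F
    fixed = len(head) + len(_SITE_338R) + len(_SITE_534R)
    v1v2, v3 = 270, 150
    tail = backbone_length - fixed - v1v2 - v3
    if tail < 0:
        raise ValueError("backbone_length too short for the default layout")
    return [(head, v1v2), (_SITE_338R, v3), (_SITE_534R, tail)]


@dataclass
class SimConfig:
    """Knobs for all three generators; defaults are the study conditions."""

    seed: int = 0
    # reference set
    n_taxa: int = 40
    backbone_length: int = 1500
    region_layout: Optional[list] = None
    taxon_divergence: float = 2.5  # percent substitutions in variable blocks
    planted_supraspecies: tuple = ()  # tuples of taxon indices (same genus)
    supraspecies_region: str = "V1-V3"
    planted_region_identity: tuple = ()  # (src_idx, dst_idx, percent identity)
    # clone library
    n_reads: int = 1000
    error_rate: float = 0.002  # per-base substitution probability
    planted_novel: tuple = ()  # (support, divergence percent) per novel taxon
    # count table
    n_sites: int = 21
    focal_site: str = "nares"
    n_count_taxa: int = 25
    site_total: int = 20000
    site_enrichments: dict = field(default_factory=dict)  # taxon idx -> factor

    def __post_init__(self):
        if not (0 <= self.error_rate <= 1):
            raise ValueError("error_rate must be a probability")
        if self.taxon_divergence >= 40 or any(
            d >= 40 for _s, d in self.planted_novel
        ):
            raise ValueError("divergences must be < 40%")


@dataclass
class SimTruth:
    """Planted ground truth shared across the generators."""

    backbone: str = ""
    variable_positions: np.ndarray = None
    region_spans: dict = field(default_factory=dict)  # name -> (start, end)
    taxon_names: dict = field(default_factory=dict)  # hmt -> (genus, epithet)
    expected_supraspecies: dict = field(default_factory=dict)  # label -> hmts
    planted_region_diffs: dict = field(default_factory=dict)  # (hmt,hmt) -> n
    read_sources: dict = field(default_factory=dict)  # read id -> hmt | "novelK"
    novel_members: dict = field(default_factory=dict)  # "novelK" -> [read ids]
    novel_seqs: dict = field(default_factory=dict)  # "novelK" -> sequence
    enrichment_factors: dict = field(default_factory=dict)  # taxon id -> factor


def _mutate(seq: np.ndarray, positions: np.ndarray, rng) -> None:
    """Substitute in place at ``positions`` (always to a different base)."""
    if len(positions) == 0:
        return
    cur = seq[positions]
    shift = rng.integers(1, 4, size=len(positions))
    # map A/C/G/T codes through a cyclic shift among the four bases
    idx = np.searchsorted(_BASES, cur)
    seq[positions] = _BASES[(idx + shift) % 4]


def simulate_reference_set(cfg: SimConfig):
    """Generate ``(ReferenceSet, SimTruth)`` with planted region structure."""
    rng = np.random.default_rng(cfg.seed)
    layout = cfg.region_layout or _default_layout(cfg.backbone_length)
    if sum(len(isl) + v for isl, v in layout) != cfg.backbone_length:
        raise ValueError("region_layout does not sum to backbone_length")

    # Assemble backbone and record island/variable structure.
    backbone = np.empty(cfg.backbone_length, dtype=np.uint8)
    variable = np.zeros(cfg.backbone_length, dtype=bool)
    pos = 0
    island_bounds = []
    for island, var_len in layout:
        enc = np.frombuffer(island.upper().encode(), dtype=np.uint8)
        backbone[pos : pos + len(enc)] = enc
        island_bounds.append((pos, pos + len(enc)))
        pos += len(enc)
        backbone[pos : pos + var_len] = _BASES[rng.integers(0, 4, size=var_len)]
        variable[pos : pos + var_len] = True
        pos += var_len
    var_positions = np.flatnonzero(variable)

    # Amplicon spans between island 0 and islands 1/2 (primer sites excluded).
    spans = {
        "V1-V2": (island_bounds[0][1], island_bounds[1][0]),
        "V1-V3": (island_bounds[0][1], island_bounds[2][0]),
    }

    truth = SimTruth(
        backbone=backbone.tobytes().decode(),
        variable_positions=var_positions,
        region_spans=spans,
    )

    p = cfg.taxon_divergence / 100.0
    seqs = []
    for i in range(cfg.n_taxa):
        seq = backbone.copy()
        hit = var_positions[rng.random(len(var_positions)) < p]
        _mutate(seq, hit, rng)
        seqs.append(seq)

    span = spans[cfg.supraspecies_region]
    in_span = var_positions[(var_positions >= span[0]) & (var_positions < span[1])]
    out_span = var_positions[(var_positions < span[0]) | (var_positions >= span[1])]

    # Planted supraspecies: identical across the region, different outside.
    for group in cfg.planted_supraspecies:
        group = sorted(group)
        src = seqs[group[0]]
        for k, j in enumerate(group[1:], start=1):
            seqs[j][span[0] : span[1]] = src[span[0] : span[1]]
            if np.array_equal(seqs[j], src):
                _mutate(seqs[j], out_span[k - 1 : k], rng)

    # Planted pairwise region identities (e.g. a 99.2% chain).  Diff
    # positions are drawn without replacement per source taxon, so two
    # plantings from the same source accumulate (d1 + d2 differences).
    used: dict = {}
    span_len = span[1] - span[0]
    for src_i, dst_j, pct in cfg.planted_region_identity:
        d = int(round(span_len * (100.0 - pct) / 100.0))
        seqs[dst_j][span[0] : span[1]] = seqs[src_i][span[0] : span[1]]
        pool = used.setdefault(src_i, set())
        avail = np.array([q for q in in_span if q not in pool])
        chosen = rng.choice(avail, size=d, replace=False)
        pool.update(int(q) for q in chosen)
        _mutate(seqs[dst_j], np.sort(chosen), rng)
        truth.planted_region_diffs[(100 + src_i, 100 + dst_j)] = d

    refset = ReferenceSet(version_tag=f"sim-seed{cfg.seed}")
    for i, seq in enumerate(seqs):
        hmt = 100 + i
        genus = GENERA[i % len(GENERA)]
        epithet = (
            EPITHETS[i // len(GENERA)]
            if i // len(GENERA) < len(EPITHETS)
            else f"sp{i:03d}"
        )
        truth.taxon_names[hmt] = (genus, epithet)
        refset.add(
            TaxonRecord(
                hmt=hmt,
                lineage=("Bacteria", "Firmicutes", "Bacilli", "Bacillales",
                         f"{genus}aceae", genus),
                species_epithet=epithet,
                refs=[RefSeqEntry(
                    ref_id=f"{hmt:03d}S001",
                    accession=f"SIM{hmt:03d}",
                    sequence=seq.tobytes().decode(),
                )],
            )
        )

    for group in cfg.planted_supraspecies:
        hmts = sorted(100 + i for i in group)
        genus = truth.taxon_names[hmts[0]][0]
        epithets = sorted(truth.taxon_names[h][1] for h in hmts)
        truth.expected_supraspecies[f"{genus}_{'_'.join(epithets)}"] = frozenset(hmts)

    refset.validate()
    return refset, truth


def simulate_clone_library(refset: ReferenceSet, truth: SimTruth, cfg: SimConfig):
    """Generate ``(reads, truth)``: reads are (id, sequence) pairs.

    Background reads are full-length copies of uniformly drawn reference
    sequences with per-base substitution error; planted novel taxa are
    fresh lineages evolved from the backbone at the stated divergence,
    each contributing ``support`` reads.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    hmts = sorted(refset.taxa)
    ref_arrays = {
        h: np.frombuffer(refset.taxa[h].refs[0].sequence.encode(), dtype=np.uint8)
        for h in hmts
    }
    backbone = np.frombuffer(truth.backbone.encode(), dtype=np.uint8)
    var_positions = truth.variable_positions

    reads = []

    def emit(name, source, template):
        read = template.copy()
        errs = np.flatnonzero(rng.random(len(read)) < cfg.error_rate)
        _mutate(read, errs, rng)
        reads.append((name, read.tobytes().decode()))
        truth.read_sources[name] = source

    counts = rng.multinomial(cfg.n_reads, np.full(len(hmts), 1.0 / len(hmts)))
    i = 0
    for h, c in zip(hmts, counts):
        for _ in range(c):
            emit(f"read{i:05d}", h, ref_arrays[h])
            i += 1

    for k, (support, divergence) in enumerate(cfg.planted_novel):
        novel = backbone.copy()
        hit = var_positions[rng.random(len(var_positions)) < divergence / 100.0]
        _mutate(novel, hit, rng)
        name = f"novel{k}"
        truth.novel_seqs[name] = novel.tobytes().decode()
        members = []
        for j in range(support):
            rid = f"nov{k}_{j:03d}"
            emit(rid, name, novel)
            members.append(rid)
        truth.novel_members[name] = members

    return reads, truth


def simulate_count_table(cfg: SimConfig):
    """Generate ``(count table, SimTruth)`` with planted focal enrichment.

    Baseline per-taxon proportions decay gently with taxon index.  For a
    planted taxon with factor f, the focal-site proportion is chosen so
    that the focal enrichment ratio (focal percent over the even-spread
    expectation) equals f in expectation; factor 1 leaves the taxon at
    ratio 1.  Unplanted taxa share the remaining focal mass pro rata and
    sit well below ratio 2.  Counts are multinomial per site.
    """
    import pandas as pd

    rng = np.random.default_rng(cfg.seed + 2)
    n = cfg.n_count_taxa
    taxa = [f"taxon{i:02d}" for i in range(n)]
    sites = [cfg.focal_site] + [f"site{j:02d}" for j in range(2, cfg.n_sites + 1)]
    base = 1.0 / (np.arange(n) + 2.0)
    base /= base.sum()

    for idx, f in cfg.site_enrichments.items():
        if not 0 <= f < cfg.n_sites:
            raise ValueError("enrichment factors must be in [0, n_sites)")

    focal = base.copy()
    planted_mass = 0.0
    base_mass = 0.0
    for idx, f in cfg.site_enrichments.items():
        pi = base[idx]
        focal[idx] = (cfg.n_sites - 1) * pi * f / (cfg.n_sites - f)
        planted_mass += focal[idx]
        base_mass += pi
    if planted_mass >= 1.0:
        raise ValueError("planted focal proportions exceed the whole column")
    unplanted = np.array([i not in cfg.site_enrichments for i in range(n)])
    scale = (1.0 - planted_mass) / base[unplanted].sum()
    focal[unplanted] = base[unplanted] * scale

    table = np.empty((n, cfg.n_sites), dtype=np.int64)
    table[:, 0] = rng.multinomial(cfg.site_total, focal)
    for j in range(1, cfg.n_sites):
        table[:, j] = rng.multinomial(cfg.site_total, base)

    truth = SimTruth(
        enrichment_factors={taxa[i]: f for i, f in cfg.site_enrichments.items()}
    )
    return pd.DataFrame(table, index=taxa, columns=sites), truth
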