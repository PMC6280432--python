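"""Iterative reference-set expansion from clone libraries.

One expansion round mirrors the curation loop used to grow a body-site
16S database from clone data: classify every clone against the current
references, set aside the ambiguous [98, 98.5)% identity band, cluster
the unassigned remainder into M-OTUs at >=98.5% identity over >=99%
coverage, promote every M-OTU with at least ``min_support`` (default 10)
members to a provisionally named candidate taxon, add the candidates'
representative sequences as new references, and re-classify.

Representatives are chosen deterministically as the cluster medoid (the
member with the highest mean identity to the rest); curators can replace
them afterwards.  Taxonomic placement of a candidate uses a
caller-supplied family hint or, failing that, a majority vote over the
genera of its representative's top three sub-threshold reference hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .alignment import DEFAULT_SCORING, Scoring, align
from .assign import (
    BAND_UNASSIGNED,
    Assignment,
    ClassifyConfig,
    classify_set,
    partition_bands,
)
from .refdb import (
    RefSeqEntry,
    ReferenceSet,
    TaxonRecord,
    allocate_hmt,
    format_provisional_name,
)

__all__ = [
    "ClusterConfig",
    "MOTU",
    "CandidateTaxon",
    "ExpansionReport",
    "greedy_cluster",
    "select_representative",
    "propose_new_taxa",
    "expansion_round",
]


@dataclass(frozen=True)
class ClusterConfig:
    """M-OTU clustering thresholds and the minimum-support rule."""

    cluster_id: float = 98.5
    cluster_cov: float = 99.0
    min_support: int = 10

    def __post_init__(self):
        if self.cluster_id <= 0 or self.cluster_cov <= 0 or self.min_support <= 0:
            raise ValueError("all ClusterConfig fields must be positive")


@dataclass
class MOTU:
    members: list  # query ids, in join order (centroid first)
    centroid: str
    size: int


@dataclass
class CandidateTaxon:
    representative: str  # sequence
    representative_id: str
    source_motu: MOTU
    hmt: int
    provisional_name: str
    lineage: tuple
    nearest_ref_identity: float
    n_refs_added: int = 1


@dataclass
class ExpansionReport:
    round: int
    n_queries: int
    band_counts: dict
    motus_total: int
    motus_supported: int
    taxa_added: int
    pct_identified_before: float
    pct_identified_after: float
    candidates: list = field(default_factory=list)
    unsupported_motus: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "round": self.round,
            "n_queries": self.n_queries,
            "band_counts": dict(self.band_counts),
            "motus_total": self.motus_total,
            "motus_supported": self.motus_supported,
            "taxa_added": self.taxa_added,
            "pct_identified_before": self.pct_identified_before,
            "pct_identified_after": self.pct_identified_after,
            "candidates": [
                {
                    "hmt": c.hmt,
                    "provisional_name": c.provisional_name,
                    "motu_size": c.source_motu.size,
                    "nearest_ref_identity": c.nearest_ref_identity,
                }
                for c in self.candidates
            ],
            "unsupported_motu_sizes": [m.size for m in self.unsupported_motus],
        }


def greedy_cluster(
    seqs: Iterable[tuple],
    cfg: ClusterConfig = ClusterConfig(),
    scoring: Scoring = DEFAULT_SCORING,
) -> list:
    """Greedy centroid clustering of ``(id, sequence)`` pairs.

    Sequences are processed by descending length (ties: lexicographic
    id).  Each sequence joins the first existing centroid it matches at
    >= cluster_id identity over >= cluster_cov query coverage
    (inclusive), else it founds a new centroid.  Deterministic.
    """
    ordered = sorted(seqs, key=lambda kv: (-len(kv[1]), kv[0]))
    if not ordered:
        raise ValueError("no sequences to cluster")
    motus = []
    centroid_seqs = []
    for qid, seq in ordered:
        placed = False
        for motu, cseq in zip(motus, centroid_seqs):
            stats = align(seq, cseq, scoring)
            if stats.identity >= cfg.cluster_id and stats.coverage >= cfg.cluster_cov:
                motu.members.append(qid)
                motu.size += 1
                placed = True
                break
        if not placed:
            motus.append(MOTU(members=[qid], centroid=qid, size=1))
            centroid_seqs.append(seq)
    return motus


def select_representative(motu: MOTU, seqs: dict, scoring: Scoring = DEFAULT_SCORING) -> str:
    """Medoid member: maximises mean identity to the other members.

    Ties are broken by longer sequence, then lexicographic id.
    """
    if motu.size == 1:
        return motu.members[0]
    means = []
    for qid in motu.members:
        total = 0.0
        for other in motu.members:
            if other == qid:
                continue
            total += align(seqs[qid], seqs[other], scoring).identity
        means.append((-total / (motu.size - 1), -len(seqs[qid]), qid))
    # max mean identity, then max length, then lexicographically smallest id
    return sorted(means)[0][2]


def _vote_lineage(representative: str, refset: ReferenceSet, scoring: Scoring):
    """Majority genus among the top-3 sub-threshold hits; ties favour the
    lexicographically smallest genus.  Returns (lineage, genus, identity
    of the single nearest reference)."""
    hits = []
    for taxon, ref in refset.iter_refs():
        stats = align(representative, ref.sequence, scoring)
        hits.append((stats.score, stats.identity, ref.ref_id, taxon))
    hits.sort(key=lambda h: (-h[0], -h[1], h[2]))
    top = hits[:3]
    tally = {}
    for _score, _ident, _rid, taxon in top:
        tally.setdefault(taxon.genus, []).append(taxon)
    genus = sorted(tally.items(), key=lambda kv: (-len(kv[1]), kv[0]))[0][0]
    lineage = tally[genus][0].lineage
    return lineage, genus, hits[0][1]


def propose_new_taxa(
    motus: Iterable[MOTU],
    cfg: ClusterConfig,
    refset: ReferenceSet,
    seqs: dict,
    family_hint: Optional[tuple] = None,
    scoring: Scoring = DEFAULT_SCORING,
):
    """Promote supported M-OTUs (size >= min_support) to candidate taxa.

    ``family_hint`` is an optional ``(family, genus_index)`` pair used
    for provisional naming; otherwise the nearest-reference genus vote
    names the candidate ``"<Genus> bacterium HMT-<n>"``.  Returns
    ``(candidates, unsupported_motus)``; the input refset is not
    mutated — allocation is tracked on a shadow copy of the namespace.
    """
    shadow = ReferenceSet(
        taxa=dict(refset.taxa), version_tag=refset.version_tag,
        retired_hmts=set(refset.retired_hmts),
    )
    candidates = []
    unsupported = []
    for motu in sorted(motus, key=lambda m: (-m.size, m.centroid)):
        if motu.size < cfg.min_support:
            unsupported.append(motu)
            continue
        rep_id = select_representative(motu, seqs, scoring)
        rep_seq = seqs[rep_id]
        hmt = allocate_hmt(shadow)
        lineage, genus, nearest_ident = _vote_lineage(rep_seq, refset, scoring)
        if family_hint is not None:
            family, genus_index = family_hint
            name = format_provisional_name(family, genus_index, hmt)
        else:
            name = format_provisional_name(genus, None, hmt)
        cand = CandidateTaxon(
            representative=rep_seq,
            representative_id=rep_id,
            source_motu=motu,
            hmt=hmt,
            provisional_name=name,
            lineage=lineage,
            nearest_ref_identity=nearest_ident,
        )
        candidates.append(cand)
        # reserve the number on the shadow namespace
        shadow.taxa[hmt] = None
    return candidates, unsupported


def expansion_round(
    queries: Iterable[tuple],
    refset: ReferenceSet,
    classify_cfg: ClassifyConfig = ClassifyConfig(),
    cluster_cfg: ClusterConfig = ClusterConfig(),
    family_hint: Optional[tuple] = None,
    round_number: int = 1,
    scoring: Scoring = DEFAULT_SCORING,
):
    """One full expansion round; returns ``(new_refset, ExpansionReport)``.

    The input refset is never mutated: candidates are added to a copy.
    Ambiguous-band clones are set aside — excluded from clustering so no
    taxon is called where none exists.
    """
    queries = list(queries)
    assignments, row_before = classify_set(queries, refset, classify_cfg)
    bands = partition_bands(assignments)
    band_counts = {
        "assigned": len(bands.assigned),
        "ambiguous_band": len(bands.ambiguous_band),
        "unassigned": len(bands.unassigned),
    }
    seqs = dict(queries)
    unassigned = [(qid, seqs[qid]) for qid in sorted(bands.unassigned)]

    new_refset = refset.copy()
    candidates: list = []
    unsupported: list = []
    motus: list = []
    if unassigned:
        motus = greedy_cluster(unassigned, cluster_cfg, scoring)
        candidates, unsupported = propose_new_taxa(
            motus, cluster_cfg, refset, seqs, family_hint, scoring
        )
        for cand in candidates:
            taxon = TaxonRecord(
                hmt=cand.hmt,
                lineage=cand.lineage,
                naming_status="unnamed",
                cultivation_status="uncultivated",
                body_site="unassigned",
                provisional_name=cand.provisional_name,
                refs=[
                    RefSeqEntry(
                        ref_id=f"{cand.hmt:03d}C01",
                        accession=cand.representative_id,
                        sequence=cand.representative,
                    )
                ],
            )
            new_refset.add(taxon)
        new_refset.validate()

    if candidates:
        _, row_after = classify_set(queries, new_refset, classify_cfg)
    else:
        row_after = row_before
    report = ExpansionReport(
        round=round_number,
        n_queries=row_before.n_reads,
        band_counts=band_counts,
        motus_total=len(motus),
        motus_supported=len(candidates),
        taxa_added=len(candidates),
        pct_identified_before=row_before.pct_identified,
        pct_identified_after=row_after.pct_identified,
        candidates=candidates,
        unsupported_motus=unsupported,
    )
    return new_refset, report
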