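"""Amplicon-region extraction, resolvability analysis and training sets.

Short-read 16S studies sequence one hypervariable region, and the choice
of region decides how many species collapse into indistinguishable
groups.  This module extracts primer-delimited regions from full-length
references (IUPAC-aware primer matching), builds a taxon-by-taxon region
identity matrix, collapses taxa into indistinguishable groups at a given
identity threshold (single-linkage connected components), and turns the
result into a naive-Bayes-style training set in which indistinguishable
same-genus taxa are merged under a supraspecies label
(e.g. ``Staphylococcus capitis_caprae``) to preserve subgenus
resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .alignment import align_semiglobal, reverse_complement
from .refdb import RefSeqEntry, ReferenceSet

__all__ = [
    "RegionDef",
    "TaxonRegionSeq",
    "CollapseReport",
    "TrainingSet",
    "PRIMERS",
    "BUILTIN_REGIONS",
    "find_primer",
    "extract_region",
    "region_identity_matrix",
    "collapse",
    "build_training_set",
    "write_training_set",
]

# Canonical primer sequences (5'->3', as synthesised).
PRIMERS = {
    "27F": "AGAGTTTGATCMTGGCTCAG",
    "338R": "TGCTGCCTCCCGTAGGAGT",
    "534R": "ATTACCGCGGCTGCTGG",
}

# IUPAC nucleotide codes as 4-bit masks over (A, C, G, T).
_IUPAC = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 5, "Y": 10, "S": 6, "W": 9, "K": 12, "M": 3,
    "B": 14, "D": 13, "H": 11, "V": 7, "N": 15,
}


@dataclass(frozen=True)
class RegionDef:
    """A primer-delimited amplicon region."""

    name: str
    fwd_primer: str
    rev_primer: str
    max_mismatches: int = 2

    def __post_init__(self):
        if not self.fwd_primer or not self.rev_primer:
            raise ValueError("primers must be non-empty")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


BUILTIN_REGIONS = {
    "V1-V2": RegionDef("V1-V2", PRIMERS["27F"], PRIMERS["338R"]),
    "V1-V3": RegionDef("V1-V3", PRIMERS["27F"], PRIMERS["534R"]),
}


@dataclass
class TaxonRegionSeq:
    hmt: Optional[int]
    region: str
    sequence: str
    extraction_status: str  # ok | fwd_missing | rev_missing


@dataclass
class CollapseReport:
    threshold: float
    groups: list  # list of frozensets of taxon ids, |group| >= 2
    excluded: list = field(default_factory=list)

    @property
    def n_indistinguishable(self) -> int:
        return sum(len(g) for g in self.groups)


@dataclass
class TrainingSet:
    """Region sequences labelled to species or supraspecies level."""

    region: str
    entries: list  # (ref_id, sequence, lineage string incl. terminal label)
    labels: dict  # hmt -> species-level label token
    supraspecies: dict  # label token -> frozenset of hmts
    flagged_cross_genus: list = field(default_factory=list)


def _mismatches(window: str, pattern_masks) -> int:
    mm = 0
    for base, pmask in zip(window, pattern_masks):
        if not (_IUPAC.get(base, 15) & pmask):
            mm += 1
    return mm


def find_primer(seq: str, primer: str, max_mm: int = 2, orientation: str = "fwd") -> Optional[int]:
    """Locate a primer site on a plus-strand sequence.

    Forward primers are matched as given (leftmost window wins); reverse
    primers are matched as their reverse complement (rightmost window
    wins).  IUPAC codes in the primer match any compatible base.  Returns
    the 0-based window start, or None.
    """
    seq = seq.upper()
    pattern = primer.upper() if orientation == "fwd" else reverse_complement(primer)
    k = len(pattern)
    if k > len(seq):
        return None
    masks = [_IUPAC.get(c, 15) for c in pattern]
    positions = range(len(seq) - k + 1)
    if orientation == "rev":
        positions = reversed(positions)
    for pos in positions:
        if _mismatches(seq[pos : pos + k], masks) <= max_mm:
            return pos
    return None


def extract_region(entry: RefSeqEntry, rdef: RegionDef, hmt: Optional[int] = None) -> TaxonRegionSeq:
    """Extract the inter-primer insert (primer sites excluded)."""
    seq = entry.sequence
    fwd = find_primer(seq, rdef.fwd_primer, rdef.max_mismatches, "fwd")
    if fwd is None:
        return TaxonRegionSeq(hmt, rdef.name, "", "fwd_missing")
    start = fwd + len(rdef.fwd_primer)
    rev = find_primer(seq, rdef.rev_primer, rdef.max_mismatches, "rev")
    if rev is None or rev <= start:
        return TaxonRegionSeq(hmt, rdef.name, "", "rev_missing")
    return TaxonRegionSeq(hmt, rdef.name, seq[start:rev], "ok")


def _taxon_regions(refset: ReferenceSet, rdef: RegionDef):
    """Per-taxon extracted region sequences; only status=ok refs kept."""
    regions = {}
    for taxon in refset.taxa.values():
        seqs = []
        for ref in taxon.refs:
            t = extract_region(ref, rdef, hmt=taxon.hmt)
            if t.extraction_status == "ok":
                seqs.append((ref.ref_id, t.sequence))
        regions[taxon.hmt] = seqs
    return regions


def region_identity_matrix(refset: ReferenceSet, rdef: RegionDef):
    """Symmetric taxon-by-taxon percent-identity matrix over a region.

    Identity comes from global end-gap-free alignment of the extracted
    regions.  A taxon pair with multiple references contributes its
    maximum inter-taxon identity (a pair is indistinguishable if *any*
    reference pair is).  Returns ``(taxon_ids, matrix, excluded)`` where
    ``excluded`` lists taxa with no extractable region.
    """
    regions = _taxon_regions(refset, rdef)
    taxon_ids = sorted(h for h, seqs in regions.items() if seqs)
    excluded = sorted(h for h, seqs in regions.items() if not seqs)
    if len(taxon_ids) < 2:
        raise ValueError("need at least 2 taxa with an extractable region")
    n = len(taxon_ids)
    mat = np.full((n, n), 100.0)
    cache = {}
    for a in range(n):
        for b in range(a + 1, n):
            best = 0.0
            for _ra, sa in regions[taxon_ids[a]]:
                for _rb, sb in regions[taxon_ids[b]]:
                    key = (sa, sb)
                    if key not in cache:
                        cache[key] = align_semiglobal(sa, sb).identity
                    best = max(best, cache[key])
            mat[a, b] = mat[b, a] = best
    return taxon_ids, mat, excluded


def collapse(matrix: np.ndarray, taxon_ids, threshold: float, linkage: str = "single") -> CollapseReport:
    """Group taxa indistinguishable at ``threshold`` percent identity.

    Single linkage: groups are connected components of the graph with an
    edge wherever pairwise identity >= threshold.  Singletons are not
    reported; ``n_indistinguishable`` counts members of groups of >= 2.
    """
    if linkage != "single":
        raise ValueError("only single linkage is implemented")
    adj = np.asarray(matrix) >= threshold
    np.fill_diagonal(adj, False)
    n_comp, comp = connected_components(csr_matrix(adj), directed=False)
    buckets = {}
    for tid, c in zip(taxon_ids, comp):
        buckets.setdefault(c, set()).add(tid)
    groups = sorted(
        (frozenset(g) for g in buckets.values() if len(g) >= 2),
        key=lambda g: sorted(g),
    )
    return CollapseReport(threshold=threshold, groups=groups)


def build_training_set(
    refset: ReferenceSet,
    rdef: RegionDef,
    group_threshold: float = 100.0,
) -> TrainingSet:
    """Build a region training set with supraspecies group labels.

    Within-genus indistinguishable groups are merged under
    ``Genus epithet1_epithet2[...]`` with epithets sorted alphabetically.
    Cross-genus groups, and groups containing unnamed taxa (which have no
    epithet), are flagged and left ungrouped.  All other taxa keep their
    species labels.
    """
    taxon_ids, mat, _excluded = region_identity_matrix(refset, rdef)
    report = collapse(mat, taxon_ids, group_threshold, "single")
    labels = {h: refset.taxa[h].species_label for h in taxon_ids}
    supraspecies = {}
    flagged = []
    for group in report.groups:
        members = [refset.taxa[h] for h in sorted(group)]
        genera = {t.genus for t in members}
        if len(genera) != 1 or any(t.naming_status == "unnamed" for t in members):
            flagged.append(frozenset(group))
            continue
        genus = members[0].genus
        epithets = sorted(t.species_epithet for t in members)
        token = f"{genus}_{'_'.join(epithets)}"
        supraspecies[token] = frozenset(group)
        for t in members:
            labels[t.hmt] = token
    entries = []
    regions = _taxon_regions(refset, rdef)
    for hmt in taxon_ids:
        taxon = refset.taxa[hmt]
        lineage = ";".join(taxon.lineage) + ";" + labels[hmt]
        for ref_id, seq in regions[hmt]:
            entries.append((ref_id, seq, lineage))
    return TrainingSet(rdef.name, entries, labels, supraspecies, flagged)


def write_training_set(ts: TrainingSet, fasta_path, tax_path):
    """Emit training FASTA + taxonomy files for naive-Bayes classifiers."""
    with open(fasta_path, "w") as fh:
        for ref_id, seq, _lineage in ts.entries:
            fh.write(f">{ref_id}\n{seq}\n")
    with open(tax_path, "w") as fh:
        for ref_id, _seq, lineage in ts.entries:
            fh.write(f"{ref_id}\t{lineage};\n")
    return Path(fasta_path), Path(tax_path)
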