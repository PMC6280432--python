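"""Data model and I/O for HMT-organised 16S rRNA reference databases.

A reference set groups curated, near-full-length 16S rRNA reference
sequences under stable human microbial taxon (HMT) numbers.  Each taxon
carries a full lineage (domain through genus), a naming / cultivation
status and a primary body site, and is represented by one to six
reference sequences whose identifiers start with the zero-padded
three-digit HMT number.  HMT numbers are never reused: numbers of
deleted taxa are retired and excluded from allocation forever.

On disk a database is a FASTA file (headers ``ref_id|accession|display
name``) plus a TSV taxonomy sidecar and an optional JSON manifest
recording the version tag and the retired-number set.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "RefSeqEntry",
    "TaxonRecord",
    "ReferenceSet",
    "read_reference_fasta",
    "write_reference_set",
    "write_taxonomy_table",
    "allocate_hmt",
    "format_provisional_name",
    "AmbiguousSequenceError",
]

HMT_MIN = 100
HMT_MAX = 999
MAX_REFS_PER_TAXON = 6

_VALID_SEQ = re.compile(r"^[ACGT]+$")
_NON_ACGT = re.compile(r"[^ACGT]")

SIDECAR_COLUMNS = [
    "ref_id",
    "hmt",
    "accession",
    "lineage",
    "species_epithet",
    "naming_status",
    "cultivation_status",
    "body_site",
    "provisional_name",
]


class AmbiguousSequenceError(ValueError):
    """Raised in strict mode when sequences contain non-ACGT characters."""

    def __init__(self, ref_ids):
        self.ref_ids = list(ref_ids)
        super().__init__(
            "sequences contain ambiguous (non-ACGT) characters: "
            + ", ".join(self.ref_ids)
        )


@dataclass
class RefSeqEntry:
    """One curated, near-full-length reference sequence."""

    ref_id: str
    accession: str
    sequence: str
    reference_grade: bool = True  # False once ambiguities were masked to N

    def __post_init__(self):
        self.sequence = self.sequence.upper()

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class TaxonRecord:
    """A species-level taxon with its HMT number and reference sequences."""

    hmt: int
    lineage: tuple  # ordered ranks, domain -> genus
    species_epithet: str = ""
    naming_status: str = "named"  # named | unnamed
    cultivation_status: str = "cultivated"  # cultivated | uncultivated
    body_site: str = "unassigned"  # oral | nasal | skin | vaginal | unassigned
    provisional_name: str = ""
    refs: list = field(default_factory=list)

    @property
    def genus(self) -> str:
        return self.lineage[-1] if self.lineage else ""

    @property
    def family(self) -> str:
        return self.lineage[-2] if len(self.lineage) >= 2 else ""

    @property
    def display_name(self) -> str:
        if self.naming_status == "unnamed":
            return self.provisional_name
        return f"{self.genus} {self.species_epithet}".strip()

    @property
    def species_label(self) -> str:
        """Species-level taxonomy token (underscore-joined, file-safe)."""
        if self.naming_status == "unnamed":
            return self.provisional_name.replace(" ", "_")
        return f"{self.genus}_{self.species_epithet}"

    def validate(self, min_ref_length: int = 0):
        if not (HMT_MIN <= self.hmt <= HMT_MAX):
            raise ValueError(f"HMT-{self.hmt} outside the {HMT_MIN}-{HMT_MAX} namespace")
        if not 1 <= len(self.refs) <= MAX_REFS_PER_TAXON:
            raise ValueError(
                f"HMT-{self.hmt} has {len(self.refs)} refs; expected 1-{MAX_REFS_PER_TAXON}"
            )
        if self.naming_status == "unnamed" and not self.provisional_name:
            raise ValueError(f"unnamed HMT-{self.hmt} lacks a provisional name")
        prefix = f"{self.hmt:03d}"
        for ref in self.refs:
            if not ref.ref_id.startswith(prefix):
                raise ValueError(
                    f"ref_id {ref.ref_id!r} does not start with HMT prefix {prefix!r}"
                )
            if ref.reference_grade and not _VALID_SEQ.match(ref.sequence):
                raise ValueError(
                    f"reference-grade sequence {ref.ref_id!r} contains non-ACGT characters"
                )
            if ref.length < min_ref_length:
                raise ValueError(
                    f"{ref.ref_id!r} is {ref.length} nt, below the {min_ref_length} nt floor"
                )


@dataclass
class ReferenceSet:
    """A versioned collection of taxa plus the retired-HMT set."""

    taxa: dict = field(default_factory=dict)  # hmt -> TaxonRecord
    version_tag: str = ""
    retired_hmts: set = field(default_factory=set)

    def add(self, taxon: TaxonRecord):
        if taxon.hmt in self.taxa:
            raise ValueError(f"HMT-{taxon.hmt} already present")
        if taxon.hmt in self.retired_hmts:
            raise ValueError(f"HMT-{taxon.hmt} is retired and may not be reused")
        self.taxa[taxon.hmt] = taxon

    def remove(self, hmt: int):
        """Delete a taxon; its HMT number is retired permanently."""
        del self.taxa[hmt]
        self.retired_hmts.add(hmt)

    def iter_refs(self) -> Iterable[tuple]:
        for taxon in self.taxa.values():
            for ref in taxon.refs:
                yield taxon, ref

    @property
    def n_refs(self) -> int:
        return sum(len(t.refs) for t in self.taxa.values())

    def validate(self, min_ref_length: int = 0):
        seen = set()
        for taxon in self.taxa.values():
            taxon.validate(min_ref_length=min_ref_length)
            for ref in taxon.refs:
                if ref.ref_id in seen:
                    raise ValueError(f"duplicate ref_id {ref.ref_id!r}")
                seen.add(ref.ref_id)
        if self.taxa.keys() & self.retired_hmts:
            raise ValueError("live taxa found among retired HMT numbers")

    def copy(self) -> "ReferenceSet":
        import copy as _copy

        return _copy.deepcopy(self)


def allocate_hmt(refset: ReferenceSet) -> int:
    """Smallest unused HMT number, skipping live and retired numbers.

    Does not mutate ``refset``; callers reserve the number by adding a
    taxon with it.
    """
    used = set(refset.taxa) | set(refset.retired_hmts)
    for candidate in range(HMT_MIN, HMT_MAX + 1):
        if candidate not in used:
            return candidate
    raise RuntimeError("HMT namespace exhausted")


def format_provisional_name(family: Optional[str], genus_index: Optional[int], hmt: int) -> str:
    """Systematic display name for an unnamed taxon.

    Unnamed genus within a known family: ``"Family [G-n] bacterium
    HMT-xxx"``.  Named (or display-string) genus with unnamed species:
    pass the genus display string as ``family`` and ``genus_index=None``,
    yielding ``"Genus bacterium HMT-xxx"``.
    """
    if genus_index is not None and not family:
        raise ValueError("genus_index given without a family name")
    if not family:
        raise ValueError("a family or genus display string is required")
    if genus_index is not None:
        return f"{family} [G-{genus_index}] bacterium HMT-{hmt}"
    return f"{family} bacterium HMT-{hmt}"


def _mask_or_reject(entries: list, mode: str):
    offenders = [e.ref_id for e in entries if _NON_ACGT.search(e.sequence)]
    if not offenders:
        return
    if mode == "strict":
        raise AmbiguousSequenceError(offenders)
    if mode == "mask":
        for e in entries:
            if _NON_ACGT.search(e.sequence):
                e.sequence = _NON_ACGT.sub("N", e.sequence)
                e.reference_grade = False
        return
    raise ValueError(f"unknown ambiguity mode {mode!r}")


def read_reference_fasta(
    path,
    taxonomy_path,
    ambiguity: str = "strict",
    min_ref_length: int = 0,
) -> ReferenceSet:
    """Load a reference database from FASTA + TSV taxonomy sidecar.

    ``ambiguity`` is ``"strict"`` (non-ACGT sequences are a hard error
    listing the offending ref_ids) or ``"mask"`` (non-ACGT characters
    become N and the record is demoted from reference grade).
    """
    import pandas as pd

    path = Path(path)
    taxonomy_path = Path(taxonomy_path)
    rows = pd.read_csv(taxonomy_path, sep="\t", dtype=str).fillna("")
    missing_cols = set(SIDECAR_COLUMNS) - set(rows.columns)
    if missing_cols:
        raise ValueError(f"taxonomy sidecar lacks columns: {sorted(missing_cols)}")
    meta = {}
    for row in rows.to_dict("records"):
        meta[row["ref_id"]] = row

    entries = []
    seen_ids = set()
    for record in SeqIO.parse(str(path), "fasta"):
        fields = record.description.split("|")
        ref_id = fields[0].strip()
        accession = fields[1].strip() if len(fields) > 1 else ""
        if ref_id in seen_ids:
            raise ValueError(f"duplicate ref_id {ref_id!r} in {path}")
        seen_ids.add(ref_id)
        entries.append(RefSeqEntry(ref_id=ref_id, accession=accession, sequence=str(record.seq)))

    orphans = [e.ref_id for e in entries if e.ref_id not in meta]
    if orphans:
        raise ValueError(f"records without a taxonomy row: {', '.join(orphans)}")
    _mask_or_reject(entries, ambiguity)

    refset = ReferenceSet()
    for entry in entries:
        row = meta[entry.ref_id]
        hmt = int(row["hmt"])
        if not entry.accession:
            entry.accession = row["accession"]
        if hmt not in refset.taxa:
            refset.taxa[hmt] = TaxonRecord(
                hmt=hmt,
                lineage=tuple(row["lineage"].split(";")),
                species_epithet=row["species_epithet"],
                naming_status=row["naming_status"] or "named",
                cultivation_status=row["cultivation_status"] or "cultivated",
                body_site=row["body_site"] or "unassigned",
                provisional_name=row["provisional_name"],
            )
        refset.taxa[hmt].refs.append(entry)

    manifest = path.with_suffix(".manifest.json")
    if manifest.exists():
        with open(manifest) as fh:
            data = json.load(fh)
        refset.version_tag = data.get("version_tag", "")
        refset.retired_hmts = set(data.get("retired_hmts", []))

    refset.validate(min_ref_length=min_ref_length)
    return refset


def write_reference_set(refset: ReferenceSet, path, taxonomy_path, manifest_path=None):
    """Write FASTA + taxonomy sidecar (+ JSON manifest) for a reference set."""
    import pandas as pd

    path = Path(path)
    records = []
    rows = []
    for taxon in sorted(refset.taxa.values(), key=lambda t: t.hmt):
        for ref in taxon.refs:
            records.append(
                SeqRecord(
                    Seq(ref.sequence),
                    id=f"{ref.ref_id}|{ref.accession}|{taxon.display_name}",
                    description="",
                )
            )
            rows.append(
                {
                    "ref_id": ref.ref_id,
                    "hmt": taxon.hmt,
                    "accession": ref.accession,
                    "lineage": ";".join(taxon.lineage),
                    "species_epithet": taxon.species_epithet,
                    "naming_status": taxon.naming_status,
                    "cultivation_status": taxon.cultivation_status,
                    "body_site": taxon.body_site,
                    "provisional_name": taxon.provisional_name,
                }
            )
    SeqIO.write(records, str(path), "fasta")
    pd.DataFrame(rows, columns=SIDECAR_COLUMNS).to_csv(taxonomy_path, sep="\t", index=False)
    if manifest_path is None:
        manifest_path = path.with_suffix(".manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(
            {
                "version_tag": refset.version_tag,
                "retired_hmts": sorted(refset.retired_hmts),
                "n_taxa": len(refset.taxa),
                "n_refs": refset.n_refs,
            },
            fh,
            indent=2,
        )
        fh.write("\n")


def write_taxonomy_table(refset: ReferenceSet, path, dialect: str = "mothur"):
    """Write a two-column taxonomy table (ref_id, semicolon lineage).

    Lineages end at the species (or provisional species-level) token.
    The ``mothur`` dialect ends every lineage with ``;`` and contains no
    spaces inside rank names; ``plain`` keeps names verbatim with no
    trailing separator.
    """
    if dialect not in ("mothur", "plain"):
        raise ValueError(f"unknown dialect {dialect!r}")
    lines = []
    for taxon in sorted(refset.taxa.values(), key=lambda t: t.hmt):
        ranks = list(taxon.lineage) + [taxon.species_label]
        for rank in ranks:
            if ";" in rank or "\t" in rank:
                raise ValueError(
                    f"rank {rank!r} of HMT-{taxon.hmt} contains a reserved delimiter"
                )
        if dialect == "mothur":
            ranks = [r.replace(" ", "_") for r in ranks]
            lineage = ";".join(ranks) + ";"
        else:
            lineage = ";".join(ranks)
        for ref in taxon.refs:
            lines.append(f"{ref.ref_id}\t{lineage}")
    Path(path).write_text("".join(line + "\n" for line in lines))
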