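"""Core sequence data model: records, FASTA I/O, deduplication, translation.

Flagellin analyses operate on two parallel collections — protein sequences
(the unit of curation, clustering and HVR typing) and their coding DNA
(the unit of region partitioning and selection analysis).  Both are carried
by :class:`SequenceRecord`.  The distinction between *observations* (every
database record) and *unique sequences* (distinct residue strings) is
central to the diversity statistic and is held by :class:`UniqueSequenceSet`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

from Bio.Data.CodonTable import standard_dna_table

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
DNA_ALPHABET = frozenset("ACGTN")

_RANKS = ("superkingdom", "phylum", "class_", "order", "family", "genus", "species")

UNKNOWN = "Unknown"


class SequenceError(ValueError):
    """Malformed sequence input (bad residue, bad FASTA, bad codon)."""


@dataclass(frozen=True)
class TaxonomyLabel:
    """Seven-rank lineage; any rank may be the sentinel ``"Unknown"``.

    The curated corpus keeps a manually filtered "Unknown" bin for records
    with implausible annotations (eukaryotic or non-motile hosts), so the
    sentinel is a first-class value, not missing data.
    """

    superkingdom: str = UNKNOWN
    phylum: str = UNKNOWN
    class_: str = UNKNOWN
    order: str = UNKNOWN
    family: str = UNKNOWN
    genus: str = UNKNOWN
    species: str = UNKNOWN

    def __post_init__(self) -> None:
        if self.superkingdom not in ("Bacteria", "Archaea", UNKNOWN):
            raise ValueError(
                f"superkingdom must be Bacteria, Archaea or {UNKNOWN!r}; "
                f"got {self.superkingdom!r}"
            )


@dataclass
class SequenceRecord:
    """One protein or coding-DNA sequence with provenance.

    Parameters
    ----------
    id :
        Unique identifier within a collection.
    residues :
        Uppercase residue string; alphabet checked against ``kind``.
    kind :
        ``"protein"`` or ``"dna"``.
    description :
        Free text (FASTA header after the first whitespace).
    taxonomy :
        Optional :class:`TaxonomyLabel`; all-"Unknown" when absent.
    accessions :
        Source database accessions, stored verbatim.
    """

    id: str
    residues: str
    kind: str = "protein"
    description: str = ""
    taxonomy: TaxonomyLabel | None = None
    accessions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("protein", "dna"):
            raise ValueError(f"kind must be 'protein' or 'dna', got {self.kind!r}")
        if not self.residues:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        self.residues = self.residues.upper()
        alphabet = PROTEIN_ALPHABET if self.kind == "protein" else DNA_ALPHABET
        bad = set(self.residues) - alphabet
        if bad:
            raise SequenceError(
                f"record {self.id!r}: illegal {self.kind} residue(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class UniqueSequenceSet:
    """Exact-string deduplication of observations into unique sequences.

    ``members`` maps each distinct residue string to the sorted ids of the
    records carrying it; the lexicographically smallest id is the
    representative of its duplicate class.
    """

    members: dict[str, list[str]]
    kind: str = "protein"

    @property
    def n_unique(self) -> int:
        return len(self.members)

    @property
    def n_total(self) -> int:
        return sum(len(ids) for ids in self.members.values())

    def representative(self, residues: str) -> str:
        return self.members[residues][0]

    def representatives(self) -> dict[str, str]:
        """Mapping residue string -> representative id."""
        return {seq: ids[0] for seq, ids in self.members.items()}


def read_fasta(path, kind: str = "protein") -> list[SequenceRecord]:
    """Parse a FASTA file into records, preserving order.

    Residues are uppercased; the description is the header text after the
    first whitespace.  Malformed headers or illegal residues raise
    :class:`SequenceError` naming the offending line.
    """
    records: list[SequenceRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        name, _, desc = header.partition(" ")
        if not name:
            raise SequenceError(f"{path}: empty FASTA id at line {header_line}")
        try:
            records.append(
                SequenceRecord(id=name, residues="".join(chunks), kind=kind,
                               description=desc.strip())
            )
        except SequenceError as exc:
            raise SequenceError(f"{path}: near line {header_line}: {exc}") from exc

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise SequenceError(
                        f"{path}: line {lineno}: sequence data before first header"
                    )
                chunks.append(line)
    flush()
    return records


def write_fasta(records: list[SequenceRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            head = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{head}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def deduplicate(records: list[SequenceRecord]) -> UniqueSequenceSet:
    """Collapse observations to unique sequences by exact string equality.

    Full-length protein strings are compared untrimmed, matching the
    unique-vs-total counting used by the diversity statistic.
    """
    if not records:
        return UniqueSequenceSet(members={})
    kinds = {rec.kind for rec in records}
    if len(kinds) > 1:
        raise ValueError(f"mixed record kinds {sorted(kinds)} cannot be deduplicated")
    members: dict[str, list[str]] = {}
    for rec in records:
        members.setdefault(rec.residues, []).append(rec.id)
    for ids in members.values():
        ids.sort()
    return UniqueSequenceSet(members=members, kind=kinds.pop())


def translate(dna: SequenceRecord) -> SequenceRecord:
    """Standard-genetic-code translation of a CDS record.

    A trailing stop codon is dropped; an internal stop is an error reporting
    the 0-based codon index; any codon containing N translates to X.
    """
    if dna.kind != "dna":
        raise ValueError(f"record {dna.id!r} is not DNA")
    seq = dna.residues
    if len(seq) % 3 != 0:
        raise SequenceError(
            f"record {dna.id!r}: length {len(seq)} not divisible by 3"
        )
    table = standard_dna_table.forward_table
    stops = set(standard_dna_table.stop_codons)
    n_codons = len(seq) // 3
    out: list[str] = []
    for i in range(n_codons):
        codon = seq[3 * i:3 * i + 3]
        if "N" in codon:
            out.append("X")
        elif codon in stops:
            if i == n_codons - 1:
                break  # trailing stop dropped
            raise SequenceError(
                f"record {dna.id!r}: internal stop codon at codon {i}"
            )
        else:
            out.append(table[codon])
    if not out:
        raise SequenceError(f"record {dna.id!r}: translates to empty protein")
    return SequenceRecord(
        id=dna.id, residues="".join(out), kind="protein",
        description=dna.description, taxonomy=dna.taxonomy,
        accessions=list(dna.accessions),
    )


def read_taxonomy_table(path) -> dict[str, TaxonomyLabel]:
    """Read a taxonomy TSV keyed by record id.

    Columns: id, superkingdom, phylum, class, order, family, genus, species.
    Missing cells become "Unknown".
    """
    out: dict[str, TaxonomyLabel] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            rid = row.get("id", "").strip()
            if not rid:
                continue
            kwargs = {}
            for rank in _RANKS:
                col = rank.rstrip("_")
                val = (row.get(col) or UNKNOWN).strip() or UNKNOWN
                kwargs[rank] = val
            out[rid] = TaxonomyLabel(**kwargs)
    return out


def attach_taxonomy(records: list[SequenceRecord],
                    table: dict[str, TaxonomyLabel]) -> list[SequenceRecord]:
    """Return records with taxonomy joined from the side table.

    Records absent from the table get an all-"Unknown" label.
    """
    unknown = TaxonomyLabel()
    return [replace(rec, taxonomy=table.get(rec.id, unknown)) for rec in records]


def write_taxonomy_table(records: list[SequenceRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["id"] + [r.rstrip("_") for r in _RANKS])
        for rec in records:
            tax = rec.taxonomy or TaxonomyLabel()
            writer.writerow([rec.id] + [getattr(tax, r) for r in _RANKS])
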