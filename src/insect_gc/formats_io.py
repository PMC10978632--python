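"""Readers and writers for the external formats the pipeline touches.

Everything is normalised at this boundary to one coordinate convention:
0-based, half-open intervals, ascending by start.  GFF3 (1-based inclusive)
is converted on read and on write.  Sequences are uppercased on read; IUPAC
ambiguity codes are retained and left to downstream GC counters to exclude.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GenomeSequence",
    "GeneModel",
    "OrthogroupTable",
    "TRNACountTable",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_newick",
    "read_orthogroups",
    "read_trnascan",
    "SENSE_CODONS",
    "STOP_CODONS",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
#: the 61 sense codons of the standard nuclear code
SENSE_CODONS = tuple(
    sorted(
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in STOP_CODONS
    )
)

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class FormatError(ValueError):
    """Raised for malformed or internally inconsistent input files."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """One assembly sequence (chromosome or scaffold)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence id must be nonempty")
        if not self.residues:
            raise FormatError(f"sequence {self.id!r} is empty")

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneModel:
    """A gene's chromosome, strand and ordered CDS segments.

    ``cds_segments`` are 0-based half-open ``(start, end)`` intervals,
    non-overlapping and ascending by start, regardless of strand.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    cds_segments: tuple[tuple[int, int], ...]
    is_primary: bool = True

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise FormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        prev_end = -1
        for start, end in self.cds_segments:
            if start < 0 or end <= start:
                raise FormatError(
                    f"gene {self.gene_id}: bad CDS segment ({start}, {end})"
                )
            if start < prev_end:
                raise FormatError(
                    f"gene {self.gene_id}: CDS segments overlap or are unsorted"
                )
            prev_end = end

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic span of the CDS: (min start, max end)."""
        return self.cds_segments[0][0], self.cds_segments[-1][1]


@dataclass(frozen=True)
class OrthogroupTable:
    """Single-copy orthogroup membership: og_id -> {species: gene_id}."""

    groups: Mapping[str, Mapping[str, str]]

    def __post_init__(self) -> None:
        for og_id, members in self.groups.items():
            if len(set(members)) != len(members):
                raise FormatError(f"orthogroup {og_id}: duplicated species")

    def species(self) -> set[str]:
        out: set[str] = set()
        for members in self.groups.values():
            out.update(members)
        return out


@dataclass(frozen=True)
class TRNACountTable:
    """tRNA gene counts keyed by *decoded codon* (anticodon reverse-complemented)."""

    species: str
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for codon, n in self.counts.items():
            if codon not in SENSE_CODONS:
                raise FormatError(f"tRNA table {self.species}: non-sense codon {codon}")
            if n < 0:
                raise FormatError(f"tRNA table {self.species}: negative count for {codon}")


# ---------------------------------------------------------------------------
# FASTA


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a (possibly gzipped) FASTA file into GenomeSequence records.

    Residues are uppercased; record order is preserved; duplicate ids and
    empty records are errors.
    """
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
            seen.add(rec.id)
            records.append(GenomeSequence(rec.id, str(rec.seq).upper()))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[GenomeSequence], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{rec.id}\n")
            for i in range(0, rec.length, width):
                out.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path: str | Path, primary_only: bool = True) -> list[GeneModel]:
    """Read gene models from an Ensembl-dialect GFF3 (gene -> mRNA -> CDS).

    Coordinates are converted from GFF3 1-based inclusive to 0-based
    half-open.  With ``primary_only`` the transcript with the greatest summed
    CDS length is kept per gene (ties broken by lexicographically smallest
    transcript id), mirroring the longest-isoform convention used when
    building single-copy orthogroup sets.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    # index CDS segments per transcript
    cds_by_tx: dict[str, list[tuple[int, int]]] = {}
    strand_by_tx: dict[str, str] = {}
    chrom_by_tx: dict[str, str] = {}
    tx_ids = {f.id for f in db.features_of_type(("mRNA", "transcript"))}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent", [])
        if not parents:
            raise FormatError(f"CDS at {cds.seqid}:{cds.start} has no Parent")
        if cds.end < cds.start:
            raise FormatError(f"CDS at {cds.seqid}:{cds.start}: end < start")
        for parent in parents:
            if parent not in tx_ids:
                raise FormatError(
                    f"CDS at {cds.seqid}:{cds.start}: parent {parent!r} is not a transcript"
                )
            cds_by_tx.setdefault(parent, []).append((cds.start - 1, cds.end))
            strand_by_tx[parent] = cds.strand
            chrom_by_tx[parent] = cds.seqid

    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        transcripts = [
            t for t in db.children(gene, featuretype=("mRNA", "transcript"))
            if t.id in cds_by_tx
        ]
        if not transcripts:
            continue

        def total_cds(t) -> int:
            return sum(e - s for s, e in cds_by_tx[t.id])

        if primary_only:
            transcripts = [min(transcripts, key=lambda t: (-total_cds(t), t.id))]
        for tx in sorted(transcripts, key=lambda t: t.id):
            segments = tuple(sorted(cds_by_tx[tx.id]))
            models.append(
                GeneModel(
                    gene_id=gene.id,
                    transcript_id=tx.id,
                    chrom=chrom_by_tx[tx.id],
                    strand=strand_by_tx[tx.id],
                    cds_segments=segments,
                    is_primary=True,
                )
            )
    return models


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as Ensembl-dialect GFF3 (inverse of :func:`read_gff3`)."""
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for m in models:
            start0, end0 = m.span
            loc = f"{m.chrom}\tinsect_gc\t"
            tail = f"\t.\t{m.strand}\t"
            out.write(
                f"{loc}gene\t{start0 + 1}\t{end0}{tail}.\tID={m.gene_id}\n"
            )
            out.write(
                f"{loc}mRNA\t{start0 + 1}\t{end0}{tail}.\t"
                f"ID={m.transcript_id};Parent={m.gene_id}\n"
            )
            for s, e in m.cds_segments:
                out.write(
                    f"{loc}CDS\t{s + 1}\t{e}{tail}0\tParent={m.transcript_id}\n"
                )


# ---------------------------------------------------------------------------
# Newick


def read_newick(text_or_path: str | Path) -> "PhyloTree":
    """Parse a rooted Newick tree with branch lengths into a PhyloTree.

    Accepts either a Newick string or a path to a file containing one.
    """
    from .phylo_stats import PhyloTree

    text = str(text_or_path)
    if not text.lstrip().startswith("("):
        text = Path(text_or_path).read_text()
    return PhyloTree.from_newick(text)


# ---------------------------------------------------------------------------
# Orthogroups


def read_orthogroups(path: str | Path) -> OrthogroupTable:
    """Read an OrthoFinder-style single-copy orthogroup TSV.

    First column is the orthogroup id, remaining columns are species (header
    row names them); each cell holds that species' single gene id or "." for
    missing.
    """
    groups: dict[str, dict[str, str]] = {}
    with _open_text(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise FormatError(f"orthogroup table {path}: need >= 2 columns")
        species = header[1:]
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(header):
                raise FormatError(f"{path}:{lineno}: expected {len(header)} columns")
            og_id = cells[0]
            members = {
                sp: gene for sp, gene in zip(species, cells[1:]) if gene and gene != "."
            }
            if og_id in groups:
                raise FormatError(f"{path}:{lineno}: duplicate orthogroup {og_id}")
            groups[og_id] = members
    return OrthogroupTable(groups)


def write_orthogroups(table: OrthogroupTable, path: str | Path) -> None:
    species = sorted(table.species())
    with open(path, "w") as out:
        out.write("orthogroup\t" + "\t".join(species) + "\n")
        for og_id, members in table.groups.items():
            row = [members.get(sp, ".") for sp in species]
            out.write(og_id + "\t" + "\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# tRNAscan-SE tabular output


def read_trnascan(path: str | Path, species: str | None = None) -> TRNACountTable:
    """Aggregate tRNAscan-SE v2 tabular output into per-codon gene counts.

    The decoded codon is the reverse complement of the anticodon column.
    Rows whose note column flags a pseudogene, rows with undetermined
    anticodons (``NNN``/``???``) and rows decoding stop codons (e.g.
    selenocysteine suppressors) are excluded.
    """
    counts: dict[str, int] = {}
    name = species
    with _open_text(path) as handle:
        past_header = False
        for lineno, line in enumerate(handle, start=1):
            stripped = line.rstrip("\n")
            if not stripped.strip():
                continue
            if not past_header:
                # header is two label lines followed by a dashed rule
                if set(stripped.replace("\t", "").replace(" ", "")) <= {"-"}:
                    past_header = True
                    continue
                if lineno > 3:
                    past_header = True  # headerless file: fall through to parse
                else:
                    continue
            cells = stripped.split("\t")
            if len(cells) < 9:
                raise FormatError(f"{path}:{lineno}: malformed tRNAscan row")
            seq_name, isotype, anticodon = cells[0].strip(), cells[4].strip(), cells[5].strip().upper()
            note = cells[9].strip().lower() if len(cells) > 9 else ""
            if name is None:
                name = seq_name.split("_")[0]
            if "pseudo" in note or isotype in {"Pseudo", "Undet"}:
                continue
            if not anticodon or "N" in anticodon or "?" in anticodon:
                continue
            if len(anticodon) != 3 or any(b not in "ACGT" for b in anticodon):
                raise FormatError(f"{path}:{lineno}: bad anticodon {anticodon!r}")
            codon = reverse_complement(anticodon)
            if codon in STOP_CODONS:
                continue
            counts[codon] = counts.get(codon, 0) + 1
    return TRNACountTable(species=name or "unknown", counts=counts)


# ---------------------------------------------------------------------------
# Protein alignments (aligned FASTA, row ids = species names)


def read_alignment_fasta(path: str | Path, og_id: str | None = None) -> "ProteinAlignment":
    from .codon_alignment import ProteinAlignment

    rows: dict[str, str] = {}
    for rec in read_fasta(path):
        rows[rec.id] = rec.residues
    if og_id is None:
        og_id = Path(path).stem
    return ProteinAlignment(og_id=og_id, rows=rows)


def translate_cds(cds: str) -> str:
    """Standard-code translation, trailing stop retained if present."""
    return str(Seq(cds).translate())
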