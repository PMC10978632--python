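"""GC-fraction computation for chromosomes and coding sequence.

GC content is defined over unambiguous bases only: gc = (#G + #C) /
(#A + #C + #G + #T).  N and other IUPAC ambiguity codes are excluded from
both numerator and denominator, so N-rich assemblies do not deflate GC.
Species-level values pool base counts across chromosomes (or genes) before
dividing — the "GC of the concatenated sequence" semantics — rather than
averaging per-sequence fractions.

Two length filters mirror standard practice for chromosome-level insect
assemblies: sequences shorter than 1 Mb are treated as unplaced scaffolds
and dropped from genome GC, and CDS shorter than 950 nt are treated as
gene fragments and dropped from CDS GC.  Both cutoffs are inclusive
(a 950 nt CDS is retained).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .formats_io import GeneModel, GenomeSequence, reverse_complement

__all__ = [
    "GCRecord",
    "gc_fraction",
    "genome_gc",
    "extract_cds",
    "cds_gc",
    "DEFAULT_MIN_CHROM_LEN",
    "DEFAULT_MIN_CDS_LEN",
]

DEFAULT_MIN_CHROM_LEN = 1_000_000
DEFAULT_MIN_CDS_LEN = 950

_GC = frozenset("GC")
_UNAMBIG = frozenset("ACGT")


@dataclass(frozen=True)
class GCRecord:
    """One (species, scope) GC fraction.

    ``gc`` is NaN when no unambiguous base was available (undefined, never
    reported as 0).  ``counted_bases`` is the denominator actually used.
    """

    species: str
    scope: str  # genome | chromosome | cds | gene
    scope_id: str
    gc: float
    counted_bases: int

    def __post_init__(self) -> None:
        if not math.isnan(self.gc) and not 0.0 <= self.gc <= 1.0:
            raise ValueError(f"gc out of [0,1]: {self.gc}")


def _gc_counts(residues: str) -> tuple[int, int]:
    """(gc_bases, counted_bases) over unambiguous bases."""
    gc = sum(1 for b in residues if b in _GC)
    counted = sum(1 for b in residues if b in _UNAMBIG)
    return gc, counted


def gc_fraction(residues: str) -> tuple[float, int]:
    """GC fraction of a nucleotide string, with the counted denominator.

    Returns (NaN, 0) when every base is ambiguous.  Empty input is an error.
    """
    if not residues:
        raise ValueError("gc_fraction of empty string")
    gc, counted = _gc_counts(residues)
    if counted == 0:
        return math.nan, 0
    return gc / counted, counted


def genome_gc(
    assembly: Iterable[GenomeSequence],
    species: str = "",
    min_chrom_len: int = DEFAULT_MIN_CHROM_LEN,
) -> list[GCRecord]:
    """Per-chromosome and pooled genome GC, dropping short scaffolds.

    Sequences shorter than ``min_chrom_len`` are excluded entirely.  The
    genome-scope record pools GC and counted-base counts over the retained
    sequences; it is not a mean of per-chromosome fractions.
    """
    records: list[GCRecord] = []
    pooled_gc = 0
    pooled_counted = 0
    for seq in assembly:
        if seq.length < min_chrom_len:
            continue
        gc, counted = _gc_counts(seq.residues)
        pooled_gc += gc
        pooled_counted += counted
        frac = gc / counted if counted else math.nan
        records.append(GCRecord(species, "chromosome", seq.id, frac, counted))
    if not records:
        raise ValueError(f"no chromosomes retained at min length {min_chrom_len}")
    frac = pooled_gc / pooled_counted if pooled_counted else math.nan
    records.append(GCRecord(species, "genome", "", frac, pooled_counted))
    return records


def extract_cds(genome: Mapping[str, GenomeSequence], gene: GeneModel) -> str:
    """Spliced CDS of a gene: segments concatenated in ascending genomic
    order, then reverse-complemented once for minus-strand genes."""
    if gene.chrom not in genome:
        raise KeyError(f"gene {gene.gene_id}: chromosome {gene.chrom!r} not in assembly")
    chrom = genome[gene.chrom]
    parts = []
    for start, end in gene.cds_segments:
        if end > chrom.length:
            raise ValueError(
                f"gene {gene.gene_id}: segment ({start}, {end}) beyond "
                f"{gene.chrom} length {chrom.length}"
            )
        parts.append(chrom.residues[start:end])
    cds = "".join(parts)
    if gene.strand == "-":
        cds = reverse_complement(cds)
    return cds


def cds_gc(
    genes: Iterable[GeneModel],
    genome: Mapping[str, GenomeSequence],
    species: str = "",
    min_cds_len: int = DEFAULT_MIN_CDS_LEN,
) -> list[GCRecord]:
    """Per-gene and pooled CDS GC, dropping gene fragments below the cutoff.

    Expects primary transcripts only.  The species-level cds record pools
    counts over all retained genes.
    """
    records: list[GCRecord] = []
    pooled_gc = 0
    pooled_counted = 0
    for gene in genes:
        cds = extract_cds(genome, gene)
        if len(cds) < min_cds_len:
            continue
        gc, counted = _gc_counts(cds)
        pooled_gc += gc
        pooled_counted += counted
        frac = gc / counted if counted else math.nan
        records.append(GCRecord(species, "gene", gene.gene_id, frac, counted))
    frac = pooled_gc / pooled_counted if pooled_counted else math.nan
    records.append(GCRecord(species, "cds", "", frac, pooled_counted))
    return records
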