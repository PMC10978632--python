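"""The GC3 pipeline: protein alignments -> trimmed codon alignments -> GC3,
codon usage and tRNA-codon correlation.

Single-copy ortholog (SCO) protein alignments are trimmed to columns where
every species has a standard residue (no gap, no X), so only codons that
are homologous across the whole orthogroup are compared.  Trimmed columns
are then back-translated against each species' unaligned CDS; a translation
check at every kept column guards against frameshifted or mis-annotated
gene models, which this filtering exists to exclude.

GC3 is the fraction of kept codons whose third base is G or C; species-level
GC3 pools codon counts over all orthogroups before dividing (an unweighted
mean of per-orthogroup GC3 is available as an option).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .formats_io import SENSE_CODONS, TRNACountTable, translate_cds
from .gc_metrics import GCRecord

__all__ = [
    "ProteinAlignment",
    "TrimmedCodonAlignment",
    "CodonUsageTable",
    "trim_alignment",
    "backtranslate",
    "gc3",
    "species_gc3",
    "per_sco_gc3",
    "codon_usage",
    "trna_codon_correlation",
    "codon_class",
]

_STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ProteinAlignment:
    """Per-orthogroup aligned protein rows (species -> aligned string)."""

    og_id: str
    rows: Mapping[str, str]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.og_id}: ragged alignment rows {sorted(lengths)}")

    @property
    def ncol(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0


@dataclass(frozen=True)
class TrimmedCodonAlignment:
    """Codon columns surviving trimming, per species."""

    og_id: str
    kept_columns: tuple[int, ...]
    rows: Mapping[str, tuple[str, ...]]


def trim_alignment(aln: ProteinAlignment) -> tuple[int, ...]:
    """Columns where no species has a gap or X (order preserved).

    Returns an empty tuple when no column survives; downstream operations
    skip such orthogroups.
    """
    if len(aln.rows) < 2:
        raise ValueError(f"{aln.og_id}: trimming needs >= 2 rows")
    kept = []
    rows = list(aln.rows.values())
    for col in range(aln.ncol):
        if all(r[col] in _STANDARD_AA for r in rows):
            kept.append(col)
    return tuple(kept)


def backtranslate(
    aln: ProteinAlignment,
    kept_columns: Sequence[int],
    cds: Mapping[str, str],
) -> TrimmedCodonAlignment:
    """Map kept protein columns back onto each species' CDS codons.

    For species *s*, the codon at kept column *k* is codon number
    ``#non-gap residues of s strictly before k`` of its CDS.  The CDS may
    carry one trailing stop codon.  Every mapped codon must translate
    (standard code) to the aligned residue, X exempt.
    """
    rows: dict[str, tuple[str, ...]] = {}
    for sp, aligned in aln.rows.items():
        if sp not in cds:
            raise KeyError(f"{aln.og_id}: no CDS for species {sp!r}")
        seq = cds[sp].upper()
        ungapped = sum(1 for c in aligned if c != "-")
        if not (3 * ungapped <= len(seq) <= 3 * ungapped + 3):
            raise ValueError(
                f"{aln.og_id}/{sp}: CDS length {len(seq)} does not match "
                f"{ungapped} aligned residues"
            )
        # running count of non-gap residues before each column
        codons = []
        residue_idx = 0
        kept_set = dict.fromkeys(kept_columns)
        col_to_codon: dict[int, str] = {}
        for col, residue in enumerate(aligned):
            if col in kept_set:
                codon = seq[3 * residue_idx : 3 * residue_idx + 3]
                if residue != "X":
                    observed = translate_cds(codon)
                    if observed != residue:
                        raise ValueError(
                            f"{aln.og_id}/{sp}: column {col} codon {codon} "
                            f"translates to {observed}, alignment has {residue}"
                        )
                col_to_codon[col] = codon
            if residue != "-":
                residue_idx += 1
        codons = tuple(col_to_codon[c] for c in kept_columns)
        rows[sp] = codons
    return TrimmedCodonAlignment(aln.og_id, tuple(kept_columns), rows)


def gc3(codons: Iterable[str]) -> float:
    """GC fraction at third codon positions.

    Codons whose third base is ambiguous are excluded from numerator and
    denominator; NaN when nothing is countable.
    """
    gc = 0
    counted = 0
    empty = True
    for codon in codons:
        empty = False
        third = codon[2]
        if third in "GC":
            gc += 1
            counted += 1
        elif third in "AT":
            counted += 1
    if empty:
        raise ValueError("gc3 of empty codon list")
    return gc / counted if counted else math.nan


def _species_codons(
    alignments: Iterable[TrimmedCodonAlignment], species: str
) -> list[str]:
    out: list[str] = []
    for aln in alignments:
        if species in aln.rows and aln.kept_columns:
            out.extend(aln.rows[species])
    return out


def species_gc3(
    alignments: Iterable[TrimmedCodonAlignment],
    species: str,
    method: str = "pooled",
) -> GCRecord:
    """Species-level GC3 over all orthogroups.

    ``pooled`` (default) sums third-position counts over every kept codon
    of every orthogroup before dividing; ``mean`` averages per-orthogroup
    GC3 values unweighted.
    """
    alignments = list(alignments)
    if method == "pooled":
        codons = _species_codons(alignments, species)
        if not codons:
            raise ValueError(f"no kept codons for species {species!r}")
        value = gc3(codons)
        counted = sum(1 for c in codons if c[2] in "ACGT")
    elif method == "mean":
        per_og = [
            gc3(aln.rows[species])
            for aln in alignments
            if species in aln.rows and aln.kept_columns
        ]
        per_og = [v for v in per_og if not math.isnan(v)]
        if not per_og:
            raise ValueError(f"no kept codons for species {species!r}")
        value = sum(per_og) / len(per_og)
        counted = len(per_og)
    else:
        raise ValueError(f"unknown method {method!r}")
    return GCRecord(species, "gc3", "", value, counted)


def per_sco_gc3(
    alignments: Iterable[TrimmedCodonAlignment],
) -> list[tuple[str, str, int, float]]:
    """Per-(orthogroup, species) GC3 rows: (og_id, species, n_codons, gc3)."""
    rows = []
    for aln in alignments:
        if not aln.kept_columns:
            continue
        for sp, codons in sorted(aln.rows.items()):
            rows.append((aln.og_id, sp, len(codons), gc3(codons)))
    return rows


def codon_class(codon: str) -> str:
    """AT3 if the third base is A/T, GC3 if G/C."""
    third = codon[2]
    if third in "AT":
        return "AT3"
    if third in "GC":
        return "GC3"
    raise ValueError(f"ambiguous third base in {codon!r}")


@dataclass(frozen=True)
class CodonUsageTable:
    """Absolute codon counts over kept SCO codons for one species.

    Stop codons are structurally absent (back-translation never maps one);
    each codon carries its AT3/GC3 class.
    """

    species: str
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        bad = set(self.counts) - set(SENSE_CODONS)
        if bad:
            raise ValueError(f"non-sense codons in usage table: {sorted(bad)}")

    def classes(self) -> dict[str, str]:
        return {codon: codon_class(codon) for codon in self.counts}


def codon_usage(
    alignments: Iterable[TrimmedCodonAlignment], species: str
) -> CodonUsageTable:
    """Absolute codon usage over all kept codons of a species' orthogroups.

    Codons containing any ambiguity code are excluded from the counts.
    """
    counts: dict[str, int] = {}
    for codon in _species_codons(alignments, species):
        if any(b not in "ACGT" for b in codon):
            continue
        counts[codon] = counts.get(codon, 0) + 1
    return CodonUsageTable(species, counts)


def trna_codon_correlation(
    trna: TRNACountTable, usage: CodonUsageTable
) -> tuple[float, float, float]:
    """Pearson correlation between tRNA gene counts and codon usage.

    Joined on the 61 sense codons; codons absent from either table count 0.
    Returns (r, t, two-sided p); all NaN if either vector is constant.
    """
    x = [trna.counts.get(c, 0) for c in SENSE_CODONS]
    y = [usage.counts.get(c, 0) for c in SENSE_CODONS]
    n = len(SENSE_CODONS)
    if len(set(x)) < 2 or len(set(y)) < 2:
        return math.nan, math.nan, math.nan
    r, p = stats.pearsonr(x, y)
    if abs(r) == 1.0:
        return r, math.inf, 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return float(r), float(t), float(p)
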