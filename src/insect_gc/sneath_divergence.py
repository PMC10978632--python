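"""Outgroup-conditioned protein-divergence scoring ("adjusted Sneath value").

The statistic asks whether a lineage has accumulated unusual amino-acid
substitutions.  Alignment columns where three nested outgroup species carry
the identical standard residue are taken as the ancestral state; for each
ingroup species the amino-acid dissimilarities between its residue and the
ancestral residue are summed over those columns and divided by the
alignment length, giving a per-protein divergence score that is 0 when the
ingroup matches the inferred ancestor everywhere.

Any symmetric, zero-diagonal, non-negative 20x20 amino-acid dissimilarity
matrix can be supplied — including the classical Sneath (1966) chemical
dissimilarity index this style of analysis was introduced with.  The
built-in default is derived at runtime from BLOSUM62,
``d(a, b) = s(a, a) + s(b, b) - 2 s(a, b)``, which satisfies the same
axioms; the choice of matrix rescales scores but does not change which
scores are zero or how they order with substitution load.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .codon_alignment import ProteinAlignment
from .phylo_stats import pearson

__all__ = [
    "AMINO_ACIDS",
    "SneathMatrix",
    "default_matrix",
    "load_matrix",
    "conserved_positions",
    "adjusted_sneath",
    "AdjustedSneathRecord",
    "sneath_compare",
]

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class SneathMatrix:
    """A 20x20 symmetric amino-acid dissimilarity with zero diagonal."""

    values: Mapping[tuple[str, str], float]
    name: str = "custom"

    def __post_init__(self) -> None:
        for a in AMINO_ACIDS:
            for b in AMINO_ACIDS:
                d = self.values.get((a, b))
                if d is None:
                    raise ValueError(f"matrix {self.name}: missing pair ({a},{b})")
                if d < 0:
                    raise ValueError(f"matrix {self.name}: negative d({a},{b})")
                if abs(d - self.values[(b, a)]) > 1e-9:
                    raise ValueError(f"matrix {self.name}: asymmetric at ({a},{b})")
            if self.values[(a, a)] != 0:
                raise ValueError(f"matrix {self.name}: nonzero diagonal at {a}")

    def __call__(self, a: str, b: str) -> float:
        return self.values[(a, b)]


@lru_cache(maxsize=1)
def default_matrix() -> SneathMatrix:
    """BLOSUM62-derived dissimilarity: d(a,b) = s(a,a) + s(b,b) - 2 s(a,b)."""
    from Bio.Align import substitution_matrices

    bl = substitution_matrices.load("BLOSUM62")
    values = {}
    for a in AMINO_ACIDS:
        for b in AMINO_ACIDS:
            values[(a, b)] = float(bl[a, a] + bl[b, b] - 2 * bl[a, b])
    return SneathMatrix(values, name="blosum62-distance")


def load_matrix(path: str | Path, name: str | None = None) -> SneathMatrix:
    """Load a user-supplied dissimilarity matrix from TSV (20 rows x 20
    columns, first column and header row are single-letter residues)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = {}
    for a in AMINO_ACIDS:
        for b in AMINO_ACIDS:
            values[(a, b)] = float(df.loc[a, b])
    return SneathMatrix(values, name=name or Path(path).stem)


def conserved_positions(
    aln: ProteinAlignment, outgroups: Sequence[str]
) -> list[tuple[int, str]]:
    """Columns whose residue is identical (and standard) in all three
    outgroups, with that shared ancestral residue."""
    if len(outgroups) != 3:
        raise ValueError(f"exactly 3 outgroups required, got {len(outgroups)}")
    missing = [s for s in outgroups if s not in aln.rows]
    if missing:
        raise KeyError(f"{aln.og_id}: outgroups absent from alignment: {missing}")
    rows = [aln.rows[s] for s in outgroups]
    out = []
    for col in range(aln.ncol):
        residues = {r[col] for r in rows}
        if len(residues) == 1:
            res = residues.pop()
            if res in AMINO_ACIDS:
                out.append((col, res))
    return out


@dataclass(frozen=True)
class AdjustedSneathRecord:
    og_id: str
    species: str
    n_conserved_positions: int
    raw_sum: float
    alignment_length: int
    adjusted: float


def adjusted_sneath(
    aln: ProteinAlignment,
    ingroup: str,
    conserved: Sequence[tuple[int, str]],
    matrix: SneathMatrix | None = None,
    normalize_by: str = "alignment_length",
) -> AdjustedSneathRecord:
    """Divergence of one ingroup species from the outgroup-conserved state.

    ``raw_sum`` adds d(ancestral, ingroup residue) over conserved columns;
    columns where the ingroup has a gap or X contribute nothing and are not
    counted in ``n_conserved_positions`` (the score measures substitution
    divergence, not indels).  ``adjusted`` divides by the alignment length
    (``normalize_by="conserved"`` divides by the used conserved-column
    count instead).  With no usable column the adjusted value is NaN.
    """
    if ingroup not in aln.rows:
        raise KeyError(f"{aln.og_id}: ingroup {ingroup!r} absent from alignment")
    matrix = matrix or default_matrix()
    row = aln.rows[ingroup]
    raw = 0.0
    used = 0
    for col, ancestral in conserved:
        residue = row[col]
        if residue not in AMINO_ACIDS:
            continue
        raw += matrix(ancestral, residue)
        used += 1
    if normalize_by == "alignment_length":
        denom = aln.ncol
    elif normalize_by == "conserved":
        denom = used
    else:
        raise ValueError(f"unknown normalize_by {normalize_by!r}")
    adjusted = raw / denom if used and denom else math.nan
    return AdjustedSneathRecord(
        og_id=aln.og_id,
        species=ingroup,
        n_conserved_positions=used,
        raw_sum=raw,
        alignment_length=aln.ncol,
        adjusted=adjusted,
    )


def sneath_compare(
    records_x: Iterable[AdjustedSneathRecord],
    records_y: Iterable[AdjustedSneathRecord],
) -> tuple[float, float, pd.DataFrame]:
    """Pair two species' adjusted values across shared orthogroups.

    Returns (Pearson r, p, paired table) for inspecting deviation from the
    y = x line; r and p are NaN when either side has zero variance.
    """
    by_og_x = {r.og_id: r.adjusted for r in records_x if not math.isnan(r.adjusted)}
    by_og_y = {r.og_id: r.adjusted for r in records_y if not math.isnan(r.adjusted)}
    shared = sorted(set(by_og_x) & set(by_og_y))
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared orthogroups with defined values")
    table = pd.DataFrame(
        {
            "og_id": shared,
            "adjusted_x": [by_og_x[o] for o in shared],
            "adjusted_y": [by_og_y[o] for o in shared],
        }
    )
    r, p = pearson(table["adjusted_x"], table["adjusted_y"])
    return r, p, table
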