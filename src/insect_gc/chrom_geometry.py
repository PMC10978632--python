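"""Position-aware statistics along chromosomes.

GC-biased gene conversion predicts elevated GC near chromosome ends, where
recombination (and hence gene conversion) is more frequent, and — under the
one-crossover-per-bivalent argument — higher GC on smaller chromosomes.
This module provides the geometric primitives for both tests: distance of a
gene from the nearest assembly end ("telomere distance", assemblies assumed
telomere-to-telomere), per-species Pearson correlation of chromosome GC
with chromosome size, and ordered per-chromosome GC3 landscapes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .formats_io import GeneModel
from .phylo_stats import pearson, ols

__all__ = [
    "SCOPositionRecord",
    "ChromSizeGCRecord",
    "telomere_distance",
    "per_species_size_gc_correlation",
    "SizeGCCorrelation",
    "landscape",
]


@dataclass(frozen=True)
class SCOPositionRecord:
    """One SCO gene's chromosomal position and GC3 in one species."""

    og_id: str
    species: str
    chrom: str
    midpoint: int
    distance_from_telomere: int
    gc3: float


@dataclass(frozen=True)
class ChromSizeGCRecord:
    species: str
    chrom: str
    length: int
    gc: float


def telomere_distance(
    gene: GeneModel, chrom_length: int, reference: str = "midpoint"
) -> int:
    """Distance (bases) from a gene to the nearest chromosome end.

    The gene's reference point is the CDS-span midpoint
    ``floor((start + end) / 2)`` by default (symmetric under coordinate
    reflection); ``reference="start"`` uses the lowest CDS coordinate
    instead.  Returns ``min(m, L - m)``.
    """
    start, end = gene.span
    if end > chrom_length:
        raise ValueError(
            f"gene {gene.gene_id} ends at {end}, beyond chromosome length {chrom_length}"
        )
    if reference == "midpoint":
        m = (start + end) // 2
    elif reference == "start":
        m = start
    else:
        raise ValueError(f"unknown reference {reference!r}")
    return min(m, chrom_length - m)


@dataclass(frozen=True)
class SizeGCCorrelation:
    species: str
    r: float
    p_value: float
    slope: float
    classification: str  # "significant-negative" | "other" | "undefined"
    n_chromosomes: int


def per_species_size_gc_correlation(
    records: Sequence[ChromSizeGCRecord], alpha: float = 0.05
) -> SizeGCCorrelation:
    """Pearson correlation of chromosome GC against chromosome length.

    Classified "significant-negative" iff r < 0 with two-sided p < alpha,
    the convention used when counting species with a small-chromosome GC
    effect.  Slope is from OLS of gc on raw length.
    """
    if len(records) < 3:
        raise ValueError("need >= 3 chromosomes")
    species = {r.species for r in records}
    if len(species) != 1:
        raise ValueError(f"records span multiple species: {sorted(species)}")
    lengths = [r.length for r in records]
    gcs = [r.gc for r in records]
    r, p = pearson(lengths, gcs)
    if math.isnan(r):
        return SizeGCCorrelation(records[0].species, r, p, math.nan, "undefined", len(records))
    slope = ols(lengths, gcs).slope
    cls = "significant-negative" if (r < 0 and p < alpha) else "other"
    return SizeGCCorrelation(records[0].species, r, p, slope, cls, len(records))


def landscape(
    records: Iterable[SCOPositionRecord], window: int = 10
) -> pd.DataFrame:
    """Per-chromosome GC3 landscape for one species.

    Records are sorted by midpoint within each chromosome; ``gc3_smooth``
    is a centred rolling mean of ``window`` genes (min_periods=1), so
    ``window=1`` reproduces the raw values.
    """
    rows = [
        (r.chrom, r.midpoint, r.og_id, r.gc3)
        for r in records
    ]
    if not rows:
        raise ValueError("no records")
    df = pd.DataFrame(rows, columns=["chrom", "midpoint", "og_id", "gc3"])
    df = df.sort_values(["chrom", "midpoint"], kind="mergesort").reset_index(drop=True)
    df["gc3_smooth"] = (
        df.groupby("chrom")["gc3"]
        .transform(lambda s: s.rolling(window, min_periods=1, center=True).mean())
    )
    return df
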