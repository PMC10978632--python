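"""End-to-end orchestration of the four analyses.

The stages compose the lower-level modules into the workflows a comparative
study runs per insect order:

1. order-level GC summary — per-species genome GC / CDS GC / SCO GC3,
   phylogenetically informed means per order, two-way ANOVA (DNA type x
   order) and Tukey HSD;
2. chromosome-size correlations — per-species Pearson r of chromosome GC
   against chromosome length;
3. telomere analysis — per-SCO phylogenetically informed mean GC3 and mean
   telomere distance, OLS regression, per-species landscapes;
4. AT-richness workup — codon usage with AT3/GC3 classes, tRNA-count vs
   codon-frequency correlation, and adjusted protein-divergence scores
   conditioned on three outgroups.

Datasets are directories in the layout ``synthetic_data.write_dataset``
emits (genomes/, alignments/, trna/, species_tree.nwk, orthogroups.tsv);
real data prepared in the same layout runs identically.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import chrom_geometry, codon_alignment, gc_metrics, phylo_stats, sneath_divergence
from .codon_alignment import ProteinAlignment, TrimmedCodonAlignment
from .formats_io import (
    GeneModel,
    GenomeSequence,
    OrthogroupTable,
    TRNACountTable,
    read_alignment_fasta,
    read_fasta,
    read_gff3,
    read_newick,
    read_orthogroups,
    read_trnascan,
)
from .phylo_stats import PhyloTree

logger = logging.getLogger(__name__)

__all__ = [
    "Dataset",
    "load_dataset",
    "trimmed_alignments",
    "species_gc_table",
    "gc_summary",
    "GCSummary",
    "size_gc_correlations",
    "telomere_table",
    "telomere_analysis",
    "TelomereAnalysis",
    "atrich_workup",
    "ATRichWorkup",
]


@dataclass
class Dataset:
    """In-memory view of one order's inputs."""

    species: list[str]
    tree: PhyloTree
    assemblies: dict[str, list[GenomeSequence]]
    genes: dict[str, list[GeneModel]]
    orthogroups: OrthogroupTable
    alignments: dict[str, ProteinAlignment]
    trna: dict[str, TRNACountTable]


def load_dataset(path: str | Path) -> Dataset:
    """Load a dataset directory (see module docstring for the layout)."""
    path = Path(path)
    tree = read_newick(path / "species_tree.nwk")
    orthogroups = read_orthogroups(path / "orthogroups.tsv")
    species = sorted(tree.tips)
    assemblies = {}
    genes = {}
    trna = {}
    for sp in species:
        assemblies[sp] = read_fasta(path / "genomes" / f"{sp}.fasta")
        genes[sp] = read_gff3(path / "genomes" / f"{sp}.gff3")
        trna_path = path / "trna" / f"{sp}.trnascan.tsv"
        if trna_path.exists():
            trna[sp] = read_trnascan(trna_path, species=sp)
    alignments = {}
    for aln_path in sorted((path / "alignments").glob("*.fasta")):
        aln = read_alignment_fasta(aln_path)
        alignments[aln.og_id] = aln
    return Dataset(species, tree, assemblies, genes, orthogroups, alignments, trna)


def _gene_index(ds: Dataset) -> dict[str, dict[str, GeneModel]]:
    return {sp: {g.gene_id: g for g in ds.genes[sp]} for sp in ds.species}


def _strip_stop(cds: str) -> str:
    if len(cds) % 3 == 0 and cds[-3:] in {"TAA", "TAG", "TGA"}:
        return cds
    return cds


def trimmed_alignments(ds: Dataset) -> dict[str, TrimmedCodonAlignment]:
    """Trim every orthogroup alignment and back-translate against CDS
    extracted from the assemblies.  Orthogroups with no surviving columns
    are skipped (logged)."""
    genomes = {sp: {s.id: s for s in ds.assemblies[sp]} for sp in ds.species}
    gene_index = _gene_index(ds)
    out: dict[str, TrimmedCodonAlignment] = {}
    for og_id, aln in sorted(ds.alignments.items()):
        members = ds.orthogroups.groups.get(og_id, {})
        cds = {}
        for sp in aln.rows:
            gene = gene_index[sp].get(members.get(sp, ""))
            if gene is None:
                break
            cds[sp] = gc_metrics.extract_cds(genomes[sp], gene)
        else:
            kept = codon_alignment.trim_alignment(aln)
            if not kept:
                logger.warning("%s: no columns survive trimming; skipped", og_id)
                continue
            out[og_id] = codon_alignment.backtranslate(aln, kept, cds)
    return out


def species_gc_table(
    ds: Dataset,
    min_chrom_len: int = gc_metrics.DEFAULT_MIN_CHROM_LEN,
    min_cds_len: int = gc_metrics.DEFAULT_MIN_CDS_LEN,
    trimmed: Mapping[str, TrimmedCodonAlignment] | None = None,
) -> pd.DataFrame:
    """Per-species genome GC, CDS GC and pooled SCO GC3."""
    if trimmed is None:
        trimmed = trimmed_alignments(ds)
    rows = []
    for sp in ds.species:
        genome_records = gc_metrics.genome_gc(ds.assemblies[sp], sp, min_chrom_len)
        genome_value = next(r.gc for r in genome_records if r.scope == "genome")
        genomes = {s.id: s for s in ds.assemblies[sp]}
        cds_records = gc_metrics.cds_gc(ds.genes[sp], genomes, sp, min_cds_len)
        cds_value = next(r.gc for r in cds_records if r.scope == "cds")
        gc3_value = codon_alignment.species_gc3(trimmed.values(), sp).gc
        rows.append((sp, genome_value, cds_value, gc3_value))
    return pd.DataFrame(rows, columns=["species", "genome_gc", "cds_gc", "sco_gc3"])


@dataclass
class GCSummary:
    means: pd.DataFrame  # rows = DNA type, columns = order
    anova: phylo_stats.AnovaResult
    tukey_dna_type: pd.DataFrame
    tukey_order: pd.DataFrame


def gc_summary(
    tables: Mapping[str, pd.DataFrame],
    trees: Mapping[str, PhyloTree],
) -> GCSummary:
    """Order-level summary: phylogenetically informed means per DNA type,
    then the two-way ANOVA (DNA type x order) with Tukey HSD post-hocs.

    ``tables[order]`` is a species_gc_table frame; ``trees[order]`` the
    order's species tree.  Needs >= 2 orders for a complete design.
    """
    if len(tables) < 2:
        raise ValueError("need >= 2 orders for the two-way design")
    dna_types = ["genome_gc", "cds_gc", "sco_gc3"]
    means: dict[str, dict[str, float]] = {t: {} for t in dna_types}
    for order, table in tables.items():
        tree = trees[order]
        missing = set(table["species"]) - set(tree.tips)
        if missing:
            raise KeyError(f"order {order}: species missing from tree: {sorted(missing)}")
        sub = tree.pruned_to(table["species"]) if set(tree.tips) - set(table["species"]) else tree
        for dna_type in dna_types:
            values = dict(zip(table["species"], table[dna_type]))
            means[dna_type][order] = phylo_stats.phylo_mean(sub, values)
    mean_table = pd.DataFrame(means).T.loc[dna_types, sorted(tables)]
    anova = phylo_stats.two_way_anova(mean_table, factor_a="dna_type", factor_b="order")
    return GCSummary(
        means=mean_table,
        anova=anova,
        tukey_dna_type=phylo_stats.tukey_hsd(anova, "dna_type"),
        tukey_order=phylo_stats.tukey_hsd(anova, "order"),
    )


def size_gc_correlations(
    ds: Dataset,
    min_chrom_len: int = gc_metrics.DEFAULT_MIN_CHROM_LEN,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-species chromosome-size vs GC Pearson correlations."""
    rows = []
    for sp in ds.species:
        records = []
        for rec in gc_metrics.genome_gc(ds.assemblies[sp], sp, min_chrom_len):
            if rec.scope != "chromosome":
                continue
            length = next(s.length for s in ds.assemblies[sp] if s.id == rec.scope_id)
            records.append(chrom_geometry.ChromSizeGCRecord(sp, rec.scope_id, length, rec.gc))
        result = chrom_geometry.per_species_size_gc_correlation(records, alpha)
        rows.append(
            (sp, result.n_chromosomes, result.r, result.p_value, result.slope,
             result.classification)
        )
    return pd.DataFrame(
        rows, columns=["species", "n_chromosomes", "r", "p", "slope", "classification"]
    )


def telomere_table(
    ds: Dataset, trimmed: Mapping[str, TrimmedCodonAlignment] | None = None
) -> pd.DataFrame:
    """Per-(orthogroup, species) GC3 and telomere distance."""
    if trimmed is None:
        trimmed = trimmed_alignments(ds)
    gene_index = _gene_index(ds)
    chrom_lengths = {
        sp: {s.id: s.length for s in ds.assemblies[sp]} for sp in ds.species
    }
    rows = []
    for og_id, aln in sorted(trimmed.items()):
        members = ds.orthogroups.groups[og_id]
        for sp, codons in sorted(aln.rows.items()):
            gene = gene_index[sp][members[sp]]
            length = chrom_lengths[sp][gene.chrom]
            dist = chrom_geometry.telomere_distance(gene, length)
            start, end = gene.span
            rows.append(
                (og_id, sp, gene.chrom, (start + end) // 2, dist,
                 codon_alignment.gc3(codons))
            )
    return pd.DataFrame(
        rows,
        columns=["og_id", "species", "chrom", "midpoint", "distance_from_telomere", "gc3"],
    )


@dataclass
class TelomereAnalysis:
    per_sco: pd.DataFrame  # og_id, mean_gc3, mean_distance (phylo-informed)
    regression: phylo_stats.OLSResult
    landscapes: dict[str, pd.DataFrame]


def telomere_analysis(
    ds: Dataset,
    trimmed: Mapping[str, TrimmedCodonAlignment] | None = None,
    min_sco: int = 10,
    landscape_window: int = 10,
) -> TelomereAnalysis:
    """Per-SCO phylogenetically informed (GC3, telomere distance) means and
    their OLS regression, plus per-species GC3 landscapes.

    Distances enter the regression in Mb.
    """
    table = telomere_table(ds, trimmed)
    ogs = table["og_id"].unique()
    if len(ogs) < min_sco:
        raise ValueError(f"only {len(ogs)} SCOs; need >= {min_sco}")
    per_og: dict[str, dict[str, tuple[float, float]]] = {}
    for row in table.itertuples():
        per_og.setdefault(row.og_id, {})[row.species] = (
            row.gc3,
            row.distance_from_telomere / 1e6,
        )
    means = phylo_stats.phylo_mean_per_sco(ds.tree, per_og)
    per_sco = pd.DataFrame(
        [(og, gc3_mean, dist_mean) for og, (gc3_mean, dist_mean) in sorted(means.items())],
        columns=["og_id", "mean_gc3", "mean_distance_mb"],
    )
    regression = phylo_stats.ols(per_sco["mean_distance_mb"], per_sco["mean_gc3"])
    landscapes = {}
    for sp in ds.species:
        records = [
            chrom_geometry.SCOPositionRecord(
                row.og_id, sp, row.chrom, row.midpoint,
                row.distance_from_telomere, row.gc3,
            )
            for row in table[table["species"] == sp].itertuples()
        ]
        landscapes[sp] = chrom_geometry.landscape(records, landscape_window)
    return TelomereAnalysis(per_sco, regression, landscapes)


@dataclass
class ATRichWorkup:
    codon_usage: dict[str, codon_alignment.CodonUsageTable]
    trna_correlation: pd.DataFrame  # species, r, t, p
    sneath: dict[str, list[sneath_divergence.AdjustedSneathRecord]]
    sneath_pairs: dict[tuple[str, str], tuple[float, float, pd.DataFrame]]


def atrich_workup(
    trimmed: Mapping[str, TrimmedCodonAlignment],
    trna: Mapping[str, TRNACountTable],
    divergence_alignments: Mapping[str, ProteinAlignment],
    outgroups: Sequence[str],
    ingroups: Sequence[str],
    matrix: sneath_divergence.SneathMatrix | None = None,
) -> ATRichWorkup:
    """Codon usage + tRNA correlation for the species with tRNA tables, and
    adjusted divergence scores for the named ingroups against three
    outgroups on the (untrimmed) divergence alignments."""
    for og_id, aln in divergence_alignments.items():
        missing = [s for s in outgroups if s not in aln.rows]
        if missing:
            raise KeyError(f"{og_id}: outgroups absent: {missing}")
    usage = {
        sp: codon_alignment.codon_usage(trimmed.values(), sp) for sp in sorted(trna)
    }
    corr_rows = []
    for sp in sorted(trna):
        r, t, p = codon_alignment.trna_codon_correlation(trna[sp], usage[sp])
        corr_rows.append((sp, r, t, p))
    corr = pd.DataFrame(corr_rows, columns=["species", "r", "t", "p"])

    sneath: dict[str, list[sneath_divergence.AdjustedSneathRecord]] = {
        sp: [] for sp in ingroups
    }
    for og_id, aln in sorted(divergence_alignments.items()):
        conserved = sneath_divergence.conserved_positions(aln, outgroups)
        for sp in ingroups:
            if sp not in aln.rows:
                continue
            sneath[sp].append(
                sneath_divergence.adjusted_sneath(aln, sp, conserved, matrix)
            )
    pairs: dict[tuple[str, str], tuple[float, float, pd.DataFrame]] = {}
    for i, a in enumerate(ingroups):
        for b in ingroups[i + 1 :]:
            try:
                pairs[(a, b)] = sneath_divergence.sneath_compare(sneath[a], sneath[b])
            except ValueError as exc:
                logger.warning("pair (%s, %s): %s", a, b, exc)
    return ATRichWorkup(usage, corr, sneath, pairs)
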