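"""Synthetic genome/annotation/alignment generator.

Emulates the statistical structure the analysis pipeline assumes, so every
stage can run and be validated without external downloads:

* an ultrametric pure-birth species tree;
* per-species baseline GC3 evolving on that tree under Brownian motion;
* multiple chromosomes of unequal length whose intergenic GC follows a
  telomere gradient ``p(d) = p_far + delta * exp(-d / lam)`` in the
  distance *d* from the nearest chromosome end;
* single-copy ortholog genes (1-3 exons, both strands) whose synonymous
  codons are sampled to a per-gene target GC3 = species baseline +
  gradient elevation at the gene's position;
* gapless protein alignments per orthogroup (all species share each
  orthogroup's amino-acid sequence; indel evolution is not modelled);
* tRNA gene counts either coupled to codon usage or decoupled from it,
  emitted in tRNAscan-SE-like tabular form;
* protein alignments with outgroup-conserved columns and Poisson
  substitution load on ingroup lineages, for divergence scoring.

Every quantity the generator knows to be true (per-gene target and realized
GC3, positions, species baselines) is recorded in truth tables; recovery
tests are written against those.  One global integer seed determines all
output byte-for-byte; sub-generators derive child seeds by hashing the seed
with a stage label.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .codon_alignment import ProteinAlignment
from .formats_io import (
    GeneModel,
    GenomeSequence,
    OrthogroupTable,
    TRNACountTable,
    reverse_complement,
    write_fasta,
    write_gff3,
    write_orthogroups,
)
from .phylo_stats import PhyloTree

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "child_seed",
    "simulate_tree",
    "simulate_bm",
    "simulate_sco_codons",
    "simulate_genome",
    "simulate_divergence",
    "make_dataset",
    "write_dataset",
    "write_trnascan",
]

_AA3 = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe", "G": "Gly",
    "H": "His", "I": "Ile", "K": "Lys", "L": "Leu", "M": "Met", "N": "Asn",
    "P": "Pro", "Q": "Gln", "R": "Arg", "S": "Ser", "T": "Thr", "V": "Val",
    "W": "Trp", "Y": "Tyr",
}

#: synonymous codons per amino acid, split by third-base class
_CODONS_BY_AA: dict[str, dict[str, list[str]]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    box = _CODONS_BY_AA.setdefault(aa, {"AT3": [], "GC3": []})
    box["AT3" if codon[2] in "AT" else "GC3"].append(codon)
for box in _CODONS_BY_AA.values():
    box["AT3"].sort()
    box["GC3"].sort()


def child_seed(seed: int, label: str) -> int:
    """Deterministic per-stage child seed (< 2^31)."""
    digest = hashlib.blake2b(f"{seed}:{label}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a synthetic dataset.

    The gradient is ``p(d) = p_far + delta * exp(-d / lam)`` with *d* the
    distance (bases) from the nearest chromosome end; it shapes both
    intergenic base composition and per-gene target GC3 (as an elevation
    over the species' Brownian-motion baseline).
    """

    seed: int = 0
    n_species: int = 6
    birth_rate: float = 1.0
    n_chromosomes: int = 3
    chrom_length_range: tuple[int, int] = (8_000_000, 16_000_000)
    gc_far: float = 0.35
    gc_delta: float = 0.10
    gc_lambda: float = 2_000_000.0
    n_sco: int = 200
    gc3_root: float = 0.35
    gc3_sigma2: float = 0.01
    protein_length_range: tuple[int, int] = (150, 400)
    intron_length_range: tuple[int, int] = (100, 1000)
    trna_coupled: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc_far <= 1.0 and 0.0 <= self.gc_delta <= 1.0):
            raise ValueError("gradient fractions must lie in [0, 1]")
        if self.gc_far + self.gc_delta > 1.0:
            raise ValueError("gc_far + gc_delta must not exceed 1")
        if self.n_species < 2:
            raise ValueError("need at least 2 species")


# ---------------------------------------------------------------------------
# Tree and trait simulation


def simulate_tree(n_species: int, birth_rate: float, seed: int) -> PhyloTree:
    """Ultrametric pure-birth (Yule) tree with tips sp01..spNN.

    Lineages split at exponential waiting times with total rate
    ``k * birth_rate``; all terminal branches are extended to the final
    splitting time, so root-to-tip depths are equal.
    """
    if n_species < 2:
        raise ValueError("need >= 2 species")
    rng = np.random.default_rng(seed)

    next_id = [0]

    def new_node():
        next_id[0] += 1
        return {"children": [], "birth": None, "label": None}

    t = 0.0
    root_time = 0.0
    active = [new_node(), new_node()]
    root_children = list(active)
    for node in active:
        node["birth"] = 0.0
    while len(active) < n_species:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        idx = int(rng.integers(k))
        parent = active.pop(idx)
        parent["split"] = t
        kids = [new_node(), new_node()]
        for kid in kids:
            kid["birth"] = t
        parent["children"] = kids
        active.extend(kids)
    # one final waiting time so the last split is not at the present
    t += rng.exponential(1.0 / (len(active) * birth_rate))
    tip_no = [0]

    def to_newick(node) -> str:
        if node["children"]:
            inner = ",".join(to_newick(c) for c in node["children"])
            length = node["split"] - node["birth"]
            return f"({inner}):{length:.10f}"
        tip_no[0] += 1
        label = f"sp{tip_no[0]:02d}"
        length = t - node["birth"]
        return f"{label}:{length:.10f}"

    inner = ",".join(to_newick(c) for c in root_children)
    return PhyloTree.from_newick(f"({inner});")


def simulate_bm(
    tree: PhyloTree, root_value: float, sigma2: float, seed: int
) -> dict[str, float]:
    """Brownian-motion tip values: Gaussian increments with variance
    sigma2 x branch length along every edge."""
    rng = np.random.default_rng(seed)
    dt = tree._tree
    value = {dt.seed_node: float(root_value)}
    out: dict[str, float] = {}
    for node in dt.preorder_node_iter():
        if node is dt.seed_node:
            continue
        step = rng.normal(0.0, math.sqrt(sigma2 * node.edge.length)) if sigma2 > 0 else 0.0
        value[node] = value[node.parent_node] + step
        if node.is_leaf():
            out[node.taxon.label] = value[node]
    return out


# ---------------------------------------------------------------------------
# Codon-level simulation


def simulate_sco_codons(
    amino_acids: str, target_gc3: float, rng: np.random.Generator
) -> tuple[str, float]:
    """Sample synonymous codons for a protein at a third-position GC target.

    Methionine and tryptophan force a G/C third base; at every other site a
    GC3-class codon is chosen with a probability adjusted so the protein's
    expected overall GC3 equals ``target_gc3``, then uniformly within the
    class.  Targets outside the achievable range for the protein are
    clamped (minimum = forced-site fraction).  Returns the codon string
    (no stop) and the realized GC3.
    """
    target = min(1.0, max(0.0, target_gc3))
    bad = set(amino_acids) - set(_CODONS_BY_AA)
    if bad:
        raise ValueError(f"invalid residues {sorted(bad)}")
    n = len(amino_acids)
    n_forced = sum(1 for aa in amino_acids if not _CODONS_BY_AA[aa]["AT3"])
    n_free = n - n_forced
    p_free = 0.0 if n_free == 0 else min(1.0, max(0.0, (target * n - n_forced) / n_free))
    codons = []
    gc = 0
    for aa in amino_acids:
        box = _CODONS_BY_AA[aa]
        if box["AT3"] and box["GC3"]:
            pick_gc = rng.random() < p_free
        else:
            pick_gc = bool(box["GC3"])
        pool = box["GC3"] if pick_gc else box["AT3"]
        codon = pool[int(rng.integers(len(pool)))]
        gc += codon[2] in "GC"
        codons.append(codon)
    return "".join(codons), gc / len(codons)


def random_protein(length: int, rng: np.random.Generator) -> str:
    aas = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(aas[i] for i in rng.integers(0, 20, size=length))


# ---------------------------------------------------------------------------
# Genome simulation


def _gradient(d: np.ndarray, p_far: float, delta: float, lam: float) -> np.ndarray:
    if math.isinf(lam):
        return np.full_like(d, p_far + delta, dtype=np.float32)
    return (p_far + delta * np.exp(-d / lam)).astype(np.float32)


def _background(length: int, p_far: float, delta: float, lam: float,
                rng: np.random.Generator) -> np.ndarray:
    """Chromosome background as an S1 byte array with gradient GC."""
    pos = np.arange(length, dtype=np.float32)
    d = np.minimum(pos, (length - 1) - pos)
    p = _gradient(d, p_far, delta, lam)
    is_gc = rng.random(length, dtype=np.float32) < p
    half = rng.integers(0, 2, size=length).astype(bool)
    arr = np.empty(length, dtype="S1")
    arr[is_gc & half] = b"G"
    arr[is_gc & ~half] = b"C"
    arr[~is_gc & half] = b"A"
    arr[~is_gc & ~half] = b"T"
    return arr


@dataclass(frozen=True)
class _PlacedGene:
    og_id: str
    chrom_index: int
    start: int
    segments: tuple[tuple[int, int], ...]
    strand: str


def _gene_structure(
    cds_len: int,
    n_exons: int,
    intron_range: tuple[int, int],
    rng: np.random.Generator,
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """(exon lengths summing to cds_len, intron lengths) for one gene."""
    if n_exons > 1:
        cuts = np.sort(rng.choice(np.arange(1, cds_len), size=n_exons - 1, replace=False))
        exon_lens = tuple(int(x) for x in np.diff([0, *cuts, cds_len]))
        introns = tuple(
            int(rng.integers(intron_range[0], intron_range[1] + 1))
            for _ in range(n_exons - 1)
        )
    else:
        exon_lens, introns = (cds_len,), ()
    return exon_lens, introns


def _place_genes(
    chrom_lengths: Sequence[int],
    og_ids: Sequence[str],
    structures: Sequence[tuple[tuple[int, ...], tuple[int, ...]]],
    strands: Sequence[str],
    rng: np.random.Generator,
) -> list[_PlacedGene]:
    """Place genes uniformly and without overlap across chromosomes.

    Each gene's genomic span is its exon lengths interleaved with its
    intron lengths; chromosome assignment is length-proportional, start
    offsets uniform in the chromosome's free space.
    """
    spans = [sum(ex) + sum(intr) for ex, intr in structures]
    n_chrom = len(chrom_lengths)
    weights = np.asarray(chrom_lengths, dtype=float)
    weights /= weights.sum()
    assignment = rng.choice(n_chrom, size=len(spans), p=weights)
    placed: list[_PlacedGene] = []
    for ci in range(n_chrom):
        idx = [i for i in range(len(spans)) if assignment[i] == ci]
        total = sum(spans[i] for i in idx)
        free = chrom_lengths[ci] - total
        if free < len(idx) + 1:
            raise ValueError(
                f"gene placement overflow on chromosome {ci}: "
                f"{total} bases of genes in {chrom_lengths[ci]}; "
                "use fewer or shorter genes or longer chromosomes"
            )
        offsets = np.sort(rng.integers(0, free, size=len(idx)))
        span_before = 0
        for k, i in enumerate(idx):
            start = int(offsets[k]) + span_before
            exon_lens, introns = structures[i]
            segments = []
            pos = start
            for j, el in enumerate(exon_lens):
                segments.append((pos, pos + el))
                pos += el
                if j < len(introns):
                    pos += introns[j]
            placed.append(_PlacedGene(og_ids[i], ci, start, tuple(segments), strands[i]))
            span_before += spans[i]
    return placed


def simulate_genome(
    config: SyntheticConfig,
    species: str,
    proteins: Mapping[str, str],
    base_gc3: float,
    seed: int,
) -> tuple[list[GenomeSequence], list[GeneModel], pd.DataFrame, dict[str, str]]:
    """One species' assembly: chromosomes, gene models, truth table, CDS map.

    Gene CDS (with trailing stop) are sampled to a target GC3 of
    ``base_gc3 + delta * exp(-d / lam)`` at the gene's placed telomere
    distance *d*; intergenic background follows the same gradient around
    ``gc_far``.  Returns (sequences, gene models, per-gene truth, og->CDS).
    """
    rng = np.random.default_rng(seed)
    lo, hi = config.chrom_length_range
    chrom_lengths = [int(rng.integers(lo, hi + 1)) for _ in range(config.n_chromosomes)]
    og_ids = sorted(proteins)

    # pre-draw per-gene structure so placement knows total spans
    exon_counts = [int(rng.integers(1, 4)) for _ in og_ids]
    strands = ["+" if rng.random() < 0.5 else "-" for _ in og_ids]
    cds_lens = [3 * len(proteins[og]) + 3 for og in og_ids]  # incl. stop
    structures = [
        _gene_structure(cds_lens[i], exon_counts[i], config.intron_length_range, rng)
        for i in range(len(og_ids))
    ]
    placed = _place_genes(chrom_lengths, og_ids, structures, strands, rng)

    arrays = [
        _background(L, config.gc_far, config.gc_delta, config.gc_lambda, rng)
        for L in chrom_lengths
    ]

    genes: list[GeneModel] = []
    truth_rows = []
    cds_map: dict[str, str] = {}
    og_index = {og: i for i, og in enumerate(og_ids)}
    for g in placed:
        i = og_index[g.og_id]
        L = chrom_lengths[g.chrom_index]
        span_start, span_end = g.segments[0][0], g.segments[-1][1]
        midpoint = (span_start + span_end) // 2
        dist = min(midpoint, L - midpoint)
        elev = config.gc_delta * (
            math.exp(-dist / config.gc_lambda) if not math.isinf(config.gc_lambda) else 1.0
        )
        target = base_gc3 + elev
        codons, realized = simulate_sco_codons(proteins[g.og_id], target, rng)
        stop = ["TAA", "TAG", "TGA"][int(rng.integers(3))]
        cds = codons + stop
        cds_map[g.og_id] = cds
        genomic = cds if g.strand == "+" else reverse_complement(cds)
        # lay genomic sequence across segments in ascending order
        cursor = 0
        arr = arrays[g.chrom_index]
        for s, e in g.segments:
            seg = genomic[cursor : cursor + (e - s)]
            arr[s:e] = np.frombuffer(seg.encode(), dtype="S1")
            cursor += e - s
        assert cursor == len(genomic)
        gene_id = f"{species}_{g.og_id}_g"
        genes.append(
            GeneModel(
                gene_id=gene_id,
                transcript_id=f"{species}_{g.og_id}_t",
                chrom=f"{species}_chr{g.chrom_index + 1}",
                strand=g.strand,
                cds_segments=g.segments,
            )
        )
        truth_rows.append(
            {
                "og_id": g.og_id,
                "species": species,
                "gene_id": gene_id,
                "chrom": f"{species}_chr{g.chrom_index + 1}",
                "midpoint": midpoint,
                "distance_from_telomere": dist,
                "target_gc3": target,
                "realized_gc3": realized,
                "strand": g.strand,
            }
        )

    sequences = [
        GenomeSequence(f"{species}_chr{i + 1}", arrays[i].tobytes().decode())
        for i in range(config.n_chromosomes)
    ]
    truth = pd.DataFrame(truth_rows).sort_values("og_id").reset_index(drop=True)
    return sequences, genes, truth, cds_map


# ---------------------------------------------------------------------------
# Divergence panels (for adjusted Sneath scoring)


def simulate_divergence(
    ancestor: str,
    outgroups: Sequence[str],
    ingroups: Sequence[str],
    rho: float,
    seed: int,
    og_id: str = "OG0000001",
) -> tuple[ProteinAlignment, dict[str, list[int]]]:
    """Alignment where outgroups copy the ancestor and each ingroup carries
    Poisson(rho x length) substitutions at uniform positions.

    Returns the alignment and the true substituted positions per ingroup.
    """
    if rho < 0:
        raise ValueError("rho must be >= 0")
    rng = np.random.default_rng(seed)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    rows: dict[str, str] = {sp: ancestor for sp in outgroups}
    true_positions: dict[str, list[int]] = {}
    for sp in ingroups:
        n_sub = int(rng.poisson(rho * len(ancestor)))
        n_sub = min(n_sub, len(ancestor))
        positions = sorted(
            int(p) for p in rng.choice(len(ancestor), size=n_sub, replace=False)
        )
        seq = list(ancestor)
        for pos in positions:
            choices = [a for a in aas if a != seq[pos]]
            seq[pos] = choices[int(rng.integers(len(choices)))]
        rows[sp] = "".join(seq)
        true_positions[sp] = positions
    return ProteinAlignment(og_id=og_id, rows=rows), true_positions


# ---------------------------------------------------------------------------
# Whole datasets


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    tree: PhyloTree
    species: list[str]
    base_gc3: dict[str, float]
    assemblies: dict[str, list[GenomeSequence]]
    genes: dict[str, list[GeneModel]]
    orthogroups: OrthogroupTable
    alignments: dict[str, ProteinAlignment]
    cds: dict[str, dict[str, str]]  # species -> og_id -> CDS (with stop)
    truth: pd.DataFrame
    trna: dict[str, TRNACountTable]


def make_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a full multi-species dataset under one seed."""
    tree = simulate_tree(config.n_species, config.birth_rate, child_seed(config.seed, "tree"))
    species = sorted(tree.tips)
    base = simulate_bm(
        tree, config.gc3_root, config.gc3_sigma2, child_seed(config.seed, "bm")
    )

    prot_rng = np.random.default_rng(child_seed(config.seed, "proteins"))
    lo, hi = config.protein_length_range
    proteins = {
        f"OG{i + 1:07d}": random_protein(int(prot_rng.integers(lo, hi + 1)), prot_rng)
        for i in range(config.n_sco)
    }

    assemblies: dict[str, list[GenomeSequence]] = {}
    genes: dict[str, list[GeneModel]] = {}
    cds: dict[str, dict[str, str]] = {}
    truth_frames = []
    groups: dict[str, dict[str, str]] = {og: {} for og in proteins}
    for sp in species:
        seqs, models, truth, cds_map = simulate_genome(
            config, sp, proteins, base[sp], child_seed(config.seed, f"genome:{sp}")
        )
        assemblies[sp] = seqs
        genes[sp] = models
        cds[sp] = cds_map
        truth_frames.append(truth)
        for m in models:
            og = m.gene_id.split("_")[1]
            groups[og][sp] = m.gene_id

    alignments = {
        og: ProteinAlignment(og_id=og, rows={sp: proteins[og] for sp in species})
        for og in proteins
    }

    trna: dict[str, TRNACountTable] = {}
    for sp in species:
        trna[sp] = _simulate_trna(
            cds[sp], sp, config.trna_coupled, child_seed(config.seed, f"trna:{sp}")
        )

    return SyntheticDataset(
        config=config,
        tree=tree,
        species=species,
        base_gc3=base,
        assemblies=assemblies,
        genes=genes,
        orthogroups=OrthogroupTable(groups),
        alignments=alignments,
        cds=cds,
        truth=pd.concat(truth_frames, ignore_index=True),
        trna=trna,
    )


def _simulate_trna(
    cds_map: Mapping[str, str], species: str, coupled: bool, seed: int
) -> TRNACountTable:
    """tRNA gene counts proportional to codon usage (coupled) or with the
    same count multiset assigned to a permuted codon order (decoupled)."""
    from .formats_io import SENSE_CODONS

    rng = np.random.default_rng(seed)
    usage: dict[str, int] = {}
    for cds in cds_map.values():
        for i in range(0, len(cds) - 3, 3):  # skip trailing stop
            codon = cds[i : i + 3]
            usage[codon] = usage.get(codon, 0) + 1
    total = sum(usage.values())
    freqs = np.array([usage.get(c, 0) / total for c in SENSE_CODONS])
    counts = 1 + rng.poisson(300 * freqs)
    if not coupled:
        counts = rng.permutation(counts)
    return TRNACountTable(
        species=species, counts={c: int(n) for c, n in zip(SENSE_CODONS, counts)}
    )


# ---------------------------------------------------------------------------
# On-disk emission


def write_trnascan(table: TRNACountTable, path: str | Path,
                   n_pseudo: int = 2, seed: int = 0) -> None:
    """Emit a tRNAscan-SE v2-style tabular file for a count table.

    Includes ``n_pseudo`` pseudogene rows and one undetermined-anticodon
    row, which readers must exclude.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for codon in sorted(table.counts):
        aa = standard_dna_table.forward_table[codon]
        anticodon = reverse_complement(codon)
        for _ in range(table.counts[codon]):
            rows.append((_AA3[aa], anticodon, ""))
    for _ in range(n_pseudo):
        rows.append(("Ala", "AGC", "pseudo"))
    rows.append(("Undet", "NNN", ""))
    with open(path, "w") as out:
        out.write("Sequence\t\ttRNA\tBounds\t\ttRNA\tAnti\tIntron Bounds\t\tInf\t\n")
        out.write("Name\ttRNA #\tBegin\tEnd\tType\tCodon\tBegin\tEnd\tScore\tNote\n")
        out.write("--------\t------\t-----\t----\t----\t-----\t-----\t----\t-----\t----\n")
        pos = 1000
        for i, (isotype, anticodon, note) in enumerate(rows, start=1):
            begin = pos + i * 200
            end = begin + 71
            score = 50.0 + float(rng.random()) * 30.0
            out.write(
                f"{table.species}\t{i}\t{begin}\t{end}\t{isotype}\t{anticodon}"
                f"\t0\t0\t{score:.1f}\t{note}\n"
            )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    """Write a dataset as standard files: per-species FASTA + GFF3, the
    species tree (Newick), orthogroup TSV, per-orthogroup aligned FASTA,
    tRNAscan-like tables, and the truth TSV."""
    outdir = Path(outdir)
    (outdir / "alignments").mkdir(parents=True, exist_ok=True)
    (outdir / "genomes").mkdir(exist_ok=True)
    (outdir / "trna").mkdir(exist_ok=True)
    for sp in ds.species:
        write_fasta(ds.assemblies[sp], outdir / "genomes" / f"{sp}.fasta")
        write_gff3(ds.genes[sp], outdir / "genomes" / f"{sp}.gff3")
        write_trnascan(
            ds.trna[sp], outdir / "trna" / f"{sp}.trnascan.tsv",
            seed=child_seed(ds.config.seed, f"trnascan:{sp}"),
        )
    (outdir / "species_tree.nwk").write_text(ds.tree.newick() + "\n")
    write_orthogroups(ds.orthogroups, outdir / "orthogroups.tsv")
    for og, aln in ds.alignments.items():
        write_fasta(
            [GenomeSequence(sp, row) for sp, row in sorted(aln.rows.items())],
            outdir / "alignments" / f"{og}.fasta",
        )
    ds.truth.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"species": ds.species, "base_gc3": [ds.base_gc3[s] for s in ds.species]}
    ).to_csv(outdir / "truth_species.tsv", sep="\t", index=False)
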