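"""Generator self-consistency: determinism, tree shape, trait simulation,
codon targeting and genome/annotation cross-validation."""

import filecmp
import math

import numpy as np
import pytest
from scipy import stats

from insect_gc import formats_io as fio
from insect_gc.gc_metrics import extract_cds, gc_fraction
from insect_gc.synthetic_data import (
    SyntheticConfig,
    child_seed,
    make_dataset,
    simulate_bm,
    simulate_sco_codons,
    simulate_tree,
    write_dataset,
)


class TestSimulateTree:
    def test_two_tips_shape(self):
        tree = simulate_tree(2, 1.0, 0)
        assert sorted(tree.tips) == ["sp01", "sp02"]
        depths = tree.tip_depths()
        assert all(d > 0 for d in depths.values())

    def test_determinism(self):
        assert simulate_tree(8, 1.0, 42).newick() == simulate_tree(8, 1.0, 42).newick()
        assert simulate_tree(8, 1.0, 42).newick() != simulate_tree(8, 1.0, 43).newick()

    def test_ultrametric_32_tips(self):
        depths = simulate_tree(32, 1.0, 5).tip_depths()
        assert len(depths) == 32
        assert max(depths.values()) - min(depths.values()) < 1e-9


class TestSimulateBm:
    def test_zero_variance_returns_root_everywhere(self):
        tree = simulate_tree(10, 1.0, 1)
        values = simulate_bm(tree, 0.42, 0.0, 7)
        assert all(v == 0.42 for v in values.values())

    def test_seed_reproducibility(self):
        tree = simulate_tree(6, 1.0, 2)
        assert simulate_bm(tree, 0.0, 1.0, 3) == simulate_bm(tree, 0.0, 1.0, 3)

    def test_star_tree_marginal_distribution(self):
        """On a star tree tips are i.i.d. Normal(root, sigma2 * depth)."""
        tree = fio.read_newick("(A:2,B:2,C:2,D:2);")
        draws = []
        for rep in range(1000):
            draws.append(simulate_bm(tree, 1.0, 0.5, 10_000 + rep)["A"])
        stat, p = stats.kstest(draws, "norm", args=(1.0, math.sqrt(0.5 * 2)))
        assert p > 0.01


class TestSimulateScoCodons:
    def test_target_zero_minimizes_gc3(self):
        rng = np.random.default_rng(0)
        codons, realized = simulate_sco_codons("ACDEFGHIKLNPQRSTVY", 0.0, rng)
        assert realized == 0.0  # no Met/Trp, so fully AT3-endable

    def test_target_one_maximizes_gc3(self):
        rng = np.random.default_rng(0)
        _, realized = simulate_sco_codons("ACDEFGHIKLMNPQRSTVWY", 1.0, rng)
        assert realized == 1.0

    def test_methionine_always_atg(self):
        rng = np.random.default_rng(0)
        codons, realized = simulate_sco_codons("M", 0.0, rng)
        assert codons == "ATG" and realized == 1.0  # clamped minimum

    def test_expected_gc3_matches_target_with_forced_sites(self):
        rng = np.random.default_rng(1)
        protein = "MW" + "K" * 98  # 2 forced GC3 sites out of 100
        realized = [simulate_sco_codons(protein, 0.30, rng)[1] for _ in range(200)]
        assert abs(np.mean(realized) - 0.30) < 0.01

    def test_invalid_residue_rejected(self):
        with pytest.raises(ValueError):
            simulate_sco_codons("MB", 0.5, np.random.default_rng(0))


class TestDatasetEmission:
    def test_gff_fasta_cross_validation(self, small_dataset):
        """Every CDS extracted from the generated FASTA translates without
        internal stop codons and ends with a stop."""
        for sp in small_dataset.species:
            genomes = {s.id: s for s in small_dataset.assemblies[sp]}
            for gene in small_dataset.genes[sp]:
                cds = extract_cds(genomes, gene)
                assert len(cds) % 3 == 0
                protein = fio.translate_cds(cds)
                assert protein.endswith("*")
                assert "*" not in protein[:-1]

    def test_truth_realized_gc3_matches_extracted_cds(self, small_dataset):
        from insect_gc.codon_alignment import gc3

        truth = small_dataset.truth
        for sp in small_dataset.species[:2]:
            genomes = {s.id: s for s in small_dataset.assemblies[sp]}
            for gene in small_dataset.genes[sp][:10]:
                og = gene.gene_id.split("_")[1]
                cds = extract_cds(genomes, gene)
                codons = [cds[i : i + 3] for i in range(0, len(cds) - 3, 3)]
                row = truth[(truth.species == sp) & (truth.og_id == og)].iloc[0]
                assert math.isclose(gc3(codons), row["realized_gc3"], abs_tol=1e-12)


def test_write_dataset_byte_determinism(tmp_path):
    config = SyntheticConfig(
        seed=3,
        n_species=2,
        n_chromosomes=2,
        chrom_length_range=(1_000_000, 1_200_000),
        gc_lambda=300_000.0,
        n_sco=5,
        protein_length_range=(100, 150),
    )
    dirs = []
    for name in ["a", "b"]:
        out = tmp_path / name
        write_dataset(make_dataset(config), out)
        dirs.append(out)
    mismatch = []
    for path in dirs[0].rglob("*"):
        if path.is_file():
            other = dirs[1] / path.relative_to(dirs[0])
            if not filecmp.cmp(path, other, shallow=False):
                mismatch.append(path.name)
    assert mismatch == []


@pytest.fixture()
def flat_config():
    return SyntheticConfig(
        seed=11,
        n_species=2,
        n_chromosomes=1,
        chrom_length_range=(1_000_000, 1_100_000),
        gc_far=0.30,
        gc_delta=0.0,
        n_sco=3,
        protein_length_range=(100, 120),
    )


class TestGradient:
    def test_delta_zero_background_matches_p_far(self, flat_config):
        ds = make_dataset(flat_config)
        chrom = ds.assemblies[ds.species[0]][0]
        gc, n = gc_fraction(chrom.residues)
        # intergenic dominates; binomial SE at n ~ 1e6 is ~5e-4
        assert abs(gc - 0.30) < 0.005

    def test_infinite_lambda_elevates_uniformly(self, flat_config):
        import dataclasses

        config = dataclasses.replace(
            flat_config, gc_delta=0.15, gc_lambda=math.inf, seed=12
        )
        ds = make_dataset(config)
        chrom = ds.assemblies[ds.species[0]][0]
        gc, _ = gc_fraction(chrom.residues)
        assert abs(gc - 0.45) < 0.005

    def test_chromosome_ends_exceed_centre(self):
        """With the gradient on, windowed GC at the chromosome ends exceeds
        central windows (direct window counting on raw sequence)."""
        config = SyntheticConfig(
            seed=13,
            n_species=2,
            n_chromosomes=1,
            chrom_length_range=(4_000_000, 4_200_000),
            gc_far=0.30,
            gc_delta=0.15,
            gc_lambda=400_000.0,
            n_sco=3,
            protein_length_range=(100, 120),
        )
        ds = make_dataset(config)
        chrom = ds.assemblies[ds.species[0]][0]
        window = 200_000
        end_gc = (
            gc_fraction(chrom.residues[:window])[0]
            + gc_fraction(chrom.residues[-window:])[0]
        ) / 2
        centre = chrom.length // 2
        centre_gc = gc_fraction(chrom.residues[centre - window : centre + window])[0]
        assert end_gc > centre_gc + 0.05


def test_child_seed_is_stable_and_in_range():
    assert child_seed(1, "tree") == child_seed(1, "tree")
    assert child_seed(1, "tree") != child_seed(1, "bm")
    assert 0 <= child_seed(123456, "genome:sp01") < 2**31
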