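import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lesionphylo import PipelineConfig
from lesionphylo.mav_detection import (
    classify_mav,
    find_multiallelic_sites,
    tip_alleles_from_counts,
)
from lesionphylo.phasing_loh import phase_pair
from lesionphylo.phylo_model import (
    assign_all_branches,
    read_count_matrix,
    read_phylogeny,
    read_variant_table,
)
from lesionphylo.pvv_detection import detect_pvvs
from lesionphylo.signature_analysis import CHANNELS, channel_of
from lesionphylo.synthetic_data import (
    MiniGenome,
    emit_phasing_evidence,
    emit_read_counts,
    generate_dataset,
    generate_genealogy,
    implant_persistent_lesion,
    sprinkle_mutations,
)


class TestGenerateGenealogy:
    def test_binary_tree_identity(self):
        t = generate_genealogy(8, seed=1, population_size=500)
        internal = [n for n in t.internal_nodes if len(t.children[n]) == 2]
        assert len(t.tips) == 8
        assert len(internal) == 7

    def test_deterministic(self):
        t1 = generate_genealogy(10, seed=4, population_size=500)
        t2 = generate_genealogy(10, seed=4, population_size=500)
        assert t1.to_newick() == t2.to_newick()

    def test_aged_topology_coalesces_early(self):
        # aged haematopoiesis: most coalescences near the root, long
        # terminal branches
        t = generate_genealogy(
            30, age_years=75.0, seed=2, population_size=2000
        )
        depth = max(t.molecular_time(tip) for tip in t.tips)
        internal_times = [
            t.molecular_time(n)
            for n in t.internal_nodes
            if n != t.root and len(t.children[n]) >= 2
        ]
        assert np.median(internal_times) < 0.25 * depth

    def test_too_few_tips(self):
        with pytest.raises(ValueError):
            generate_genealogy(2, seed=0)


@pytest.fixture(scope="module")
def sprinkle_setup():
    rng = np.random.default_rng(3)
    genome = MiniGenome.random(rng, length=30_000)
    tree = generate_genealogy(10, seed=3, population_size=500)
    return rng, genome, tree


class TestSprinkleMutations:
    @pytest.fixture
    def setup(self, sprinkle_setup):
        return sprinkle_setup

    def test_poisson_counts(self, setup):
        rng, genome, tree = setup
        sig = np.ones(96)
        total_years = sum(
            tree.length[n] for n in tree.parent if tree.parent[n]
        )
        counts = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            variants, _, mol = sprinkle_mutations(tree, 2.0, sig, genome, r)
            counts.append(len(variants))
        assert np.mean(counts) == pytest.approx(2.0 * total_years, rel=0.1)

    def test_zero_length_branch_no_mutations(self, setup):
        rng, genome, tree = setup
        t = tree.copy()
        tip = t.tips[0]
        t.length[tip] = 0.0
        t._time_cache.clear()
        variants, branches, mol = sprinkle_mutations(
            t, 5.0, np.ones(96), genome, np.random.default_rng(0)
        )
        assert branches.count(tip) == 0
        assert mol.length[tip] == 0.0

    def test_rate_must_be_positive(self, setup):
        rng, genome, tree = setup
        with pytest.raises(ValueError):
            sprinkle_mutations(
                tree, 0.0, np.ones(96), genome, np.random.default_rng(0)
            )

    def test_context_matches_reference(self, setup):
        rng, genome, tree = setup
        variants, _, _ = sprinkle_mutations(
            tree, 3.0, np.ones(96), genome, np.random.default_rng(5)
        )
        for _, v in variants.head(50).iterrows():
            assert genome.context_at(v["chrom"], v["pos"]) == v["context"]
            assert v["context"][1] == v["ref"]

    def test_channel_distribution_follows_signature(self, setup):
        rng, genome, tree = setup
        sig = np.zeros(96)
        # C>T at all 16 contexts, uniform
        for ch in CHANNELS:
            if "[C>T]" in ch:
                sig[CHANNELS.index(ch)] = 1.0
        variants, _, _ = sprinkle_mutations(
            tree, 10.0, sig, genome, np.random.default_rng(6)
        )
        folded = [
            channel_of(v["context"], v["ref"], v["alt"])
            for _, v in variants.iterrows()
        ]
        assert all("[C>T]" in ch for ch in folded)
        # chi-square against uniform across the 16 C>T contexts
        obs = pd.Series(folded).value_counts()
        chi = stats.chisquare(obs.reindex(
            [c for c in CHANNELS if "[C>T]" in c], fill_value=0
        ))
        assert chi.pvalue > 1e-4


class TestImplantAndRecover:
    def test_simple_mav_recovered(self, adult_dataset):
        ds = adult_dataset
        cfg = PipelineConfig()
        assignments = {
            a.variant_id: a.branch
            for a in assign_all_branches(ds.tree, ds.counts, cfg)
        }
        pairs = find_multiallelic_sites(ds.counts)
        by_rows = {}
        for p in pairs:
            alleles = tip_alleles_from_counts(p, ds.tree, ds.counts, cfg)
            classify_mav(p, ds.tree, assignments, tip_allele=alleles)
            by_rows[p.variant_ids] = p
        for lesion in ds.truth["lesions"]:
            if lesion["kind"] != "mav":
                continue
            key = tuple(lesion["variant_rows"])
            assert key in by_rows
            got = by_rows[key]
            assert got.category == lesion["expected_category"]
            assert got.lesion_node == lesion["lesion_node"]
            if got.category == "separated":
                assert got.mmld == pytest.approx(lesion["expected_mmld"])

    def test_pvv_recovered_with_exact_mmld(self, adult_dataset):
        ds = adult_dataset
        calls = {c.variant_id: c for c in detect_pvvs(ds.tree, ds.counts)}
        for lesion in ds.truth["lesions"]:
            if lesion["kind"] != "pvv":
                continue
            (row,) = lesion["variant_rows"]
            assert row in calls
            call = calls[row]
            assert call.status == "pass"
            assert call.lesion_node == lesion["lesion_node"]
            assert call.mmld == pytest.approx(lesion["expected_mmld"])

    def test_pvv_short_segment_rejected(self):
        rng = np.random.default_rng(1)
        genome = MiniGenome.random(rng, length=20_000)
        tree = generate_genealogy(10, seed=9, population_size=500)
        with pytest.raises(ValueError):
            implant_persistent_lesion(
                tree, "pvv", genome, rng, n_divisions=1
            )


class TestReadCounts:
    def test_carrier_vaf_near_half(self):
        rng = np.random.default_rng(0)
        samples = [f"S{i}" for i in range(40)]
        carriers = [frozenset(samples[:20])]
        mtr, dep = emit_read_counts(carriers, samples, rng, coverage=30)
        vaf = mtr[0, :20].sum() / dep[0, :20].sum()
        assert vaf == pytest.approx(0.5, abs=0.05)

    def test_noncarriers_almost_never_positive(self):
        rng = np.random.default_rng(1)
        samples = [f"S{i}" for i in range(50)]
        mtr, dep = emit_read_counts(
            [frozenset()], samples, rng, coverage=30
        )
        assert mtr.sum() == 0

    def test_seed_reproducibility(self):
        samples = ["A", "B", "C"]
        m1, d1 = emit_read_counts(
            [frozenset(["A"])], samples, np.random.default_rng(5)
        )
        m2, d2 = emit_read_counts(
            [frozenset(["A"])], samples, np.random.default_rng(5)
        )
        assert np.array_equal(m1, m2) and np.array_equal(d1, d2)

    def test_bad_coverage(self):
        with pytest.raises(ValueError):
            emit_read_counts([], [], np.random.default_rng(0), coverage=0)


class TestPhasingEvidence:
    def make_inputs(self, same_haplotype=True):
        rng = np.random.default_rng(2)
        genome = MiniGenome.random(rng, length=20_000)
        variants = pd.DataFrame(
            [
                {"chrom": "chr1", "pos": 5000, "ref": "C", "alt": "T"},
                {"chrom": "chr1", "pos": 5000, "ref": "C", "alt": "G"},
            ]
        )
        carriers = [frozenset(["A", "B"]), frozenset(["C", "D"])]
        haps = [0, 0 if same_haplotype else 1]
        samples = ["A", "B", "C", "D", "E"]
        return variants, carriers, haps, samples, genome, rng

    def test_same_haplotype_matches(self):
        variants, carriers, haps, samples, genome, rng = self.make_inputs(True)
        snps, obs = emit_phasing_evidence(
            variants, carriers, haps, samples, genome, rng,
            pairs_per_sample=8,
        )
        assert len(snps) == 1
        snp = snps.iloc[0]
        o1 = [
            (r["var_base"], r["snp_base"])
            for _, r in obs.iterrows()
            if r["sample"] in ("A", "B")
        ]
        o2 = [
            (r["var_base"], r["snp_base"])
            for _, r in obs.iterrows()
            if r["sample"] in ("C", "D")
        ]
        v = phase_pair(
            o1, o2, alt1="T", alt2="G", ref="C",
            snp_alleles=(snp["ref"], snp["alt"]),
        )
        assert v.result == "matching"

    def test_opposite_haplotypes_conflict(self):
        variants, carriers, haps, samples, genome, rng = self.make_inputs(False)
        snps, obs = emit_phasing_evidence(
            variants, carriers, haps, samples, genome, rng,
            pairs_per_sample=8,
        )
        snp = snps.iloc[0]
        o1 = [
            (r["var_base"], r["snp_base"])
            for _, r in obs.iterrows()
            if r["sample"] in ("A", "B") and r["var_base"] == "T"
        ]
        o2 = [
            (r["var_base"], r["snp_base"])
            for _, r in obs.iterrows()
            if r["sample"] in ("C", "D") and r["var_base"] == "G"
        ]
        v = phase_pair(
            o1, o2, alt1="T", alt2="G", ref="C",
            snp_alleles=(snp["ref"], snp["alt"]),
            mode="lcm",
        )
        assert v.result == "conflicting"

    def test_zero_snp_probability_uninformative(self):
        variants, carriers, haps, samples, genome, rng = self.make_inputs()
        snps, obs = emit_phasing_evidence(
            variants, carriers, haps, samples, genome, rng,
            snp_probability=0.0,
        )
        assert len(snps) == 0 and len(obs) == 0


class TestDatasetRoundTrip:
    def test_full_determinism(self):
        d1 = generate_dataset("fetal", seed=21)
        d2 = generate_dataset("fetal", seed=21)
        assert d1.tree.to_newick() == d2.tree.to_newick()
        assert np.array_equal(d1.counts.mtr, d2.counts.mtr)
        assert d1.truth == d2.truth

    def test_files_round_trip(self, tmp_path, adult_dataset):
        ds = adult_dataset
        ds.write(tmp_path)
        tree = read_phylogeny((tmp_path / "tree.nwk").read_text())
        assert sorted(tree.tips) == sorted(ds.tree.tips)
        variants = read_variant_table(tmp_path / "variants.tsv")
        assert len(variants) == len(ds.counts)
        mtr, samples = read_count_matrix(tmp_path / "mtr.tsv")
        assert samples == ds.counts.samples
        assert np.array_equal(mtr, ds.counts.mtr)
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert truth["seed"] == ds.truth["seed"]

    def test_unknown_preset(self):
        with pytest.raises(ValueError):
            generate_dataset("nope", seed=0)
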