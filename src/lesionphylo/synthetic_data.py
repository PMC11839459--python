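"""Self-contained synthetic fixtures with machine-readable ground truth.

Generates genealogies (via the stem-cell population simulator),
clock-like mutations with real trinucleotide contexts drawn from a
two-chromosome mini-genome, implanted persistent lesions in MAV- and
PVV-generating geometries, ~30x read counts with binomial allele
sampling, and heterozygous-SNP read-pair phasing evidence.  Everything
is deterministic under (config, seed) and the emitted truth suffices to
score detection without re-simulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from lesionphylo.abc_duration import (
    LineageTree,
    PopulationSimParams,
    induced_phylogeny,
    simulate_population,
)
from lesionphylo.config import PipelineConfig
from lesionphylo.phylo_model import Phylogeny, VariantCallMatrix
from lesionphylo.signature_analysis import BASES, CHANNELS, revcomp

__all__ = [
    "MiniGenome",
    "SyntheticDataset",
    "generate_genealogy",
    "sprinkle_mutations",
    "implant_persistent_lesion",
    "emit_read_counts",
    "emit_phasing_evidence",
    "generate_dataset",
    "PRESETS",
]


class MiniGenome:
    """A small random reference providing real trinucleotide contexts."""

    def __init__(self, chroms: dict[str, str]):
        self.chroms = chroms
        self._index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in chroms.items():
            for i in range(1, len(seq) - 1):
                tri = seq[i - 1:i + 2]
                self._index.setdefault(tri, []).append((name, i + 1))

    @classmethod
    def random(cls, rng: np.random.Generator, length: int = 60_000,
               n_chroms: int = 2) -> "MiniGenome":
        chroms = {
            f"chr{i + 1}": "".join(
                rng.choice(list(BASES), size=length)
            )
            for i in range(n_chroms)
        }
        return cls(chroms)

    def context_at(self, chrom: str, pos: int) -> str:
        seq = self.chroms[chrom]
        return seq[pos - 2:pos + 1]

    def sample_site(
        self, trinuc: str, rng: np.random.Generator,
        used: set[tuple[str, int]],
    ) -> tuple[str, int] | None:
        """A site whose reference-strand context equals ``trinuc``."""
        sites = self._index.get(trinuc, [])
        if not sites:
            return None
        for _ in range(50):
            chrom, pos = sites[int(rng.integers(len(sites)))]
            if (chrom, pos) not in used:
                used.add((chrom, pos))
                return chrom, pos
        return None

    def trinucleotide_frequencies(self) -> dict[str, float]:
        total = sum(len(v) for v in self._index.values())
        return {k: len(v) / total for k, v in self._index.items()}


def generate_genealogy(
    n_tips: int,
    age_years: float = 75.0,
    population_size: int = 2_000,
    fit_clones: tuple[tuple[float, float], ...] = (),
    seed: int = 0,
) -> Phylogeny:
    """Sampled stem-cell genealogy with real-time branch lengths."""
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    if n_tips > population_size:
        raise ValueError("cannot sample more tips than the population size")
    params = PopulationSimParams(
        population_size=population_size,
        age_years=age_years,
        growth_years=min(1.0, 0.5 * age_years),
        fit_clones=fit_clones,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    pop = simulate_population(params, rng)
    tips = rng.choice(pop.n_tips, size=n_tips, replace=False)
    phylo, _ = induced_phylogeny(pop, tips)
    return phylo


def _sample_channels(signature: np.ndarray, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    sig = np.asarray(signature, dtype=float)
    if sig.shape != (96,) or sig.sum() <= 0:
        raise ValueError("signature must be a positive 96-vector")
    return rng.choice(96, size=n, p=sig / sig.sum())


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _place_snv(channel: int, genome: MiniGenome, rng: np.random.Generator,
               used: set[tuple[str, int]]) -> dict | None:
    """Choose a genomic site and strand for a folded 96-channel SNV."""
    ch = CHANNELS[channel]
    ctx, ref, alt = ch[0] + ch[2] + ch[6], ch[2], ch[4]
    if rng.random() < 0.5:
        site = genome.sample_site(ctx, rng, used)
        if site is None:
            return None
        chrom, pos = site
        return {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                "vclass": "SNV", "context": ctx}
    rc = revcomp(ctx)
    site = genome.sample_site(rc, rng, used)
    if site is None:
        return None
    chrom, pos = site
    return {"chrom": chrom, "pos": pos, "ref": _COMPLEMENT[ref],
            "alt": _COMPLEMENT[alt], "vclass": "SNV", "context": rc}


def sprinkle_mutations(
    tree: Phylogeny,
    rate_per_year: float,
    signature: np.ndarray,
    genome: MiniGenome,
    rng: np.random.Generator,
    used_sites: set[tuple[str, int]] | None = None,
) -> tuple[pd.DataFrame, list[str], Phylogeny]:
    """Clock-like Poisson mutations on every branch.

    Returns (variant table, per-variant true branch, molecular-time tree
    whose branch lengths are the simulated mutation counts).
    """
    if rate_per_year <= 0:
        raise ValueError("mutation rate must be positive")
    used = used_sites if used_sites is not None else set()
    rows: list[dict] = []
    branches: list[str] = []
    mol = tree.copy()
    for node in tree.preorder():
        if tree.parent[node] is None:
            mol.length[node] = 0.0
            continue
        n_mut = rng.poisson(rate_per_year * tree.length[node])
        placed = 0
        for ch in _sample_channels(signature, n_mut, rng):
            rec = _place_snv(int(ch), genome, rng, used)
            if rec is None:
                continue
            rows.append(rec)
            branches.append(node)
            placed += 1
        mol.length[node] = float(placed)
    mol._time_cache.clear()
    return pd.DataFrame(rows), branches, mol


@dataclass
class LesionTruth:
    kind: str  # "mav" | "pvv"
    lesion_node: str
    repair_node: str
    path: list[str]
    expected_category: str  # simple | separated | unrelated | pass
    expected_mmld: float | None
    variant_rows: list[int]  # indices into the emitted variant table
    haplotype: int
    alleles: list[str]


def _enumerate_paths(tree: Phylogeny, n_divisions: int) -> list[list[str]]:
    """All chains of ``n_divisions`` consecutive parent/child coalescences."""
    multi = [n for n in tree.internal_nodes if len(tree.children[n]) >= 2]
    paths = [[n] for n in multi]
    for _ in range(n_divisions - 1):
        paths = [
            p + [c]
            for p in paths
            for c in tree.children[p[-1]]
            if len(tree.children[c]) >= 2
        ]
    return paths


def implant_persistent_lesion(
    tree: Phylogeny,
    kind: str,
    genome: MiniGenome,
    rng: np.random.Generator,
    n_divisions: int | None = None,
    haplotype: int = 0,
    used_sites: set[tuple[str, int]] | None = None,
    molecular_tree: Phylogeny | None = None,
) -> tuple[list[dict], list[frozenset[str]], LesionTruth]:
    """Implant one persistent lesion in MAV or PVV geometry.

    Returns (variant rows, per-variant carrier tip sets, truth record).
    MAV lesions span >= 1 division (1 division = simple geometry); PVV
    lesions span >= 2 divisions so a wild-type subclade separates the
    mutant ones.  Carriers of the two MAV alleles sit in the subclades
    shed at the ends of the path; intermediate subclades keep the
    reference allele.
    """
    if kind not in ("mav", "pvv"):
        raise ValueError("kind must be 'mav' or 'pvv'")
    if n_divisions is None:
        n_divisions = 1 if kind == "mav" else 2
    if kind == "mav" and n_divisions < 1:
        raise ValueError("a MAV lesion must span at least one division")
    if kind == "pvv" and n_divisions < 2:
        raise ValueError("a PVV lesion must span at least two divisions")
    paths = _enumerate_paths(tree, n_divisions)
    if not paths:
        raise ValueError(
            f"tree has no lesion path spanning {n_divisions} divisions"
        )
    used = used_sites if used_sites is not None else set()
    # draw a site uniformly over the genome
    chrom = list(genome.chroms)[int(rng.integers(len(genome.chroms)))]
    seq = genome.chroms[chrom]
    while True:
        pos = int(rng.integers(2, len(seq)))  # 1-based, with both flanks
        if (chrom, pos) not in used:
            break
    used.add((chrom, pos))
    ctx = genome.context_at(chrom, pos)
    ref = ctx[1]
    alts = [b for b in BASES if b != ref]
    rng.shuffle(alts)

    # choose a path and subclades; for PVVs prefer geometries whose
    # negative fraction within the lesion clade can move the rho screen
    # (a lone negative tip in a large clade is genuinely undetectable)
    order = list(range(len(paths)))
    rng.shuffle(order)
    choice = None
    fallback = None
    for pi in order:
        path = paths[pi]
        first, last = path[0], path[-1]
        down_child = {path[i]: path[i + 1] for i in range(len(path) - 1)}
        if len(path) == 1:
            kids = list(tree.children[first])
            combos = [
                (kids[a], kids[b])
                for a in range(len(kids))
                for b in range(len(kids))
                if a != b
            ]
        else:
            shed_first = [
                c for c in tree.children[first] if c != down_child[first]
            ]
            combos = [
                (sf, lk)
                for sf in shed_first
                for lk in tree.children[last]
            ]
        ci = list(range(len(combos)))
        rng.shuffle(ci)
        for k in ci:
            c1, c2 = combos[k]
            fc = tree.clade_tips(c1)
            lc = tree.clade_tips(c2)
            cand = (path, fc, lc)
            if fallback is None:
                fallback = cand
            if kind == "mav":
                choice = cand
                break
            total = len(tree.clade_tips(first))
            neg = total - len(fc) - len(lc)
            if total > 0 and 0.15 <= neg / total <= 0.85:
                choice = cand
                break
        if choice is not None:
            break
    if choice is None:
        choice = fallback
    path, first_clade, last_clade = choice
    first, last = path[0], path[-1]

    # reference-only subclades shed strictly between the ends
    n_ref_between = sum(
        len(tree.children[p]) - 1 for p in path[1:-1]
    )

    rows: list[dict] = []
    carriers: list[frozenset[str]] = []
    if kind == "mav":
        alt1, alt2 = alts[0], alts[1]
        rows.append({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt1,
                     "vclass": "SNV", "context": ctx})
        carriers.append(first_clade)
        rows.append({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt2,
                     "vclass": "SNV", "context": ctx})
        carriers.append(last_clade)
        if n_divisions == 1:
            category = "simple"
        elif n_ref_between >= 2:
            category = "unrelated"
        else:
            category = "separated"
        alleles = [alt1, alt2]
    else:
        alt = alts[0]
        rows.append({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                     "vclass": "SNV", "context": ctx})
        carriers.append(frozenset(first_clade | last_clade))
        category = "pass"
        alleles = [alt]

    mol = molecular_tree if molecular_tree is not None else tree
    mmld = mol.path_length(first, last) if n_divisions > 1 else 0.0
    truth = LesionTruth(
        kind=kind,
        lesion_node=first,
        repair_node=last,
        path=path,
        expected_category=category,
        expected_mmld=mmld,
        variant_rows=[],
        haplotype=haplotype,
        alleles=alleles,
    )
    return rows, carriers, truth


def emit_read_counts(
    carriers: list[frozenset[str]],
    samples: list[str],
    rng: np.random.Generator,
    coverage: float = 30.0,
    error_rate: float = 1e-6,
    het_vaf: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson depth and binomial variant reads per variant x sample."""
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    n_var, n_smp = len(carriers), len(samples)
    dep = rng.poisson(coverage, size=(n_var, n_smp))
    p = np.full((n_var, n_smp), error_rate)
    for i, carrier_set in enumerate(carriers):
        for j, s in enumerate(samples):
            if s in carrier_set:
                p[i, j] = het_vaf
    mtr = rng.binomial(dep, p)
    return mtr, dep


def emit_phasing_evidence(
    variant_rows: pd.DataFrame,
    carriers: list[frozenset[str]],
    haplotypes: list[int],
    samples: list[str],
    genome: MiniGenome,
    rng: np.random.Generator,
    snp_probability: float = 1.0,
    pairs_per_sample: int = 4,
    error_rate: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Heterozygous SNPs within 1 kb plus read-pair observations.

    Each variant's haplotype determines which SNP allele its reads
    co-occur with; carrier samples also yield reference read pairs from
    the opposite haplotype, and non-carriers yield reference pairs from
    both.
    """
    snp_rows: list[dict] = []
    obs_rows: list[dict] = []
    snp_at: dict[tuple[str, int], tuple[int, str, str]] = {}
    for i, (_, var) in enumerate(variant_rows.iterrows()):
        key = (str(var["chrom"]), int(var["pos"]))
        if key not in snp_at:
            if rng.random() > snp_probability:
                continue
            offset = int(rng.integers(50, 1000))
            if rng.random() < 0.5:
                offset = -offset
            snp_pos = max(2, key[1] + offset)
            seq = genome.chroms[key[0]]
            snp_ref = seq[min(snp_pos, len(seq)) - 1]
            snp_alt = rng.choice([b for b in BASES if b != snp_ref])
            snp_at[key] = (snp_pos, snp_ref, str(snp_alt))
            snp_rows.append(
                {"chrom": key[0], "pos": snp_pos, "ref": snp_ref,
                 "alt": str(snp_alt)}
            )
        snp_pos, snp_ref, snp_alt = snp_at[key]
        # haplotype 0 carries the SNP ref allele, haplotype 1 the alt
        hap_base = {0: snp_ref, 1: snp_alt}
        var_hap = haplotypes[i]
        for s in samples:
            is_carrier = s in carriers[i]
            for _ in range(pairs_per_sample):
                if is_carrier and rng.random() < 0.5:
                    var_base, snp_base = str(var["alt"]), hap_base[var_hap]
                else:
                    other = 1 - var_hap if is_carrier else int(rng.random() < 0.5)
                    var_base, snp_base = str(var["ref"]), hap_base[other]
                if error_rate > 0 and rng.random() < error_rate:
                    snp_base = hap_base[0] if snp_base == hap_base[1] else hap_base[1]
                obs_rows.append(
                    {"sample": s, "chrom": key[0], "var_pos": key[1],
                     "var_base": var_base, "snp_pos": snp_pos,
                     "snp_base": snp_base}
                )
    return pd.DataFrame(snp_rows), pd.DataFrame(obs_rows)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

PRESETS = {
    "adult-hspc": dict(
        n_tips=40, age_years=75.0, rate_per_year=15.0,
        n_mav_simple=2, n_mav_separated=1, n_pvv=3,
    ),
    "fetal": dict(
        n_tips=30, age_years=0.75, rate_per_year=60.0,
        n_mav_simple=1, n_mav_separated=0, n_pvv=1,
    ),
    "chemo": dict(
        n_tips=30, age_years=50.0, rate_per_year=40.0,
        n_mav_simple=3, n_mav_separated=2, n_pvv=4,
    ),
    "bronchus-apobec": dict(
        n_tips=20, age_years=60.0, rate_per_year=25.0,
        n_mav_simple=3, n_mav_separated=1, n_pvv=1,
    ),
}


@dataclass
class SyntheticDataset:
    tree_realtime: Phylogeny
    tree: Phylogeny  # molecular time (mutation counts)
    counts: VariantCallMatrix
    het_snps: pd.DataFrame
    read_pairs: pd.DataFrame
    truth: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "tree.nwk").write_text(self.tree.to_newick() + "\n")
        (outdir / "tree_realtime.nwk").write_text(
            self.tree_realtime.to_newick() + "\n"
        )
        self.counts.variants.to_csv(
            outdir / "variants.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            self.counts.mtr, columns=self.counts.samples
        ).to_csv(outdir / "mtr.tsv", sep="\t", index_label="variant")
        pd.DataFrame(
            self.counts.dep, columns=self.counts.samples
        ).to_csv(outdir / "dep.tsv", sep="\t", index_label="variant")
        self.het_snps.to_csv(outdir / "snps.tsv", sep="\t", index=False)
        self.read_pairs.to_csv(outdir / "readpairs.tsv", sep="\t", index=False)
        (outdir / "truth.json").write_text(json.dumps(self.truth, indent=2))


def generate_dataset(
    preset: str = "adult-hspc",
    seed: int = 0,
    coverage: float = 30.0,
    signature: np.ndarray | None = None,
    **overrides,
) -> SyntheticDataset:
    """Generate a full synthetic dataset with ground truth."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}")
    cfg = dict(PRESETS[preset])
    cfg.update(overrides)
    rng = np.random.default_rng(seed)
    genome = MiniGenome.random(rng)
    if signature is None:
        signature = np.ones(96)

    tree_rt = generate_genealogy(
        cfg["n_tips"], age_years=cfg["age_years"], seed=seed
    )
    used: set[tuple[str, int]] = set()
    variants, true_branches, tree_mol = sprinkle_mutations(
        tree_rt, cfg["rate_per_year"], signature, genome, rng, used_sites=used
    )
    carriers: list[frozenset[str]] = [
        tree_rt.clade_tips(b) for b in true_branches
    ]
    rows = variants.to_dict("records")
    haplotypes = [int(rng.integers(2)) for _ in rows]

    lesion_truths: list[LesionTruth] = []

    def add_lesion(kind: str, n_div: int) -> None:
        lrows, lcarriers, truth = implant_persistent_lesion(
            tree_mol, kind, genome, rng, n_divisions=n_div,
            haplotype=0, used_sites=used, molecular_tree=tree_mol,
        )
        truth.variant_rows = list(
            range(len(rows), len(rows) + len(lrows))
        )
        rows.extend(lrows)
        carriers.extend(lcarriers)
        haplotypes.extend([truth.haplotype] * len(lrows))
        lesion_truths.append(truth)

    for _ in range(cfg["n_mav_simple"]):
        add_lesion("mav", 1)
    for _ in range(cfg["n_mav_separated"]):
        add_lesion("mav", 2)
    for _ in range(cfg["n_pvv"]):
        add_lesion("pvv", 2)

    variants = pd.DataFrame(rows)
    samples = sorted(tree_mol.tips)
    mtr, dep = emit_read_counts(carriers, samples, rng, coverage=coverage)
    counts = VariantCallMatrix(
        variants=variants, mtr=mtr, dep=dep, samples=samples
    )
    # phasing evidence only for lesion variants (the clock-like bulk
    # never enters the phasing module)
    lesion_idx = [i for t in lesion_truths for i in t.variant_rows]
    het_snps, read_pairs = emit_phasing_evidence(
        variants.iloc[lesion_idx].reset_index(drop=True),
        [carriers[i] for i in lesion_idx],
        [haplotypes[i] for i in lesion_idx],
        samples, genome, rng,
    )
    truth = {
        "seed": seed,
        "preset": preset,
        "config": {k: v for k, v in cfg.items()},
        "true_branch": true_branches + [None] * (len(rows) - len(true_branches)),
        "haplotypes": haplotypes,
        "lesions": [
            {
                "kind": t.kind,
                "lesion_node": t.lesion_node,
                "repair_node": t.repair_node,
                "path": t.path,
                "expected_category": t.expected_category,
                "expected_mmld": t.expected_mmld,
                "variant_rows": t.variant_rows,
                "haplotype": t.haplotype,
                "alleles": t.alleles,
            }
            for t in lesion_truths
        ],
    }
    return SyntheticDataset(
        tree_realtime=tree_rt,
        tree=tree_mol,
        counts=counts,
        het_snps=het_snps,
        read_pairs=read_pairs,
        truth=truth,
    )
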