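"""Read-pair phasing against nearby germline heterozygous SNPs.

Phasing evidence is consumed from a pre-extracted observation table
(sample, chrom, var_pos, var_base, snp_pos, snp_base) rather than raw
alignments, keeping the module testable without BAM files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

__all__ = [
    "PhasingVerdict",
    "find_phasing_snps",
    "phase_pair",
    "phase_pvv_subclades",
    "read_based_loh_check",
    "binomial_matching_test",
    "extract_read_pairs",
    "read_observation_table",
]

MAX_SNP_DISTANCE = 1000  # closed interval, bp

MATCHING, CONFLICTING, UNINFORMATIVE = "matching", "conflicting", "uninformative"


@dataclass
class PhasingVerdict:
    result: str  # matching | conflicting | uninformative
    mode: str  # clonal | lcm
    evidence: dict = field(default_factory=dict)


def read_observation_table(path_or_buf) -> pd.DataFrame:
    df = pd.read_csv(path_or_buf, sep="\t", dtype={"chrom": str})
    required = {"sample", "chrom", "var_pos", "var_base", "snp_pos", "snp_base"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"observation table missing columns: {sorted(missing)}")
    return df


def find_phasing_snps(
    variant_chrom: str, variant_pos: int, het_snps: pd.DataFrame
) -> pd.DataFrame:
    """Heterozygous SNPs within 1 kb (closed) of the variant locus."""
    sel = (het_snps["chrom"].astype(str) == str(variant_chrom)) & (
        (het_snps["pos"] - int(variant_pos)).abs() <= MAX_SNP_DISTANCE
    )
    return het_snps.loc[sel].reset_index(drop=True)


def _other_allele(base: str, snp_alleles: tuple[str, str]) -> str | None:
    a, b = snp_alleles
    if base == a:
        return b
    if base == b:
        return a
    return None


def _haplotype_support(
    observations: Iterable[tuple[str, str]],
    variant_base: str,
    ref_base: str,
    snp_alleles: tuple[str, str],
    mode: str,
) -> set[str]:
    """SNP alleles on the haplotype inferred to carry ``variant_base``.

    Direct evidence: read pairs carrying the variant base phase it to the
    observed SNP base.  Reference evidence (clonal samples only): read
    pairs carrying the reference base place the variant on the
    complementary SNP allele.
    """
    support: set[str] = set()
    for var_b, snp_b in observations:
        if snp_b not in snp_alleles:
            continue
        if var_b == variant_base:
            support.add(snp_b)
        elif mode == "clonal" and var_b == ref_base:
            other = _other_allele(snp_b, snp_alleles)
            if other is not None:
                support.add(other)
    return support


def phase_pair(
    obs_alt1: Sequence[tuple[str, str]],
    obs_alt2: Sequence[tuple[str, str]],
    alt1: str,
    alt2: str,
    ref: str,
    snp_alleles: tuple[str, str],
    mode: str = "clonal",
) -> PhasingVerdict:
    """Phase the two mutant alleles of a MAV against one het SNP.

    ``obs_alt*`` hold (variant-locus base, SNP-locus base) read-pair
    observations from samples carrying the respective alt.  In ``lcm``
    mode only direct variant-base evidence counts, because reference
    reads may come from contaminating normal cells.
    """
    if mode not in ("clonal", "lcm"):
        raise ValueError(f"unknown phasing mode {mode!r}")
    h1 = _haplotype_support(obs_alt1, alt1, ref, snp_alleles, mode)
    h2 = _haplotype_support(obs_alt2, alt2, ref, snp_alleles, mode)
    evidence = {"alt1_support": sorted(h1), "alt2_support": sorted(h2),
                "n_obs_alt1": len(obs_alt1), "n_obs_alt2": len(obs_alt2)}
    if not h1 or not h2:
        return PhasingVerdict(UNINFORMATIVE, mode, evidence)
    if h1 & h2:
        return PhasingVerdict(MATCHING, mode, evidence)
    return PhasingVerdict(CONFLICTING, mode, evidence)


def phase_pvv_subclades(
    subclade_obs: dict[str, Sequence[tuple[str, str]]],
    alt: str,
    ref: str,
    snp_alleles: tuple[str, str],
    mode: str = "clonal",
) -> PhasingVerdict:
    """Pairwise phasing across the positive subclades of a PVV.

    Matching if any subclade pair phases to the same SNP allele;
    conflicting if some pair demonstrably differs and none match;
    uninformative with fewer than two evidenced subclades.
    """
    supports = {
        name: _haplotype_support(obs, alt, ref, snp_alleles, mode)
        for name, obs in subclade_obs.items()
    }
    informative = {k: v for k, v in supports.items() if v}
    evidence = {"subclade_support": {k: sorted(v) for k, v in supports.items()}}
    if len(informative) < 2:
        return PhasingVerdict(UNINFORMATIVE, mode, evidence)
    names = sorted(informative)
    any_match = any_conflict = False
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            sa, sb = informative[names[a]], informative[names[b]]
            if sa & sb:
                any_match = True
            else:
                any_conflict = True
    if any_match:
        return PhasingVerdict(MATCHING, mode, evidence)
    if any_conflict:
        return PhasingVerdict(CONFLICTING, mode, evidence)
    return PhasingVerdict(UNINFORMATIVE, mode, evidence)


def read_based_loh_check(
    negative_subclade_obs: Sequence[tuple[str, str]],
    phased_snp_base: str,
    ref_base: str,
    depth: int,
    min_depth: int = 13,
) -> str:
    """Check negative-subclade reads for the mutation-bearing chromosome.

    ``no_loh`` when the negative subclade carries read pairs reporting
    the SNP allele phased with the mutation together with the reference
    base at the variant locus; ``loh`` when no such read exists despite
    adequate depth; ``unassessable`` otherwise.
    """
    supporting = sum(
        1
        for var_b, snp_b in negative_subclade_obs
        if snp_b == phased_snp_base and var_b == ref_base
    )
    if supporting >= 1:
        return "no_loh"
    if depth >= min_depth:
        return "loh"
    return "unassessable"


def extract_read_pairs(
    bam_path,
    sample: str,
    chrom: str,
    var_pos: int,
    snp_pos: int,
    min_base_quality: int = 20,
) -> pd.DataFrame:
    """Optional convenience: pull read-pair observations from a BAM.

    Emits one row per read pair covering both loci, in the observation
    table schema.  Tests never rely on this path; pre-extracted tables
    are the supported input.
    """
    import pysam

    lo, hi = min(var_pos, snp_pos), max(var_pos, snp_pos)
    by_name: dict[str, dict[int, str]] = {}
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for read in bam.fetch(chrom, lo - 1, hi):
            if read.is_secondary or read.is_supplementary or read.is_duplicate:
                continue
            bases = by_name.setdefault(read.query_name, {})
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                if rpos + 1 in (var_pos, snp_pos):
                    if read.query_qualities[qpos] < min_base_quality:
                        continue
                    bases[rpos + 1] = read.query_sequence[qpos].upper()
    rows = [
        {"sample": sample, "chrom": chrom, "var_pos": var_pos,
         "var_base": bases[var_pos], "snp_pos": snp_pos,
         "snp_base": bases[snp_pos]}
        for bases in by_name.values()
        if var_pos in bases and snp_pos in bases
    ]
    return pd.DataFrame(
        rows,
        columns=["sample", "chrom", "var_pos", "var_base", "snp_pos",
                 "snp_base"],
    )


def binomial_matching_test(n_matching: int, n_total: int) -> float:
    """Exact two-sided binomial test against p = 0.5.

    Two-sidedness by doubling the smaller tail, capped at 1.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_matching <= n_total:
        raise ValueError("n_matching must be within [0, n_total]")
    lower = stats.binom.cdf(n_matching, n_total, 0.5)
    upper = stats.binom.sf(n_matching - 1, n_total, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))
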