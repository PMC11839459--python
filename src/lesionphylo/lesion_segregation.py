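"""Per-branch strand-asymmetry (lesion segregation) testing.

For each phylogeny branch, the reference-strand orientation of the
mutated pyrimidine defines a binary sequence ordered by genomic
position.  Segregation of many same-cycle lesions with parental strands
shows up as long runs of one state, detected by a binomial test, a
Wald-Wolfowitz runs test and the rl20 run-length statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from lesionphylo.phasing_loh import binomial_matching_test

__all__ = [
    "StrandSequence",
    "SegregationResult",
    "strand_states",
    "runs_test",
    "rl20",
    "test_branches",
    "benjamini_hochberg",
]


@dataclass
class StrandSequence:
    """Ordered strand states (+/-) per chromosome with positions."""

    chromosomes: dict[str, np.ndarray]  # chrom -> array of +1/-1, position order

    @property
    def n_mutations(self) -> int:
        return sum(len(v) for v in self.chromosomes.values())

    def flat(self) -> np.ndarray:
        return np.concatenate(
            [self.chromosomes[c] for c in sorted(self.chromosomes)]
        ) if self.chromosomes else np.array([], dtype=int)


@dataclass
class SegregationResult:
    branch: str
    n_mutations: int
    binomial_p: float
    runs_p: float
    rl20: int
    binomial_q: float | None = None
    runs_q: float | None = None
    positive: bool | None = None
    skipped: bool = False


def strand_states(variants: pd.DataFrame) -> StrandSequence:
    """Strand state per SNV: '+' when the reference base is a pyrimidine.

    Requires columns chrom, pos, ref; rows are sorted by position within
    each chromosome.
    """
    bad = variants.loc[~variants["ref"].isin(list("ACGT"))]
    if len(bad) or (variants["ref"].str.len() != 1).any():
        raise ValueError("strand states are defined for SNVs only")
    chroms: dict[str, np.ndarray] = {}
    for chrom, grp in variants.groupby("chrom"):
        grp = grp.sort_values("pos")
        chroms[str(chrom)] = np.where(grp["ref"].isin(["C", "T"]), 1, -1)
    return StrandSequence(chromosomes=chroms)


def _runs(seq: np.ndarray) -> list[int]:
    """Run lengths of a +/-1 sequence."""
    if len(seq) == 0:
        return []
    change = np.flatnonzero(np.diff(seq) != 0)
    bounds = np.concatenate([[-1], change, [len(seq) - 1]])
    return list(np.diff(bounds))


def runs_test(seq: np.ndarray) -> float:
    """Two-sided Wald-Wolfowitz runs test (normal approximation).

    Uses mean 1 + 2*n1*n2/n and the standard variance; runs never span
    chromosome boundaries when called through :func:`test_branches`.
    """
    seq = np.asarray(seq)
    n1 = int((seq > 0).sum())
    n2 = int((seq < 0).sum())
    n = n1 + n2
    if n < 2 or n1 == 0 or n2 == 0:
        raise ValueError("runs test needs both states present")
    r = len(_runs(seq))
    mean = 1.0 + 2.0 * n1 * n2 / n
    var = (2.0 * n1 * n2 * (2.0 * n1 * n2 - n)) / (n**2 * (n - 1.0))
    if var <= 0:
        return 1.0
    z = (r - mean) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def rl20(strand_seq: StrandSequence) -> int:
    """Run-length statistic: shortest run among the longest runs that
    jointly cover at least 20% of all mutations.

    Runs are counted per chromosome (never across boundaries), pooled,
    and sorted by decreasing length.
    """
    all_runs: list[int] = []
    for seq in strand_seq.chromosomes.values():
        all_runs.extend(_runs(seq))
    total = sum(all_runs)
    if total == 0:
        raise ValueError("empty strand sequence")
    target = 0.2 * total
    acc = 0
    for length in sorted(all_runs, reverse=True):
        acc += length
        if acc >= target:
            return int(length)
    return int(min(all_runs))  # unreachable: runs sum to total


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def test_branches(
    branch_variants: dict[str, pd.DataFrame],
    min_mutations: int = 20,
    rl20_threshold: int = 6,
    alpha: float = 0.05,
) -> tuple[list[SegregationResult], list[str]]:
    """Run all three statistics per branch with BH adjustment per family.

    A branch is positive when rl20 >= 6 and at least one of the
    binomial or runs tests has BH-adjusted p < 0.05.  Branches with
    fewer than ``min_mutations`` SNVs are skipped and reported.
    """
    results: list[SegregationResult] = []
    skipped: list[str] = []
    for branch in sorted(branch_variants):
        variants = branch_variants[branch]
        if len(variants) < min_mutations:
            skipped.append(branch)
            continue
        ss = strand_states(variants)
        flat = ss.flat()
        n_plus = int((flat > 0).sum())
        binom_p = _adjacent_agreement_test(ss)
        if n_plus in (0, len(flat)):
            runs_p = 0.0  # single-state genome-wide: maximal run deficit
        else:
            # runs test within chromosomes: pool z via concatenation of
            # per-chromosome sequences with boundaries respected
            runs_p = _runs_test_by_chromosome(ss)
        results.append(
            SegregationResult(
                branch=branch,
                n_mutations=len(flat),
                binomial_p=binom_p,
                runs_p=runs_p,
                rl20=rl20(ss),
            )
        )
    if results:
        bq = benjamini_hochberg(np.array([r.binomial_p for r in results]))
        rq = benjamini_hochberg(np.array([r.runs_p for r in results]))
        for r, b, q in zip(results, bq, rq):
            r.binomial_q = float(b)
            r.runs_q = float(q)
            r.positive = r.rl20 >= rl20_threshold and (
                r.binomial_q < alpha or r.runs_q < alpha
            )
    return results, skipped


def _adjacent_agreement_test(ss: StrandSequence) -> float:
    """Two-sided binomial test of same-strand agreement between adjacent
    mutations (within chromosomes) against 0.5.

    Unlike a test of the global +/- balance, adjacent-pair agreement
    detects chromosome-scale strand blocks even when the genome-wide
    strand counts are balanced.
    """
    same = total = 0
    for seq in ss.chromosomes.values():
        if len(seq) < 2:
            continue
        agree = seq[1:] == seq[:-1]
        same += int(agree.sum())
        total += len(agree)
    if total == 0:
        return 1.0
    return binomial_matching_test(same, total)


def _runs_test_by_chromosome(ss: StrandSequence) -> float:
    """Runs test pooled over chromosomes without crossing boundaries.

    Observed runs are summed per chromosome; the null mean and variance
    are additive over chromosomes (minus the per-chromosome constants),
    giving a single pooled z.
    """
    total_r = 0.0
    total_mean = 0.0
    total_var = 0.0
    for seq in ss.chromosomes.values():
        n1 = int((seq > 0).sum())
        n2 = int((seq < 0).sum())
        n = n1 + n2
        if n == 0:
            continue
        total_r += len(_runs(seq))
        if n1 == 0 or n2 == 0 or n < 2:
            total_mean += 1.0
            continue
        total_mean += 1.0 + 2.0 * n1 * n2 / n
        total_var += (2.0 * n1 * n2 * (2.0 * n1 * n2 - n)) / (n**2 * (n - 1.0))
    if total_var <= 0:
        return 1.0
    z = (total_r - total_mean) / np.sqrt(total_var)
    return float(2.0 * stats.norm.sf(abs(z)))
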