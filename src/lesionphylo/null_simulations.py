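"""Null models for artefactual MAV/PVV generation.

Two mechanisms can mimic persistent-lesion variants: independent
co-occurring mutations at the same locus, and somatic reversion of an
existing mutation.  Both are simulated through the *same* detection code
paths as the real pipeline so that calibration and detection cannot
drift apart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from lesionphylo.config import PipelineConfig
from lesionphylo.mav_detection import MavPair, classify_mav
from lesionphylo.phylo_model import Phylogeny, _branch_model
from lesionphylo.pvv_detection import (
    find_lesion_node,
    screen_variant,
    walk_lesion_path,
)

__all__ = [
    "NullSimConfig",
    "NullOutcome",
    "sample_branch_pairs",
    "enumerate_branch_pair_proportions",
    "simulate_independent_pvv",
    "simulate_reversion",
    "weighted_contamination",
]

MAV_CATEGORIES = ("simple", "separated", "unrelated")
PVV_CATEGORIES = ("terminal", "not_detected", "fail", "pass")


@dataclass
class NullSimConfig:
    reps_mav: int = 50_000
    reps_pvv: int = 10_000
    reps_reversion: int = 2_000
    mean_depth: float = 30.0
    error_rate: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.reps_mav, self.reps_pvv, self.reps_reversion) <= 0:
            raise ValueError("replicate counts must be positive")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")


@dataclass
class NullOutcome:
    category: str
    mmld: float | None = None


def _positive_length_branches(tree: Phylogeny) -> tuple[list[str], np.ndarray]:
    branches = [
        n for n in sorted(tree.parent) if tree.parent[n] is not None
        and tree.length[n] > 0
    ]
    weights = np.array([tree.length[b] for b in branches], dtype=float)
    return branches, weights


def _classify_pair_cached(
    tree: Phylogeny, b1: str, b2: str, cache: dict
) -> str:
    key = (b1, b2) if b1 <= b2 else (b2, b1)
    if key not in cache:
        pair = MavPair(variant_ids=(0, 1))
        pair = classify_mav(pair, tree, {0: key[0], 1: key[1]})
        cache[key] = pair.category
    return cache[key]


def sample_branch_pairs(
    tree: Phylogeny, n: int, seed: int | None = None
) -> dict[str, float]:
    """Monte-Carlo proportions of MAV categories for random branch pairs.

    Unordered pairs of *distinct* branches are drawn with probability
    proportional to the product of branch lengths (two independent
    length-weighted draws, rejecting self-pairs), then classified with
    the real MAV classifier including the two-or-more intervening
    reference-subclade reclassification.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    branches, weights = _positive_length_branches(tree)
    if len(branches) < 2:
        raise ValueError("need >= 2 branches with positive length")
    rng = np.random.default_rng(seed)
    probs = weights / weights.sum()
    cache: dict = {}
    counts = {c: 0 for c in MAV_CATEGORIES}
    done = 0
    while done < n:
        batch = min(n - done, 10_000)
        a = rng.choice(len(branches), size=2 * batch, p=probs)
        i, j = a[:batch], a[batch:]
        for bi, bj in zip(i, j):
            if bi == bj:
                continue  # rejected self-pair; redrawn by the outer loop
            counts[_classify_pair_cached(tree, branches[bi], branches[bj], cache)] += 1
            done += 1
            if done == n:
                break
    return {c: counts[c] / n for c in MAV_CATEGORIES}


def enumerate_branch_pair_proportions(tree: Phylogeny) -> dict[str, float]:
    """Exact product-weight enumeration over all distinct branch pairs."""
    branches, weights = _positive_length_branches(tree)
    if len(branches) < 2:
        raise ValueError("need >= 2 branches with positive length")
    cache: dict = {}
    mass = {c: 0.0 for c in MAV_CATEGORIES}
    for a in range(len(branches)):
        for b in range(a + 1, len(branches)):
            w = weights[a] * weights[b]
            mass[_classify_pair_cached(tree, branches[a], branches[b], cache)] += w
    total = sum(mass.values())
    return {c: mass[c] / total for c in MAV_CATEGORIES}


# ---------------------------------------------------------------------------
# PVV null simulations
# ---------------------------------------------------------------------------


def _simulate_counts(
    tree: Phylogeny,
    samples: list[str],
    positive: set[str],
    rng: np.random.Generator,
    null_config: NullSimConfig,
    pipeline_config: PipelineConfig,
) -> tuple[np.ndarray, np.ndarray]:
    dep = rng.poisson(null_config.mean_depth, size=len(samples))
    p = np.where(
        [s in positive for s in samples],
        pipeline_config.het_vaf,
        null_config.error_rate,
    )
    mtr = rng.binomial(dep, p)
    return mtr, dep


def _run_detection_once(
    tree: Phylogeny,
    positive: set[str],
    rng: np.random.Generator,
    null_config: NullSimConfig,
    pipeline_config: PipelineConfig,
) -> NullOutcome:
    model = _branch_model(tree, sorted(tree.tips))
    samples = model.samples
    mtr, dep = _simulate_counts(tree, samples, positive, rng, null_config,
                                pipeline_config)
    if not dep.any():
        return NullOutcome("not_detected")
    ll = model.loglik(mtr, dep, pipeline_config)
    branch = model.branches[int(np.argmax(ll))]
    if tree.is_tip(branch):
        return NullOutcome("terminal")
    cand = screen_variant(tree, samples, mtr, dep, branch, pipeline_config)
    if cand is None:
        return NullOutcome("not_detected")
    lesion = find_lesion_node(cand, tree)
    call = walk_lesion_path(cand, lesion, tree)
    if call.status == "pass":
        return NullOutcome("pass", mmld=call.mmld)
    return NullOutcome("fail")


def simulate_independent_pvv(
    tree: Phylogeny,
    null_config: NullSimConfig | None = None,
    pipeline_config: PipelineConfig | None = None,
    reps: int | None = None,
) -> list[NullOutcome]:
    """Simulate PVV-like patterns from two independent mutations.

    Per replicate two distinct branches are drawn length-weighted, every
    tip in either clade is a carrier, per-sample depths are Poisson and
    variant reads binomial (het VAF inside, error rate outside), and the
    full assign / screen / walk pipeline classifies the outcome.
    """
    null_config = null_config or NullSimConfig()
    pipeline_config = pipeline_config or PipelineConfig()
    reps = reps if reps is not None else null_config.reps_pvv
    rng = np.random.default_rng(null_config.seed)
    branches, weights = _positive_length_branches(tree)
    if len(branches) < 2:
        raise ValueError("need >= 2 branches with positive length")
    probs = weights / weights.sum()
    out = []
    for _ in range(reps):
        while True:
            a, b = rng.choice(len(branches), size=2, p=probs)
            if a != b:
                break
        positive = set(tree.clade_tips(branches[a])) | set(
            tree.clade_tips(branches[b])
        )
        out.append(
            _run_detection_once(tree, positive, rng, null_config, pipeline_config)
        )
    return out


def simulate_reversion(
    tree: Phylogeny,
    null_config: NullSimConfig | None = None,
    pipeline_config: PipelineConfig | None = None,
    reps: int | None = None,
) -> list[NullOutcome]:
    """Simulate PVV-like patterns from somatic reversion.

    The mutation branch is drawn with probability proportional to
    (branch length x total descendant branch length); the reversion
    branch is drawn length-weighted from within the mutation clade.
    Carriers are the mutation clade minus the reversion clade.
    """
    null_config = null_config or NullSimConfig()
    pipeline_config = pipeline_config or PipelineConfig()
    reps = reps if reps is not None else null_config.reps_reversion
    rng = np.random.default_rng(null_config.seed)

    def descendant_branches(node: str) -> list[str]:
        out = []
        stack = list(tree.children[node])
        while stack:
            n = stack.pop()
            if tree.length[n] > 0:
                out.append(n)
            stack.extend(tree.children[n])
        return sorted(out)

    branches = [
        n for n in sorted(tree.parent)
        if tree.parent[n] is not None and tree.length[n] > 0
    ]
    desc = {b: descendant_branches(b) for b in branches}
    weights = np.array(
        [tree.length[b] * sum(tree.length[d] for d in desc[b]) for b in branches]
    )
    eligible = weights > 0
    if not eligible.any():
        return []
    probs = weights / weights.sum()
    out = []
    for _ in range(reps):
        mi = rng.choice(len(branches), p=probs)
        mut_branch = branches[mi]
        dlist = desc[mut_branch]
        dw = np.array([tree.length[d] for d in dlist], dtype=float)
        rev_branch = dlist[rng.choice(len(dlist), p=dw / dw.sum())]
        positive = set(tree.clade_tips(mut_branch)) - set(
            tree.clade_tips(rev_branch)
        )
        out.append(
            _run_detection_once(tree, positive, rng, null_config, pipeline_config)
        )
    return out


def weighted_contamination(
    proportions: list[dict[str, float]], weights: list[float]
) -> dict[str, float]:
    """Observed-count-weighted mean of per-phylogeny category proportions."""
    if len(proportions) != len(weights):
        raise ValueError("proportions and weights must align")
    total = float(sum(weights))
    if total <= 0:
        raise ValueError("weights sum to zero")
    cats = sorted({c for p in proportions for c in p})
    return {
        c: sum(w * p.get(c, 0.0) for p, w in zip(proportions, weights)) / total
        for c in cats
    }
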