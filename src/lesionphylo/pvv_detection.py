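"""Phylogeny-violating variant (PVV) detection.

Internal-branch mutations are screened for beta-binomial
overdispersion of their variant-read counts, separately within and
outside the assigned clade.  Screened candidates are resolved into a
lesion node, walked down the lesion path, and emitted as pass/fail
calls with a minimum molecular lesion duration (MMLD).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from lesionphylo.config import PipelineConfig
from lesionphylo.phylo_model import (
    BranchAssignment,
    Phylogeny,
    VariantCallMatrix,
    assign_all_branches,
)

__all__ = [
    "OverdispersionResult",
    "PvvCall",
    "fit_beta_binomial_rho",
    "subclade_genotypes",
    "screen_candidates",
    "find_lesion_node",
    "walk_lesion_path",
    "pvv_mmld",
    "detect_pvvs",
]

RHO_MIN = 1e-6
RHO_MAX = 0.89


@dataclass
class RhoFit:
    rho: float
    p_hat: float
    log_likelihood: float


@dataclass
class OverdispersionResult:
    within: RhoFit | None
    outside: RhoFit | None

    @property
    def rho_within(self) -> float | None:
        return self.within.rho if self.within else None

    @property
    def rho_outside(self) -> float | None:
        return self.outside.rho if self.outside else None


@dataclass
class PvvCall:
    variant_id: int
    assigned_branch: str
    overdispersion: OverdispersionResult
    lesion_node: str | None = None
    path: list[str] = field(default_factory=list)
    repair_or_loss_node: str | None = None
    status: str | None = None  # pass | fail | indeterminate
    shed_genotypes: list[tuple[str, str]] = field(default_factory=list)
    mmld: float | None = None
    vclass: str | None = None


def _betabinom_loglik(mtr: np.ndarray, dep: np.ndarray, p: float, rho: float
                      ) -> float:
    if rho < 1e-9:
        return float(stats.binom.logpmf(mtr, dep, p).sum())
    a = p * (1.0 - rho) / rho
    b = (1.0 - p) * (1.0 - rho) / rho
    return float(stats.betabinom.logpmf(mtr, dep, a, b).sum())


def _loglik_grid(mtr: np.ndarray, dep: np.ndarray, p: np.ndarray,
                 rho: np.ndarray) -> np.ndarray:
    """Log-likelihood on the (rho, p) grid, shape (len(rho), len(p))."""
    p = p[None, :, None]
    r = rho[:, None, None]
    a = p * (1.0 - r) / r
    b = (1.0 - p) * (1.0 - r) / r
    return stats.betabinom.logpmf(mtr[None, None, :], dep[None, None, :], a, b
                                  ).sum(axis=2)


def fit_beta_binomial_rho(mtr, dep) -> RhoFit:
    """Joint maximum-likelihood (p, rho) fit of a beta-binomial.

    The beta-binomial is parameterized by mean ``p`` and overdispersion
    ``rho`` via ``alpha = p(1-rho)/rho``, ``beta = (1-p)(1-rho)/rho``
    (the ``rho -> 0`` limit is binomial).  ``rho`` is searched on a
    log-spaced grid over [1e-6, 0.89] followed by bounded local
    refinement; the fit is deterministic for fixed input.
    """
    mtr = np.asarray(mtr, dtype=np.int64)
    dep = np.asarray(dep, dtype=np.int64)
    keep = dep > 0
    mtr, dep = mtr[keep], dep[keep]
    if len(dep) < 2:
        raise ValueError("need >= 2 samples with non-zero depth")

    rho_grid = np.geomspace(RHO_MIN, RHO_MAX, 25)
    pooled = max(min(mtr.sum() / dep.sum(), 1.0 - 1e-9), 1e-9)
    p_grid = np.unique(np.concatenate([np.linspace(0.01, 0.99, 33), [pooled]]))
    ll = _loglik_grid(mtr, dep, p_grid, rho_grid)
    ri, pi = np.unravel_index(np.argmax(ll), ll.shape)
    rho, p, best = float(rho_grid[ri]), float(p_grid[pi]), float(ll[ri, pi])

    # two rounds of bounded coordinate refinement around the grid optimum
    for _ in range(2):
        res = optimize.minimize_scalar(
            lambda q: -_betabinom_loglik(mtr, dep, q, rho),
            bounds=(1e-9, 1.0 - 1e-9),
            method="bounded",
            options={"xatol": 1e-9},
        )
        if -res.fun >= best:
            p, best = float(res.x), float(-res.fun)
        lo = rho_grid[max(ri - 1, 0)]
        hi = rho_grid[min(ri + 1, len(rho_grid) - 1)]
        res = optimize.minimize_scalar(
            lambda r: -_betabinom_loglik(mtr, dep, p, r),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-7},
        )
        if -res.fun >= best:
            rho, best = float(res.x), float(-res.fun)
    # joint polish (coordinate descent can stall on curved ridges)
    def neg(x):
        q = min(max(x[0], 1e-9), 1.0 - 1e-9)
        r = min(max(x[1], RHO_MIN), RHO_MAX)
        return -_betabinom_loglik(mtr, dep, q, r)

    res = optimize.minimize(
        neg, [p, rho], method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 400},
    )
    if -res.fun >= best:
        p = float(min(max(res.x[0], 1e-9), 1.0 - 1e-9))
        rho = float(min(max(res.x[1], RHO_MIN), RHO_MAX))
        best = float(-res.fun)
    # when the likelihood is flat in rho (e.g. all-zero counts with p at
    # its boundary) prefer the parsimonious no-overdispersion solution
    ll_min = _betabinom_loglik(mtr, dep, p, RHO_MIN)
    if ll_min >= best - 1e-4:
        rho, best = RHO_MIN, max(best, ll_min)
    return RhoFit(rho=rho, p_hat=p, log_likelihood=best)


# ---------------------------------------------------------------------------
# Subclade genotyping
# ---------------------------------------------------------------------------

POSITIVE, NEGATIVE, MIXED, INDETERMINATE = (
    "positive",
    "negative",
    "mixed",
    "indeterminate",
)


def subclade_genotypes(
    tree: Phylogeny,
    mtr_by_tip: dict[str, int],
    dep_by_tip: dict[str, int],
    config: PipelineConfig,
) -> dict[str, str]:
    """Label every node's clade positive / negative / mixed / indeterminate.

    A subclade is positive when its pooled VAF and variant reads meet the
    positive thresholds and no tip inside is confidently negative;
    negative when pooled variant reads are zero at adequate pooled depth;
    mixed when it contains both a confidently positive and a confidently
    negative tip; indeterminate otherwise.
    """
    labels: dict[str, str] = {}
    pooled: dict[str, tuple[int, int, bool, bool]] = {}
    for node in tree.postorder():
        kids = tree.children[node]
        if not kids:
            m, d = mtr_by_tip.get(node, 0), dep_by_tip.get(node, 0)
            tip_pos = (
                d > 0
                and m >= config.positive_subclade_min_reads
                and m / d >= config.positive_subclade_min_vaf
            )
            tip_neg = m == 0 and d >= config.negative_subclade_min_depth
            pooled[node] = (m, d, tip_pos, tip_neg)
        else:
            m = sum(pooled[c][0] for c in kids)
            d = sum(pooled[c][1] for c in kids)
            has_pos = any(pooled[c][2] for c in kids)
            has_neg = any(pooled[c][3] for c in kids)
            pooled[node] = (m, d, has_pos, has_neg)
        m, d, has_pos, has_neg = pooled[node]
        if has_pos and has_neg:
            labels[node] = MIXED
        elif (
            d > 0
            and m >= config.positive_subclade_min_reads
            and m / d >= config.positive_subclade_min_vaf
            and not has_neg
        ):
            labels[node] = POSITIVE
        elif m == 0 and d >= config.negative_subclade_min_depth:
            labels[node] = NEGATIVE
        else:
            labels[node] = INDETERMINATE
    return labels


def _maximal_positive_nodes(tree: Phylogeny, labels: dict[str, str]) -> list[str]:
    out = []
    for node in tree.preorder():
        if labels[node] == POSITIVE:
            p = tree.parent[node]
            if p is None or labels[p] != POSITIVE:
                out.append(node)
    return out


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------


@dataclass
class PvvCandidate:
    variant_id: int
    assigned_branch: str
    overdispersion: OverdispersionResult
    labels: dict[str, str]
    trigger: str  # "within" | "outside" | "both"


def _counts_by_tip(counts: VariantCallMatrix, i: int) -> tuple[dict, dict]:
    mtr = {s: int(counts.mtr[i, k]) for k, s in enumerate(counts.samples)}
    dep = {s: int(counts.dep[i, k]) for k, s in enumerate(counts.samples)}
    return mtr, dep


def screen_variant(
    tree: Phylogeny,
    samples: list[str],
    mtr_row: np.ndarray,
    dep_row: np.ndarray,
    assigned_branch: str,
    config: PipelineConfig,
    variant_id: int = 0,
) -> PvvCandidate | None:
    """Screen one internal-branch mutation for phylogeny violation.

    Returns a candidate when either (a) rho within the assigned clade
    reaches the threshold and the clade contains a confidently negative
    subclade, or (b) rho outside reaches the threshold and a confidently
    positive subclade exists outside the clade; otherwise ``None``.
    """
    node = assigned_branch
    if tree.is_tip(node):
        return None
    clade = tree.clade_tips(node)
    in_mask = np.array([s in clade for s in samples])
    mtr_by_tip = {s: int(m) for s, m in zip(samples, mtr_row)}
    dep_by_tip = {s: int(d) for s, d in zip(samples, dep_row)}
    labels = subclade_genotypes(tree, mtr_by_tip, dep_by_tip, config)

    def side_fit(mask):
        m = mtr_row[mask]
        d = dep_row[mask]
        if (d > 0).sum() < 2:
            return None
        return fit_beta_binomial_rho(m, d)

    neg_inside = any(
        labels[n] == NEGATIVE
        for n in tree.nodes
        if n != node and tree.is_within(n, node)
    )
    pos_outside = any(
        labels[n] == POSITIVE
        for n in _maximal_positive_nodes(tree, labels)
        if not tree.is_within(n, node) and not tree.is_within(node, n)
    )
    # the rho fit is the expensive step: only fit sides whose subclade
    # requirement is already met
    fit_in = side_fit(in_mask) if neg_inside else None
    fit_out = side_fit(~in_mask) if (pos_outside and (~in_mask).any()) else None
    od = OverdispersionResult(within=fit_in, outside=fit_out)

    hit_in = fit_in is not None and fit_in.rho >= config.rho_threshold
    hit_out = fit_out is not None and fit_out.rho >= config.rho_threshold
    if not (hit_in or hit_out):
        return None
    trigger = "both" if (hit_in and hit_out) else ("within" if hit_in else "outside")
    return PvvCandidate(
        variant_id=variant_id,
        assigned_branch=node,
        overdispersion=od,
        labels=labels,
        trigger=trigger,
    )


def screen_candidates(
    counts: VariantCallMatrix,
    tree: Phylogeny,
    assignments: list[BranchAssignment],
    config: PipelineConfig | None = None,
) -> list[PvvCandidate]:
    """Screen every internal-branch assignment (see :func:`screen_variant`)."""
    config = config or PipelineConfig()
    counts.check_against_tree(tree)
    out: list[PvvCandidate] = []
    for asg in assignments:
        cand = screen_variant(
            tree,
            counts.samples,
            counts.mtr[asg.variant_id],
            counts.dep[asg.variant_id],
            asg.branch,
            config,
            variant_id=asg.variant_id,
        )
        if cand is not None:
            out.append(cand)
    return out


def find_lesion_node(
    candidate: PvvCandidate, tree: Phylogeny
) -> str:
    """Minimal ancestor of the assigned branch covering every positive
    subclade."""
    labels = candidate.labels
    positives = _maximal_positive_nodes(tree, labels)
    cur = candidate.assigned_branch
    while any(not tree.is_within(p, cur) for p in positives):
        parent = tree.parent[cur]
        if parent is None:
            break
        cur = parent
    return cur


def walk_lesion_path(
    candidate: PvvCandidate,
    lesion_node: str,
    tree: Phylogeny,
    vclass: str | None = None,
) -> PvvCall:
    """Descend through the unique mixed child, shedding uniform subclades.

    The walk stops at the first node whose children are all uniform (the
    repair-or-loss node).  Two mixed children at any step fail the call;
    an indeterminate child at a decision point flags it indeterminate.
    A pass requires at least two positive uniform subclades separated on
    the tree by a negative one (minimal witness
    positive/negative/positive along the path).
    """
    labels = candidate.labels
    call = PvvCall(
        variant_id=candidate.variant_id,
        assigned_branch=candidate.assigned_branch,
        overdispersion=candidate.overdispersion,
        lesion_node=lesion_node,
        vclass=vclass,
    )
    path = [lesion_node]
    shed: list[tuple[str, str]] = []
    cur = lesion_node
    status = None
    while True:
        kids = tree.children[cur]
        mixed = [c for c in kids if labels[c] == MIXED]
        indet = [c for c in kids if labels[c] == INDETERMINATE]
        uniform = [c for c in kids if labels[c] in (POSITIVE, NEGATIVE)]
        if indet:
            status = "indeterminate"
            break
        if len(mixed) >= 2:
            status = "fail"
            shed.extend((c, labels[c]) for c in uniform)
            break
        if not mixed:
            shed.extend((c, labels[c]) for c in kids)
            break
        shed.extend((c, labels[c]) for c in uniform)
        cur = mixed[0]
        path.append(cur)

    call.path = path
    call.repair_or_loss_node = cur
    call.shed_genotypes = shed
    if status is None:
        status = "pass" if _violates_phylogeny(tree, shed) else "fail"
    call.status = status
    if status == "pass":
        call.mmld = tree.path_length(lesion_node, cur)
    return call


def _violates_phylogeny(tree: Phylogeny, shed: list[tuple[str, str]]) -> bool:
    """True when the shed subclades witness a phylogeny violation.

    Requires at least two positive uniform subclades separated on the
    tree by a negative one, i.e. a confidently negative subclade lies
    inside the minimal clade covering all positives (the minimal witness
    is positive/negative/positive along the path).  Stated on the tree
    rather than the shed sequence because the ordering of the repair
    node's children is arbitrary.
    """
    positives = [n for n, lab in shed if lab == POSITIVE]
    negatives = [n for n, lab in shed if lab == NEGATIVE]
    if len(positives) < 2 or not negatives:
        return False
    cover = tree.mrca(positives)
    return any(tree.is_within(n, cover) for n in negatives)


def pvv_mmld(call: PvvCall, tree: Phylogeny) -> float:
    """Sum of branch lengths between lesion node and repair/loss node."""
    if call.status != "pass":
        raise ValueError("MMLD is defined only for pass calls")
    return tree.path_length(call.lesion_node, call.repair_or_loss_node)


def detect_pvvs(
    tree: Phylogeny,
    counts: VariantCallMatrix,
    config: PipelineConfig | None = None,
    assignments: list[BranchAssignment] | None = None,
) -> list[PvvCall]:
    """End-to-end PVV detection: assign, screen, locate, walk."""
    config = config or PipelineConfig()
    if assignments is None:
        assignments = assign_all_branches(tree, counts, config)
    calls = []
    for cand in screen_candidates(counts, tree, assignments, config):
        lesion = find_lesion_node(cand, tree)
        vclass = str(counts.variants.iloc[cand.variant_id]["vclass"])
        calls.append(walk_lesion_path(cand, lesion, tree, vclass=vclass))
    return calls
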