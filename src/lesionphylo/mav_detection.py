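"""Multi-allelic variant (MAV) discovery and classification.

A MAV is a pair of distinct mutations whose reference loci overlap.
Pairs are classified hierarchically as ``simple`` (both assigned
branches share a parent node), ``separated`` (one branch lies within the
clade of the other's parent and the lesion path has at most one
intervening reference-only subclade) or ``unrelated``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from lesionphylo.config import PipelineConfig
from lesionphylo.phylo_model import Phylogeny, VariantCallMatrix

__all__ = [
    "MavPair",
    "find_multiallelic_sites",
    "classify_mav",
    "tip_alleles_from_counts",
    "tip_alleles_from_clades",
    "trace_mav_lesion_path",
    "mav_mmld",
    "mavs_per_node",
]

REF, ALT1, ALT2, UNKNOWN = 0, 1, 2, -1


@dataclass
class MavPair:
    variant_ids: tuple[int, int]
    branches: tuple[str, str] | None = None
    category: str | None = None  # simple | separated | unrelated
    lesion_node: str | None = None
    lesion_repair_node: str | None = None
    mmld: float | None = None
    path: list[str] = field(default_factory=list)
    shed_genotypes: list[tuple[str, str]] = field(default_factory=list)
    error: str | None = None
    alleles: tuple[str, str] | None = None


def find_multiallelic_sites(counts: VariantCallMatrix) -> list[MavPair]:
    """All unordered pairs of distinct variants with locus overlap.

    SNV pairs overlap when chrom and pos coincide with differing alt
    alleles; for indels and MNVs any reference-interval intersection
    counts.
    """
    n = len(counts)
    intervals = [counts.ref_interval(i) for i in range(n)]
    order = sorted(range(n), key=lambda i: intervals[i])
    out: list[MavPair] = []
    for a in range(n):
        i = order[a]
        ci, si, ei = intervals[i]
        for b in range(a + 1, n):
            j = order[b]
            cj, sj, ej = intervals[j]
            if cj != ci or sj > ei:
                break
            vi = counts.variants.iloc[i]
            vj = counts.variants.iloc[j]
            if (
                vi["vclass"] == "SNV"
                and vj["vclass"] == "SNV"
                and (vi["pos"] != vj["pos"] or vi["alt"] == vj["alt"])
            ):
                continue
            pair = tuple(sorted((i, j)))
            out.append(
                MavPair(
                    variant_ids=pair,
                    alleles=(
                        str(counts.variants.iloc[pair[0]]["alt"]),
                        str(counts.variants.iloc[pair[1]]["alt"]),
                    ),
                )
            )
    out.sort(key=lambda p: p.variant_ids)
    return out


def tip_alleles_from_counts(
    pair: MavPair,
    tree: Phylogeny,
    counts: VariantCallMatrix,
    config: PipelineConfig,
) -> dict[str, int]:
    """Per-tip genotype at the MAV locus from read counts.

    A tip is called alt1/alt2 when it meets the positive-subclade read
    thresholds for exactly one member variant, ref when neither variant
    has any reads at adequate depth, and unknown otherwise.
    """
    i, j = pair.variant_ids
    out: dict[str, int] = {}
    for s in tree.tips:
        k = counts.sample_index(s)
        m1, m2 = counts.mtr[i, k], counts.mtr[j, k]
        d1, d2 = counts.dep[i, k], counts.dep[j, k]

        def pos(m, d):
            return (
                d > 0
                and m >= config.positive_subclade_min_reads
                and m / d >= config.positive_subclade_min_vaf
            )

        p1, p2 = pos(m1, d1), pos(m2, d2)
        if p1 and not p2:
            out[s] = ALT1
        elif p2 and not p1:
            out[s] = ALT2
        elif (
            m1 == 0
            and m2 == 0
            and min(d1, d2) >= config.negative_subclade_min_depth
        ):
            out[s] = REF
        else:
            out[s] = UNKNOWN
    return out


def tip_alleles_from_clades(
    tree: Phylogeny, branch1: str, branch2: str
) -> dict[str, int]:
    """Implied genotypes when the two mutant clades are taken as exact."""
    c1 = tree.clade_tips(branch1)
    c2 = tree.clade_tips(branch2)
    out = {}
    for s in tree.tips:
        if s in c1 and s in c2:
            out[s] = UNKNOWN
        elif s in c1:
            out[s] = ALT1
        elif s in c2:
            out[s] = ALT2
        else:
            out[s] = REF
    return out


_LABEL = {REF: "ref", ALT1: "alt1", ALT2: "alt2"}


def _clade_alleles(
    tree: Phylogeny, node: str, tip_allele: dict[str, int],
    cache: dict[str, frozenset[int]],
) -> frozenset[int]:
    if node not in cache:
        cache[node] = frozenset(
            a for t in tree.clade_tips(node)
            if (a := tip_allele.get(t, UNKNOWN)) != UNKNOWN
        )
    return cache[node]


def trace_mav_lesion_path(
    tree: Phylogeny,
    lesion_node: str,
    tip_allele: dict[str, int],
) -> tuple[list[str], str, list[tuple[str, str]], str | None]:
    """Walk from the lesion node down the unique mixed child.

    At each step the subtree-allele census (ref counts as an allele,
    unknown tips are ignored) identifies children whose clades carry
    two or more distinct alleles; exactly one such child may exist for
    a single-lesion interpretation.  Returns ``(path, repair_node,
    shed_events, error)`` where shed events are ``(node, label)`` for
    every uniform subclade shed in order, including the children of the
    repair node.
    """
    cache: dict[str, frozenset[int]] = {}
    path = [lesion_node]
    shed: list[tuple[str, str]] = []
    cur = lesion_node
    while True:
        kids = tree.children[cur]
        mixed = [
            c for c in kids if len(_clade_alleles(tree, c, tip_allele, cache)) >= 2
        ]
        uniform = [c for c in kids if c not in mixed]
        if len(mixed) >= 2:
            for c in uniform:
                al = _clade_alleles(tree, c, tip_allele, cache)
                if len(al) == 1:
                    shed.append((c, _LABEL[next(iter(al))]))
            return path, cur, shed, "two_mixed_children"
        if not mixed:
            for c in kids:
                al = _clade_alleles(tree, c, tip_allele, cache)
                if len(al) == 1:
                    shed.append((c, _LABEL[next(iter(al))]))
            return path, cur, shed, None
        for c in uniform:
            al = _clade_alleles(tree, c, tip_allele, cache)
            if len(al) == 1:
                shed.append((c, _LABEL[next(iter(al))]))
        cur = mixed[0]
        path.append(cur)


def _intervening_reference_subclades(
    tree: Phylogeny, path: list[str], shed: list[tuple[str, str]]
) -> int:
    """Reference-only subclades shed strictly between the two mutant
    subclades, i.e. at path nodes other than the lesion node and the
    repair node (subclades shed at the endpoints are siblings of the
    mutant clades, not between them)."""
    if len(path) < 3:
        return 0
    between = set(path[1:-1])
    return sum(
        1
        for root, lab in shed
        if lab == "ref" and tree.parent[root] in between
    )


def classify_mav(
    pair: MavPair,
    tree: Phylogeny,
    assignments: dict[int, str],
    tip_allele: dict[str, int] | None = None,
) -> MavPair:
    """Hierarchical simple / separated / unrelated classification.

    ``assignments`` maps variant id to assigned branch (node id).  When
    ``tip_allele`` is omitted, genotypes are implied from the assigned
    clades (used by the null simulations); supply read-count-derived
    genotypes for real data.  Ancestor-nested branch pairs are
    unrelated: one lesion cannot place both alternate alleles on a
    single line of descent.  Separated pairs whose lesion path crosses
    two or more reference-only subclades are reclassified unrelated.
    """
    i, j = pair.variant_ids
    try:
        b1, b2 = assignments[i], assignments[j]
    except KeyError as exc:
        raise ValueError(f"variant {exc} has no branch assignment") from exc
    pair.branches = (b1, b2)
    p1, p2 = tree.parent[b1], tree.parent[b2]

    if b1 == b2 or tree.is_within(b1, b2) or tree.is_within(b2, b1):
        pair.category = "unrelated"
        return pair

    if p1 is not None and p1 == p2:
        pair.category = "simple"
        pair.lesion_node = p1
        pair.lesion_repair_node = p1
        pair.path = [p1]
        pair.mmld = 0.0
        return pair

    # candidate encompassing parents, deepest (smallest clade) first
    candidates = []
    if p1 is not None and tree.is_within(b2, p1):
        candidates.append(p1)
    if p2 is not None and tree.is_within(b1, p2):
        candidates.append(p2)
    if not candidates:
        pair.category = "unrelated"
        return pair
    lesion = min(candidates, key=lambda n: (len(tree.clade_tips(n)), n))

    if tip_allele is None:
        tip_allele = tip_alleles_from_clades(tree, b1, b2)
    path, repair, shed, err = trace_mav_lesion_path(tree, lesion, tip_allele)
    pair.lesion_node = lesion
    pair.path = path
    pair.shed_genotypes = shed
    pair.error = err
    if err is not None:
        pair.category = "unrelated"
        return pair
    if _intervening_reference_subclades(tree, path, shed) >= 2:
        pair.category = "unrelated"
        return pair
    pair.category = "separated"
    pair.lesion_repair_node = repair
    pair.mmld = tree.path_length(lesion, repair)
    return pair


def mav_mmld(pair: MavPair, tree: Phylogeny) -> float:
    """Sum of branch lengths along the lesion path (0 for simple)."""
    if pair.category == "simple":
        return 0.0
    if pair.category != "separated" or pair.lesion_repair_node is None:
        raise ValueError("MMLD is defined only for classified simple/separated MAVs")
    return tree.path_length(pair.lesion_node, pair.lesion_repair_node)


def mavs_per_node(
    tree: Phylogeny,
    mavs: list[MavPair],
    config: PipelineConfig | None = None,
) -> float | None:
    """Lesion-consistent MAVs per post-development coalescence.

    Returns None when the tree has no post-development nodes.
    """
    from lesionphylo.phylo_model import count_post_development_nodes

    n_nodes = count_post_development_nodes(tree, config)
    if n_nodes == 0:
        return None
    n_mav = sum(1 for p in mavs if p.category in ("simple", "separated"))
    return n_mav / n_nodes
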