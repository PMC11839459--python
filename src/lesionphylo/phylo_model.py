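"""Somatic-phylogeny data model, I/O and mutation-to-branch assignment.

Branch lengths are molecular time (mutation counts).  A *branch* is the
edge above a node and is identified by the node id; the root's (possibly
zero-length) stem is itself assignable, representing mutations acquired
before the first captured cell division.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from lesionphylo.config import PipelineConfig

__all__ = [
    "Phylogeny",
    "VariantCallMatrix",
    "BranchAssignment",
    "read_phylogeny",
    "read_variant_table",
    "read_count_matrix",
    "read_vcf",
    "assign_branch",
    "assign_all_branches",
    "count_post_development_nodes",
]


class PhylogenyError(ValueError):
    """Raised for malformed trees or unknown nodes."""


@dataclass
class Phylogeny:
    """A rooted tree with mutation-count branch lengths.

    ``parent[node]`` is ``None`` for the root; ``children`` preserves the
    order in the source Newick; ``length[node]`` is the length of the
    edge above ``node`` (0 for the root unless a stem length was given).
    """

    root: str
    parent: dict[str, str | None]
    children: dict[str, list[str]]
    length: dict[str, float]

    def __post_init__(self) -> None:
        self._validate()
        self._tip_cache: dict[str, frozenset[str]] = {}
        self._time_cache: dict[str, float] = {}

    # -- construction / validation -------------------------------------

    def _validate(self) -> None:
        roots = [n for n, p in self.parent.items() if p is None]
        if roots != [self.root]:
            raise PhylogenyError("tree must have exactly one root")
        seen: set[str] = set()
        stack = [self.root]
        while stack:
            n = stack.pop()
            if n in seen:
                raise PhylogenyError(f"cycle involving node {n!r}")
            seen.add(n)
            stack.extend(self.children.get(n, []))
        if seen != set(self.parent):
            raise PhylogenyError("disconnected nodes present")
        for n, ln in self.length.items():
            if ln < 0:
                raise PhylogenyError(f"negative branch length on {n!r}")

    # -- basic queries ---------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        return list(self.preorder())

    @property
    def tips(self) -> list[str]:
        return [n for n in self.preorder() if not self.children[n]]

    @property
    def internal_nodes(self) -> list[str]:
        return [n for n in self.preorder() if self.children[n]]

    def is_tip(self, node: str) -> bool:
        self._check(node)
        return not self.children[node]

    def _check(self, node: str) -> None:
        if node not in self.parent:
            raise PhylogenyError(f"unknown node {node!r}")

    def preorder(self) -> Iterable[str]:
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(self.children[n]))

    def postorder(self) -> Iterable[str]:
        out = list(self.preorder())
        return reversed(out)

    # -- clade / ancestry semantics -------------------------------------

    def clade_tips(self, node: str) -> frozenset[str]:
        """Sample ids of all tips at or below ``node``."""
        self._check(node)
        if node not in self._tip_cache:
            if not self.children[node]:
                self._tip_cache[node] = frozenset([node])
            else:
                acc: set[str] = set()
                for c in self.children[node]:
                    acc |= self.clade_tips(c)
                self._tip_cache[node] = frozenset(acc)
        return self._tip_cache[node]

    def is_within(self, a: str, b: str) -> bool:
        """True if ``a`` lies within the clade of ``b`` (a node is within
        its own clade)."""
        self._check(a)
        self._check(b)
        n: str | None = a
        while n is not None:
            if n == b:
                return True
            n = self.parent[n]
        return False

    def ancestors(self, node: str) -> list[str]:
        """Nodes on the path from ``node`` (inclusive) to the root."""
        self._check(node)
        out = []
        n: str | None = node
        while n is not None:
            out.append(n)
            n = self.parent[n]
        return out

    def mrca(self, nodes: Iterable[str]) -> str:
        nodes = list(nodes)
        if not nodes:
            raise PhylogenyError("mrca of empty node set")
        common: list[str] | None = None
        for n in nodes:
            anc = self.ancestors(n)
            if common is None:
                common = anc
            else:
                s = set(anc)
                common = [x for x in common if x in s]
        assert common
        return common[0]

    # -- molecular time --------------------------------------------------

    def molecular_time(self, node: str) -> float:
        """Sum of branch lengths from the root to ``node`` (root = 0).

        The root's own stem length does not count towards molecular
        time: time zero is the zygote at the top of the stem's clade.
        """
        self._check(node)
        if node not in self._time_cache:
            p = self.parent[node]
            if p is None:
                self._time_cache[node] = 0.0
            else:
                self._time_cache[node] = self.molecular_time(p) + self.length[node]
        return self._time_cache[node]

    def path_length(self, ancestor: str, descendant: str) -> float:
        """Sum of branch lengths from ``ancestor`` down to ``descendant``."""
        if not self.is_within(descendant, ancestor):
            raise PhylogenyError(
                f"{descendant!r} is not within the clade of {ancestor!r}"
            )
        return self.molecular_time(descendant) - self.molecular_time(ancestor)

    # -- serialization ---------------------------------------------------

    def to_newick(self) -> str:
        def fmt(node: str) -> str:
            kids = self.children[node]
            label = node
            body = "" if not kids else "(" + ",".join(fmt(c) for c in kids) + ")"
            ln = self.length.get(node, 0.0)
            if self.parent[node] is None and ln == 0.0:
                return f"{body}{label}"
            return f"{body}{label}:{ln:.12g}"

        return fmt(self.root) + ";"

    def copy(self) -> "Phylogeny":
        return Phylogeny(
            root=self.root,
            parent=dict(self.parent),
            children={k: list(v) for k, v in self.children.items()},
            length=dict(self.length),
        )


def read_phylogeny(newick: str) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`.

    Tips must be uniquely named; non-root branch lengths are mandatory.
    Unnamed internal nodes are assigned deterministic ids ``nd1`` ...
    in preorder.
    """
    try:
        dtree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise PhylogenyError(f"malformed Newick: {exc}") from exc

    parent: dict[str, str | None] = {}
    children: dict[str, list[str]] = {}
    length: dict[str, float] = {}
    counter = [0]
    used: set[str] = set()

    def name_of(dnode) -> str:
        if dnode.taxon is not None and dnode.taxon.label:
            return str(dnode.taxon.label)
        if dnode.label:
            return str(dnode.label)
        counter[0] += 1
        return f"nd{counter[0]}"

    def walk(dnode, parent_name: str | None) -> None:
        name = name_of(dnode)
        if name in used:
            raise PhylogenyError(f"duplicate node name {name!r}")
        used.add(name)
        parent[name] = parent_name
        children[name] = []
        if parent_name is not None:
            children[parent_name].append(name)
            if dnode.edge.length is None:
                raise PhylogenyError(f"missing branch length above {name!r}")
            length[name] = float(dnode.edge.length)
        else:
            length[name] = float(dnode.edge.length or 0.0)
        if parent_name is not None and length[name] < 0:
            raise PhylogenyError(f"negative branch length above {name!r}")
        for child in dnode.child_nodes():
            walk(child, name)

    walk(dtree.seed_node, None)
    root_name = next(n for n, p in parent.items() if p is None)
    return Phylogeny(root=root_name, parent=parent, children=children, length=length)


# ---------------------------------------------------------------------------
# Variant call matrix
# ---------------------------------------------------------------------------

_VALID_CLASSES = {"SNV", "indel", "MNV"}


@dataclass
class VariantCallMatrix:
    """Variant records plus variant x sample read-count matrices."""

    variants: pd.DataFrame  # columns: chrom, pos, ref, alt, vclass[, context]
    mtr: np.ndarray
    dep: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.mtr = np.asarray(self.mtr, dtype=np.int64)
        self.dep = np.asarray(self.dep, dtype=np.int64)
        nv, ns = self.mtr.shape
        if self.dep.shape != (nv, ns):
            raise ValueError("MTR and DEP shapes differ")
        if len(self.variants) != nv:
            raise ValueError("variant table and matrices differ in length")
        if len(self.samples) != ns:
            raise ValueError("sample list and matrices differ in width")
        if (self.mtr < 0).any() or (self.dep < 0).any():
            raise ValueError("negative read counts")
        if (self.mtr > self.dep).any():
            raise ValueError("MTR exceeds DEP")
        bad = set(self.variants["vclass"]) - _VALID_CLASSES
        if bad:
            raise ValueError(f"unknown variant classes: {sorted(bad)}")
        self._sample_index = {s: i for i, s in enumerate(self.samples)}

    def __len__(self) -> int:
        return len(self.variants)

    def sample_index(self, sample: str) -> int:
        return self._sample_index[sample]

    def check_against_tree(self, tree: Phylogeny) -> None:
        tips = set(tree.tips)
        if tips != set(self.samples):
            missing = tips - set(self.samples)
            extra = set(self.samples) - tips
            raise ValueError(
                f"sample set mismatch with tree tips (missing={sorted(missing)}, "
                f"extra={sorted(extra)})"
            )

    def ref_interval(self, i: int) -> tuple[str, int, int]:
        """1-based inclusive reference interval touched by variant ``i``.

        SNV: single base.  Deletion/MNV: the span of reference bases
        replaced.  Insertions occupy the single anchor base.
        """
        rec = self.variants.iloc[i]
        start = int(rec["pos"])
        end = start + max(len(rec["ref"]), 1) - 1
        return str(rec["chrom"]), start, end


def read_variant_table(path_or_buf) -> pd.DataFrame:
    df = pd.read_csv(path_or_buf, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt", "vclass"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    df["pos"] = df["pos"].astype(int)
    return df


def read_count_matrix(path_or_buf) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path_or_buf, sep="\t", index_col=0)
    return df.to_numpy(dtype=np.int64), [str(c) for c in df.columns]


def read_vcf(path) -> VariantCallMatrix:
    """Import a VCF with per-sample AD fields into a call matrix."""
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    rows, mtr_rows, dep_rows = [], [], []
    for rec in vf:
        for alt in rec.alts or ():
            if len(rec.ref) == 1 and len(alt) == 1:
                vclass = "SNV"
            elif len(rec.ref) != len(alt):
                vclass = "indel"
            else:
                vclass = "MNV"
            rows.append(
                {"chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref,
                 "alt": alt, "vclass": vclass}
            )
            ai = (rec.alts or ()).index(alt) + 1
            m, d = [], []
            for s in samples:
                ad = rec.samples[s].get("AD")
                if ad is None or ad[0] is None:
                    m.append(0)
                    d.append(0)
                else:
                    m.append(int(ad[ai]))
                    d.append(int(sum(x or 0 for x in ad)))
            mtr_rows.append(m)
            dep_rows.append(d)
    return VariantCallMatrix(
        variants=pd.DataFrame(rows),
        mtr=np.array(mtr_rows, dtype=np.int64),
        dep=np.array(dep_rows, dtype=np.int64),
        samples=samples,
    )


# ---------------------------------------------------------------------------
# Branch assignment
# ---------------------------------------------------------------------------


@dataclass
class BranchAssignment:
    variant_id: int
    branch: str
    log_likelihood: float
    p_value: float


class _BranchModel:
    """Cached per-tree structures for vectorized branch assignment."""

    def __init__(self, tree: Phylogeny, samples: Sequence[str]):
        tree_tips = set(tree.tips)
        if set(samples) != tree_tips:
            raise ValueError("counts must cover exactly the tree tips")
        self.tree = tree
        self.samples = list(samples)
        sample_idx = {s: i for i, s in enumerate(self.samples)}
        # branches ordered for deterministic tie-breaking: smallest clade
        # first, then lexicographic id
        self.branches = sorted(
            tree.nodes, key=lambda n: (len(tree.clade_tips(n)), n)
        )
        self.inside = np.zeros((len(self.branches), len(self.samples)), dtype=bool)
        for bi, b in enumerate(self.branches):
            for t in tree.clade_tips(b):
                self.inside[bi, sample_idx[t]] = True

    def loglik(self, mtr: np.ndarray, dep: np.ndarray, config: PipelineConfig
               ) -> np.ndarray:
        lh = stats.binom.logpmf(mtr, dep, config.het_vaf)
        le = stats.binom.logpmf(mtr, dep, config.error_rate)
        return self.inside @ (lh - le) + le.sum()


_MODEL_CACHE: dict[tuple[int, tuple[str, ...]], _BranchModel] = {}


def _branch_model(tree: Phylogeny, samples: Sequence[str]) -> _BranchModel:
    key = (id(tree), tuple(samples))
    model = _MODEL_CACHE.get(key)
    if model is None:
        model = _BranchModel(tree, samples)
        _MODEL_CACHE.clear()  # keep at most one tree's worth of cache
        _MODEL_CACHE[key] = model
    return model


def assign_branch(
    variant_id: int,
    tree: Phylogeny,
    counts: VariantCallMatrix,
    config: PipelineConfig | None = None,
) -> BranchAssignment:
    """Maximum-likelihood single-branch assignment of one variant.

    Each candidate branch implies success probability ``het_vaf`` for
    tips inside its clade and ``error_rate`` outside; the branch with the
    highest summed binomial log-likelihood wins, ties broken toward the
    smallest clade then lexicographic id.  The p-value is the probability
    of the observed counts under the winning assignment.
    """
    config = config or PipelineConfig()
    counts.check_against_tree(tree)
    mtr = counts.mtr[variant_id]
    dep = counts.dep[variant_id]
    if not dep.any():
        raise ValueError("zero depth in every sample: no information")
    model = _branch_model(tree, counts.samples)
    ll = model.loglik(mtr, dep, config)
    best = int(np.argmax(ll))  # argmax takes the first maximum: tie order ok
    return BranchAssignment(
        variant_id=variant_id,
        branch=model.branches[best],
        log_likelihood=float(ll[best]),
        p_value=float(np.exp(ll[best])),
    )


def assign_all_branches(
    tree: Phylogeny,
    counts: VariantCallMatrix,
    config: PipelineConfig | None = None,
) -> list[BranchAssignment]:
    return [
        assign_branch(i, tree, counts, config)
        for i in range(len(counts))
        if counts.dep[i].any()
    ]


def count_post_development_nodes(
    tree: Phylogeny, config: PipelineConfig | None = None
) -> int:
    """Internal non-root coalescences at or beyond the development cutoff."""
    config = config or PipelineConfig()
    return sum(
        1
        for n in tree.internal_nodes
        if n != tree.root
        and len(tree.children[n]) >= 2
        and tree.molecular_time(n) >= config.development_cutoff
    )
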