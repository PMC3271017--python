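"""Rooted trees and site-independent sequence evolution down the tree.

The simulator takes a rooted phylogeny with branch lengths (expected
substitutions per site), a root protein sequence, and a substitution model;
every site evolves independently, and every branch independently of every
other branch.  On an edge of length ``t`` the child residue at each site is
drawn from the row of ``P(t) = exp(Q t)`` selected by the parent residue.
Replicate simulations reuse the tree, so transition matrices are computed
once per distinct branch length and cached on the model.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from typing import Iterable, Iterator, Sequence

import dendropy
import numpy as np

from dyadsel.substmodel import AA_INDEX, ALPHABET, RateMatrix

__all__ = [
    "PhyloTree",
    "SequenceSet",
    "parse_newick",
    "evolve_once",
    "simulate_replicates",
]

GAP_CHARS = set("-.")


class NewickError(ValueError):
    """Malformed Newick input."""


@dataclass(frozen=True)
class PhyloTree:
    """Rooted phylogeny flattened to preorder arrays.

    ``parent[i]`` is the preorder index of node ``i``'s parent (−1 for the
    root), so iterating nodes in index order always visits a parent before
    its children — the property the simulator relies on.  Polytomies are
    allowed and simulated as independent children.
    """

    names: tuple[str, ...]
    parent: np.ndarray  # int, -1 at root
    branch_lengths: np.ndarray  # float, 0.0 at root
    is_leaf: np.ndarray  # bool

    def __post_init__(self):
        n = len(self.names)
        if n == 0:
            raise NewickError("empty tree")
        if (self.parent == -1).sum() != 1 or self.parent[0] != -1:
            raise ValueError("tree must have exactly one root, first in preorder")
        if np.any(self.parent[1:] >= np.arange(1, n)):
            raise ValueError("parent indices must precede children (preorder)")
        bl = self.branch_lengths[1:]
        if np.any(~np.isfinite(bl)) or np.any(bl < 0):
            raise NewickError("branch lengths must be finite and non-negative")
        leaves = self.leaf_names
        if len(set(leaves)) != len(leaves) or any(not x for x in leaves):
            raise ValueError("leaf labels must be unique and non-empty")

    @property
    def n_nodes(self) -> int:
        return len(self.names)

    @property
    def n_leaves(self) -> int:
        return int(self.is_leaf.sum())

    @property
    def leaf_names(self) -> tuple[str, ...]:
        return tuple(n for n, lf in zip(self.names, self.is_leaf) if lf)

    def scaled(self, factor: float) -> "PhyloTree":
        """Return a copy with every branch length multiplied by ``factor``.

        Lets trees whose branch lengths are in other units (e.g. PAM/100)
        be converted to expected substitutions per site.
        """
        if factor <= 0:
            raise ValueError("branch scale factor must be positive")
        return PhyloTree(
            names=self.names,
            parent=self.parent,
            branch_lengths=self.branch_lengths * factor,
            is_leaf=self.is_leaf,
        )

    def to_newick(self) -> str:
        children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in range(1, self.n_nodes):
            children[self.parent[i]].append(i)

        def render(i: int) -> str:
            if not children[i]:
                body = self.names[i]
            else:
                body = "(" + ",".join(render(c) for c in children[i]) + ")"
                if not self.is_leaf[i] and not self.names[i].startswith("_node"):
                    body += self.names[i]
            if self.parent[i] >= 0:
                body += f":{self.branch_lengths[i]:g}"
            return body

        return render(0) + ";"


def parse_newick(text: str) -> PhyloTree:
    """Parse a rooted Newick string into a :class:`PhyloTree`.

    Unnamed internal nodes are auto-labelled ``_node<i>`` by preorder index;
    polytomies are preserved.  Raises :class:`NewickError` (with the
    underlying parser's position information) on malformed input, and on
    negative branch lengths.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=False,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickError(f"malformed Newick: {exc}") from exc
    return _from_dendropy(tree)


def _from_dendropy(tree: dendropy.Tree) -> PhyloTree:
    nodes = list(tree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    names, parent, bl, leaf = [], [], [], []
    for i, nd in enumerate(nodes):
        label = None
        if nd.taxon is not None and nd.taxon.label:
            label = nd.taxon.label
        elif nd.label:
            label = nd.label
        names.append(label if label else f"_node{i}")
        parent.append(-1 if nd.parent_node is None else index[id(nd.parent_node)])
        edge = nd.edge.length
        if nd.parent_node is None:
            bl.append(0.0)
        else:
            if edge is None:
                raise NewickError(f"missing branch length above node {names[-1]!r}")
            if edge < 0:
                raise NewickError(f"negative branch length {edge} above node {names[-1]!r}")
            bl.append(float(edge))
        leaf.append(nd.is_leaf())
    return PhyloTree(
        names=tuple(names),
        parent=np.array(parent, dtype=int),
        branch_lengths=np.array(bl, dtype=float),
        is_leaf=np.array(leaf, dtype=bool),
    )


def read_newick(path) -> PhyloTree:
    with open(path) as fh:
        return parse_newick(fh.read())


class SequenceSet:
    """An ordered, labelled collection of equal-length protein sequences.

    One simulation replicate's leaves, or an observed domain set.  Stored
    internally as a (n_sequences, length) uint8 index array over the
    20-letter alphabet for fast dyad counting.
    """

    def __init__(self, labels: Sequence[str], idx: np.ndarray):
        labels = tuple(labels)
        idx = np.asarray(idx, dtype=np.uint8)
        if idx.ndim != 2 or idx.shape[0] != len(labels):
            raise ValueError("index array must be (n_sequences, length)")
        if idx.shape[1] == 0:
            raise ValueError("sequences must be non-empty")
        if len(set(labels)) != len(labels):
            raise ValueError("sequence labels must be unique")
        self.labels = labels
        self.idx = idx

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str]]) -> "SequenceSet":
        labels, seqs = [], []
        for label, seq in records:
            labels.append(label)
            seqs.append(encode_sequence(seq, where=label))
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise ValueError(f"sequences must have equal length, got lengths {sorted(lengths)}")
        return cls(labels, np.vstack(seqs))

    @classmethod
    def from_fasta(cls, path) -> "SequenceSet":
        from Bio import SeqIO

        return cls.from_records((r.id, str(r.seq)) for r in SeqIO.parse(path, "fasta"))

    @property
    def n_sequences(self) -> int:
        return self.idx.shape[0]

    @property
    def length(self) -> int:
        return self.idx.shape[1]

    @property
    def records(self) -> list[tuple[str, str]]:
        return [(lb, "".join(ALPHABET[i] for i in row)) for lb, row in zip(self.labels, self.idx)]

    def sequence(self, label: str) -> str:
        row = self.idx[self.labels.index(label)]
        return "".join(ALPHABET[i] for i in row)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for label, seq in self.records:
                fh.write(f">{label}\n{seq}\n")

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SequenceSet)
            and self.labels == other.labels
            and np.array_equal(self.idx, other.idx)
        )

    def __repr__(self) -> str:
        return f"SequenceSet(n={self.n_sequences}, length={self.length})"


def encode_sequence(seq: str, where: str = "sequence") -> np.ndarray:
    """Encode a protein string to indices; gaps and nonstandard residues raise."""
    if not seq:
        raise ValueError(f"{where}: empty sequence")
    out = np.empty(len(seq), dtype=np.uint8)
    for pos, c in enumerate(seq):
        code = AA_INDEX.get(c.upper())
        if code is None:
            kind = "gap character" if c in GAP_CHARS else "nonstandard residue"
            raise ValueError(f"{where}: {kind} {c!r} at position {pos}")
        out[pos] = code
    return out


def degap(seq: str) -> str:
    """Remove gap characters (explicit preprocessing, never implicit)."""
    return "".join(c for c in seq if c not in GAP_CHARS)


def _evolve_indices(
    tree: PhyloTree, root_idx: np.ndarray, m: RateMatrix, rng: np.random.Generator
) -> np.ndarray:
    """Evolve a root index array down the tree; returns (n_leaves, L) leaves.

    Visits nodes in preorder; for each edge draws one uniform per site and
    inverts the cached cumulative transition distribution of the parent
    residue.
    """
    length = root_idx.shape[0]
    states = np.empty((tree.n_nodes, length), dtype=np.uint8)
    states[0] = root_idx
    for i in range(1, tree.n_nodes):
        t = tree.branch_lengths[i]
        if t == 0.0:
            states[i] = states[tree.parent[i]]
            continue
        cum = m.cumulative_transition(t)
        u = rng.random(length)
        rows = cum[states[tree.parent[i]]]  # (L, 20)
        states[i] = (u[:, None] < rows).argmax(axis=1)
    return states[tree.is_leaf]


def evolve_once(
    tree: PhyloTree, root_seq: str, m: RateMatrix, rng: np.random.Generator
) -> SequenceSet:
    """Simulate one neutral replicate; returns the leaf sequences.

    ``root_seq`` must be ungapped and over the 20-letter alphabet.  The same
    generator state always yields the same output.
    """
    root_idx = encode_sequence(root_seq, where="root sequence")
    leaves = _evolve_indices(tree, root_idx, m, rng)
    return SequenceSet(tree.leaf_names, leaves)


def replicate_rng(seed: int, index: int) -> np.random.Generator:
    """Independent, individually reproducible stream for replicate ``index``.

    Streams are keyed by the (seed, index) pair fed to NumPy's seed
    sequence, so replicate ``i`` of a run can be regenerated alone.
    """
    return np.random.default_rng([seed, index])


def simulate_replicates(
    tree: PhyloTree, root_seq: str, m: RateMatrix, n_reps: int, seed: int
) -> Iterator[SequenceSet]:
    """Yield ``n_reps`` independent neutral replicates (a generator).

    Memory does not grow with ``n_reps``; consumers stream the replicates.
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    root_idx = encode_sequence(root_seq, where="root sequence")
    leaf_names = tree.leaf_names

    def gen() -> Iterator[SequenceSet]:
        for i in range(n_reps):
            leaves = _evolve_indices(tree, root_idx, m, replicate_rng(seed, i))
            yield SequenceSet(leaf_names, leaves)

    return gen()
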