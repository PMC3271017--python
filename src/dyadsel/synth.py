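"""Synthetic trees, root sequences and datasets for end-to-end studies.

Emulates the study design the test was built for: a few dozen homologous
protein domains (default 41) of ~70 residues related by a rooted tree with
a mix of short and long branches, evolved either neutrally or under a
selective constraint that every lineage keeps at least one copy of a target
dyad.  The constrained generator reproduces motif turnover: the copy that
satisfies the constraint is free to migrate, so a leaf may hold a dyad at a
position unrelated to the root's.

Topologies are uniform over labelled rooted bifurcating shapes (sequential
random joins); branch lengths are i.i.d. exponential.  The default branch
mean (0.25 expected substitutions per site) puts the neutral
containing-count of a two-residue motif in the mid single digits for a
41-leaf, 70-site problem — comparable divergence to a metazoan domain
family — and is deliberately fixed rather than tuned per experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from dyadsel.dyadtest import count_occurrences
from dyadsel.substmodel import RateMatrix
from dyadsel.treesim import PhyloTree, SequenceSet, encode_sequence

__all__ = [
    "SynthSpec",
    "RejectionCapError",
    "sample_tree",
    "sample_root",
    "generate_dataset",
    "generate_selected_dataset",
]


class RejectionCapError(RuntimeError):
    """A constrained edge exhausted its resampling budget (branch too long)."""


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic dataset.

    root_mode: "stationary" (i.i.d. from the model's stationary
    distribution), "fixed" (use ``root_seq`` verbatim) or "dyad_seeded"
    (stationary with exactly one planted copy of ``dyad``).
    selection: None for neutral evolution or "keep_dyad" to require every
    node of the tree to retain >= 1 copy of ``dyad``.
    """

    n_leaves: int = 41
    seq_length: int = 70
    branch_mean: float = 0.25
    branch_law: str = "exponential"
    root_mode: str = "stationary"
    root_seq: str | None = None
    dyad: str = "HD"
    selection: str | None = None
    seed: int = 0
    rejection_cap: int = 10_000

    def __post_init__(self):
        if self.n_leaves < 2:
            raise ValueError("n_leaves must be >= 2")
        if self.seq_length < 2:
            raise ValueError("seq_length must be >= 2")
        if self.branch_mean <= 0:
            raise ValueError("branch_mean must be > 0")
        if self.branch_law != "exponential":
            raise ValueError(f"unsupported branch law {self.branch_law!r}")
        if self.root_mode not in ("stationary", "fixed", "dyad_seeded"):
            raise ValueError(f"unknown root_mode {self.root_mode!r}")
        if self.root_mode == "fixed" and not self.root_seq:
            raise ValueError("root_mode='fixed' requires root_seq")
        if self.selection not in (None, "keep_dyad"):
            raise ValueError(f"unknown selection mode {self.selection!r}")


def _tree_rng(spec: SynthSpec) -> np.random.Generator:
    return np.random.default_rng([spec.seed, 1001])


def _root_rng(spec: SynthSpec) -> np.random.Generator:
    return np.random.default_rng([spec.seed, 1002])


def _evolve_rng(spec: SynthSpec) -> np.random.Generator:
    return np.random.default_rng([spec.seed, 1003])


def sample_tree(spec: SynthSpec) -> PhyloTree:
    """Random rooted bifurcating tree with exponential branch lengths.

    Built by sequential random joins: starting from the ``n_leaves``
    labelled tips (T1..Tn), two uniformly chosen lineages are joined until
    one root remains, giving a uniform distribution over labelled rooted
    topologies.  Deterministic under ``spec.seed``.
    """
    rng = _tree_rng(spec)
    n = spec.n_leaves
    subtrees = [f"T{i + 1}" for i in range(n)]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        right = subtrees.pop(j)
        left = subtrees.pop(i)
        bl, br = rng.exponential(spec.branch_mean, size=2)
        subtrees.append(f"({left}:{bl:.10g},{right}:{br:.10g})")
    from dyadsel.treesim import parse_newick

    return parse_newick(subtrees[0] + ";")


def sample_root(spec: SynthSpec, m: RateMatrix) -> str:
    """Draw a root sequence according to ``spec.root_mode``."""
    if spec.root_mode == "fixed":
        return spec.root_seq
    rng = _root_rng(spec)
    idx = rng.choice(20, size=spec.seq_length, p=m.pi)
    if spec.root_mode == "dyad_seeded":
        pos = int(rng.integers(0, spec.seq_length - 1))
        a, b = spec.dyad
        idx[pos] = m.alphabet.index(a)
        idx[pos + 1] = m.alphabet.index(b)
    return m.decode(idx)


def _contains(idx: np.ndarray, a: int, b: int) -> bool:
    return bool(((idx[:-1] == a) & (idx[1:] == b)).any())


def generate_dataset(
    spec: SynthSpec, m: RateMatrix, tree: PhyloTree | None = None, root: str | None = None
) -> SequenceSet:
    """Generate one leaf set under ``spec`` (neutral or constrained).

    ``tree`` and ``root`` default to ``sample_tree``/``sample_root`` under
    the spec's seed.  With ``selection=None`` this is exactly one neutral
    replicate: the unconstrained path consumes the random stream identically
    to the constrained path when no resampling occurs, so switching
    selection off on the same seed recovers the neutral output whenever the
    constraint never rejected.
    """
    if tree is None:
        tree = sample_tree(spec)
    if root is None:
        root = sample_root(spec, m)
    rng = _evolve_rng(spec)
    root_idx = encode_sequence(root, where="root sequence")
    constrained = spec.selection == "keep_dyad"
    if constrained:
        a, b = (m.alphabet.index(c) for c in spec.dyad)
        if not _contains(root_idx, a, b):
            raise ValueError(
                f"selection requires the root to contain the {spec.dyad} dyad"
            )
    states = np.empty((tree.n_nodes, len(root_idx)), dtype=np.uint8)
    states[0] = root_idx
    for i in range(1, tree.n_nodes):
        t = tree.branch_lengths[i]
        parent = states[tree.parent[i]]
        if t == 0.0:
            states[i] = parent
            continue
        cum = m.cumulative_transition(t)
        rows = cum[parent]
        for attempt in range(spec.rejection_cap):
            u = rng.random(len(root_idx))
            child = (u[:, None] < rows).argmax(axis=1).astype(np.uint8)
            if not constrained or _contains(child, a, b):
                states[i] = child
                break
        else:
            raise RejectionCapError(
                f"edge into node {tree.names[i]!r} (length {t:.3g}) failed to "
                f"retain the {spec.dyad} dyad within {spec.rejection_cap} resamples"
            )
    return SequenceSet(tree.leaf_names, states[tree.is_leaf])


def generate_selected_dataset(
    spec: SynthSpec, m: RateMatrix, tree: PhyloTree | None = None, root: str | None = None
) -> SequenceSet:
    """Dataset in which every node keeps >= 1 copy of the target dyad.

    Per-edge rejection sampling: an edge outcome that loses the last copy
    is redrawn (up to ``spec.rejection_cap`` times).  Copies are free to
    migrate, so leaves satisfy the constraint without positional
    conservation — the motif-turnover scenario.  The root must contain the
    dyad; use root_mode="dyad_seeded".
    """
    if spec.selection != "keep_dyad":
        spec = replace(spec, selection="keep_dyad")
    return generate_dataset(spec, m, tree=tree, root=root)
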