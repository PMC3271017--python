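"""Dyad counting, Monte-Carlo null distributions and the selection test.

The test statistic for a dyad (an ordered pair of adjacent residues, e.g.
HD) is the number of sequences in a set that contain at least one copy of
it.  Simulating neutral evolution down the observed phylogeny many times
yields an empirical null distribution of that statistic; the p-value is the
fraction of neutral replicates whose statistic is at least the observed
value.  Because sequences at the leaves of one tree are correlated, the
null is typically multimodal — a parametric approximation is deliberately
not offered.

When every neutral replicate falls below the observation the p-value is
reported as an explicit upper bound (``< 1/n_reps``), never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from dyadsel.substmodel import AA_INDEX, ALPHABET
from dyadsel.treesim import SequenceSet

__all__ = [
    "DyadNull",
    "DyadTestResult",
    "count_occurrences",
    "n_sequences_containing",
    "build_null",
    "empirical_pvalue",
    "scan_all_dyads",
    "multi_copy_fraction",
    "mean_containing_count",
    "ALL_DYADS",
]

#: All 400 ordered residue pairs in row-major alphabet order.
ALL_DYADS = tuple(a + b for a in ALPHABET for b in ALPHABET)


def _dyad_codes(dyad: str) -> tuple[int, int]:
    if len(dyad) != 2 or any(c not in AA_INDEX for c in dyad):
        raise ValueError(f"dyad must be two standard one-letter residues, got {dyad!r}")
    return AA_INDEX[dyad[0]], AA_INDEX[dyad[1]]


def count_occurrences(seq, dyad: str) -> int:
    """Number of (possibly overlapping) occurrences of ``dyad`` in ``seq``.

    Counts positions ``i`` with ``seq[i:i+2] == dyad``; order matters and
    overlaps all count (``HH`` occurs twice in ``HHH``).
    """
    a, b = _dyad_codes(dyad)
    if isinstance(seq, str):
        if len(seq) < 2:
            return 0
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        return int(np.count_nonzero((arr[:-1] == ord(dyad[0])) & (arr[1:] == ord(dyad[1]))))
    arr = np.asarray(seq)
    if arr.size < 2:
        return 0
    return int(np.count_nonzero((arr[:-1] == a) & (arr[1:] == b)))


def _containing_mask(s: SequenceSet, a: int, b: int) -> np.ndarray:
    """Boolean per sequence: contains at least one copy of the dyad."""
    hits = (s.idx[:, :-1] == a) & (s.idx[:, 1:] == b)
    return hits.any(axis=1)


def _copy_counts(s: SequenceSet, a: int, b: int) -> np.ndarray:
    hits = (s.idx[:, :-1] == a) & (s.idx[:, 1:] == b)
    return hits.sum(axis=1)


def n_sequences_containing(s: SequenceSet, dyad: str) -> int:
    """Number of sequences in the set with at least one copy of ``dyad``."""
    a, b = _dyad_codes(dyad)
    return int(_containing_mask(s, a, b).sum())


@dataclass(frozen=True)
class DyadNull:
    """Empirical null histogram of the containing-count statistic.

    ``histogram[k]`` is the number of neutral replicates in which exactly
    ``k`` of the leaf sequences contained at least one copy of the dyad;
    support runs 0..n_leaves and the histogram sums to ``n_reps``.
    """

    dyad: str
    histogram: np.ndarray
    n_reps: int

    def __post_init__(self):
        if int(self.histogram.sum()) != self.n_reps:
            raise ValueError("histogram must sum to n_reps")

    @property
    def n_leaves(self) -> int:
        return len(self.histogram) - 1

    def tail_count(self, observed: int) -> int:
        return int(self.histogram[observed:].sum())

    def mean(self) -> float:
        k = np.arange(len(self.histogram))
        return float((k * self.histogram).sum() / self.n_reps)


@dataclass(frozen=True)
class DyadTestResult:
    """Outcome of the empirical overrepresentation test for one dyad."""

    dyad: str
    observed: int
    exceedances: int
    n_reps: int

    @property
    def p_value(self) -> float:
        """Empirical p; equals the bound 1/n_reps when no replicate reached
        the observation (see :attr:`p_is_upper_bound`)."""
        if self.exceedances == 0:
            return 1.0 / self.n_reps
        return self.exceedances / self.n_reps

    @property
    def p_is_upper_bound(self) -> bool:
        return self.exceedances == 0

    def __str__(self) -> str:
        rel = "<" if self.p_is_upper_bound else "="
        return f"{self.dyad}: observed={self.observed}, p {rel} {self.p_value:g}"


def build_null(reps: Iterable[SequenceSet], dyad: str) -> DyadNull:
    """Accumulate the null histogram over replicates in a single pass."""
    a, b = _dyad_codes(dyad)
    hist = None
    n_leaves = None
    n_reps = 0
    for s in reps:
        if n_leaves is None:
            n_leaves = s.n_sequences
            hist = np.zeros(n_leaves + 1, dtype=np.int64)
        elif s.n_sequences != n_leaves:
            raise ValueError(
                f"heterogeneous leaf counts across replicates: {s.n_sequences} != {n_leaves}"
            )
        hist[int(_containing_mask(s, a, b).sum())] += 1
        n_reps += 1
    if n_reps == 0:
        raise ValueError("at least one replicate is required")
    return DyadNull(dyad=dyad, histogram=hist, n_reps=n_reps)


def empirical_pvalue(null: DyadNull, observed: int) -> DyadTestResult:
    """Test an observed containing-count against the neutral null.

    The p-value is the probability, under neutrality, of a containing-count
    at least as high as the observation.
    """
    if not 0 <= observed <= null.n_leaves:
        raise ValueError(f"observed count {observed} outside support 0..{null.n_leaves}")
    return DyadTestResult(
        dyad=null.dyad,
        observed=int(observed),
        exceedances=null.tail_count(int(observed)),
        n_reps=null.n_reps,
    )


def scan_all_dyads(
    reps: Iterable[SequenceSet], observed: SequenceSet, alpha: float = 0.01
) -> pd.DataFrame:
    """Run the overrepresentation test for all 400 ordered dyads at once.

    A single pass over the replicates accumulates all 400 null histograms
    simultaneously.  Returns a table with columns ``dyad, observed,
    exceedances, n_reps, p_value, p_is_upper_bound, flagged`` sorted by
    p-value; ``flagged`` marks ``p_value <= alpha`` (no multiple-testing
    correction — the scan is read against the expected ``400 * alpha``
    false positives).
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    obs_counts = _all_dyad_containing_counts(observed)
    n_leaves = observed.n_sequences
    hist = np.zeros((400, n_leaves + 1), dtype=np.int64)
    n_reps = 0
    for s in reps:
        if s.n_sequences != n_leaves:
            raise ValueError(
                f"replicate leaf count {s.n_sequences} != observed set size {n_leaves}"
            )
        counts = _all_dyad_containing_counts(s)
        hist[np.arange(400), counts] += 1
        n_reps += 1
    if n_reps == 0:
        raise ValueError("at least one replicate is required")

    # tail counts: replicates with containing-count >= observed, per dyad
    cum_from_right = np.cumsum(hist[:, ::-1], axis=1)[:, ::-1]
    exceed = cum_from_right[np.arange(400), obs_counts]
    p = np.where(exceed > 0, exceed / n_reps, 1.0 / n_reps)
    table = pd.DataFrame(
        {
            "dyad": list(ALL_DYADS),
            "observed": obs_counts,
            "exceedances": exceed,
            "n_reps": n_reps,
            "p_value": p,
            "p_is_upper_bound": exceed == 0,
        }
    )
    table["flagged"] = (table["p_value"] <= alpha) & (alpha > 0)
    return table.sort_values("p_value", kind="stable").reset_index(drop=True)


def _all_dyad_containing_counts(s: SequenceSet) -> np.ndarray:
    """Containing-count of every ordered dyad in one set (length-400 array)."""
    codes = s.idx[:, :-1].astype(np.int16) * 20 + s.idx[:, 1:]
    counts = np.zeros(400, dtype=np.int64)
    for row in codes:
        counts[np.unique(row)] += 1
    return counts


def multi_copy_fraction(reps: Iterable[SequenceSet], dyad: str) -> float:
    """Fraction of replicates with >= 1 sequence carrying >= 2 dyad copies.

    High values mean new copies of the motif arise readily under neutral
    drift — the raw material for motif turnover.
    """
    a, b = _dyad_codes(dyad)
    n_reps = 0
    n_multi = 0
    for s in reps:
        n_reps += 1
        if (_copy_counts(s, a, b) >= 2).any():
            n_multi += 1
    if n_reps == 0:
        raise ValueError("at least one replicate is required")
    return n_multi / n_reps


def mean_containing_count(reps: Iterable[SequenceSet], dyad: str) -> float:
    """Mean over replicates of the number of dyad-containing sequences."""
    a, b = _dyad_codes(dyad)
    total = 0
    n_reps = 0
    for s in reps:
        total += int(_containing_mask(s, a, b).sum())
        n_reps += 1
    if n_reps == 0:
        raise ValueError("at least one replicate is required")
    return total / n_reps


def type_i_error_rate(
    tree,
    root_seq: str,
    m,
    dyad: str = "HD",
    n_trials: int = 1000,
    n_reps: int = 250,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Monte-Carlo estimate of the test's type-I error under neutrality.

    Each trial simulates ``n_reps + 1`` fresh neutral replicates down the
    tree, treats the first as the "observed" dataset and the rest as the
    null, and rejects when the empirical p-value is at most ``alpha``.
    Returns the fraction of trials rejected, which for a calibrated test
    should sit near ``alpha``.
    """
    from dyadsel.treesim import simulate_replicates

    rejections = 0
    for trial in range(n_trials):
        reps = simulate_replicates(tree, root_seq, m, n_reps + 1, seed + trial)
        observed = next(reps)
        null = build_null(reps, dyad)
        res = empirical_pvalue(null, n_sequences_containing(observed, dyad))
        if res.p_value <= alpha:
            rejections += 1
    return rejections / n_trials


def results_table(results: Iterable[DyadTestResult]) -> pd.DataFrame:
    """Tabulate test results (TSV-ready)."""
    return pd.DataFrame(
        {
            "dyad": [r.dyad for r in results],
            "observed": [r.observed for r in results],
            "exceedances": [r.exceedances for r in results],
            "n_reps": [r.n_reps for r in results],
            "p_value": [r.p_value for r in results],
            "p_is_upper_bound": [r.p_is_upper_bound for r in results],
        }
    )
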