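"""Proteome residue and dyad composition, and the dyad log-odds table.

For a collection of protein sequences the single-residue distribution
``p(a)`` and the adjacent-pair (dyad) distribution ``pi(a, b)`` are counted
empirically; the log-odds of dyad ``ab`` is

    s(a, b) = log_base( pi(a, b) / (p(a) * p(b)) )

Negative values mean the dyad occurs less often than its residue
frequencies would predict under independence (underrepresentation).
Dyads are counted within sequences only, never across record boundaries,
and in first-then-second order (HD and DH are distinct cells).
Nonstandard residues (B, J, O, U, X, Z, gaps) are excluded from the single
counts, and any adjacent pair touching one is excluded from the dyad
counts; they are never remapped, which would silently distort pi.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from dyadsel.substmodel import AA_INDEX, ALPHABET

__all__ = [
    "CompositionTable",
    "LogOddsTable",
    "composition",
    "log_odds",
    "split_by_species",
    "merge_compositions",
]

_ENCODE = np.full(256, -1, dtype=np.int16)
for _aa, _i in AA_INDEX.items():
    _ENCODE[ord(_aa)] = _i
    _ENCODE[ord(_aa.lower())] = _i


@dataclass(frozen=True)
class CompositionTable:
    """Empirical single-residue and dyad counts and distributions.

    Integer counts are kept so that compositions of disjoint collections
    merge exactly; the probability views are derived.
    """

    single_counts: np.ndarray  # (20,) int
    dyad_counts: np.ndarray  # (20, 20) int
    n_sequences: int

    @property
    def n_residues(self) -> int:
        return int(self.single_counts.sum())

    @property
    def n_dyads(self) -> int:
        return int(self.dyad_counts.sum())

    @property
    def single(self) -> np.ndarray:
        """p(a): single-residue probability vector (sums to 1)."""
        return self.single_counts / self.single_counts.sum()

    @property
    def dyad(self) -> np.ndarray:
        """pi(a, b): dyad probability matrix (sums to 1)."""
        return self.dyad_counts / self.dyad_counts.sum()

    def to_tsv(self, path) -> None:
        """Write counts (single as a header block, dyads as a 20x20 table)."""
        letters = list(ALPHABET)
        with open(path, "w") as fh:
            fh.write(f"# n_sequences\t{self.n_sequences}\n")
            fh.write("residue\t" + "\t".join(letters) + "\n")
            fh.write("count\t" + "\t".join(str(int(c)) for c in self.single_counts) + "\n")
            pd.DataFrame(self.dyad_counts, index=letters, columns=letters).to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "CompositionTable":
        with open(path) as fh:
            n_sequences = int(fh.readline().split("\t")[1])
            fh.readline()
            single = np.array([int(x) for x in fh.readline().split("\t")[1:]])
            dyads = pd.read_csv(fh, sep="\t", index_col=0)
        return cls(
            single_counts=single,
            dyad_counts=dyads.loc[list(ALPHABET), list(ALPHABET)].to_numpy(dtype=np.int64),
            n_sequences=n_sequences,
        )


@dataclass(frozen=True)
class LogOddsTable:
    """20x20 dyad log-odds; cells with zero dyad probability are NaN.

    ``defined`` flags the numeric cells.  Rows are the first residue of the
    dyad, columns the second.
    """

    s: np.ndarray
    base: float
    source: str = ""

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.s)

    def value(self, dyad: str) -> float:
        return float(self.s[AA_INDEX[dyad[0]], AA_INDEX[dyad[1]]])

    def to_dataframe(self) -> pd.DataFrame:
        letters = list(ALPHABET)
        return pd.DataFrame(self.s, index=letters, columns=letters)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# log base\t{self.base:g}\n")
            if self.source:
                fh.write(f"# source\t{self.source}\n")
            self.to_dataframe().to_csv(fh, sep="\t", float_format="%.6f")


def _iter_fasta(source) -> Iterator[tuple[str, str]]:
    """Yield (header, sequence) from FASTA path/handle or (label, seq) pairs."""
    if isinstance(source, (str, Path)):
        opener = gzip.open if str(source).endswith(".gz") else open
        from Bio import SeqIO

        with opener(source, "rt") as fh:
            for rec in SeqIO.parse(fh, "fasta"):
                yield rec.description, str(rec.seq)
        return
    for item in source:
        if isinstance(item, tuple):
            yield item
        else:  # Bio.SeqRecord
            yield item.description, str(item.seq)


def composition(fasta) -> CompositionTable:
    """Count residue and dyad frequencies over a protein FASTA collection.

    ``fasta`` may be a path (plain or gzipped), an open handle, an iterable
    of ``(label, sequence)`` pairs, or of Bio.SeqRecord objects.  Raises if
    the collection contains no valid dyad at all.
    """
    single = np.zeros(20, dtype=np.int64)
    dyads = np.zeros((20, 20), dtype=np.int64)
    n_sequences = 0
    for _, seq in _iter_fasta(fasta):
        if not seq:
            continue
        n_sequences += 1
        codes = _ENCODE[np.frombuffer(seq.encode("latin-1"), dtype=np.uint8)]
        valid = codes >= 0
        np.add.at(single, codes[valid], 1)
        a, b = codes[:-1], codes[1:]
        pair_ok = (a >= 0) & (b >= 0)
        np.add.at(dyads, (a[pair_ok], b[pair_ok]), 1)
    if dyads.sum() == 0:
        raise ValueError("no valid adjacent standard-residue pair in the input")
    return CompositionTable(single_counts=single, dyad_counts=dyads, n_sequences=n_sequences)


def merge_compositions(*tables: CompositionTable) -> CompositionTable:
    """Exact count-weighted merge; equals composition of the concatenation."""
    if not tables:
        raise ValueError("nothing to merge")
    return CompositionTable(
        single_counts=sum(t.single_counts for t in tables),
        dyad_counts=sum(t.dyad_counts for t in tables),
        n_sequences=sum(t.n_sequences for t in tables),
    )


def log_odds(c: CompositionTable, base: float = 2.0, source: str = "") -> LogOddsTable:
    """Dyad log-odds s(a,b) = log_base(pi(a,b) / (p(a) p(b))).

    The logarithm base is explicit (default 2) and recorded in the output;
    cells whose dyad was never seen are NaN rather than -inf.
    """
    if base <= 0 or base == 1:
        raise ValueError("log base must be positive and != 1")
    p = c.single
    pi = c.dyad
    expected = np.outer(p, p)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.log(pi / expected) / np.log(base)
    s[pi == 0] = np.nan
    return LogOddsTable(s=s, base=float(base), source=source)


# UniProt-style header: "... OS=Homo sapiens OX=9606 GN=..."; the species
# name runs until the next KEY= token or end of header.
_UNIPROT_OS = re.compile(r"\bOS=(.+?)(?:\s+[A-Z]{2}=|$)")


def split_by_species(
    fasta,
    min_sequences: int = 1000,
    pattern: str | re.Pattern | None = None,
) -> dict[str, list[tuple[str, str]]]:
    """Group records by species tag; keep species with > min_sequences records.

    The UniProt ``OS=`` convention is tried first; ``pattern`` (a regex with
    one capture group) is the fallback for other header dialects.  A record
    from which no species can be parsed is an error, reported with its id.
    Species at or below the threshold are dropped (strictly "more than").
    """
    fallback = re.compile(pattern) if isinstance(pattern, str) else pattern
    groups: dict[str, list[tuple[str, str]]] = {}
    for header, seq in _iter_fasta(fasta):
        match = _UNIPROT_OS.search(header)
        if match is None and fallback is not None:
            match = fallback.search(header)
        if match is None:
            rec_id = header.split()[0] if header.split() else "<empty header>"
            raise ValueError(f"no species tag parsable from record {rec_id!r}")
        groups.setdefault(match.group(1).strip(), []).append((header, seq))
    return {sp: recs for sp, recs in groups.items() if len(recs) > min_sequences}
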