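"""Checked-in synthetic fixtures (small, text-only).

``domain41.nwk`` / ``domain41_root.fasta`` are a synthetic stand-in for a
41-taxon, 70-residue protein-domain study: a random rooted bifurcating tree
(exponential branch lengths, mean 0.25 expected substitutions per site) and
an HD-seeded root drawn from the substitution model's stationary
composition.  Under neutral evolution the mean number of HD-containing
leaves is ~9 of 41, a realistic mid-range regime for the dyad test.
"""

from importlib import resources

__all__ = ["load_domain41"]


def load_domain41():
    """Return (PhyloTree, root_sequence) for the 41-leaf synthetic fixture."""
    from Bio import SeqIO

    from dyadsel.treesim import parse_newick

    pkg = resources.files(__name__)
    tree = parse_newick((pkg / "domain41.nwk").read_text())
    with (pkg / "domain41_root.fasta").open() as fh:
        rec = next(SeqIO.parse(fh, "fasta"))
    return tree, str(rec.seq)
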