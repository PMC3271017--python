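# dyadsel

Monte-Carlo detection of positively selected amino-acid **dyad motifs**
(ordered two-residue motifs such as His-Asp) in protein domains that show
no positional conservation.

## The problem

A motif can be functionally essential yet invisible to alignment-based
conservation analysis: if selection only requires *at least one copy
somewhere in the domain*, a new copy arising by chance mutation can replace
the old one, and the motif's position migrates through the family (motif
turnover). `dyadsel` asks the question the right way around: given the
family's phylogeny, how often would neutral evolution alone produce as many
motif-bearing sequences as we observe?

It is aimed at molecular evolution researchers with a domain family, a
rooted tree with branch lengths, and a candidate motif.

## The method

- **Substitution model.** A reversible continuous-time Markov chain over
  the 20 amino acids whose rate matrix `Q` is equivalent to BLOSUM62:
  the target-pair distribution is recovered from the published scores and
  background, the conditional matrix `M(a,b) = joint(a,b)/p(a)` is taken to
  its principal matrix logarithm, small negative rates are repaired, and
  `Q` is normalised to one expected substitution per site per unit time.
  Transition probabilities are computed spectrally,
  `P(t) = U exp(Λt) U⁻¹`.
- **Neutral null.** The root sequence is evolved down the tree
  site-independently many times (default 10 000); for each replicate the
  statistic is the number of leaf sequences containing ≥ 1 copy of the
  dyad. The empirical p-value of the observed count `x` is
  `#{replicates ≥ x}/n`, reported as the bound `< 1/n` when no replicate
  reaches it.
- **Cross-validation scan.** The same test applied to all 400 ordered
  dyads in a single pass, read against the expected `400·α` false
  positives.
- **Proteome log-odds.** For any FASTA collection,
  `s(a,b) = log₂(π(a,b)/(p(a)·p(b)))` — negative values flag dyads that are
  underrepresented relative to residue composition.
- **Synthetic data.** Generators for random trees, stationary or
  motif-seeded roots, and selection-constrained datasets (every lineage
  forced to keep ≥ 1 copy, position free to migrate) make the whole
  pipeline testable end to end.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Generate a selection-constrained 41-leaf, 70-residue dataset and test it
against its own neutral null:

```sh
$ dyadsel pipeline --reps 10000 --seed 7 --out pipe_demo
HD: observed=41, p < 0.0001
```

All 41 leaves carry the HD dyad (the selection constraint), while none of
the 10 000 neutral replicates had all 41 leaves carrying it, so neutrality
is rejected at the resolution of the replicate count
(`pipe_demo/test_result.tsv`):

```
dyad  observed  exceedances  n_reps  p_value  p_is_upper_bound
HD    41        0            10000   0.0001   True
```

The same machinery is available as a library:

```python
from dyadsel import (build_blosum62_rate_matrix, simulate_replicates,
                     build_null, empirical_pvalue, n_sequences_containing)
from dyadsel.data import load_domain41

model = build_blosum62_rate_matrix()
tree, root = load_domain41()            # bundled 41-leaf synthetic fixture
null = build_null(simulate_replicates(tree, root, model, 10_000, seed=1), "HD")
print(empirical_pvalue(null, observed=41))
```

Other subcommands: `dyadsel test` / `dyadsel scan` for observed FASTA sets
against a user tree and root, `dyadsel logodds` for proteome tables
(optionally split per species), `dyadsel synth` for dataset generation and
`dyadsel model` to export `Q`, `π` and `P(t)` as TSV. Every run writes a
JSON manifest with hashed inputs, seed and parameters.

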