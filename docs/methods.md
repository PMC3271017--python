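# Methods

## The problem

Some protein motifs are maintained by selection without being positionally
conserved: a two-residue motif (a *dyad*, e.g. His-Asp) can be present in
almost every member of a domain family while sitting at a different
position in each, because a newly arisen copy can substitute for the loss
of the old one (motif turnover). Column-wise conservation scores are blind
to this. `dyadsel` tests for such selection by simulating neutral evolution
of the family down its phylogeny and asking how often neutrality alone
produces as many motif-bearing sequences as observed.

## Substitution model

Evolution is modelled as a site-independent, branch-independent,
continuous-time Markov chain over the 20 standard amino acids with
instantaneous rate matrix `Q` and transition probabilities
`P(t) = exp(Qt)`, evaluated through the spectral form
`P(t) = U exp(Λt) U⁻¹`. The chain is reversible, so all spectral
computations are done in the symmetric similarity frame
`diag(√π) Q diag(1/√π)` (real eigenvalues, orthogonal eigenbasis); the
resulting `P(t)` has its rare `O(1e-16)` negative entries clamped and rows
renormalised, with an error raised if any row sum was off by more than
1e-8 beforehand.

`Q` is made equivalent to BLOSUM62 as follows:

1. The published integer half-bit scores `s(a,b)` and the published
   background vector seed a reconstruction of the target-pair
   distribution: `joint(a,b) = p(a) p(b) exp(c·s(a,b))`, with the scalar
   `c` solved (Brent) so the joint sums to exactly 1. `c` would be
   `ln(2)/2` for unrounded scores; solving absorbs the integer rounding.
2. The model's background/stationary vector is the marginal of that joint.
   It differs from the published 3-decimal background by at most 0.0038
   per residue — the footprint of score rounding — which is the tolerance
   used when the two are compared in tests.
3. The conditional matrix `M = joint / π` (row-stochastic, reversible) is
   taken to its principal matrix logarithm in the symmetric frame. The log
   exists and is real here because all eigenvalues of `M` are positive
   (smallest ≈ 0.058).
4. The logarithm leaves two slightly negative off-diagonal rates (worst
   ≈ −0.0056); they are clamped to zero. Because detailed balance pairs
   negative entries symmetrically, clamping preserves reversibility
   exactly. Changes larger than a configurable threshold (default 0.01)
   raise an error, as they would indicate a corrupted input table.
5. Diagonals are reset so rows sum to zero and `Q` is rescaled to one
   expected substitution per site per unit time, so branch lengths in
   expected substitutions per site are usable directly as times. Trees in
   other units (e.g. PAM/100) are converted with a branch-scale factor
   rather than guessed at.

## Simulation

A replicate starts from the root sequence and, for each edge in preorder,
draws every child residue from the `P(branch length)` row of its parent
residue. Transition matrices are computed once per distinct branch length
and cached, since many replicates share one tree. Replicate `i` of a run
uses the NumPy stream keyed by `[seed, i]`, so replicates are independent
and individually regenerable; `simulate_replicates` is a generator and
memory does not grow with the replicate count. Gapped roots are rejected
(degapping is an explicit preprocessing step), polytomies are simulated
as independent children, and zero-length edges copy the parent.

## The test

For a dyad `d` the statistic is the number of sequences in a set
containing at least one copy of `d` (overlapping copies count when copies
are counted, but one sequence counts once regardless of copy number).
The null distribution is the histogram of this statistic over `n`
neutral replicates; the p-value of an observed count `x` is
`#{replicates ≥ x} / n`. When no replicate reaches `x` the result is
reported as the explicit bound `< 1/n` together with the raw exceedance
count, never as zero. The statistic's null is typically multimodal
(leaf sequences are correlated through the tree), which is why no
parametric approximation is offered.

`scan_all_dyads` accumulates all 400 ordered-pair histograms in a single
pass and reports raw p-values with a flag at a chosen `alpha`; no
multiple-testing correction is applied, because the intended reading is a
comparison of the flagged count against the expected `400·alpha` false
positives. `multi_copy_fraction` (replicates with a sequence carrying ≥2
copies) and `mean_containing_count` summarise the turnover regime: a high
multi-copy fraction means new copies arise readily, so presence can be
maintained while position migrates.

## Proteome log-odds

For a sequence collection, `p(a)` is the single-residue distribution and
`π(a,b)` the adjacent-pair distribution (pairs never straddle record
boundaries; order matters; pairs touching a nonstandard residue are
excluded rather than remapped). The dyad log-odds is
`s(a,b) = log_base(π(a,b) / (p(a)·p(b)))`; negative values mean the dyad
is underrepresented relative to residue composition. The base is an
explicit parameter (default 2) recorded in every output, since the
absolute scale of reported log-odds values is meaningless without it.
Counts are kept as integers so compositions of disjoint collections merge
exactly. Species splitting follows the UniProt `OS=` convention with a
configurable regex fallback and keeps species with strictly more than a
threshold (default 1000) of records.

## Synthetic data

The generator emulates a family of a few dozen short domains related by a
rooted tree: random labelled bifurcating topology (sequential random
joins), i.i.d. exponential branch lengths, and a root drawn from the
model's stationary distribution, optionally with one planted copy of a
target dyad. The default scale — 41 leaves, 70 residues, branch mean 0.25
expected substitutions per site — was fixed once so that the neutral mean
number of motif-containing leaves sits in the mid single digits to low
teens (measured ≈ 8–15 with a motif-bearing root, ≈ 3 with a motif-free
root, across seeds), a realistic regime for a metazoan domain family; a
41-leaf tree and HD-seeded root generated this way ship as a bundled
text fixture (`dyadsel.data.load_domain41`).

Selection ("keep at least one copy") is implemented by per-edge rejection
sampling: an edge outcome that leaves the child without a copy is redrawn,
up to a cap (default 10 000) whose exhaustion raises an error rather than
silently biasing the sample. Rejection gives the exact conditioned
distribution per edge with a simple correctness argument; conditioned
path-sampling would be faster on very long branches but is not needed at
this scale. Copies are free to migrate, reproducing turnover: on
long-branch trees most leaves carry the dyad away from the root's planted
position.

What the generator does *not* emulate: real domain composition beyond the
stationary distribution, indels (sequences stay aligned by construction),
among-site rate variation, and tree uncertainty. Passing tests therefore
demonstrate the statistical machinery is correct and calibrated under its
own model, not that any particular real family is under selection.

## Numerical and design choices

- Alphabet order is alphabetical one-letter (`ACDEFGHIKLMNPQRSTVWY`)
  everywhere, including TSV headers.
- Transition-matrix agreement is checked against an independent
  Taylor-series matrix exponential (1e-8 entrywise over random times), plus
  semigroup (Chapman–Kolmogorov), stationarity and long-time-limit checks.
- Per-cell simulator calibration uses 3 binomial standard deviations with
  an allowance for the ~1 of 400 cells expected beyond 3 SD by chance, and
  a hard 5 SD cap.
- Type-I calibration runs 1000 trials, each with a fresh observation and a
  fresh 250-replicate null at `alpha = 0.05`, asserting the rejection rate
  inside the 99% binomial band around 0.05. The empirical p-value without
  the +1 correction is slightly anti-conservative (continuous-case rate
  13/251 ≈ 0.052) while the integer statistic is slightly conservative;
  both effects are well inside the band (measured ≈ 0.04–0.05).
- The neutral 400-dyad scan is asserted pooled over three runs against the
  exact Binomial(1200, 0.01) 99% band, because a single run's band
  includes zero.

## Known limitations

- The rate matrix is "a" BLOSUM62-equivalent, not "the" one any particular
  earlier implementation used: published constructions form a family, and
  only invariants plus downstream statistics are contractual.
- Motifs longer than two residues are out of scope (the counting layer is
  the natural extension point).
- p-values are bounded below by `1/n_reps`; claims beyond that bound
  require more replicates, not extrapolation.
- The test conditions on the input tree and root; uncertainty in either is
  not propagated.
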