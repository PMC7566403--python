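# Methods

## Substitution model

Codon evolution follows a reversible Goldman–Yang-style Markov process over
the 61 sense codons of the standard genetic code (codons ordered
alphabetically over A,C,G,T; stop codons excluded). For codons differing at
exactly one position the instantaneous rate is
`q_ij ∝ π_j · κ^[transition] · ω^[nonsynonymous]`; all other off-diagonal
rates are zero. Each single-ω generator is scaled so that
`Σ_i π_i (−q_ii) = 1`, making a branch length the expected number of
substitutions per codon on that branch.

Equilibrium frequencies π come from the alignment: `F3x4` (default,
position-specific nucleotide frequencies renormalized over sense codons),
`F1x4` (pooled) or `uniform`. Exact zero frequencies (possible in short
alignments) are floored at 1e-10 and renormalized inside the likelihood so
the spectral decomposition stays defined; the reported π keeps the raw
zeros.

### Mixture scaling in the branch-site model

In the branch-site mixture the four site classes share a *common* scale
factor per branch — the proportion-weighted mean rate over the classes
active on that branch — rather than each class being scaled to unit rate
individually. Equivalently, the class with generator Q(ω)/m(ω) runs on an
effective branch length t·m(ω)/f. This is the standard convention for
codon mixture models and it is what makes ω₂ identifiable: with per-class
scaling ω₂ would only change the synonymous/nonsynonymous *composition* of
a fixed number of substitutions on one short branch, which carries almost
no information (we measured a log-likelihood range of ≈0.1 across
ω₂ ∈ [1, 16] at the generating parameters). The simulator uses the same
convention, and the single-ω scaling of `build_rate_matrix` is unchanged.

## Likelihood computation

Felsenstein pruning over the unrooted tree, with:

* site-pattern compression (identical columns computed once, weighted);
* a symmetric eigendecomposition of `diag(√π) Q diag(1/√π)`, so P(t) for
  every branch costs two small matrix products after one `eigh` per ω;
* per-node rescaling of partial likelihoods (log-scale accumulator) against
  underflow on deep trees;
* for the branch-site mixture, the traversal is rooted at the parent of the
  single foreground branch: the four classes share the two background
  pruning passes (background ω₀ and ω = 1) and differ only in the
  transition matrix crossed on the foreground branch, roughly halving the
  cost per evaluation.

Unresolved codons (gaps, Ns, and stop codons observed in data — the latter
with a warning) contribute a unit partial likelihood, i.e. are treated as
missing for that taxon and site. Time reversibility makes the result
independent of the rooting; this is tested directly, and the pruning value
is tested against exhaustive enumeration over all 61² internal-state
assignments on a quartet tree.

## Fitting

Models follow the statsmodels convention: `BranchModel(aln, tree)` /
`BranchSiteModel(aln, tree)` are built from data, `.fit()` maximizes both
hypotheses and returns a results object with the estimates, the paired
H0/H1 fits, the LRT and `summary()`.

Optimization is bounded L-BFGS-B on transformed parameters: log κ
(bounds 1e-3…100), log ω (1e-6…999), log branch scale (e^±8), stick-breaking
logits for (p0, p1) (bounds ±10), and ω₂ = 1 + e^u (so ω₂ ≥ 1 by
construction). Multi-start with a deterministic start schedule (default 3
restarts; ties broken by likelihood, then lexicographically smallest
parameter vector). Fits are warm-started along the model hierarchy: the
shared one-ω fit seeds H0, and each H1 starts from its H0 optimum plus
elevated-ω starts — the ω₂ ≈ 1 anchor sits on a flat boundary of the
profile, so an elevated start (ω₂ = 3) is always included. If the H1 search
ends marginally below the H0 optimum (numerically possible at the
boundary), the boundary point itself is reported, and any residual negative
LRT is clamped to zero (with a warning beyond −0.01) since a nested null
cannot truly fit better.

Branch lengths: by default the input lengths act as relative lengths with
one free global scale estimated under every hypothesis ("scale" mode; the
species topology is used ignoring its lengths, which start uniform at 0.1).
A "per-branch" mode first optimizes each length under the one-ω model by
coordinate descent and then holds the profile fixed up to the free scale —
this mirrors estimating the gene tree once and reusing it, at roughly 40×
the cost, and is exposed as `--full-branch-opt` in the CLI.

## QC and the CMD diagnostic

Before testing, each gene alignment is reduced to codon columns fully
resolved in every taxon; genes then need ≥ 20 codons and ≥ 1 variable
column. The low-quality screen translates each column to amino acids,
computes Shannon entropy normalized by ln(n_taxa) to [0, 1], smooths with a
centered 3-column moving average (truncated at the ends) and flags any
column above 0.5; a flagged gene is excluded. The entropy screen is a
transparent re-specification of block-filtering tools of the BMGE family,
which motivated the window of 3 and the 0.5 threshold; amino-acid (rather
than nucleotide) entropy was chosen because misalignment and frameshift
damage show up most clearly in translation.

A CMD ("codon with multiple differences") is an alignment column where at
least one query taxon differs from a fully resolved reference codon at ≥ 2
of the 3 positions; each column counts at most once, and columns whose
reference codon is unresolved are excluded from the denominator so the
proportion is a within-gene rate. CMD load is related to test outcomes with
a two-sample permutation test on the Welch t statistic (label permutations,
two-sided, +1-corrected; exact enumeration when there are at most `n_perm`
arrangements, in which case no correction is applied) and to estimates with
Kendall's τ-b (tie-corrected, normal-approximation p, via scipy). With zero
variance in both groups the Welch t is defined as 0 for equal means and ±∞
otherwise.

## Scan, classification, FDR

Per gene: QC → branch H0/H1 → branch-site H0/H1 (reusing the branch model's
length profile) → LRTs. Genes with foreground ω̂ (ω₁ or ω₂) above 500 are
flagged as unreliable — such values mean the synonymous rate estimate is
near zero — and are excluded before a Benjamini–Hochberg correction applied
separately per model (an alternative reading, capping only nominally
significant genes, is available via `cap_only_significant`). Lists:

* list i — branch LRT > 3.8415 and ω₀ ≤ 1 < ω₁,
* list ii — branch LRT > 3.8415 and ω₀ < ω₁ < 1,
* list iii — branch-site LRT > 3.8415 and ω₂ > 1 (ω₂ exactly 1 with a
  significant LRT is classified as none),

with dual membership (a branch list plus list iii) allowed. The χ²₁
reference for the branch-site test is deliberately conservative relative to
the 50:50 boundary mixture. The all-branch specificity scan refits the
branch model with every branch in turn as foreground and calls a gene
"focal-specific" only when the designated focal branch alone is significant
at the Bonferroni level α / n_branches.

## Enrichment

Candidate-versus-background overrepresentation uses the exact upper-tail
hypergeometric probability (log-space binomial summation, cross-checked
against scipy). The background defaults to the genes actually tested in the
scan (annotation restricted to them) to avoid coverage bias; terms with
fewer than 3 background genes are skipped. Family-wise error rates come
from the permutation distribution of the *minimum* p across terms: each of
the (default 10,000) permutations redraws a candidate set of the same size
from the background, all terms share that one null sample, and
`fwer(term) = (1 + #{min-p ≤ p_obs}) / (n_perm + 1)`, which enforces
fwer ≥ per-term permutation p.

## Synthetic data

The simulator draws the root codon of each site from π and propagates
states down the tree from P(t) rows (an event-level Gillespie trace mode
records every substitution for counting oracles). Defaults define the study
conditions: the 20-taxon owl/outgroup topology with the owl-ancestor
foreground and uniform 0.1 branch lengths, κ = 2, uniform π, background
ω = 0.2, 300-codon genes, per-taxon-per-codon masking at 2% (emulating
zero-coverage masking; with 20 taxa this removes roughly a third of codon
columns after the missing-data filter) and gap columns at 0.5%. Masking and
gap injection use random streams separate from the evolutionary draws, so
the unmasked residues are identical across masking settings and every
output is byte-reproducible from its seed. Regime mixes in
`simulate_gene_set` are assigned deterministically by largest-remainder
counts; per-gene seeds derive from the master seed and a CRC of the gene id.

What the generator does *not* emulate: alignment error (sequences are
simulated already aligned in frame), indels beyond whole gap columns,
among-site rate variation beyond the ω classes, multinucleotide mutation
events, base-composition heterogeneity across lineages, and annotation
errors. Passing calibration and recovery tests therefore demonstrates
correctness of the inference machinery under the model's own assumptions,
not robustness to real-data artifacts — the CMD diagnostic exists precisely
because multinucleotide events violate these assumptions in real data.

## Validation studies and sizes

The acceptance studies (shared between `tests/test_acceptance.py` and
`scripts/acceptance.py`) use one optimizer start per hypothesis and these
sizes, chosen as the smallest giving stable binomial/recovery estimates:
branch-model type-I error over 100 null replicates and branch-site over 60
(300-codon genes on the 20-taxon tree); power over 30 replicates of 500
codons at ω_fg = 4 vs ω_bg = 0.2; κ recovery over 5 replicates of 2,000
codons; planted-term enrichment in a 500-gene background at odds ratio 8
with 10,000 permutations; and full-null FDR control over 4 replicates of
40 genes × 150 codons (320 gene×model tests). Under a global null the
per-model BH step bounds the expected fraction of tests flagged at
q ≤ 0.05, which is the reported `discovery_proportion`; the indicator of
any false discovery per replicate is reported alongside.

## Known limitations

* ω is estimated as a single ratio parameter; dN and dS are not reported
  separately.
* The branch-site optimizer can park ω₂ at a large value with a tiny p2
  proportion when the signal is genuinely branch-wide; the branch model is
  the appropriate test for that situation (the worked example in the README
  shows the effect).
* "Scale" branch-length mode assumes the input topology's relative lengths
  are adequate; strongly heterogeneous real branch lengths warrant
  "per-branch" mode.
* The entropy screen's window and threshold are a declared re-specification,
  not a reproduction of any particular trimming tool's kernel.
* GO-style annotation is treated as flat term sets; no ontology-graph
  propagation.
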