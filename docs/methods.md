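# Methods

## Substitution model

Amino-acid evolution is modelled as a reversible continuous-time Markov
chain Q_ij = s_ij π_j built from the LG exchangeabilities and stationary
frequencies (shipped as PAML-dialect text in `src/ohnoscope/data/lg.dat`),
normalized so −Σ_i π_i Q_ii = 1 (branch lengths in expected substitutions
per site).  Model frequencies are used as-is; no "+F" re-estimation is
offered.  Transition matrices come from the symmetric eigendecomposition
of D^{1/2} Q D^{−1/2} (D = diag π), cached per model, with negative
round-off entries clipped and rows renormalized; t = 0 short-circuits to
the exact identity so that hard zero-length contradictions yield true zero
likelihoods.

Rate heterogeneity uses the discrete-gamma approximation with k
equal-probability bins (default k = 4) and the **mean-of-bin** convention:
category rate r_c is the conditional mean of the mean-1 gamma within bin
c, computed from regularized incomplete gamma functions and rescaled to
mean exactly 1.  Mean-of-bin (rather than median) matches the classical
ML tools this pipeline replaces; the two conventions differ numerically
(e.g. for α = 0.5, k = 4 the rates are 0.0334/0.2519/0.8203/2.8944).
The engine is alphabet-generic, so two- and three-state toy models
exercise the same code paths that the 20-state analyses use; closed-form
binary-symmetric results serve as oracles in the tests.

## Likelihood engine

Per-site likelihoods are computed by Felsenstein pruning over collapsed
unique site patterns, with per-node, per-category scaling factors carried
in log space (underflow-safe at any tree size).  Gaps ('-') and totally
ambiguous residues ('X') contribute flat conditional vectors; 'X' still
counts as sequence for the gap-column filter ("more than 10% gaps" is a
strict inequality, and the 10% threshold is configurable).  Sites whose
likelihood is exactly zero (possible only with zero-length branches)
report a log floor of −745 (configurable) so that downstream resampling
stays finite.

Branch lengths are optimized by exact coordinate ascent: one depth-first
sweep maintains the "outside" partial of every edge, so each
one-dimensional bounded Brent search (bounds [1e-8, 20]) maximizes the
true likelihood in that branch given all others; the total log-likelihood
is therefore nondecreasing across sweeps, and iteration stops when a full
sweep improves it by less than `tol` (default 1e-6) or after `max_rounds`
(default 50).  Each branch search first brackets locally around the
current value and falls back to the full interval when the local optimum
touches the bracket.  All branches initialize at 0.1.  Only the unrooted
edge set is identifiable under a reversible model; the two root-adjacent
branch lengths of a rooted input are reported individually but only their
sum is meaningful.

The gamma shape α is estimated by bounded search in log α over
[0.05, 50], alternating with branch-length optimization (3 outer cycles).
A fit is flagged "effectively homogeneous" when it is within 2
log-likelihood units of the α = 50 (essentially rate-homogeneous) model —
a likelihood-ratio-style criterion, since on finite homogeneous data the
ML shape can sit at a large interior value rather than at the bound.

For topology comparison, per-topology branch lengths (and, per policy,
α) are optimized independently.  The default "shared-estimate" policy
estimates α once on the first topology and reuses it, mirroring a single
dataset-level rate model; "per-topology-estimate" and "fixed" are
available.  During these optimization passes partial likelihoods are
accumulated in float32 (the final reported site log-likelihoods are
always recomputed in float64); combined with a convergence tolerance of
1e-2 log-likelihood units inside the orthology runner, this keeps a full
nine-topology assessment under ~10 s without measurably affecting
bootstrap probabilities, which depend on between-topology differences of
tens of log units.

## Topology space and the 1–2–4 constraint

Rooting on the outgroup edge identifies the 15 unrooted five-OTU
topologies with the 15 rooted four-leaf trees over {C, A, B, G}.  The 2R
compatibility rule is: **C must form a cherry with exactly one subtype
slot**.  Rationale: a strict 1–2–4 history places the four paralogue slots
on a balanced ((·,·),(·,·)) tree; a cyclostome gene orthologous to one
slot — or occupying the lost fourth (δ) slot — is always sister to a
single extant subtype, whereas a purely gnathostome cherry would imply
cyclostome divergence between the two duplication rounds.  Nine topologies
survive, three per cherry partner (two caterpillars and one balanced
shape each); the six excluded trees are the gnathostome-cherry
caterpillars.  Topology ids T01…T15 are assigned by sorted canonical
newick.

In four-subtype mode each balanced topology ((C,X),(Y,Z)) is compatible
both with "C orthologous to X" and with "C occupies the δ slot"; it is
counted in both sums and the dual counting is reported explicitly, since
the data cannot separate the two without a fourth extant paralogue.

Multi-member OTUs are expanded onto the backbone with fixed rooted
subtrees so that only the backbone varies across the comparison.  When the
user supplies none, the fallback builds one UPGMA subtree per OTU
(average linkage on p-distances) — UPGMA rather than neighbour joining
because the expansion requires a *rooted* shape and only the shape is
used (lengths are re-optimized on every backbone).

## RELL bootstrap and orthology probabilities

RELL resamples site indices with replacement (multinomial counts), sums
the fixed per-site log-likelihoods per topology, and awards each of B
replicates (default 10,000, giving ±0.01 Monte-Carlo error on a BP) to
the argmax topology; exact floating-point ties split the replicate's mass
equally and are counted.  Hypothesis probabilities are sums of BPs over
supporting topologies; in three-subtype mode they partition unit mass.
Everything is reproducible bit-for-bit from the integer seed.

## Marginal ancestral reconstruction

For a node v, column i and category c, the posterior is proportional to
w_c · D_v^{(c)}(x) · U_v^{(c)}(x), where D is the pruning (inside)
partial, U the outside partial with the stationary prior folded in at the
root, and the sum over categories implements site-specific category
weighting (categories that explain the column better contribute more).
Posterior rows normalize to 1; at a leaf the posterior is the observed
residue (non-gap columns).  MAP sequences take the per-column argmax with
an alphabetical tie-break; ties (relative tolerance 1e-9) are flagged,
and downstream event inference treats tied positions as 'X' (no call)
rather than guessing.

Event inference is a deterministic edge-wise diff of node/leaf triplet
states in pre-order; an event is flagged a **reversion** when the new
state equals a state held by an ancestor older than the most recent
change at that position, so multi-step histories (Ser→Ala→Ser) are
labelled correctly.

## Synthetic data

The generator realizes the 2R history explicitly: outgroup split, two
duplication nodes (the pairing fixes which subtypes are WGD2 sisters),
per-subtype species radiations, a single cyclostome gene grafted onto the
stem of its orthologous subtype, and pruning of lost paralogues (δ lost
by default, matching the extant three-subtype situation).  Default
conditions: three species per gnathostome subtype (a
chondrichthyan/actinopterygian/sarcopterygian-like sampling), 2000
columns, γ shape 1.0 with one category drawn per column,
duplication-era/stem branches at 0.1 and within-radiation branches at
0.05 expected substitutions per site, outgroup stem 0.25.  These are the
study conditions for the recovery experiments, not tuning knobs.

The three pocket columns are overwritten **after** simulation by the
deterministic event scenario (each lineage's state is the root state
modified by the events on its ancestral path, with from-state validation
and duplicate-event rejection), so signature and event ground truth is
exact while all remaining columns exercise the stochastic machinery.
What the simulator does *not* emulate: indels and alignment error
(sequences are generated aligned), compositional drift across lineages,
site-specific structural constraints, and correlated substitutions —
so passing recovery tests demonstrate correctness of the inference
machinery under the model, not robustness to real-data misspecification.

The shipped `fig6` scenario places hagfish+lamprey RAR1/2/3 against
catshark/gar/zebrafish/frog/chicken/human α/β/γ with an amphioxus-like
outgroup, plants S→A at 232 on the β/γ stem, the three reversions
(cyclostome RAR1 crown, actinopterygian γ crown stem, frog stem) and the
γ-stem changes I270M and V395A, over 450 ungapped columns so that the
human-RARα reference positions 232/270/395 are literal column numbers.
Branches that carry planted events get length 0.2 and all others 0.05
(outgroup 0.3): event-bearing branches are the divergent ones, which also
makes the marginal reconstruction recover the scenario-determined node
states robustly.  One caveat is deliberate: under this event history the
base of the γ group (node5, the RAR1+γ ancestor) carries Ala-232, because
the single mutation on the β/γ stem with a later reversion in RAR1 leaves
every intermediate ancestor with alanine.  A marginal reconstruction on
*real* data can instead favour serine there (reconstruction and
most-parsimonious event scenario need not agree node-by-node); the
fixture asserts the value its own generative history determines.

## Problem sizes and numerical choices in the shipped studies

- Orthology recovery study: 20 seeds × 3 cyclostome placements at the
  default conditions above, B = 10,000; success criterion: aggregated
  probability of the true hypothesis ≥ 0.95 in ≥ 18/20 seeds per
  placement.
- Consistency trend: alignment lengths 100/500/2000, four seeds.
- ASR recovery: 20-leaf trees, all branches 0.05, 300 columns, 10 seeds,
  ≥ 90% mean MAP root-sequence identity.
- Oracle equivalence: 200 random instances with ≤ 4 leaves, ≤ 3 states,
  ≤ 4 sites against exhaustive enumeration at |Δ log L| ≤ 1e-8.

## Known limitations

- No topology search: trees are user-supplied or enumerated; ML tree
  inference and alignment construction are out of scope.
- No invariant-sites category, codon models, partitioned models, or
  approximately-unbiased topology tests (only RELL BPs are computed).
- Gap handling is column filtering plus flat conditionals; indel states
  are not reconstructed.
- The four-subtype (δ) decomposition reports dual-counted sums rather
  than resolving the inherent non-identifiability.
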