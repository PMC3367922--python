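# Methods

This note documents the models, algorithms and design decisions behind
`phylogrammar`, at the level a user fitting or extending the models
needs.

## The generative model

A phylo-grammar generates an alignment in two steps.

1. **Nonterminal transformations.** Starting from START, production
   rules rewrite nonterminals until only pseudoterminals remain. Rule
   kinds are: transition (NT -> NT'), emission (NT -> left
   pseudoterminals, NT*, right pseudoterminals), return (NT* -> NT),
   bifurcation (NT -> NT' NT''), and end (NT -> epsilon). A grammar
   with no bifurcations whose emissions all fall on one fixed side is a
   phylo-HMM; otherwise it is a phylo-SCFG.
2. **Token evolution.** Each emission's chain draws a token tuple
   (single column, column pair, or codon triplet) from its initial
   distribution; the tuple evolves down the tree, each branch applying
   `exp(Q t)` of the branch's (possibly hybrid-resolved) generator.

**Emission-rule semantics.** The grammar dialect historically writes an
emitting nonterminal `k` with an emission rule `k -> (chain_k k*)`, a
return rule `k* -> k`, and transition/end rules from the unstarred
symbol. Read literally this recursion never terminates (emit, return to
`k`, emit again). We adopt the interpretation the accompanying HMM
diagrams intend: *entering* an emitting nonterminal emits its tuple
once, after which its non-emission rules decide the continuation. The
engine resolves the starred symbol through the return rule, so grammars
that instead write transitions directly from `k*` also work.

**End weights and global normalization.** End rules carry weight 1
alongside a stay/leave probability group that already sums to one; rule
weights at a decision point therefore need not be normalized. The DP
treats all rule probabilities as unnormalized weights and the model is
normalized globally over derivations of the observed alignment length.
Posteriors and EM counts are ratios of derivation weights, so they are
insensitive to this convention.

## Likelihood machinery

* **Pruning.** Felsenstein's postorder recursion, vectorized over
  columns: messages are `(L, S)` arrays rescaled per column by their
  maximum, with accumulated log scales, so megabase-scale alignments
  stay in floating-point range.
* **Matrix exponentials.** Each chain component is eigendecomposed
  once; `exp(Q t) = A exp(Lambda t) A^{-1}` when the decomposition
  reconstructs `Q` to ~1e-9 relative accuracy, otherwise
  scaling-and-squaring (`scipy.linalg.expm`). Both paths are tested
  against each other. Transition matrices are cached per (component,
  branch length).
* **Missing data.** Gaps and unrecognized characters (including IUPAC
  ambiguity codes) are wildcards: indicator 1 for every state. The
  grammars have no indel process, so gaps cannot be informative. An
  all-wildcard column has likelihood exactly 1.
* **Initial distributions.** The grammar listings omit initial
  distributions; a chain with no `initial` entries gets its stationary
  distribution when the generator is irreducible (the standard
  convention for reversible models), else uniform. A hybrid chain's
  root distribution is its default component's. Declared distributions
  that do not sum to one are renormalized with a warning (as are
  probability groups).
* **Ancestral reconstruction** is marginal: an inside-outside pass on
  the tree gives, per node and column, the posterior over states; the
  point reconstruction is its argmax, so the most-probable character
  always agrees with the reported posterior. Reconstruction conditions
  on the single best parse (each column uses the chain of its
  CYK/Viterbi nonterminal); marginalizing over parses instead would be
  a straightforward extension but is not what the point-estimate
  output is for.

## Grammar-level dynamic programming

* **Phylo-HMM engine.** Emission log-likelihoods per state are
  precomputed for every start position by vectorized pruning; forward,
  backward and Viterbi then run position-by-position (supporting mixed
  emission widths, e.g. codon emissions). Non-emitting nonterminals
  are eliminated by weighted path closure, with cycle detection; rule
  attributions are kept per closure path so EM counts flow back to the
  original rules.
* **Phylo-SCFG engine.** Inside/outside/CYK over column spans in
  linear space (adequate for the span-structured grammars and modest
  lengths this path targets; the HMM engine covers long alignments).
  Within a span, symbols are evaluated in topological order of the
  non-consuming transition edges; a cycle of such transitions is
  rejected. Banding with limit `N` skips every two-sided (pair)
  emission cell wider than `N`, which bounds memory and time; banded
  likelihoods are non-decreasing in `N` and reach the unbanded value
  at the alignment length.
* **Ties** in CYK/Viterbi break deterministically toward the
  lowest-index rule and smallest split point.

## EM training

E-step: expected rule usages from forward/backward or inside/outside;
expected substitution counts `c(i->j)` and wait times `w(i)` per chain
component from per-branch joint endpoint posteriors. For a branch of
length `t` with eigendecomposed generator, the conditional path
integrals use the closed form

    J_kl = (e^{lambda_k t} - e^{lambda_l t}) / (lambda_k - lambda_l)

(`t e^{lambda t}` on the diagonal), assembled with one matrix product
per branch; defective generators fall back to 24-point Gauss-Legendre
quadrature of the interval integral.

M-step: each probability group is renormalized from the usage counts of
the rules whose weight expressions contain its members (constant
factors such as the `1/(K-1)` fan-out cancel). Each rate parameter `r`
updates to `sum(counts over entries containing r) / sum(w_i * other
factors)`. Entries whose rates are products of several trainable
parameters (e.g. `u * r_k`) are handled by one coordinate-ascent sweep
per iteration — later updates see earlier ones; exactness is not
claimed for tied products, so a step that decreases the likelihood is
rejected and training stops (in practice traces are monotone). Rates
driven below `1e-6` are floored with a warning. Initial distributions
are not trained: stationary defaults track the updated rates
automatically. Defaults: `tol = 1e-4` relative improvement,
`max_iter = 30`, both CLI-settable.

**Identifiability caveat.** Only products of tied factors are
identifiable (e.g. a global `u` times per-state multipliers `r_k`), and
fast chains near substitution saturation sit on flat likelihood
ridges; EM then converges to the ridge rather than the generating
point. The recovery tests therefore target identifiable quantities
(the overall rate, the stay probability).

## Built-in models

| constructor | parameters (defaults) | notes |
|---|---|---|
| `jukes_cantor(u)` | `u = 1` | `u = 1/3` gives one expected substitution per unit time |
| `raser_chain(s, f, r_sf, r_fs, u)` | `0.1, 2.0, 0.01, 0.01, 1.0` | latent slow/fast class, `#=GR CLASS` row; the printed seed values |
| `discrete_gamma_rates(shape, K)` | — | equal-probability bins, bin *means* (not midpoints), so the rates average exactly 1 — required for the rate-multiplier role |
| `phastcons_hmm(K, base, rates, stay_prob)` | `stay_prob = 0.9` | start uniform `1/K`; leave mass split evenly; end weight 1; `K = 1` forces `stay_prob = 1` with a warning |
| `dless_hmm(tree, base, slow_scale, stay_prob)` | `slow_scale = 0.3` | simplified one-scale form: one nonterminal per tree node whose hybrid chain scales every branch in that node's subtree, plus a neutral background state; unlabeled nodes are auto-named `node1, node2, ...` in preorder |
| `nielsen_yang(code, kappa, omega, pi)` | standard code, `2.0, 0.5`, uniform | `rate(i->j) = pi_j kappa^[ts] omega^[nonsyn]` for single-nucleotide neighbors, 0 otherwise; reversible; `normalize=True` rescales to unit expected rate; codes from the NCBI tables so e.g. the vertebrate mitochondrial code (60 sense codons) plugs in directly |

Codon frequencies default to uniform over sense codons;
`codon_frequencies` estimates them from in-frame alignment counts with
a pseudocount.

## The simulator

The simulator samples a parse under the rule weights, then evolves each
emission down the tree by sampling child states from `exp(Q t)` rows
(hybrid components resolved per branch). It writes the ground truth
into the output: the parse as a `#=GC` row, sampled hidden classes as
`#=GR` rows, and the tree under `#=GF NH`.

Length control: phylo-HMMs sample exactly the required number of
non-end steps, which is exact conditioning whenever end weights are
uniform across states (true of every built-in model); phylo-SCFGs use
rejection. Endpoint sampling is exact for the likelihood; a separate
Gillespie path sampler supports event counting (used to verify the
one-substitution-per-unit-time calibration).

What the simulator does *not* emulate about real data: indels beyond
uninformative gaps, alignment error, context-dependent substitution,
rate variation beyond what the grammar encodes, and base-composition
heterogeneity across lineages. Passing recovery tests therefore show
the estimators are correct *under the model*, not that the model
captures any particular biological dataset.

## Numerical choices and problem sizes

* Probability-group normalization is checked to 1e-9; generator rows
  sum to zero within 1e-10; DP posteriors normalize within 1e-9.
* Macro arithmetic is exact-rational whenever operands are rational
  (`(&/ 1 3)` -> `1/3`), so pgroup seeds built by macros normalize
  exactly; symbolic operands degrade gracefully to a macro-free
  arithmetic form consumed by the expression parser.
* Neighbor-joining distances are Jukes-Cantor-corrected mismatch
  fractions (clamped just below the 3/4 divergence ceiling); negative
  inferred branch lengths are clamped to zero with a warning; a
  2-taxon input splits the distance evenly across the root.
* The test suite and the acceptance script size their experiments to
  run comfortably on one CPU: enumeration oracles on trees of up to 4
  leaves, chains of up to 8 states and alignments of up to 6 columns;
  EM recovery on 5,000-column (rate) and 10,000-column (stay
  probability) simulated alignments; 1,000-column fixtures for the
  ancestral-consistency rate. These sizes give sampling errors
  comfortably inside the asserted tolerances.

## Known limitations

* The SCFG inside/outside tables are dense `O(L^2)` arrays; genuinely
  long paired-structure alignments need banding (`-l`), mirroring how
  such screens are run in practice.
* Same-span bifurcation cycles (a bifurcation both of whose operands
  can derive the empty string) are not supported; the engine's
  evaluation order assumes at least one operand consumes columns.
* Rule-weight expressions are products (optionally divided by a
  constant); arbitrary algebraic parameter ties are out of scope.
* Rerooting is exactly likelihood-invariant for reversible chains;
  non-reversible chains (the engine allows them) are root-sensitive by
  design, and no attempt is made to detect reversibility for the user.
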