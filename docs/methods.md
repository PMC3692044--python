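# Methods

This note documents the models behind each feature, the tunable
parameters and their defaults, the numerical choices, what the
synthetic-data generators do and do not emulate, and the design
decisions taken where the design was genuinely open.

## Site scanning

A site is an exact Watson–Crick match to the reverse complement of the
seed. With m6 the match of miRNA positions 2–7 and m7 of 2–8 (1-based
from the 5′ end), a UTR window matching m7 is a 7mer-m8, upgraded to
8mer when the UTR nucleotide opposite miRNA position 1 is a literal A;
a window matching only m6 is a 6mer, upgraded to 7mer-A1 by the same A
rule. The A1 nucleotide is required to be A in the UTR, not to be
complementary to the miRNA's first residue — the standard convention,
reflecting the preference of Argonaute's t1 pocket for adenosine. G:U
wobbles and mismatch seeds are never matched; only the maximal class of
a window is reported; overlapping sites of the same miRNA are all
reported. All site classes are returned by default and can be filtered
downstream. Coordinates are 0-based half-open everywhere, covering the
full matched region including the A of the A1 classes.

## Thermodynamic features

The default energy engine is deliberately self-contained: a
nearest-neighbor model over the six pair types (Watson–Crick + G:U)
with

* dinucleotide stack energies from the shipped table
  (`data/nn_stacks.tsv`; Watson–Crick values in the style of the
  standard published nearest-neighbor sets, wobble terms simplified),
* duplex initiation +4.09 kcal/mol, terminal AU/GU penalty
  +0.45 kcal/mol per helix end,
* affine interior-loop/bulge penalty 3.2 + 0.4·(unpaired nt), capped at
  30 unpaired nt,
* for single-strand folding, a per-pair cost of 1.6 kcal/mol standing
  in for loop-entropy terms (no explicit hairpin penalty; minimum
  hairpin loop 3 nt),

all at fixed 37 °C (RT = 0.6163 kcal/mol). Hybrid MFEs come from an
exhaustive dynamic program over intermolecular structures (stacks,
bulges, interior loops; no intramolecular pairs); ensemble energies
from the matching inside recursion, so −RT ln Z ≤ MFE holds by
construction, as does ΔG open ≥ 0 (the constraint only removes states
from Z). Energies of destabilizing duplexes are capped at 0.0 — "no
stable interaction" rather than a positive ΔG. `N` never pairs.

The engine is *a* consistent nearest-neighbor parameterisation, not a
reproduction of any particular folding program's numbers; the test
suite checks sign and rank agreement against an external engine on
clear-cut duplexes, and all algebraic invariants exactly. Windows:

| parameter | default | meaning |
| --- | --- | --- |
| `open_flank` | 70 nt | UTR context on each side of the site for ΔG open |
| `duplex_upstream` | 15 nt | target extension 5′ of the site for 3′-half pairing in ΔG duplex |

Both follow the accessibility-feature lineage of site-accessibility
target predictors and are exposed as config/CLI parameters, not claims
about any reference implementation. Partition functions are computed in
linear (not log) space; with the shipped parameters this is safe for
windows up to a few hundred nt, far beyond the default window size.

## Over-representation (P.over)

The UTR composition is modeled as an order-1 Markov chain fitted to the
UTR itself (initial = mononucleotide frequencies, transitions =
normalized dinucleotide counts, all-zero rows → uniform; `N` positions
are excised before fitting rather than inventing transition semantics
for them). The observed count *n* is the number of seed-match
occurrences **with overlaps counted** ("AAA" contains two "AA") — the
well-defined choice matching substring-enumeration semantics, and the
one the exact solver is built for.

* Binomial variant: P(X ≥ n), X ~ Binomial(L−k+1, p) with p the chain
  probability of the motif, computed with the stable survival function.
* Exact variant: a product automaton of (i) the KMP/failure-function
  matching automaton of the motif, which handles self-overlap
  correctly, (ii) the last emitted nucleotide, conditioning the Markov
  transition, and (iii) the occurrence count truncated at *n*, advanced
  L steps. The full count distribution sums to 1 to 1e-12; n = 0 gives
  p = 1 and n > L−k+1 gives exactly 0.

The seed span used for the feature defaults to positions 2–8 (7-nt
matches), configurable to 2–7. The exact statistic is validated against
brute-force enumeration of all 4^L sequences on randomized small
instances; binomial vs exact agree within 5% for non-self-overlapping
7-mers on 5-kb near-uniform UTRs.

## Conservation features

**BLS** maps the site to alignment columns via the reference row
(±2 columns of slop for alignment jitter), tests each species' gap-
stripped segment for the exact seed match, and sums the branch lengths
of the minimal spanning subtree of the present species (0 for ≤ 1
species; the root is not forced into the subtree). Unnormalized by
default; a flag divides by total tree length for cross-tree
comparability. Alignment rows for species absent from the tree are
ignored with a warning.

**phyloP-style test.** The likelihood-ratio flavor with a single
branch-scale parameter λ multiplying every branch length: λ̂ is
optimized by bounded scalar minimization in [1e-4, 10] (Brent,
xatol 1e-6) of the Felsenstein pruning log-likelihood (columns
independent, gaps/N as missing data, leaves without data pruned), and
LRT = 2(ℓ(λ̂) − ℓ(1)) is referred to χ²₁. The reported p-value is the
one-sided conservation p: ½·sf(LRT) when λ̂ < 1 and 1 − ½·sf(LRT) when
λ̂ > 1, which is uniform under neutrality, so rejecting at p < α has
type-I error α. The score is −log₁₀ of the directional tail, signed
positive for conservation and negative for acceleration; the
measure-zero boundary case LRT ≈ 0 reports p = 1, score = 0. This is a
"phyloP-style" statistic — self-contained and calibrated — not a
reproduction of published phyloP/PHAST numbers.

Neutral model: JC69 by default (closed-form transition probabilities,
closed-form test oracles); HKY85 (arbitrary equilibrium frequencies,
transition/transversion ratio κ, matrix exponential, unit mean rate)
via config.

## Context features

Committed interpretations of the context-score lineage, isolated in one
constants block:

* **AU content**: flank position i (1 = adjacent, up to 30 nt each
  side) carries weight 1/(i+1); value = A/U weight sum ÷ available
  weight sum; positions beyond the UTR are excluded from both sums
  (zero available flank → 0 with a warning).
* **UTR position**: distance from site midpoint to the nearer UTR end,
  capped at 1500 nt.
* **3′ pairing**: UTR region up to 15 nt 5′ of the seed match vs miRNA
  positions 9..end; best contiguous Watson–Crick run over register
  offsets (±8), 1.0 per paired position in miRNA 13–16 and 0.5
  elsewhere, minus 0.5 per offset step, floored at 0 (negatives carry
  no information the floor does not). The site-type-specific window
  asymmetries of the original context score are collapsed to one
  symmetric window.

## Linear model, aggregation, percentiles

Site features are aggregated to miRNA–UTR pair level by summation
(energies, context, conservation), with two exceptions chosen here:
UTR position is averaged (summing positions is not meaningful) and the
P.over features are recomputed at pair level, since they are functions
of the total match count. The site count is its own feature. A feature
available in only some sites is summed over those sites (NaN =
unavailable); a feature available nowhere is omitted.

Fitting is ordinary least squares of log₂ fold-change on features, with
explicit rank diagnostics that name constant/collinear columns, and
R² = 1 − RSS/TSS. Prediction is exactly linear. No published
coefficients exist for the combined model, so none are shipped as such;
the two demo models (`data/demo_model_synthetic*.txt`) were fitted on
the package's synthetic dataset at generative R² = 0.15 and are labeled
synthetic. When conservation inputs are absent the pipeline falls back
to the conservation-free demo variant and flags it in the
`model_variant` column (refitting at scoring time has no training
data).

Percentile scores orient every feature so 100 = strongest predicted
repression: lower-is-stronger for all ΔG features, both P.over
p-values, UTR position and the predicted score; higher-is-stronger for
BLS, phyloP score, AU content, 3′ pairing and site count. The
percentile of a value in a background sample of size m is
(r − 1)/(m − 1)·100 with r the averaged-tie rank, clipped to [0, 100] —
so the background extremes map exactly to 0 and 100 and ties are
averaged. BED export scales the percentile to the 0–1000 BED score
field (0 when no percentile is attached); BED records stay in UTR-local
coordinates (genome liftover is out of scope).

## Synthetic data

The generators produce the study conditions the tests measure under:

* i.i.d. UTRs of configurable composition;
* planted sites: the exact match string of the requested class written
  at the requested positions, guard nucleotides preventing class
  upgrades, and a background scrub that mutates stray 6mer cores until
  the only matches are the planted ones (verified by exhaustive scan) —
  ground truth for scanner recovery;
* alignments evolved down a tree by sampling each branch's transition
  matrix, with per-window rate scales λ (λ < 1 = negative selection,
  λ = 0 freezes a window; λ < 0 is an error); no indels, so alignments
  are trivially correct — alignment-jitter behavior is tested with
  small manual fixtures instead, because simulating indels plus
  realignment would test an aligner, not this package;
* feature/response tables: independent uniform features over
  documented plausible ranges with Gaussian noise; the noise level for
  a target generative R² has a closed form used by tests
  (σ² = Var(signal)·(1−R²)/R²). The default target R² of 0.15 reflects
  the weak per-pair explanatory power typical of repression modeling on
  transcriptomics data.

Everything is a pure function of its arguments including the seed.
These generators emulate composition, match placement and neutral or
uniformly-scaled substitution — not real UTR evolution, expression
context, or correlated features — so passing tests demonstrate
correctness of the algorithms under their stated models, not predictive
performance on biological data. Test problem sizes (e.g. 60–240-nt
UTRs, 15-nt ΔG-open flanks in bulk runs, 7-column conservation sites,
2000 null simulations) were chosen as the smallest scales at which the
checked properties are informative.

## Known limitations

* The built-in energy model's absolute kcal/mol values are
  parameterisation-dependent; ranks, signs and algebraic identities are
  the reliable outputs.
* The exact P.over automaton is O(L·k·n) per evaluation; for
  chromosome-scale L the binomial variant is the practical choice.
* Conservation features require a user-supplied tree and alignment
  whose ungapped reference row equals the UTR; there is no bundled
  multi-species database.
* The one-sided phyloP-style p is calibrated under the fitted JC69/HKY
  neutral model; model misspecification shifts it as in any LRT.
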