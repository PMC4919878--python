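# Methods

## Model

`branchprior` fits two generative models for the branch lengths
*t₁…tₙ* ≥ 0 of an unrooted phylogeny (units: expected substitutions per
site), treating each input tree as one independent observation.

**Exponential.** All branches i.i.d. Exp(λ):
ℓ(λ) = n·log λ − λ·T with T = Σtᵢ. The MLE λ̂ = n/T is closed-form and is
computed directly, never through the optimizer.

**Compound Dirichlet.** Tree length T ~ Gamma(α_T, β_T) with β_T a *rate*
(mean tree length α_T/β_T), and proportions x = t/T ~ Dirichlet with
concentration α on each of the s external branches and α·c on each of the
m = n − s internal branches. By change of variables t = T·x
(Jacobian T^(n−1)):

```
ℓ = α_T·log β_T − lnΓ(α_T) + (α_T−1)·log T − β_T·T
  + lnΓ(sα + mαc) − s·lnΓ(α) − m·lnΓ(αc)
  + (α−1)·Σ_ext log xᵢ + (αc−1)·Σ_int log xⱼ
  − (n−1)·log T
```

For star trees (m = 0) the internal terms vanish identically and c is
unidentifiable; fits and profiles over c on such data raise an error rather
than returning an arbitrary number.

The rate convention for β_T deserves emphasis because shape/scale confusion
is the canonical bug in gamma parameterizations: the implementation is
pinned by a generative round-trip test asserting
exp(ℓ)·T^(n−1) = GammaPDF(T)·DirichletPDF(x) against `scipy.stats` to
1e-10 relative over a thousand draws, and all expected values in the unit
tests were frozen from an independent 50-digit arbitrary-precision
transcription of the formula written before the implementation.

All gamma functions are evaluated in log space (`scipy.special.gammaln`);
raw Γ would overflow already around s ≈ 60–70 tips, a perfectly ordinary
dataset size for this workflow.

## Parameters and estimation

| parameter | meaning | default | estimated? |
|---|---|---|---|
| λ | exponential rate (1/subst-per-site) | — | closed form n/ΣT |
| α_T | gamma shape on T | 1 | fixed |
| β_T | gamma rate on T (1/T units) | α_T / mean(T) | closed form unless supplied |
| α | Dirichlet concentration, external branches | 1 | free in `alpha_only`, `joint` |
| c | internal:external concentration ratio | 1 | free in `c_only`, `joint` |

With one observed tree length per tree, (α_T, β_T) are not jointly
identifiable, so the gamma component is handled by fixing the shape and
using the closed-form rate MLE for known shape. This matches how the
informed-prior workflow is used: α and c are the quantities the outside
data is asked to inform, and α_T = 1 reduces the tree-length marginal to an
exponential — the familiar special case.

Free parameters are optimized on the log scale (positivity by
construction) with Nelder-Mead started at α = c = 1, function tolerance
1e-8, parameter tolerance 1e-6, at most 500 iterations. A fit that stops
on the iteration cap is returned with `converged=False` and a logged
warning; the prior exporter refuses unconverged fits. The likelihood for a
set of trees depends on each tree only through
(s, m, T, Σ log x_ext, Σ log x_int); these sufficient statistics are
precomputed once, so one likelihood evaluation is O(#trees) regardless of
tree size, and a 1,000-tree joint fit takes milliseconds.

`alpha_only` mode fixes c = 1 by default (the single-parameter
parameterization commonly reported alongside joint fits); `c_only` fixes
α = 1. Both accept explicit fixed values. Fits can pool all trees or run
per tree.

## Tree handling

Parsing uses dendropy (Newick and Nexus, translate tables honored).
External branches are exactly the edges incident to a leaf. Rooted inputs
are unrooted before harvesting by merging the two edges adjacent to a
degree-2 root (lengths summed): the compound Dirichlet is defined on
unrooted-tree branch counts and MrBayes' unconstrained branch lengths are
unrooted, so keeping the root would inject a spurious extra branch.
Polytomies are accepted and simply yield fewer internal branches; the
counts are recorded, not rejected.

Zero-length branches would make log xᵢ infinite, so they are floored to a
configurable ε (default 1e-9, warned) — strict mode rejects instead. Trees
carrying no branch lengths at all are excluded from fitting with a logged
count; public repositories are uneven in this respect.

## Synthetic data

The simulator emulates sets of ML trees from outside datasets: a random
unrooted bifurcating topology on s tips (sequential random attachment of
each new tip to a uniformly chosen existing edge), with branch lengths
drawn from the chosen generative family. The default study conditions used
throughout the tests and the acceptance script are 65-tip trees —
matching an intraspecific mtDNA alignment of realistic size — with
α = 0.11, c = 1.35, α_T = 1, β_T = 2.5 for the compound Dirichlet (mean
tree length 0.4, a typical intraspecific ML tree length) and rate 40 for
the exponential.

What the generator does *not* emulate: phylogenetic estimation error (its
branch lengths are exact draws, whereas real ML branch lengths are
estimates with sampling noise and occasional zero-collapse), topology
realism (no birth–death or coalescent shape; irrelevant here because the
likelihoods depend only on the lengths and the internal/external split),
rate heterogeneity across genes, and alignment artifacts. Recovery tests
on simulated data therefore validate the estimators and their
implementation, not the adequacy of either distribution as a prior for any
particular empirical dataset.

Tree counts in tests are scaled to what the properties need: bulk
closed-form checks use 1,000 samples, recovery uses 1,000 65-tip trees,
consistency uses 10 → 1,000 trees across seeds, and the bias sign test
uses 200 replicates of 12 trees.

## Search and matrix preparation

TreeBASE access sits behind a transport interface. The recorded-transcript
transport replays a JSON file of study metadata and matrix bodies, so the
entire pipeline — synonym search, concurrent download, inclusive
taxon-count filtering, Study-ID dedup with the first-synonym naming rule —
runs offline and deterministically; the live transport implements the same
interface over HTTP (phylows endpoints) with 3 retries and exponential
backoff. The packaged transcript is synthetic: fabricated studies and
matrices shaped like TreeBASE downloads, with a manifest of expected
stage-by-stage counts.

Synonym matching is case-insensitive whole-token matching over title +
abstract (gene symbols are case-variable; substring matching would let
`coi` hit `choice`). The sequence count is the matrix row count, checked
against the NTAX dimension.

Nexus post-processing is deliberately textual. The document model keeps
each block as raw text; ambiguity normalization is a validated regex
substitution of `{...}` sets by their IUPAC codes. This is what makes the
contract "a file needing no repair passes through byte-identical" hold —
any reserializing parser would reflow whitespace. The one place the matrix
is rebuilt is gene excision (charset columns extracted, NCHAR updated), and
rebuilt matrices are written non-interleaved, the dialect every ML program
accepts; interleaved inputs are de-interleaved at parse time. Charset
ranges are 1-based inclusive with `a-b\3` codon steps; a single audited
function converts them to 0-based indices. Charset-to-gene matching is
case-insensitive containment in either direction — gene naming in public
archives is too inconsistent for exact matching — and a file with no
matching charset is returned whole with a `cannot excise` flag for manual
review rather than guessed at. Excision is opt-in.

## Numerical and design notes

* Frozen oracle values: exponential ℓ(λ=10) = 1.0129254649702284 and
  compound-Dirichlet ℓ(α_T=1, β_T=2, α=0.5, c=2) = −0.08460246810365518 on
  the quartet sample (external 0.1, 0.2, 0.3, 0.4; internal 0.05); flat
  case on the 3-taxon star = 1.1147984280919267.
* The flat parameterization α_T = β_T = α = c = 1 collapses the density to
  −T + lnΓ(n) − (n−1)·log T, used as an independent closed-form check.
* The m = 0 density is verified to integrate to 1 by importance sampling
  (200,000 draws, i.i.d. exponential proposal, 3-SE band).
* Profile curves are evaluated on user-supplied sorted positive grids; the
  optimizer is cross-checked against dense grids (10,000-point
  single-parameter, 100×100 joint) rather than trusted.
* Stochastic tests fix seeds. One seeded check (simulator pooled mean)
  combines its z-statistic across five seeds: a single stream can
  legitimately open 3 SE off, and the multi-seed statistic tests the same
  3-sigma contract with more power against genuine bias.
* Renderers emit MrBayes 3.2 syntax (`unconstrained:exponential(λ)`,
  `unconstrained:gammadir(α_T,β_T,α,c)`); parameter order is pinned to
  3.2.x. A neutral `key=value` format covers other consumers. BEAST XML is
  out of scope.

## Known limitations

* Confidence intervals on fitted parameters are not computed, and no model
  selection between the two families is offered: a better fit to outside
  branch lengths does not by itself make a distribution the better prior.
* The live TreeBASE transport depends on the service's endpoint stability;
  only the transcript transport is exercised by tests.
* Amino-acid ambiguity codes are not normalized; matrices are assumed
  nucleotide.
* The compound-Dirichlet fitter assumes strictly positive lengths; heavily
  zero-collapsed ML trees will lean on the ε floor, which slightly inflates
  the density's log-proportion terms for those branches.
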