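# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `chemspace`, in the package's own terms.

## The chemical space and its timeline

The unit of analysis is the molecular formula (MF): an element→count
multiset with the year of first publication. Substance records are
parsed from a flat Hill-style dialect (element symbol + optional count;
no charges, isotopes, hydrates or brackets — such records are rejected
into an auditable skip report, since the similarity model operates on
plain compositions only). All isomers collapse onto one MF carrying the
minimum year; ties on year break by lexicographically smallest record id
so the collapse is deterministic. The chemical space at year t is the
cumulative set of MFs with year ≤ t, which is monotone by construction.

## Element similarity

For each MF and each element Q with count q, every n ∈ {1..q} yields a
template (R, n): the residual formula after removing n atoms of Q, plus
the slot size. The template identity deliberately excludes the element —
that is what lets different elements "hold" the same template and is the
formal counterpart of chemical replaceability. One-element formulas
(e.g. O₂) produce templates with an empty residual; they are legal and
participate, encoding the interchangeability of elemental substances.
Template holdings are sets, not multisets: a template reachable through
many compounds counts once.

Co-occurrence c(x, y) = |templates of x ∩ templates of y| for x ≠ y.
The diagonal uses the *shared* convention: c(x, x) counts only x's
templates held by at least one other element. This is the convention
under which the normalised similarity

    s(x, y) = sqrt( c(x, y)² / ((Σ_x′ c(x′, y)) (Σ_y′ c(x, y′))) )

is provably bounded by 0.5: the shared diagonal guarantees
c(x, x) ≥ c(x, y) for every y, hence each column sum is at least
2·c(x, y). An `all` diagonal convention (count every template) is
available as a config switch. Column sums include the diagonal term;
zero-denominator pairs get s = 0, and the similarity matrix carries a
zero diagonal (the self-similarity enters only through the
normalisation). The normalisation is evaluated literally as
sqrt(c²/denominator) so independent re-implementations agree bit for
bit.

Year-by-year matrices are built from one incrementally grown template
index; because the index is a plain union over formulas, incremental and
from-scratch computation agree exactly.

## Optimal element sequences

The cost of a permutation α of the roster is
L(S, α) = −Σ_{x, y≠x} s(x, y)/|α(x) − α(y)| with 0-based positions and
adjacent distance 1. L is invariant under sequence reversal, so optima
always come in mirror pairs and all quality checks compare costs, not
orders.

The genetic algorithm uses:

- an initial population of random permutations (default 1500),
- partially-mapped crossover (PMX): the child takes a random segment of
  one parent verbatim and places each displaced value of the other
  parent by following the segment's mapping chain,
- slice mutations (a random contiguous slice moved to a random
  location), applied per offspring with probability 0.3,
- Boltzmann parent selection: weights exp(−(L − L_min)/kT) with kT
  starting at 0.7 and multiplied by 0.7 every 200 generations; each of
  the population_size/2 pairs draws two *distinct* parents by weighted
  choice (without replacement inside a pair, independently across
  pairs). Pairing the whole population without replacement would give
  every individual exactly one mating and remove selection pressure
  entirely, so it is not used.
- generational replacement over 600 generations (defaults), with the
  best-ever individual tracked externally and returned.

Elements whose similarity row is entirely zero carry no cost signal;
by default they are excluded from optimisation and appended in stable
roster order (flag-controlled).

A year's periodic system is the ensemble of the `keep` best sequences
(default 15) from `n_runs` independent optimisations (default 50), with
run seeds spawned deterministically from one master seed and ties on
cost broken by run index. Tests and desk-scale runs use scaled-down
populations and generation counts (typically 120–200 each); on matrices
of ≤ 8 elements the scaled GA still matches exhaustive enumeration in
≥ 95% of seeded runs.

## Comparing sequences and periodic systems

B_α = {{x, y} : |α(x) − α(y)| ≤ r} is the radius-r pair set;
z(α→α′) = |B_α ∩ B_α′|/|B_α|. The radius defaults to r = 4 and is a
documented knob; qualitative conclusions (change-point detection) are
checked at r ∈ {2, 4, 8}. An empty pair set (single-element roster)
compares as 1 by convention.

Ensembles are compared by the mean of z over all ordered sequence pairs
(15 × 15 = 225 at full scale). When two years span different rosters
(new elements discovered in between), each pair set is built on its own
sequence and then restricted to pairs whose both elements are common to
both rosters — denominators included. This makes z̄ insensitive to mere
roster growth and isolates genuine similarity-structure change; it is
one consistent reading of an underdetermined case and is flagged here
deliberately.

The evolution matrix stores raw z̄ for every ordered year pair and a
column-normalised version (each column divided by its maximum, so every
column attains 1). Raw values are kept because column normalisation is
global and would otherwise prevent incremental extension. Row slices
give the preservation profile (how much of a year persists later) and
anticipation profile (how much was already present earlier); the
anticipation span is the longest run of consecutive past years above a
threshold.

On synthetic timelines, a planted family reshuffle shows up as lower
mean cross-boundary z̄ than within-segment z̄ at r ∈ {2, 4, 8}. The
stricter feature sometimes seen on the real historical matrix — the most
similar system being always an adjacent year's — is *not* asserted on
synthetic data: cumulative corpora converge quickly, so distant years
become nearly as similar as adjacent ones and the arg-max is dominated
by optimiser stochasticity at desk scale. The monotone counterpart that
is stable (and tested) is distance decay: adjacent years are on average
more similar than maximally separated ones.

## Family detection

Families are contiguous high-similarity blocks on the diagonal of a
similarity matrix reshuffled by an optimised sequence. The CV pass:

a. *Diagonal suppression* — each diagonal pixel becomes the mean of its
   immediate left/right neighbours (edge rows use the single available
   neighbour), removing the self-similarity streak that obscures block
   shapes.
b. *Intensity scaling, up-sampling, blurring, padding* — the
   off-diagonal value range is contrast-stretched to 8-bit [0, 255]
   (for a matrix attaining the 0.5 bound this is exactly the fixed
   s/0.5·255 mapping; for dimmer matrices it keeps contrast in the
   regime the fixed threshold sum expects); the image is up-sampled by
   15, Gaussian-blurred with σ derived from the sampled window size w
   by the usual kernel-size convention σ = 0.3·((w−1)/2 − 1) + 0.8, and
   zero-padded by one up-sampled pixel. Gaussian rather than box
   blurring keeps a unique gradient maximum at each block boundary,
   which the edge detector's non-maximum suppression needs.
c. *Canny edges* — thresholds (th, 40) are specified in 8-bit Sobel
   units (the convention of the common 3×3-aperture implementation) and
   divided by the Sobel ramp gain 8 for the gradient-magnitude units of
   the scikit-image backend.
d. *Diagonal-square detection* — generic contour analysis breaks here:
   adjacent family blocks touch at shared diagonal corners and nested
   structure creates T-junctions, merging edge rings. Instead every
   candidate interval [p, q) with 2 ≤ q − p ≤ 20 is scored by the
   fraction of its square's upper-triangle perimeter (top and right
   sides, walked with a ±u/4 strip, excluding a u/2 band around the
   diagonal) covered by edge pixels; candidates with coverage ≥ 0.6
   enter greedy non-maximum suppression (best coverage first, ties to
   the earlier/shorter interval, overlapping extents suppressed). Each
   surviving square maps to the family {order[p], …, order[q−1]}, an
   interval of the sequence by construction.

Parameter sets are sampled per image: blur window uniform over
{17, 19, 21, 23}; th on the integer grid 0..39 with p(th) ∝ exp(−th/β),
β = 20, and the threshold sum fixed at 40. N = 25 parameter sets per
image and M = 3 consensus iterations are the defaults; both are exposed.

The SNR consensus: every family gathers itself plus the
highest-Tanimoto family from each other collection; the gathered set is
replaced by its majority family (elements present in ≥ ⌈half⌉ of the
gathered families, ties counting as present); empty, one-element and
duplicate families are dropped after every step; the iteration runs M
times and the pool then collapses into one cleaned collection. The
procedure is order-invariant over the input pool (families are kept in
a canonical sort) and does not enforce disjointness — overlapping
families are legitimate output. Within a single CV pass the greedy
square selection does yield disjoint intervals; overlap can arise
across sequences and parameter sets.

Family trajectories link each family at year t to its best-Tanimoto
match at t+1 (positive matches only); a next-year family matched by two
or more current families is a merge, a current family that is the best
backward match of two or more next-year families is a split.

## Diversity statistics

A[x, y] accumulates distinct formulas containing x up to year y;
T[x, y] accumulates distinct templates held by x. The variability is
log(count[y+1]) − log(count[y]), labelled by the later year, masked
(not clipped) where either count is zero — an element's first year has
no predecessor ratio — and clipped to [0.0, 0.1] for display. The log
base is 10 (configurable): with the 0.1 ceiling this saturates at ≈26%
annual growth, a sensible cap; natural log would saturate at ≈10.5%.

## The synthetic chemical space

The generator emulates the statistical features the analysis depends
on, with planted ground truth:

- a roster of elements with staggered discovery years (no record may
  use an element before its discovery),
- disjoint planted families of mutually substitutable elements,
- skeletons: base formulas with exactly one substitutable slot of
  multiplicity m (m alternates 1/2 in the generated pools, planting
  valence-like patterns); each skeleton belongs to one family,
- exponential growth of the *cumulative* record count: the total tracks
  round(n₀ · g^(y − y₀)) and each year emits the successive difference,
  with the start-year batch standing in for the corpus accumulated
  before the window. Default g = 2^(1/16), the observed ≈16-year
  doubling time of the real corpus; n₀ is the cumulative size at the
  start year. Making the cumulative count exponential (rather than the
  yearly increments alone) avoids a decades-long transient in the
  log-linear growth fit and is what lets the doubling time be read off
  the slope exactly,
- substitution noise: with probability `noise_rate` a slot is filled
  from the discovered elements *outside* the skeleton's family.

Randomness flows through per-year substreams derived from one seed, so
extending the year range never perturbs earlier years.

The `planted_spec` helper builds skeleton pools programmatically with
residuals over a C/H/O/N/S/P backbone, guaranteed distinct across the
whole pool (a residual collision between families would plant spurious
cross-family similarity). Its default of 12–20 skeletons per family is
deliberate: similarity counts *distinct shared contexts* (template
sets, not multisets), so if a family has few contexts and many records,
substitution noise quickly grants every outside element the same few
templates and the planted signal saturates away. Keeping roughly
10–20 records per context preserves a within:cross co-occurrence ratio
of ≈3–4 at 20% noise — the regime in which the real corpus operates,
where distinct compound contexts vastly outnumber elements. Backbone
elements (C, H, O, …) appear in every residual and form their own small
high-similarity groups; detectors will legitimately report them in
addition to the planted families, and recovery is therefore measured as
best-match Tanimoto against the planted truth.

What the generator does **not** emulate: chemical plausibility (valence
rules, charge balance) beyond slot multiplicities, multi-slot
substitution, non-exponential growth episodes (wars, database
artefacts), and any structure-level (graph) information. Passing
recovery tests therefore demonstrates the pipeline's correctness on
corpora with planted replaceability structure, not fidelity to the
historical record.

## Numerical choices and degenerate inputs

- Seeds: every stochastic component takes an explicit seed or
  Generator; derived seeds come from `SeedSequence` spawning and stay
  below 2³¹.
- Empty corpus → empty roster and matrices; single-element rosters
  compare as z = 1 by convention (logged); GA on < 2 active elements
  returns the trivial order with cost 0.
- Isomer-collapse and ensemble ties break deterministically (smallest
  id; run index).
- The pipeline runner checksums every artifact into a manifest and
  skips stages whose artifacts verify, so interrupted runs resume and
  reruns with identical config reproduce identical non-image artifacts.

## Problem sizes used in the validation suite

Unit and acceptance tests run on deliberately small instances chosen to
keep the full suite desk-scale: rosters of ~20 elements, corpora of a
few hundred formulas, GA populations of 120–200 over 100–200
generations, ensembles of 4–5 sequences from 6–8 runs, and 8–15 CV
parameter sets per image. Full-scale defaults (population 1500,
600 generations, 15-of-50 ensembles, N = 25) remain the library
defaults.

## Known limitations

- The formula dialect is intentionally narrow; records with charges,
  hydrates or brackets are skipped, not normalised.
- The CV detector assumes families are contiguous in the optimised
  sequence (true for block-structured similarity; an under-optimised
  sequence degrades detection before the detector itself does).
- The square detector's coverage threshold (0.6) and the NMS rule are
  fixed engineering choices, not sampled parameters.
- Evolution-matrix comparisons across rosters use the intersection-
  restriction rule described above; other readings are possible.
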