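# Methods

This note documents the models, estimators, numerical conventions and
design choices behind `barcodekit`, and what the synthetic data generator
does and does not emulate.

## Distances

Both estimators operate under **pairwise deletion**: for each sequence
pair, a column is compared only if both sequences carry an unambiguous
base. Gaps (`-`), missing symbols (`N`, `?`) *and* IUPAC ambiguity codes
are dropped column-wise. Dropping ambiguity codes (rather than expanding
them fractionally) is conservative and keeps every distance a
deterministic function of the alignment.

With `P` and `Q` the transition (A↔G, C↔T) and transversion proportions
among the `n` compared sites:

* p-distance: `d = P + Q`
* Kimura two-parameter: `d = -½ ln((1 − 2P − Q)·√(1 − 2Q))`

A pair is **undefined** when `1 − 2P − Q ≤ 0` or `1 − 2Q ≤ 0` (the
correction's log-domain boundary, reached under saturation) or when fewer
than `min_overlap` sites were compared (default 20 — chosen so that a
~170 bp mini-barcode with heavy missing data cannot produce distances from
a handful of shared sites). At the operation level an undefined distance
raises `UndefinedDistanceError`; in a matrix it is stored as NaN, counted,
excluded from all summaries and matching, and logged. Silently propagating
NaN through means would corrupt every downstream rate, and imputation
would invent signal; exclusion-with-count is the only auditable choice.

Barcoding-gap fractions use **strict** inequalities at the cutoff
(default 0.05 substitutions/site): the fraction of interspecific distances
*greater than* the cutoff and of intraspecific distances *lower than* it.
Distribution overlap is declared when max(intra) ≥ min(inter).

## Identification (best match / best close match)

Each sequence is queried against all others at the locus. The minimal
defined distance defines the neighbor set (ties within `tie_tolerance`,
default 0 — exact ties only, for determinism). All-conspecific neighbors →
correct; mixed → ambiguous; all-heterospecific → incorrect. Best close
match additionally rejects queries whose nearest neighbor lies beyond a
threshold. The threshold is the **95th percentile (linear interpolation)
of all intraspecific pairwise distances**, the established convention for
this method; the percentile is configurable. Species with a single
sequence at the locus can never be identified correctly by construction,
so they are reported as singletons and excluded from the success
denominator rather than being allowed to deflate rates deterministically.
The full category breakdown is always returned, so a stricter success
definition (ambiguous counted as failure is the default; exclusion is
recomputable) costs the caller one division.

## Trees and the discrimination criterion

Neighbor joining uses the Q criterion with Studier–Keppler updates.
Ties in Q are broken by the lowest (row, column) index pair, making the
topology reproducible across platforms. Negative branch lengths are
retained as computed — clamping would break the exact-additivity
guarantees the tests rely on — with optional clamping to zero at Newick
export only. The implementation is cross-checked in the test suite against
an independent NJ implementation (scikit-bio) on exact path-length
matrices.

Bootstrap support resamples alignment columns with replacement (same
length), rebuilds the distance matrix and tree, and reports the percentage
of replicates containing each internal bipartition. Replicates with
undefined distances are skipped and logged. Internal edges of length ≤
1e-12 are assigned support 0: a zero-length edge carries no phylogenetic
signal, and deterministic tie-breaking would otherwise manufacture 100%
support for arbitrary resolutions of what is really a polytomy (the
identical-sequences case).

A label (species or region) is an **exclusive cluster** when some edge of
the unrooted tree bipartitions the leaves into exactly that label's
specimens versus all others. **Discriminated** additionally requires at
least one vouchered specimen in the cluster and, when supports are present
and `min_support > 0`, support of the separating edge at or above it. The
default `min_support` is 0 — the criterion itself does not involve
support; support thresholds are display conventions. The overall rate
counts only labels with ≥ 2 specimens: a singleton leaf is trivially its
own cluster and says nothing about cohesion.

Specimens with undefined distances must be resolved before NJ; the
pipeline prunes the specimen with the most undefined entries, iteratively,
and logs each removal. Pruning (vs imputing) keeps every branch length a
function of observed data.

## Combinations

All 2^k − 1 non-empty locus subsets are evaluated. Concatenation is
**complete-case** (a specimen needs every locus in the subset) because
distance methods are sensitive to large missing blocks; an 'N'-padding
mode is available behind a flag, with the padded blocks excluded
site-wise by pairwise deletion. Model pairing follows standard practice
for this evaluation design: K2P for matching and gap analysis, p-distance
for NJ trees; both are configurable. The best-close-match threshold is
recomputed per combination from that combination's own intraspecific
distances. Ranking is by best-close-match success, then best-match, then
tree discrimination, then label (stable and total).

## Diagnostics

A column is diagnostic for a species pair when each species is fixed for
one state and the states differ, with the gap character counted as a fifth
state — this is what lets a species-fixed deletion (e.g. a 6 bp indel in a
~170 bp mini-barcode) register as a diagnostic feature. Missing symbols
disqualify a column by default (`allow_missing` relaxes this by ignoring
such sequences column-wise). Consecutive diagnostic columns merge into
blocks; a block is an *indel* when one species' state string is entirely
gaps. Coordinates are 1-based inclusive alignment columns, with a helper
to map them to any specimen's ungapped coordinates and a BED-style
(0-based, half-open) export.

## Synthetic libraries

The generator emulates the statistical structure of a small multi-locus
reference library built from curated wood/leaf collections:

* A random bifurcating species genealogy per locus (topology by repeated
  random joins, exponential branch lengths), rescaled so the mean
  leaf-to-leaf path equals a target depth. Loci can optionally share one
  genealogy shape (`linked_loci`) to mimic plastid linkage; independent
  genealogies are the default for simplicity.
* Sequences evolve by the K80 (two-parameter) substitution model with
  transition/transversion ratio `kappa` (default 2.0), the same model
  family the downstream K2P estimator inverts — deliberately matched so
  parameter-recovery tests are meaningful.
* **Calibration**: the species tree's mean path is set to
  `inter_depth − intra_depth` and every specimen hangs from its species
  leaf on a pendant branch of `intra_depth/2`. Expected specimen-level
  divergence is then `intra_depth` within species and `inter_depth`
  between, which the K2P estimator recovers within ~10% at 5 kb.
* Each species independently receives one fixed gap block
  (`indel_length` columns, probability `indel_rate`) — the mechanism
  behind diagnostic indel mini-barcodes.
* Dropout is an **exact rounded count** of specimens removed at random,
  not per-specimen Bernoulli, so recovery rates in tests are deterministic
  (e.g. 35/39 = 89.74%).

The default configuration reproduces the study conditions this toolkit is
aimed at: 6 species sampled (4, 5, 6, 6, 7, 11) = 39 specimens across four
tissue types, all vouchered, species split between two broad regions, and
four loci with aligned lengths 234/239/173/350 bp, recovery rates
0.67/0.82/0.90/0.70, intraspecific depths 0.020/0.0026/0.0045/0.0063 and
interspecific depths 0.080/0.0099/0.0091/0.0073 (a divergent, indel-rich
nuclear spacer; a slow coding plastid locus; a short variable plastid
spacer with a diagnostic indel; and a long, very slow coding locus whose
intra- and interspecific distances nearly coincide — deliberately kept
overlapping, as that is the realistic failure mode of slow coding
barcodes). Indel rates are 0.5 (ITS2-like) and 0.2 (mini-barcode-like),
giving on the order of 18 and 6 expected gap columns respectively.

What the generator does **not** emulate: rate heterogeneity across sites,
codon structure, recombination, coalescent genealogy variance,
alignment error, sequencing error/chimeras, and GC bias (base composition
is uniform, so simulated GC ≈ 50% regardless of the real loci's values).
Passing tests therefore demonstrate correctness of the estimators and
decision rules under the stated model, not robustness to alignment or
sequencing artifacts in real libraries.

## Numerical and degenerate-input conventions

* Percentiles: numpy linear interpolation.
* All randomness flows through `numpy.random.default_rng` seeds; a
  library-level seed fans out to per-stage seeds by fixed integer offsets,
  so stages are individually reproducible.
* Identical sequences: zero matrices are legal everywhere; NJ resolves
  them deterministically and bootstrap reports no supported resolution.
* One-species libraries: interspecific summaries are empty and the gap
  report refuses (`InsufficientDataError`) rather than emitting NaN rows.
* Problem sizes in tests and the acceptance script (39-specimen demo
  library, 5 kb parameter-recovery loci, 50–100 random trees) were chosen
  as the smallest sizes at which the statistical assertions are stable.

## Known limitations

* Only K2P and p-distance; no gamma rate correction or other models.
* NJ only; no likelihood or Bayesian trees, no outgroup rooting.
* The concatenation treats loci as one unpartitioned matrix.
* The region-clustering report applies the species criterion to region
  labels verbatim; with independent per-locus genealogies the synthetic
  libraries carry no real geographic signal, so that report is exercised,
  not validated, by simulation.
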