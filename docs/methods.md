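# Methods

## Model and assumptions

The encoder treats a protein sequence as a trajectory of an iterated
midpoint map inside the unit disk. For a fixed arrangement φ of the 20
amino acids on the circle (vertex i at angle 2πi/20, i = 1…20,
counterclockwise from the positive x axis, so the largest-valued amino
acid sits at (1, 0)), the curve is

    ψ₀ = (0, 0),   ψᵢ = (ψᵢ₋₁ + φ(sᵢ)) / 2.

Unrolling gives ψᵢ = Σⱼ φ(sⱼ) / 2^(i−j+1): each point is an
exponentially weighted history of the residues seen so far, so nearby
points encode similar recent subsequences. Two consequences are load-
bearing and asserted in tests: ‖ψᵢ‖ ≤ (1 + ‖ψᵢ₋₁‖)/2 < 1 (points stay
strictly inside the disk) and ‖ψᵢ‖ ≥ 2^(−i) > 0 (the origin is never
reached), so quadrant assignment is total. For a homopolymer vⁿ the
closed form ψᵢ = φ(v)(1 − 2^(−i)) is exact and is used as an oracle.

The arrangement is driven by a physicochemical index: sorting the 20
values ascending assigns ranks 1…20. This is only well defined when all
20 values are distinct, which is why the catalog filter removes any
index in which two amino acids share a value, and any index with a
missing (NA) value — an index with NA cannot be totally ordered, a case
the AAindex format allows but the arrangement cannot use. The filter is
idempotent and order-preserving. "Redundant" is read as a within-index
tie between amino acids; de-duplication of entire identical indices is
a different operation and is deliberately not performed.

Each curve is summarised per quadrant. The half-open convention
Q1: x>0, y≥0; Q2: x≤0, y>0; Q3: x<0, y≤0; Q4: x≥0, y<0 is rotationally
symmetric, so no axis is privileged. Within a quadrant the pairwise
Euclidean distance matrix is formed and its largest eigenvalue taken.
For a symmetric non-negative matrix this is real, non-negative, bounded
between the mean and the maximum row sum, invariant under point
reordering, homogeneous of degree 1 under scaling of the point set, and
non-decreasing as points are appended (eigenvalue interlacing). It
therefore captures both the spread and the count of the points — unlike
the plain frequency (count/N) summary kept as the `fcgr` baseline.
Eigenvalues are *not* normalised by quadrant size by default: they grow
with sequence length, which is intentional (length is signal for the
target use case of comparing homologous families); `normalize_eigen
= "by_n"` divides each eigenvalue by its quadrant's point count for
users comparing sequences of very different lengths.

## Parameters

| parameter | default | meaning |
|---|---|---|
| catalog size k | 158 | indices used; features per sequence = 4k (632) |
| PCA components | 6 | dimensionality of the reduced space |
| distance metric | euclidean | also manhattan, cosine, seuclidean |
| tree method | upgma | also nj |
| normalize_eigen | none | or by_n (eigenvalue / quadrant count) |
| within/between divergence | 0.05 / 0.40 | generator per-site substitution rates |
| root length | 300 | generator sequence length (residues) |

All quantities are dimensionless; distances inherit the (arbitrary)
scale of the feature space.

## Numerical choices

- **Eigenvalues**: dense symmetric decomposition (`scipy.linalg.eigh`,
  largest index only) up to 512×512; Lanczos (`eigsh`, k=1, tol 1e−10)
  above. Empty and 1×1 quadrant matrices return 0, the natural limit,
  keeping features total. Asymmetric input is rejected rather than
  symmetrised.
- **Curve iteration**: evaluated as the linear filter
  y = 0.5·x + 0.5·y₋₁ (`scipy.signal.lfilter`) in double precision with
  no intermediate rounding.
- **PCA**: mean-centering only by default (scaling by flag), full SVD
  solver, with a deterministic sign convention — the largest-magnitude
  loading of each component is made positive — so repeated runs and row
  permutations give identical scores.
- **Standardized Euclidean**: per-column sample (n−1) standard
  deviation; zero-variance columns are dropped with a warning (they
  cannot contribute to any pairwise difference).
- **Trees**: UPGMA and neighbor joining are implemented in-package so
  that merge ties break deterministically toward the lexicographically
  smallest leaf label, making the topology a pure function of the
  labelled matrix (scipy's index-order linkage cannot express this);
  scipy average-linkage cophenetics and additive-matrix closed forms
  act as independent oracles in the test suite. NJ branch lengths are
  kept as computed (no clamping), so exactly additive inputs are
  reproduced to round-off.
- **Text formats**: TSV with full `repr` float precision, so identical
  inputs and flags give byte-identical outputs.
- **Residue policy**: non-standard symbols (B, J, O, U, X, Z, gaps) are
  skipped with a warning after uppercasing; `strict=True` raises. A
  fully filtered sequence is an error, not an empty curve.

## Synthetic data: what it does and does not emulate

The generator draws a uniform-random ancestor, mutates it once per
family at the between-family rate to obtain family roots, and mutates
each root independently per descendant at the within-family rate.
Mutations replace a site with a uniform draw from all 20 letters, so a
nominal rate p changes a site with probability 19p/20, and two
descendants of one root differ at ≈ 2p(19/20) of sites — a closed form
the tests check against observed Hamming fractions.

This emulates divergence *levels*, not biology: there is no position-
specific conservation, no substitution-matrix structure, no indels, and
no length variation. Passing the family-recovery test therefore shows
that the pipeline separates sequence populations at realistic
divergence contrasts; it does not certify performance on real protein
families, where composition bias and indels matter. Notably, at the
default contrast (5% within, 40% between) the task is easy enough that
the frequency-only baseline also recovers every family — the
distribution-vs-frequency gap documented on real data shows up only on
harder discrimination problems than this generator's defaults produce.

The bundled catalogs are synthetic for the same reason: the shipped
AAindex1 fixture file (plus one genuine hydropathy entry whose tied
values exercise the filter) and the deterministic 158-entry
`synthetic_catalog` stand in for a curated non-redundant AAindex
selection. Only the induced amino-acid orderings matter downstream, and
random tie-free orderings are, if anything, less correlated than real
physicochemical scales.

## Known limitations

- Raw eigen-features are length-sensitive; comparing sequences of very
  different lengths without `by_n` normalisation conflates length with
  composition.
- UPGMA assumes clock-like divergence; use `--method nj` when rates
  vary across lineages.
- The 4-quadrant segmentation is coarse; finer angular segmentations
  are out of scope.
- Cosine distance is undefined for an all-zero reduced vector and is
  rejected with the offending sequence named.

## Problem sizes used by the shipped studies

The test suite and `scripts/acceptance.py` run the recovery study at
3 families × 5 descendants × 300 residues over 20 seeded draws with the
full 158-index catalog (≈0.2 s per sequence for feature extraction,
about two minutes per study on one CPU), and the dimension contract on
a single 500-residue sequence.
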