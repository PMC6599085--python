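# Methods

This note documents the models, numerical conventions and design choices
behind `rnashotgun`, and what the synthetic-data generators do and do not
emulate.

## Mass arithmetic

All masses are monoisotopic, built from atomic masses hard-coded from the
NIST/AME tables to ≥ 8 decimals (H 1.00782503, C 12, N 14.00307400,
O 15.94491462, P 30.97376163, S 31.97207100) so results do not drift with
library versions. A modified residue is a parent ribonucleoside (A, C, G, U)
plus a signed elemental delta (e.g. ho⁵U = U + O; cmo⁵U = U + C2H2O3; s⁴U =
U − O + S). Deltas may remove atoms; they are validated when the residue is
registered. Pseudouridine and other isomers carry a `mass_silent` flag so
that quantification can warn that such states cannot be separated by mass
alone — positional knowledge (e.g. which residue sits at position 34) is the
user's responsibility.

Isotope labels re-assign natural-abundance atoms to a specific isotope; one
¹⁸O raises the monoisotopic mass by 17.9991596 − 15.9949146 = 2.0042450 Da,
the "+2 Da" signature of metabolic ¹⁸O₂ labelling. The registry serializes
to TSV (code, parent, signed delta formula, flags) and round-trips exactly.

## Digestion model

RNase T1 cleaves 3′ of guanosine, leaving 5′-OH and a 2′,3′-cyclic phosphate
that hydrolyses to a linear 3′-phosphate. Defaults: any residue with parent
base G is cleavable except 2′-O-methylguanosine (the 2′-O-methyl blocks the
transesterification); 7-methylguanosine is cleavable. Both are overridable
per residue. The default 3′-end chemistry of internal fragments is the
linear phosphate, with the cyclic form available by flag, because published
fragment tables do not always state which form they assume; the molecule's
own 3′ terminus always keeps its hydroxyl. Coordinates are 1-based linear
positions (no Sprinzl numbering); the anticodon wobble position is an
explicit annotation.

Fragment neutral mass uses residue-sum bookkeeping:

    M = Σ nucleoside masses + p · 79.96633 − w · 18.01056

with p = (n−1) backbone bridges plus any terminal phosphates and w = (n−1)
condensations plus one more for a cyclic terminus. This is verified against
full elemental-composition summation (two independent routes) to 1e-6 Da in
the tests, and against pyteomics' element masses as an external oracle.

## Ion calculus

Negative-mode ions are [M + k·Δ − zH]ᶻ⁻ with proton mass 1.007276 Da (the
electron matters at 4-decimal m/z) and averaged isotopologue spacing
Δ = 1.0033548 Da (¹³C−¹²C); exact per-isotopologue envelopes are available
through a per-element multinomial convolution, cross-checked against
brute-force enumeration of all isotopologue placements for small
compositions. Reported m/z precision is 4 decimals; nominal (integer) values
are display-only. CID series follow the standard oligonucleotide
nomenclature: c (5′ piece, 3′-phosphate), y (3′ piece, 5′-OH), w (3′ piece,
5′-phosphate) and a−B (5′ piece with 3′-OH, minus water and the 3′-terminal
nucleobase; for 2′-O-methyl residues the methyl stays with the sugar).
Complementarity c_i + y_(n−i) = M + H₂O holds by construction and is tested
at scale.

## XIC quantification

XICs sum centroid intensities within ±tol ppm of the target m/z per scan
(default 20 ppm — Orbitrap-class accuracy with headroom; the tolerance is a
parameter because instrument settings vary). Peak integration: apex = global
maximum; bounds extend outward until intensity falls below
`boundary_fraction × apex` (default 0.05) or a clear valley (a local minimum
below half the apex followed by a ≥ 2× rise) separates a neighbouring peak;
the area is the trapezoidal integral over the bounds. A peak is "detected"
only when the apex exceeds `min_snr` (default 3) times the baseline, taken
as the trace median. These defaults are ordinary chromatographic practice;
all are configurable.

State frequencies are peak-area ratios across the wobble states of one
locus. This is only meaningful when all states share the same fragment
coordinates — ESI response of oligonucleotide anions is governed mainly by
the phosphate backbone, not the base modification — so differing coordinates
raise an error rather than a warning. Each state is quantified at one
designated charge (the lowest supplied; optional summing across charges
behind a flag) with isotopologues M+0..M+2 summed, which cancels envelope
differences between states of near-identical composition. Mass-silent
collisions (e.g. U vs Ψ at the same locus) are merged under a combined label
with a warning.

## mzML

Reading is a streaming lxml parser covering centroided MS1 spectra, scan
times (minute/second units), polarity, and 32/64-bit float arrays with or
without zlib compression; profile spectra are rejected explicitly. Writing
emits a minimal valid mzML (64-bit uncompressed arrays, no timestamps) so
identical inputs give byte-identical files; the test suite validates the
format against Bioconductor's mzR as an independent implementation.

## Phylogenomic screen

Ortholog matrices are boolean organisms × families tables (TSV, with
organism metadata columns). Queries use a small boolean language
(`(cmoA & cmoB | trmR) & !trhP & !(trhP1 & trhP2)`) parsed by recursive
descent; `&` binds tighter than `|`. The bypass screen intersects family
presence across the reference genome, every query-selected gap organism and
any must-also-have genomes, then filters to families annotated
uncharacterized. Context ranking scores each candidate as (number of
organisms where it lies within `proximity_bp` of an anchor family on the
same replicon) + `fusion_bonus` × (number of organisms where it is fused
with an anchor), ties broken lexicographically. Defaults proximity_bp = 5000
and fusion_bonus = 2 make one fusion event outrank a single proximity hit,
mirroring how fusion evidence is usually weighted in gene-context arguments.

Fisher's exact test uses the probability-≤-observed two-sided rule (via
scipy), with sidedness an explicit parameter; an independent exhaustive
same-margin enumeration (`fisher_enumerate`, pure integer arithmetic) serves
as the oracle in tests. The odds ratio is the sample ad/bc, infinite when
bc = 0. Applied to the published 584-organism counts (49/84 organisms with
the peptidase-U32 hydroxylase also carrying the rhodanese-family one, and
22/32 for the two-gene variant), the two-sided p-values are 2.6e-4 and
7.3e-4, matching the printed 0.0003 and 0.0007 to one significant figure.
Whether those printed values were one- or two-sided, or computed over
bacteria only, is not derivable from the text; the two-sided, all-organism
reading is used here.

## Phenotype estimators

Doubling time is 1/slope of a least-squares fit of log₂(OD) against time over
a caller-supplied window (≥ 3 positive-OD points); the window is explicit
because automatic exponential-phase detection would be silent guessing.
Relative pausing is the mean per-replicate Fluc/Rluc of the test strain
divided by the reference mean, with SD across replicates — both estimators
are invariant to rescaling their inputs.

## Synthetic data: what it emulates and what it does not

`simulate_run` plants each wobble state of a locus as a Gaussian elution peak
(σ = 0.1 min, scans every 0.03 min) whose noise-free area is total abundance
× planted frequency; apexes are staggered by ~4σ per state and snapped to
the scan grid so that the noise-free case recovers the planted ratio
exactly. Noise defaults approximate an Orbitrap-class nano-LC run: Gaussian
2 ppm m/z jitter, 5 % multiplicative lognormal intensity noise, and ~20
exponential-intensity baseline centroids per scan scattered over m/z
600–2000. Not emulated: chromatographic tailing, co-elution of unrelated
species at nearby m/z, retention-time drift between runs, dynamic range
compression and MS2. Passing recovery tests therefore show the target-list /
XIC / integration / ratio machinery is correct under realistic mass accuracy
and counting noise — not that any real sample would be this clean.

`simulate_ortholog_matrix` plants 7 gap organisms (downstream families
present, upstream hydroxylase absent, bypass family present, with mixed
cmoAB/trmR modes), curated reference and must-also-have genomes carrying the
full pathway, background organisms whose pathway content never matches the
gap query, and 50 decoy families at a 30 % background presence rate. Flip
noise applies to decoy cells only: it models ortholog-call error in the
candidate background, whereas noise in the curated query families would
change the selected-organism set itself rather than stress the screen.
Context evidence places the bypass gene near cmoA in 2 gap organisms and
fused with trmR in 1. Real ortholog tables have phylogenetic correlation
structure, paralog confusion and lineage-specific loss that this generator
does not model.

`simulate_growth_reporter` draws exponential OD curves with lognormal noise
(σ = 0.02) and reporter counts with Poisson dispersion around planted F/R
ratios (Rluc mean 10,000 counts, 4 replicates), matching typical
plate-reader magnitudes.

## Problem sizes and degenerate inputs

The recovery studies run at deliberately small scale — 19 planted
frequencies × 1 run each, 20 matrix seeds, 100 phenotype seeds — chosen as
the smallest sizes at which the tested tolerances (±0.02 absolute frequency
error, ≥ 18/20 rank-1 recovery, < 2 % estimator bias) are meaningful.
Degenerate inputs fail loudly: empty XIC traces, loci with mismatched
coordinates, empty organism selections, self-pairs in co-occurrence tests,
non-positive growth slopes and single-residue CID precursors all raise (or,
where harmless, warn) rather than returning silent zeros.

## Known limitations

Average (non-monoisotopic) masses and adducts other than deprotonation are
out of scope; so are other nucleases, cross-run retention alignment,
fragmentation-intensity prediction, orthology inference itself (matrices are
inputs), and significance tests comparing strains (those depend on wet-lab
replicates no simulation can stand in for). Database-version-dependent
candidate counts from the original screen (ORF totals, intersection sizes)
are reproduced in shape by the synthetic generator, not in number.
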