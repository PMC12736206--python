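# Methods

## Model

The package treats molecular recognition as shared periodicity in
electron–ion interaction potential (EIIP) series. The underlying assumption
— inherited from the informational spectrum method (ISM) tradition — is
that long-range (5–1000 Å) electronic properties relevant to
protein–ligand recognition are encoded in the distribution of valence
electrons along the primary structure, so two molecules that interact
share characteristic frequencies in their EIIP spectra. The package makes
that assumption operational; it does not test it. Predictions are
spectral-compatibility rankings, not binding affinities or poses.

### Encoding

* Proteins: one EIIP value (Ry) per residue from the classical tabulated
  set shipped as package data (`ismsm/data/amino_acid_eiip.csv`). Applying
  the AQVN→EIIP formula to residue atomic composition does **not**
  reproduce that table (Leu/Ile are 0.0000 Ry tabulated but not by
  composition); because the provenance of published protein results is
  ambiguous on this point, a clearly-labeled `computed` table is provided
  alongside the default `tabulated` one.
* Molecules: `per-group` mode (default) yields one element per heavy atom
  in canonical SMILES order, valued at the EIIP of the heavy atom plus its
  bonded hydrogens; `per-atom` mode expands explicit hydrogens and values
  each atom by its own valence-electron count. Both readings of "atomic
  group" are supported because the published definition is ambiguous;
  per-group is the default as it keeps series lengths comparable to heavy
  atom counts and is insensitive to hydrogen-display conventions.
* Valence numbers are valence-*electron* counts (H=1, C=4, N=5, O=6, P=5,
  S=6, halogens=7), the AQVN convention; not bonding valences.

### Spectra

The DFT is taken after mean-centering (EIIP series have large DC offsets
that would otherwise leak into low bins) and zero-padding to a shared even
grid L (default 512, or the next power of two above the longest sequence;
758-residue tau needs 1024). A shared grid is required for the bin-wise
cross-spectrum product to be meaningful across different-length molecules;
zero-padding was chosen over truncation/resampling because it preserves
every series unchanged and only interpolates the spectrum. Padding means
an off-grid frequency can shift by one bin; all frequency comparisons
therefore use a 1-bin tolerance, and reported frequencies are rounded to
three decimals (the field's F(0.xxx) notation).

S/N is the amplitude at the queried bin divided by the mean amplitude over
all bins — the standard ISM usage; an all-zero spectrum (constant series,
e.g. a pure alkane in per-group mode) has undefined S/N at the operation
level, and is treated as S/N = 0 ("no shared information") inside the
screening loop so one such compound does not abort a library scan.

Peak extraction takes local maxima (boundary bins count against their one
neighbor), greedily selected by amplitude with a minimum bin separation;
equal-amplitude ties go to the lower frequency for determinism.

## Localization

* Sliding window: default length 64, step 1. A 64-residue window resolves
  the lowest frequency of practical interest here (~0.08, period ≈ 12.5
  residues, ≈ 5 periods per window) while keeping residue-scale
  localization. Windows are mean-centered and padded to the analysis grid;
  the response is the amplitude at the bin matched to the target frequency.
* Domain call: maximal contiguous run of windows with response ≥ 0.7 × max,
  reported as first-window-start to last-window-end (1-based inclusive).
  The threshold and the run rule are package choices — published analyses
  report only resulting intervals, not a rule. Ties between equal-length
  runs go to the earlier run.
* CWT: Morlet mother wavelet with ω₀ = 6 (the standard admissibility-safe
  choice), implemented by direct convolution (the wavelet-transform
  library named in early planning is not available in the runtime
  environment; the implementation is validated against a naive
  direct-integration oracle to ~1e-8, the envelope-truncation level at the
  6σ kernel support). The scale ladder is geometric over
  [s₀/4, 4s₀] with s₀ = (ω₀/2π)/f. Coefficient magnitudes are binned into
  five quantile bands ("five shades"); cells inside the cone of influence
  (within √2·scale of an edge) are excluded from the quantile fit and
  flagged, since boundary effects inflate coefficients. Hotspots are
  band ≥ 4 cells at the scale nearest s₀, merged into 1-based residue
  intervals.

## Scoring

Sigmoid orientation: the published (a,b) pairs as printed give s ≈ 0 for
every realistic molecular weight at the favorable end, which contradicts
the score's stated purpose. The defaults follow the cited reference
implementation's documentation — logP (1, −5), logS (−1, −5), MW
(0.012, −6), d (−1, 0) — so that favorable values score high; the literal
printed pairs remain available via `convention="printed"`. Toxicity
weights are 1.0/0.8/0.6 for none/low/high risk. Druglikeness d is an
input: the reference fragment library is proprietary, so `druglikeness`
normalizes caller-supplied fragment scores (Σvᵢ/n with caller-defined n).

k-means runs on standardized features (zero mean, unit variance), best of
`restarts` initializations (default 10) under a fixed seed (default 42),
k = 5 by default. Centroid distances — and therefore Total Score 2 =
S/N / distance — are measured in the standardized space, the same space
the clustering optimizes. Constant columns are dropped with a warning. A
compound exactly at its centroid is reported rank-first with a
zero-distance flag rather than an infinite score. The within/between
variance decomposition is computed from the standardized total sum of
squares and sums to 100%.

## Screening

A compound qualifies through its best frequency (per-frequency values are
all reported); the S/N hit cutoff defaults to 20, the lower edge of the
S/N range where well-behaved drug-like chemotypes concentrate in published
ISM screens, and is configurable because no published cutoff exists.
Per-compound spectra are always crossed with the protein spectrum (pair
CS), not used alone. Compounds are processed in sorted-id order so ranked
output is independent of library order; ties break by compound id;
identical inputs and seed give byte-identical output.

## Synthetic data

Generators emulate the structural features the method detects, not
realistic biochemistry:

* `make_planted_sequence` — cosine of amplitude A at f₀ (whole series, or
  only inside a burst region) plus Gaussian noise of sd σ, directly in
  EIIP space; fixture SNR ≡ A/σ. Default σ = A/3 (SNR 3) is the hardest
  condition the recovery criteria state.
* `make_planted_protein` — the same signal quantized to nearest-EIIP
  residues: a real amino-acid string whose encoding carries f₀ with
  quantization noise; exercises the FASTA→encode path.
* `make_ortholog_family` — n = 12 members (a mammalian ortholog set's
  size), shared f₀, independent noise, ±10% length jitter.
* `make_decoy_library` — random chain-grammar SMILES (alkane / aromatic /
  heteroatom fragments); the optional matched ligand quantizes
  sign(cos 2πf₀m) onto an O/N chain-atom palette, a square wave whose
  fundamental sits at f₀. Chemically exotic but valid-valence SMILES.
* `make_blob_admet` — Gaussian blobs 10σ apart on centered Hadamard
  directions. Even spreading matters: per-feature standardization
  down-weights features that mix signal and noise, and uneven random
  directions can halve the class margin (observed, not hypothetical).

What a green fixture test establishes: the pipeline recovers planted
periodicities, regions and cluster structure at SNR 3 from inputs obeying
its own preconditions. What it does not establish: that real
protein–ligand pairs share EIIP frequencies, that decoy SMILES resemble
real chemical libraries, or that score conventions match any particular
published screen.

## Numerical choices

* Frequencies live in (0, 0.5]; bin matching uses `round(f·L)` clamped to
  [1, L/2], 1-bin tolerance.
* Sigmoid evaluated in its numerically stable branch per sign of a·p+b.
* All randomness flows through `numpy.random.default_rng(seed)`; every
  fixture requires an explicit seed.

## Known limitations

* Grid choice can shift a reported frequency by one bin; comparisons
  across analyses must share a grid or use the bin tolerance.
* Domain/hotspot defaults (window 64, threshold 0.7, band 4) are package
  choices; reproducing specific published residue intervals may require
  different settings.
* S/N correlates with molecule size (larger series, more spectral energy);
  Total Score deliberately trades this against druglikeness, but raw S/N
  rankings favor large compounds.
* The CWT edge treatment excludes, rather than corrects, cone-of-influence
  cells; hotspots at sequence termini are flagged, not rescued.
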