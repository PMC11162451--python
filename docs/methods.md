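# Methods

## The setting

A formalin-fixed paraffin-embedded (FFPE) tissue slide is dissected into a
rectangular grid of voxels; each voxel is digested with trypsin and
quantified by label-free DIA mass spectrometry. Two families of questions
follow. First, *digest quality*: FFPE fixation chemically modifies
proteins (formaldehyde adducts, oxidation), and modifications on or near
lysine can block trypsin, so the rates of semi-tryptic peptides, missed
cleavages, and open-search mass shifts are diagnostic of the preparation.
Second, *spatial biology*: proteins whose intensity profiles across voxels
co-vary are candidates for shared regulation, and the summed intensity of
an annotated protein set per voxel localizes a biological process on the
slide. `voxelprot` implements both, plus a synthetic-data generator that
makes every estimator testable against known truth.

## Digest model

Trypsin cleaves C-terminal to K or R unless the next residue is P
(proline suppression is on by default and configurable off, matching
common search-engine settings); up to `max_missed` retained sites are
enumerated by `in_silico_digest`. A peptide in protein context is
*fully tryptic* when both termini conform (a protein terminus always
conforms), *semi-tryptic* when exactly one does, *non-tryptic* otherwise.
A peptide is *miscleaved* when it retains ≥ 1 internal cleavage-conforming
site.

**Counting unit.** All QC percentages are over *unique peptides*: distinct
(sequence, modification-set) pairs per voxel. Spectrum-level (PSM)
counting would weight abundant peptides more; whether published
percentages are per peptide or per PSM is often unstated, and per-peptide
is the reading consistent with "percentage of total peptides". Pooled
("overall") statistics aggregate the per-voxel unique counts.

**Modification catalog.** Shifts are frozen at full monoisotopic
precision from standard atomic masses: methylation CH2 = +14.01565 Da,
oxidation/hydroxylation O = +15.99491, formylation CO = +27.99491,
dihydroxy O2 = +31.98983, deamidation +0.98402, carbamidomethyl +57.02146,
acetylation +42.01057. Matching uses a 0.01 Da tolerance. Frequency
tables exclude, by default, the carbamidomethyl and acetylation shifts
(fixed/common search modifications); exclusions are by shift value only,
so residue-specific exclusions (e.g. Met-oxidation but not Pro-oxidation,
both +15.9949) cannot be expressed — a known limitation. The conventional
"C-term acetylation" exclusion very likely means protein *N-terminal*
acetylation; it is honored as an acetylation-shift exclusion either way.

**K:R ratio.** The cleavage-preference ratio counts peptides ending in K
vs R (protein C-terminal peptides excluded, since their terminus is not a
cleavage) and, as an independent context, the preceding residue
(`prev_aa`) K vs R (protein N-terminal peptides excluded). A value near
0.5 means arginine cleavage is twice as frequent.

## Spatial matrix model

Matrices are protein × voxel log2 intensities with missing values.
The pipeline keeps rows quantified in every voxel ("fully quantified"),
quantile-normalizes the voxels (each column's sorted values are replaced
by the row-wise means of the column-sorted matrix — idempotent, and
exactly distribution-equalizing), and ranks proteins by the standard
error of intensity across voxels, SE = sd(row, n−1) / √n_voxels. The
spatial-variability filter retains SE strictly greater than the cutoff
(default 0.18). Two open choices were resolved as follows: SE means
standard error of the mean rather than plain standard deviation (that is
what "SE" abbreviates; the cutoff is a parameter, so the other convention
is reachable by rescaling), and SE is computed on the log2 scale.

## Co-regulation networks

Spatial co-regulation between proteins is the Pearson correlation r of
their intensity profiles across voxels. The weighted co-expression
convention maps r to an adjacency strength in [0, 1] by a soft-threshold
power β: unsigned `a = |r|^β` (default β = 6) or signed
`a = ((1+r)/2)^β` (default β = 12). Unsigned is the default because
inverse regulation is biologically informative here (anti-correlated
partners of a seed protein are reported from the signed r matrix kept
alongside). The topological overlap matrix

    TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)

smooths adjacency by shared neighbors; modules are flat cuts (default
height 0.5) of average-linkage clustering on `1 − TOM`, with singleton
clusters labelled "0" (unassigned). Seed neighborhoods default to the
top-k rule (k = 23); a published adjacency *cutoff* stated as "less than"
a tiny value is internally inconsistent with selecting the *closest*
proteins, so the threshold rule's direction is configurable and top-k is
the default. Ties everywhere break by ascending accession for
determinism. Because x ↦ x^β is monotone on |r|, unsigned neighborhood
rankings are invariant to β.

## Term maps and enrichment

A term map sums member-protein intensity per voxel. Summation defaults
to the *linear* scale (2^x back-transform of log2 entries) because adding
log intensities has no physical meaning; a log2-sum is available behind a
flag since the convention in published figures is often unstated. Maps
are min–max scaled to [0, 1] (an all-equal map is drawn mid-ramp at 0.5
to stay visually neutral without dividing by zero) and rendered as SVG
polygons along a linear dark-blue (0,0,139) → dark-red (139,0,0) ramp;
excluded voxels are grey. Enrichment of a query set against term
membership uses the upper-tail hypergeometric test with
Benjamini–Hochberg adjustment across tested terms. This is a
database-local computation: its p-values depend only on the supplied
annotation and universe, and are not comparable to web-service FDRs
computed against external interaction databases.

## Synthetic data generator

The generator defines the package's study conditions; defaults are fixed
once and used by tests and the acceptance script alike.

**Layout.** 4 × 5 grid of unit squares numbered row-major from 1, with
voxels {2, 5, 8} flagged excluded → 17 analysis voxels, the design of a
macrodissected slide whose three voxels were suspended for suspected
contamination.

**Intensity model.** `x_pv = μ_p + λ_p·s_m(v) + ε_pv`, with μ = 20 (log2),
ε ~ N(0, σ²) i.i.d., σ = 0.25. Spatial profiles over retained voxels:
*gradient* (linear in voxel index, 0 → 1), *hotspot* (1 at a chosen voxel,
decaying as exp(−d) in grid distance with unit scale), *uniform*
(constant). Two planted modules of 24 proteins (one hotspot, one
gradient) with loading |λ| = 4; the last 15 % of each module's members
carry a negated loading (anti-regulated partners). 1320 background
proteins have λ = 0. Missingness is missing-completely-at-random at rate
0.3 outside a designated fully quantified core (all module proteins plus
405 background proteins = 453), giving 1368 total proteins of which ≈ 453
survive the fully-quantified filter. Effect sizes and noise are chosen
for testability: the module/background separation under the SE filter and
the ≈ 3:1 quantified/fully-quantified ratio mirror the scale of a real
slide, but no published effect-size or noise figures exist to calibrate
against.

**Proteome.** Synthetic proteins are concatenated tryptic blocks
(7–14 residues): interiors free of K/R/P except one forced proline and
at least one methionine (neither at a block start), terminal residue K
with probability 1/3 (so arginine cleavage is preferred ≈ 2:1, matching
the observed digest preference). This composition control guarantees that
every tryptic product has modification-eligible residues and that
trimming a terminus always produces a non-conforming (semi-tryptic) end —
the properties that make exact parameter recovery possible. Real
proteomes are messier; passing recovery tests demonstrates estimator
correctness, not robustness to real sequence composition.

**Peptide sampling.** Per record, one global random stream is consumed in
documented order: protein → tryptic fragment → terminal-lysine
methylation (p_methyl_K = 0.08 per terminal K; a methylated lysine is
left uncleaved with probability 0.9, merging the peptide across the site)
→ plain miscleavage (p = 0.12) → semi-tryptic trimming (p = 0.022; 1–3
residues off a uniformly chosen terminus) → modification channels →
voxel (uniform over retained) → spectral count (1 + Poisson(1)).
Modification channels carry a *per-peptide* probability; the site is
drawn among residue *types* present by preference weight (oxidation
+15.9949 at 0.065 on P:M = 3:1; dihydroxy +31.9898 at 0.03 on P;
formylation +27.9949 at 0.02 on K; deamidation +0.98402 at 0.03 on N/Q),
falling back to a uniform position if no preferred residue is present.
Per-peptide probabilities make the realized shift frequency exactly
binomial in the configured rate, which is what the recovery tests assert
to within 3σ. These defaults reproduce the qualitative landscape of FFPE
digests: ~2.4 % semi-tryptic, ~15 % miscleaved, ~16 % modified peptides,
oxidation ≈ 6.8 %, methylation ≈ 3 % sitting exclusively on lysine, and
miscleaved-and-modified peptides dominated by lysine methylation.

**What the generator does not emulate.** Raw spectra, retention times,
DIA windows, search-engine scoring and FDR, intensity-dependent
missingness, correlated noise between neighboring voxels, shared peptides
between proteins, and real amino-acid composition. Tests passing on this
generator validate the estimators' arithmetic and the recovery of planted
structure, not performance on real search output.

## Numerical choices

- Quantile normalization uses a stable argsort; with ties the column
  values are still exactly equal after one pass, making the map
  idempotent to 1e-12.
- Correlation on a zero-variance row/column raises an error naming the
  offending protein/voxel rather than emitting NaN.
- TOM is computed by matrix product (`(A@A)_ij − a_ij` with unit
  diagonal) and symmetrized; it equals the brute-force triple loop to
  1e-12 and its denominator is provably ≥ 1.
- The SE filter is strictly exclusive at the boundary (SE = cutoff drops).
- Degenerate inputs: an all-equal heatmap maps to 0.5; an empty
  fully-quantified selection, empty FASTA, or < 2 retained voxels raise
  typed errors; an empty retained list from the SE filter is allowed.
- Seeds: every generator derives an independent stream from
  `(config.seed, stream_id)`; identical configs give bit-identical
  outputs, including byte-identical SVG and manifest hashes.

## Pipeline

Stages run in fixed order qc → rank → spatial → network → termmap on
synthetic or user-supplied inputs, writing TSV/JSON/SVG plus a manifest
of sha256 hashes. Quantile normalization is an on-by-default stage
toggle; exact noise-free collinearity checks disable it, since a
per-column monotone (not affine) remap is only approximately
correlation-preserving. Problem sizes throughout the tests and the
acceptance script (5000 peptides, ≤ 1368 proteins, 17 voxels, ≤ 30-node
brute-force TOM oracles) were chosen so the whole suite verifies the full
default study design in seconds.

## Known limitations

- Exclusion lists are shift-valued, not (shift, residue)-valued.
- The SE cutoff convention (sd vs sd/√n) is resolved by documentation and
  a parameter, not by evidence.
- The hypergeometric enrichment is a local stand-in; its FDR values are
  not comparable to STRING's database-versioned results.
- Spectral-count resampling mimics only sampling noise between datasets,
  not different acquisition chemistry.
- Protein-level quantile normalization compresses extreme spatial signal
  (the sorted-value averaging pulls module peaks toward the background
  distribution), so module detection at the default cut height can
  dissolve after normalization even when it is exact on the raw matrix;
  the pipeline's normalization toggle and the cut height are the knobs,
  and the seed-network term map does not depend on module detection.
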