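# Methods

This note documents the statistical models, defaults, and design choices
behind methylworm, and what the synthetic-data generator does and does not
emulate.

## Study design and data model

The package targets a 3-genotype × 3-replicate label-free design: wild type
(WT) plus knockouts of a Type I arginine methyltransferase (KO1, writes
MMA/ADMA) and a Type II enzyme (KO2, writes MMA/SDMA). Two data streams are
analyzed: methyl-enriched SCX fractions (E1–E3) quantified at the peptide
level, and an unfractionated whole-cell lysate quantified at the protein
level. All abundances are handled in log2.

## Methyl-restricted FDR

Target-decoy FDR computed over all PSMs underestimates the error of the small
methylated subpopulation, because methyl PSMs are rarer and score lower than
unmodified ones. The estimator therefore ranks only methyl-bearing PSMs
(targets and decoys together) by search score and picks the most permissive
cutoff at which `#decoys ≥ c / #targets ≥ c ≤ 0.01`. The plain ratio (not
`(decoys+1)/targets`) is used; score ties are kept or dropped as a block so a
tie never splits. If decoys dominate everywhere, the retained set is empty
with a warning rather than an exception. The threshold is global across
fractions by default (`per_fraction=True` computes it within each fraction).
Localization filtering is per modification site and inclusive at the 0.75
boundary; a PSM survives only if at least one methyl site survives.
Fraction-duplicate collapse treats peptide identity as (sequence, full
modification set) — two proteoforms of one sequence stay distinct — and keeps
the row whose summed abundance across samples is highest, recording the
source fraction. Row-level rather than per-sample selection keeps each
peptide's quantitative profile internally consistent.

## Neutral-loss discrimination of ADMA vs SDMA

Constants are derived from atomic monoisotopic masses: dimethylamine
C₂H₇N = 45.058 Da (ADMA), methylamine CH₅N = 31.042 Da (SDMA); the proton is
1.007276 Da. Both the parent ion and the loss ion are measured with
σ = 0.02 Da, so the acceptance threshold on the residual is the propagated
σ_Δ = √(0.02² + 0.02²) ≈ 0.028 Da, applied at exactly 1σ_Δ. "Parent ions"
include the precursor and every annotated b/y fragment (a `precursor_only`
flag restricts this); loss fragments are assumed to keep their parent's
charge. Candidate theoretical losses for a parent are all (a, s) with
1 ≤ a+s ≤ the number of dimethyl-arginines inside the parent's residue span.
Per (parent, loss peak) pair the single best theory (minimum |residual|, ties
toward fewer total losses, then toward ADMA — the dominant form) is kept.
Relative intensity is gated at 0.1% of the spectrum base peak. Localization:
an event whose span contains exactly as many candidate arginines as its loss
multiplicity assigns its form(s) to those residues; single-form events assign
forms, mixed (ADMA+SDMA) events that localize record positions but keep forms
at spectrum level, since the form-to-residue mapping is underdetermined.
Site verdicts require at least one unambiguous localized event; conflicting
forms on one site yield `unresolved-DMA` with a conflict flag. Dimethyl sites
without neutral-loss confirmation are tabulated as "DMA (unresolved)" so
confirmed ADMA and SDMA remain separate evidence classes.

## Missingness and imputation

Features are classified per row against the genotype design:

- **complete** — no missing values;
- **MNAR** — at least one genotype group entirely missing while another is
  entirely observed (the intensity-censoring signature, e.g. an ablated
  modification in a knockout);
- **MAR** — otherwise, with at most 1 missing value per group (the default
  reading of "few"; configurable);
- **drop** — anything else (reported, excluded).

MAR rows are imputed by KNN-TN: per-feature mean/SD are estimated by
truncated-normal maximum likelihood with the global minimum observed value as
the detection limit (the left-truncated likelihood is unbounded along
μ→−∞, σ→∞ when most mass sits at the limit, so estimates are clamped to the
moment estimates beyond 3·SD); rows are standardized by these estimates;
neighbors are the `k = 10` nearest features by Euclidean distance over
co-observed samples (≥ 3 shared samples required — a stability choice for a
9-sample design); each missing cell is the inverse-distance-weighted mean of
neighbor values, back-transformed. The procedure is deterministic. Features
with fewer than 2 observed values go to the down-shift path; a cell with no
usable neighbor is imputed at its feature's truncated-normal mean (reported).

MNAR rows are imputed per sample column from
`Normal(μ_s − 1.8·σ_s, (0.3·σ_s)²)` with μ_s, σ_s computed from the observed
values of that column of the full matrix (the per-column convention of the
common desktop implementation); columns with fewer than 2 observed values
fall back to global statistics. Draws are seeded.

VSN fits a per-sample generalized-log transform
`h_s(x) = arcsinh(a_s + b_s·x)/ln 2`. Per-sample scale factors come from
robust median-ratio calibration against the row-wise geometric mean; the glog
crossover point from a least-trimmed-squares fit (best 75% of features) of
the noise model `Var ≈ σ_a² + σ_m²·mean²` on the log-variance scale, which
keeps the huge intensity dynamic range from dominating. For large x,
h_s(x) → log2(x) + const; b_s > 0 by construction, so the transform is
rank-preserving within each sample. This is a deliberate simplification of
the reference VSN estimator: it is accepted by the variance-stabilization
property (the SD-vs-mean trend after transform shrinks by more than an order
of magnitude on additive-plus-multiplicative noise), not by parameter
equality with the reference implementation.

Pipeline order is classify → impute (both paths) → VSN. Imputation never
alters observed cells; per-cell provenance (observed / knn-tn / downshift) is
emitted.

## Protein summarization and protein-level significance

Peptide rows of one protein are centered and combined by an iterative
consensus: start at the per-sample median, weight each peptide by
`max(0, Pearson r(peptide, consensus))²`, recompute the weighted average, and
iterate to 1e-8 (≤100 iterations); peptides with weight < 0.01 are excluded
and the consensus refit. Negative correlations get weight zero and cannot
flip the consensus sign; if everything is mutually anti-correlated the single
highest-variance peptide is used, with a warning. Per-sample protein
abundance = consensus + mean offset of the peptides used — per-sample output
is the default. This iterative squared-correlation consensus is a faithful
simplification of the factor-analytic reference method; it is validated by
recovery properties (median |error| of protein log2FC ≤ 0.2 under 30%
uncorrelated noise peptides at noise SD 0.5), not output equality.

Protein two-group significance is the PECA order statistic: with n peptide
Welch p-values and the lower median at rank k = ⌊(n+1)/2⌋ (k = n/2 for even
n), `p_protein = BetaCDF(p_median; k, n−k+1)` — exactly uniform under the
null. Benjamini–Hochberg converts p to q.

## Differential PTM statistics

For methyl peptides with protein-level data, the adjusted contrast removes
the protein-abundance component: `Δ_adj = Δ_PTM − Δ_protein`,
`SE² = SE²_PTM + SE²_protein`, with Satterthwaite df combining the two
comparisons (`df = SE⁴ / (SE⁴_PTM/df_PTM + SE⁴_protein/df_protein)`; the
source method does not pin the df rule, so this choice is documented and
test-covered). Without protein data, a plain Welch test. Degenerate
zero-variance cases use the t = ±∞ convention.

After an initial BH pass, features with q ≥ 0.05 form an empirical null N of
t-statistics, and every feature is re-scored as
`p = (1 + #{t ∈ N : |t| ≥ |t_i|}) / (1 + |N|)` — a two-sided empirical tail
with add-one smoothing (the tail convention was open; empirical two-sided is
implemented). Recalibration is skipped with a warning when fewer than 20
features enter the null. Final BH, then calls: up if log2FC > 0.585 and
q < 0.05, down if log2FC < −0.585 and q < 0.05, strict inequalities;
"fold change" is the difference of group means of log2 abundances.

Two structural properties of this published procedure are worth knowing.
First, the recalibrated p has a floor of 1/(1+|N|), so with ~180 features the
smallest achievable q is roughly `n_features / ((1+|N|)·k)` where k features
share the floor — a single strong-|t| true effect that narrowly misses the
initial BH pass joins the null, raises the null's maximum |t|, and can push
the floor q above 0.05, collapsing all calls for that dataset. Second, when a
feature's knockout values are entirely censored and down-shift-imputed, its
measured fold change is reconstructed as ≈ (WT level − column mean) − 1.8σ_s
regardless of the true (deeper) loss; recovery of fully-censored ablated
features is therefore bounded by the spread of WT levels relative to 1.8σ_s,
empirically ~50–90% depending on the draw. Both effects are inherent to the
method, not to this implementation; the test suite measures statistical power
on complete matrices (where it exceeds 90% for effects ≤ −5 log2 at noise SD
0.3, n = 3/group) and separately checks that ablated peptides that escape
censoring are recovered.

## Methylome summary and motifs

Site counting is proteoform-aware: the unique key is (protein, position,
form), so a residue carrying MMA and ADMA counts as two sites; per-protein
residue counts and density use (protein, position) once. Density is
100 × methylated residues of a class / all residues of that class in the full
sequence, regardless of MS coverage; proteins with zero residues of the class
are excluded with a warning. Motif windows are ±7 residues, padded with a
dedicated gap symbol at protein termini (excluded from counts; 'X' is not
used because it is a legal ambiguity code). Enrichment scores are binomial
tails against position-independent proteome-wide background frequencies (the
reference web tool's bounded-window background is approximated by this):
`−log10 P(X ≥ k)` for overrepresentation, `log10 P(X ≤ k)` (negative) for
depletion, 0 at exact background rate; p = 0 or 1 backgrounds score ±∞ by the
natural limit, and tails are floored at 1e−300 before taking logs.

## Synthetic-data generator

The generator emulates the study conditions with complete ground truth.
Defaults: 60 proteins of 120–400 residues with 40% carrying RGG repeat
blocks; 180 methyl sites (the scale of the quantified study), 74% on lysine
with form mix 0.107/0.107/0.786 (mono/di/tri — trimethyl dominant), arginine
split 0.256 MMA / 0.744 DMA with 90% of DMA being ADMA; R-sites fall in RG
contexts with probability 0.7; 36 arginine sites are knockout-1-dependent
with ablation log2FC uniform in [−9, −5]. PSM scores are Gaussian
(targets N(3,1), decoys N(0.5,1)); for every decoy a matching "false target"
is emitted from the decoy distribution so the realized FDR is recountable.
Localization probabilities straddle 0.75 (85% high). Spectra carry singly
charged b/y ladders with log-normal intensities, neutral-loss companions at
5% of parent intensity, and independent per-peak mass errors of
σ = 0.02 Da (so parent-minus-loss differences have the propagated σ√2).
Abundances follow baseline N(25, 2²) + genotype effect (30% of proteins,
N(0, 1.5²)) + peptide offset N(0,1) + noise N(0, 0.3²); MNAR censoring
removes values below the global 4% quantile, MAR dropout is 4%. Trypsin
digestion uses the classic rule (no cleavage before proline) with a
`trypsin_p` flag; monoisotopic residue masses come from a single embedded
table; genotype labels are fixed WT/KO1/KO2.

What the generator does not emulate: chromatographic structure, isotope
envelopes, charge-state deconvolution, co-eluting interference, shared
(razor) peptides, protein-level MNAR structure tied to biology, or
search-engine score semantics (a generic monotone score is emitted, since the
exported score type is not specified). Passing tests therefore demonstrate
correctness of the statistical machinery under a faithful but idealized error
model, not performance on raw instrument data.

## Problem sizes and determinism

The default test suite and the acceptance script use the study-scale defaults
above (180 features, 9 samples, 500-spectrum classifier benchmarks, 20-seed
FDR/imputation sweeps, 4000-draw type-I estimates) — sizes chosen so every
property is measured with useful Monte-Carlo precision while the whole suite
runs in well under a minute per module. All randomness flows from explicit
seeds (`SimConfig.seed` fans out to independent per-stage streams; the
pipeline derives per-stage seeds from one global seed), so every reported
number is bit-reproducible.
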