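# Methods and design notes

This note records the models implemented by the package, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerically delicate choices. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Nomenclature

The parser implements the common LIPID MAPS-style shorthand grammar:
`CLASS(chain[/|_chain...])[adduct]`, with chain tokens
`[O-|P-][d|t]C:D[(OH)|(nOH)|;On]`. `O-` marks an alkyl-ether linkage,
`P-` a vinyl-ether (plasmalogen) linkage; `d`/`t` mark di-/trihydroxy
sphingoid bases (the hydroxyl count is recorded on the chain). `/`
separates chains of known sn-position, `_` chains of unknown position;
the distinction is recorded but not used downstream. A name with a
single bare `C:D` token (e.g. `PC(34:1)`) is species-level: only totals
are known and the chain list is empty.

Two ambiguities are resolved by convention:

* A single unprefixed ester chain (`LPC(16:0)`) is indistinguishable
  from a species-level descriptor in shorthand; such names always parse
  at species level. Prefixed single chains (`SPH(d18:1)`) are
  chain-resolved.
* Species-level names with an odd carbon total are flagged odd-chain
  (an odd total forces at least one odd chain); even species-level
  totals are treated as not-odd because the chains are unresolved.

The class vocabulary is configuration (a text file of codes, seeded with
common glycero-, glycerophospho- and sphingolipid codes); unknown codes
parse with a warning rather than failing, since export dialects disagree
on class naming. Adducts (`+H`, `-H`, ...) are parsed but excluded from
the canonical name: two adduct ions of one species are duplicates for
the deduplication stage, not distinct analytes.

## Experiment container

`LipidExperiment` holds a lipids × samples matrix with lipid and sample
annotations and an append-only provenance log; every transforming
operation returns a new container and appends exactly one record.
Missing measurements are NaN, never 0; readers map exported zeros to
missing only when the dialect mapping says so (default: 0 is a real
measurement). The assay kind moves along `raw_area → concentration →
normalized_concentration → log2` (or `raw_area → log2` without internal
standards).

On-disk format is a directory of three TSVs plus a JSON provenance file
— diffable and language-neutral by design. Within-sample duplicate
identifications are kept as separate rows (duplicate index entries)
until `deduplicate_lipids` resolves them, so no information is lost
before the dedup policy is applied.

Per-lipid retention time is the median of the per-sample values, stored
at import together with the spread; the reference filter tests this
consensus value. Technical replicates (samples sharing factor levels and
batch, marked `technical`) collapse by NaN-ignoring mean (or median)
after calibration and before imputation; both orders work and the chosen
order is logged in provenance.

## Filtering

Reference filtering applies, per lipid, the class's retention-time
window, total-carbon bounds, double-bond bounds and odd-chain policy, in
that fixed order, attributing each removed lipid to the first rule it
violates — so per-rule counts sum exactly to the total removed
(`removed + retained = input` is asserted throughout). Internal-standard
rows are exempt: they are spiked compounds the calibration stage needs,
not identifications to vet. Classes without a reference entry are kept
with a warning by default (configurable to drop); silent removal of
whole classes would be worse than noisy retention.

Deduplication policies: `keep_max_area` (row with the largest total
area survives — the most intense identification wins, the common
convention and the default), `keep_nearest_rt` (row closest to the
duplicate group's median retention time), `merge_sum` (per-sample sum,
treating missing as 0 when at least one value is present).

Missingness filtering has two scopes. `overall` removes a lipid whose
missing fraction across all samples exceeds the threshold. `per_group`
removes it only when the fraction exceeds the threshold in *every* level
of a grouping factor: a lipid well-measured in one condition but
censored in another is exactly the biology a differential analysis wants
to keep, and with left-censored missingness a strong down-regulation
produces that pattern. The pipeline defaults to `overall`; the shipped
end-to-end configuration uses `per_group` on the contrast factor for
this reason.

## Calibration and recovery

The calibration curve is an unweighted OLS line of measured area on
nominal concentration (weighted 1/x fitting is a config option, not the
default, as no weighting scheme is canonical for these data). The
linearity range is the longest contiguous run of at least 3 dilution
levels (all levels when only 2–3 exist) whose own fit reaches the r²
threshold (default 0.98). Candidate runs are tried longest-first and,
within a length, with the most top levels trimmed first: detector
saturation at the top of the series is the physically expected failure
mode. No qualifying run is an error advising manual review of the
series; a silent fallback would hide a broken dilution series.

Recovery is `100 × (measured IS concentration) / (nominal spiked
concentration)` per sample per standard. Normalization converts each
analyte's area through its class-matched standard's curve and divides by
that standard's recovery fraction in the same sample — per (sample,
class-matched standard), not per sample average, so class-specific
extraction differences are respected (a per-sample overall mean is
available for designs with few standards). Classes without a mapped
standard raise an error by default (`skip_normalization` is opt-in):
silently misnormalizing a class is worse than failing. Out-of-linearity
concentrations are kept but flagged in a parallel boolean matrix rather
than dropped; negative inversions (area below the fitted intercept)
become missing with a log entry.

The simulator's measurement model places recovery on the analyte amount
*before* the instrument response: `area = slope · (conc · recovery) +
intercept`, then multiplicative log-normal noise. Extraction losses
reduce the amount of lipid reaching the detector; the intercept is an
instrument background and is not attenuated. Under this model the
noise-free inversion is exact, which the tests exploit.

## Imputation

Default `half_min`: each lipid's missing entries become half its minimum
observed value — the standard left-censoring surrogate, guaranteeing
strictly positive values and hence a finite log2 without pseudocounts.
`knn` (k = 5 by default, a common metabolomics choice) imputes each
missing cell as the mean over the k nearest samples by Euclidean
distance on co-observed lipids. `zero` exists for exploratory use only
and is flagged in provenance. Imputation operates on the concentration
scale before the log transform; observed cells are never altered, and a
lipid missing everywhere is an error pointing at `filter_missingness`.
The package does not try to distinguish censored from random missingness
algorithmically; the generator produces left-censored missingness
because that is the dominant physical mechanism.

## Exploratory analysis

PCA mean-centers (and by default unit-variance scales) lipids and
decomposes by SVD, with a deterministic sign convention (the
largest-magnitude loading in each component is positive). Constant
lipids under scaling are left centered rather than dividing by zero.
PLS-DA fits a NIPALS PLS2 model against a one-hot group matrix;
explained variance is the share of centered X variance captured per
component. Analyses run on log2 data; the transform is recorded in
provenance. Summary profiles aggregate per-sample abundance by class,
total chain length or double-bond count. Hierarchical ordering (average
linkage, Euclidean) is provided as a heat-map utility; the clustering
menu is deliberately limited.

## Differential analysis

Per lipid, OLS on a treatment-coded design matrix (intercept + factor
dummies + optional batch dummies). The contrast is a difference of level
coefficients on the first factor. Rank deficiency (e.g. batch confounded
with condition) is detected by pivoted QR and reported with the aliased
column names.

Variance moderation follows the standard empirical-Bayes treatment for
omics linear models, implemented from its defining formulas: with
`zᵢ = log s²ᵢ` and residual df `d`, moments of `zᵢ − ψ(d/2) + log(d/2)`
are matched to the scaled-F model using digamma/trigamma identities; the
trigamma inverse is solved by Newton iteration. When the observed
variances are under-dispersed relative to pure chi-squared noise the
prior df is infinite and all variances collapse to the common value;
`prior_df=0` disables moderation and reproduces the classical t exactly
(asserted to 1e-10). The implementation is cross-validated against the
Bioconductor reference implementation in the test suite (agreement to
~1e-14); that library is never used in the computation path. With fewer
than 2 residual df the moment estimates are undefined and the code falls
back to unmoderated t with a warning.

`remove_batch` centers each lipid within batch and restores the grand
mean. It is intended for exploration and visualization; testing should
prefer `batch_mode="covariate"`, which loses no degrees-of-freedom
bookkeeping. On a balanced orthogonal design the two routes give
identical contrast estimates (asserted to 1e-8); removal warns when
batch is confounded with a declared factor, since it would then absorb
signal.

Significance is strict: `adjusted_p < alpha`, alpha default 0.05.
Enrichment is one-sided hypergeometric over-representation of
significant lipids within sets defined by class, chain-length bins
(default ≤30, 31–40, 41–50, >50 total carbons) and double-bond bins
(0, 1–2, 3–5, >5), BH-adjusted across sets. The bins are configurable;
no canonical granularity exists. Zero significant lipids yields an empty
table with a notice, not an error. Rank-based (GSEA-style) enrichment is
out of scope; over-representation was chosen because it is exact,
assumption-light and directly interpretable at these set sizes.

## Synthetic data

The generator defines the study conditions used throughout the tests:
4 lipid classes × 25 species by default, 12 samples in two balanced
groups and two balanced batches, biological spread 0.4 on the log2
scale, measurement noise σ = 0.05 (multiplicative log-normal on areas),
10% left-censoring per sample, per-sample recoveries uniform in 0.7–0.9,
planted log2FC ±1.5 effects on 10% of analytes, per-class response
slopes of 2–6·10⁴ area units per concentration unit with small positive
intercepts, and a 6-level geometric dilution series bracketing the
nominal spike concentration. Decoys (odd-chain, out-of-bounds carbons,
wrong retention window; 2 per rule per class) give the filter true
positives; they are excluded from the planted-effect ground truth.
Effects at species level are composed so chain splits are even-carbon
except where a decoy deliberately is not.

What it does not emulate: adduct multiplicity and in-source
fragmentation (duplicates are tested with constructed fixtures instead),
chromatographic drift, matrix effects beyond a per-sample scalar,
between-class response nonlinearity, isotope patterns, and
missing-at-random mechanisms. Passing tests therefore demonstrate
correctness of the computational pipeline under a clean, known
generative model — not robustness to every artifact of real instrument
data.

Two auxiliary simulators serve the statistical-stage calibration
studies. `simulate_log2_experiment` produces log2-scale matrices
directly (base + effect + batch + Gaussian noise) for type-I-error,
false-discovery and batch-algebra studies, where the measurement layer
would add run time without changing the quantity under study.
`simulate_annotation` produces balanced annotation frames for
enrichment-calibration studies. The enrichment-null study uses a 20,000-
lipid balanced annotation: the hypergeometric p-value is discrete, and
at realistic lipidome sizes (hundreds of lipids) its atoms are coarse
enough that a Kolmogorov–Smirnov comparison against the continuous
uniform rejects on discreteness alone; at this size the support is fine
enough for the continuous comparison to be meaningful. The study draws a
fixed half of lipids as "significant" per permutation, which makes the
conditional hypergeometric null exact.

Problem sizes in the validation suite (500 lipids × 12 samples × 100
null simulations; 50 spiked simulations; 200 permutations; a 300-lipid
end-to-end study) were chosen as the smallest sizes at which the
binomial/KS tolerances of the checks are informative.

## Numerical choices

* OLS via `scipy.stats.linregress` (calibration) and pinv-based batch
  solves (differential); contrast SEs from `c (XᵀX)⁻¹ cᵀ`.
* Trigamma inverse: Newton iteration from the asymptotic starting point
  `0.5 + 1/x`, 50-iteration cap, relative tolerance 1e-10.
* kNN imputation ties (equidistant samples) resolve by sample order.
* PCA sign fixing: per component, flip so the largest-|loading| entry is
  positive.
* Degenerate inputs error early with the offending entity named: empty
  experiments, single-level factors, inverted reference bounds,
  sub-2-level calibration series, all-missing lipids.

## Known limitations

Designs are fixed-effect factorial with a single batch covariate; no
random effects, duplicate-correlation or time-course modelling. Only the
`MS_METABOLITE_DATA` named range of mwTab is read. Raw-spectra
processing (mzML, peak picking, alignment) is upstream of this package's
scope. Per-lipid (rather than per-class) response factors and
isotope-dilution corrections are not modelled.
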