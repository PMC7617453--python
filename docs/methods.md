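# Methods

This note records the models, conventions and design choices behind
`xenotrace`, in the spirit of a package vignette: what is computed, under
which assumptions, and what the synthetic benchmarks do and do not show.

## In-silico digestion and species-unique libraries

Trypsin is modeled as cleaving C-terminal to K or R except before proline
(`rule="trypsin"`; `"trypsin/p"` drops the proline restriction, matching
the two conventions search engines offer). Peptides with up to
`max_missed` (default 2) missed cleavages are enumerated as concatenations
of adjacent fully-cleaved fragments; monoisotopic masses are residue sums
plus one water, using pyteomics' residue table.

Isoleucine and leucine are indistinguishable by mass, so every uniqueness
decision and every evidence match operates on an I/L-collapsed key (both
mapped to `J`); original sequences are retained for reporting. Species
uniqueness is evaluated over the union of all missed-cleavage variants of
**both** proteomes, so a peptide unique at 0 missed cleavages cannot
collide with a missed-cleavage peptide of the other species.

A peptide is *observable* when its length is within 7–30 residues and its
monoisotopic mass within 700–4,600 Da — a common working definition of the
tryptic peptides an MS run can actually see; both windows are
configurable. iBAQ denominators (and the expected count of the
observed/expected ratio) use **0-missed observable** peptides only, the
standard iBAQ convention; counting missed-cleavage variants is available
but not default. Library content is necessarily proteome-release
dependent; the library export embeds its construction parameters for that
reason.

Residues outside the 20-letter alphabet are rejected with their position by
default; the `skip-peptide` policy instead drops the affected peptides,
which is the right behavior for databases containing B/Z/X placeholders.

## Species assignment, parsimony, iBAQ, enrichment

Observed peptides are aggregated (intensities summed across samples — the
label-free analysis pools measurements), I/L-collapsed and labeled
unique-to-A / unique-to-B / shared / unmatched. Protein groups are formed
by greedy set cover over the observed peptide sets (deterministic
tie-break: coverage, then accession), with proteins whose observed set is
contained in the lead's grouped under it — the classical parsimony
heuristic; on small instances it is verified against exhaustive minimal
cover. Groups with fewer than `min_peptides` (default 2, the common
two-peptide identification rule) distinct peptides are dropped.

A group is **host-exclusive** when all of its distinct observed peptides
are unique to the host library (strict mode; a relaxed mode requires ≥ 1
host-unique and 0 graft-unique). Host-exclusive groups are the candidate
microenvironment-transferred set: a pure sorted graft population has no
other reason to yield host-unique peptides. Each peptide's intensity is
credited to exactly one parsimony group (selection order; razor-style
splitting is deliberately not performed).

iBAQ = assigned intensity sum / observable peptide count; ppm normalizes
over quantifiable groups to 10⁶ (groups with zero observable peptides are
flagged non-quantifiable and excluded); iBAQ score = log₁₀ ppm. The
enrichment rule flags proteins whose iBAQ score **and** observed/expected
ratio are strictly above their species-class arithmetic means, each class
on its own; classes with fewer than two quantifiable members leave the
flag undefined. A variant thresholding the *sum* of the two metrics
against the mean sum is available behind `rule="sum"`. Note the rule's
selectivity depends entirely on the joint distribution of the two metrics:
on real xenograft data, where coverage is sparse and abundance heavy-
tailed, it selects a few percent of a class; on the synthetic conditions
here (roughly symmetric metrics) it selects closer to half, which the
benchmarks therefore do not treat as a recovery metric.

## Differential labeling (spectral counts)

Counts are normalized by scaling each sample column to the mean raw column
total — the closest published equivalent of "normalized spectrum counts"
from vendor software, and idempotent. NA values are treated as zeros at
load time; zeros are non-detections and become missing on the log2 scale.
Missing entries are imputed per sample from
Normal(mean − 1.8·sd, (0.3·sd)²) over that sample's observed values — the
conventional left-censored assumption — with a mandatory seed.

The moderated t-test follows the empirical-Bayes scheme of the limma
family: per-protein residual variances are modeled as scaled inverse-χ²
draws; the prior (d₀, s₀²) is fitted by method of moments on log variances
(digamma/trigamma matching, with a Newton trigamma inverse); posterior
variances s̃² = (d₀s₀² + d s²)/(d₀+d) give t on d+d₀ df. When the observed
log-variances are *under*-dispersed relative to χ² the prior df is
infinite (full shrinkage, normal reference); a degenerate fit falls back
to the ordinary t and is flagged. The implementation is cross-checked
against R/limma `eBayes` on a fixed matrix in the test suite (agreement of
coefficients, prior df, prior variance, t and p). BH q-values come from
statsmodels. Contrast sign convention: first-named group minus second.

Zq is implemented as a robust standardization of log2-ratios,
(x − median)/(1.4826·MAD) — units of standard deviation. The full WSPP
hierarchical weighting is **not** implemented; outputs are labeled
"Zq-style" accordingly.

Calibration caveat: on the negative-binomial benchmark (3 vs 3 samples)
the pooled type-I error sits near 0.048 rather than exactly 0.05 — the
mild conservatism of a t-approximation on log counts at n = 3, shared by
the reference implementations; rows containing imputed values are locally
anticonservative but rare at the default abundance settings.

## Transcript features and ORA

GC content excludes N from the denominator and treats U as T. The
between-set comparison uses Welch's unequal-variance two-tailed t-test
(the robust default when variances are not known to be equal). ORA is the
hypergeometric upper tail P[X ≥ k] per term with BH across terms;
annotation is a user-supplied two-column term→gene file, so results do not
depend on a bundled database version. Fold enrichment is (k/n)/(K/N).

## Spatial niche proximity

Analysis is 2-D (section images); coordinates are in μm with an arbitrary
origin, and no edge correction is applied (a documented limitation —
distances near the field border are biased upward for query and background
alike, which the matched-background design largely cancels). Query and
background cells are each measured by Euclidean nearest-neighbour distance
to the reference class (k-d tree, verified against the all-pairs minimum);
the background is subsampled without replacement to the query count,
seeded, so the two ECDFs are size-matched.

The KS statistic is the ECDF supremum; p-values are reported both from the
asymptotic KS distribution and from seeded label permutations,
p = (1 + #{stat\* ≥ stat})/(n_perm + 1). The Anderson–Darling statistic is
the two-sample midrank version normalized by its null standard deviation
(the same normalization scipy reports; agreement is tested), also with a
permutation p — the two-sample reading is the one that matches a
query-vs-background comparison design. Permutation p-values are preferred
for calibration statements: the KS null distribution is discrete at
moderate n, so tail-based p-values are conservative, while the permutation
level is exact up to tie-induced discreteness.

## Synthetic data

The generators emulate, at desk scale, the structure of a PDX label-free
experiment: a graft proteome and a host proteome with 1,900 conserved
ortholog pairs (iid substitutions at rate 0.15 per residue — approximately
the human–mouse protein divergence — no indels, so ortholog tryptic maps
stay comparable) plus 120 species-specific proteins per side, sequence
composition from an empirical amino-acid frequency table, lengths
log-normal around 330 residues. In the simulated run all graft proteins
are present with log-normal abundances (σ = 1 natural-log unit); 8 host
proteins are planted at 8× the median graft abundance (the transferred
set) and the remaining host proteins are absent, as expected for a pure
sorted graft population. Each observable 0-missed peptide is detected with
probability logistic in log₁₀ abundance (slope 2 per decade, midpoint 0.3
in median-abundance units), and detected peptides carry intensity =
protein abundance × log-normal noise (CV 0.3), so that with full detection
and no noise iBAQ equals true abundance exactly; shared peptides are
emitted once with summed contributions.

Count matrices are negative-binomial (dispersion size 8) around log-normal
per-protein means (median 30, σ = 1), two groups of three samples, with a
configurable fraction of proteins carrying a log2 shift in group B;
missingness arises naturally from zero counts at low abundance. Point
patterns place reference and background cells uniformly (CSR) in a
1000 × 1000 μm field; attracted query cells are rejection-sampled with
acceptance exp(−d/λ) toward the nearest reference, λ = 25 μm by default.

Every generator is a pure function of its configuration including the
seed; byte-identical reruns are part of the test suite. What passing
benchmarks on these generators shows is that the *pipeline logic* is sound
— species calls trace to true origins, planted signals are recovered at
the configured effect sizes, null calibrations hold. What they cannot
show: robustness to real ortholog structure (domain-level conservation,
indels, paralogs), PTMs, chimeric spectra, or search-engine FDR behavior,
all of which live upstream of this pipeline's peptide-level inputs.

## Benchmark problem sizes

The test suite runs the end-to-end recovery at full PDX scale over 20
evidence seeds (plus 20 zero-transfer controls) on one library build; the
differential calibration at 50 × 1,000-protein null runs and 20 spiked
runs; the spatial calibration at 1,000 CSR fields (199–499 permutations
each) and power at 100 attracted fields. `scripts/acceptance.py` uses the
same conditions with 30 null and 15 spiked differential runs and 300 CSR
fields, completing in a few minutes on one CPU.

## Known limitations

- Parsimony grouping is the greedy heuristic; adversarial instances exist
  where it exceeds the true minimal cover (not observed under the
  generators or in typical nested/subset protein-inference structure).
- The enrichment rule ("both metrics above class means") is a faithful
  implementation of a crude published rule, not a calibrated test; treat
  its output as a ranking heuristic.
- Zq-style standardization is not the full WSPP model.
- The asymptotic KS p is conservative at small n; use the permutation p.
- No PSM-level probabilities, no isobaric-label quantification, no
  spectrum simulation, no 3-D tissue geometry.
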