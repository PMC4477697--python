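# Methods

`protasm` re-implements the identification post-processing layer of a large
multi-engine shotgun-proteomics study: target-decoy FDR control, parsimony
protein/gene assembly with a two-step stringent/rescue strategy,
spectral-count quantification with a pairwise signature evaluation,
identification-free LC-MS/MS quality control, and variant-peptide vetting.
This note records the models, the defaults and why, the numerical choices,
and what the synthetic fixtures do and do not demonstrate.

## Target-decoy FDR and q-values

Search engines score every spectrum against target sequences and their
reversed ("decoy") counterparts. Under the equal-chance assumption — a false
match is as likely to hit a decoy as a target — each decoy match betrays one
false target match, so the false-discovery proportion of an accepted set is
estimated as

    FDR = 2 · D / (T + D)

clipped to [0, 1], where T and D are accepted target and decoy counts. An
accepted set whose matches are 1% reversed decoys therefore carries a 2%
PSM FDR. A record's q-value is the smallest such FDR over all score
thresholds that accept it; ties on score enter the accepted set together,
and a reverse running minimum enforces monotonicity. The convention is
isolated in `protasm.fdr` so a D/T variant (appropriate for separate decoy
searches) can be swapped in.

Calibration: on simulations where ground truth is known per PSM, the pooled
estimate at a 2% threshold tracks the true false-match proportion of the
accepted set within binomial noise (200 seeds; see the acceptance suite).
The estimator inherits the generator's symmetric construction — random
matches draw uniformly from the combined target+decoy peptide space — which
is exactly the assumption the doubling relies on.

## Multi-engine combination

Engines score on incommensurable scales, so each engine's scores are first
converted to per-engine q-values; for a spectrum identified by several
engines the record with the lowest q-value is kept (ties: higher raw score,
then engine name), and engine-specific spectra pass through unchanged — an
inclusive union. Merged-set q-values are then recomputed ordering records by
their per-engine q. The tie-break and the q-value scale are conventions
chosen here; the combination rule itself (best scoring record, inclusive
union) is standard.

## Parsimony assembly

Accepted PSMs define observed peptides (distinct bare sequences;
modification states collapse for the "distinct peptides" rule — the
conservative reading). Proteins indiscernible on the observed peptides merge
into one group; a minimal set of groups covering all observed peptides is
selected greedily (largest remaining coverage first; ties: larger spectral
count, then smallest member accession), followed by a redundancy-elimination
pass so that removing any selected group would orphan at least one peptide.
Groups failing the distinct-peptide or spectral-count minima are dropped
together with the peptides only they explained. The protein-group
representative is the lexicographically smallest accession — a deterministic
replacement for an arbitrary choice. At gene level, accessions collapse to
genes first; a gene's length is its longest isoform, and the member with the
shortest such length represents the group (Occam's razor).

Greedy set cover is not optimal on adversarial dense incidence structures
(counterexamples need peptides shared across many unrelated proteins in a
specific pattern). On protein-inference-shaped instances — proteins carrying
unique peptides plus a minority of shared ones, the structure real evidence
and the generator produce — greedy plus pruning matched an exhaustive
minimum-cover search on all tested random instances with up to 12 proteins.

Group-level FDR applies the same doubling over groups, a group counting as
decoy when any member is a decoy; mixed target/decoy groups (possible only
if a reversed peptide collides with a target peptide) are surfaced in
diagnostics rather than silently absorbed.

## Two-step stringent/rescue strategy

In very large assemblies, PSM-level FDR control plus the two-peptide rule no
longer bounds the protein-level FDR: false PSMs accumulate across samples
onto otherwise unsupported proteins, and raising a per-protein
spectral-count minimum discards genuine low-abundance proteins. The two-step
procedure assembles first at a very stringent PSM threshold (default 0.1%
q-value), which fixes the group inventory and its FDR, then re-admits PSMs
at a relaxed threshold (default 1%) only when at least one mapped protein
(gene, at gene level) belongs to an inventory group. Mappings to
non-inventory proteins are pruned; rescued PSMs update inventory spectral
counts but can never add or resurrect a group, so the group set — and with
it the group FDR — is invariant by construction. The "median PSM FDR" of the
rescued set is reported as the median q-value of rescued PSMs (the
alternative set-level reading is also computable from the report).

The tradeoff sweep reproduces the motivating phenomenon: at a fixed
group-FDR cap, the spectral-count minimum required grows with the PSM FDR
threshold, and the stringent setting yields at least as many target groups
as a conventional 2% pass. The effect needs the regime that created it —
many samples, heavy-tailed protein abundance (lognormal sigma 2), decent
engine score separation — and disappears at small scale. With shared
peptides present, an absent protein can inherit the spectral count of an
abundant homolog, something its decoy cannot mirror, which makes the
group-level doubling anti-conservative in the sweep; the property is
therefore demonstrated on maps without shared peptides.

## Spectral-count quantification and signature evaluation

Counts are tallied per non-decoy group and sample; a PSM whose peptide maps
to several retained groups counts once in each (inclusive counting).
Duplicate samples resolve to the column with the larger total (ties:
lexicographically first). The minimum-average filter keeps features with
total count at least ceil(average × n_samples) — 45 counts for a 1.4 average
over 32 samples.

Group comparison is a quasi-Poisson rate test: a two-group log-linear model
for counts with log sample totals as offsets, Pearson-X² dispersion, Wald
statistic on the log rate ratio, and a t reference with n−2 degrees of
freedom. The implementation is closed-form and vectorized across features;
it reproduces `statsmodels` GLM (Poisson family, scale='X2') to machine
precision, which the suite checks feature by feature so the two routes stay
independent. Fold changes use a 0.5 pseudocount on group sums.
Benjamini–Hochberg correction runs across features. The signature is the
set of features at or beyond the fold-change criterion in either direction
and below the FDR ceiling.

Pairwise evaluation asks whether the signature stands out when only one
sample per group is available. For each cross-group sample pair, every
feature gets a total-count-normalized, pseudocounted log ratio. Signature
features, oriented by their expected direction, are the positives; the
comparison population enters each non-signature feature under *both*
orientations, making it symmetric by construction, so the Mann–Whitney AUC
is exactly 0.5 in expectation under exchangeability and approaches 1.0 under
perfect separation — the two limits that anchor this construction, since the
original description leaves the ROC population ambiguous.

## Identification-free quality control

Each run is a vector of instrument metrics (44 by default). Columns with
insufficient variation are excluded first: a column is dropped when its MAD
falls strictly below `rel_floor` times the magnitude of its median (a robust
coefficient of variation; exactly-constant columns drop at any positive
floor), alongside a configurable name-pattern list for fields known to be
uninformative. Robust PCA is median centering and MAD scaling followed by a
classical eigendecomposition; a minimum-covariance-determinant mode is
available, and plain mean/no-scaling PCA is kept for rotation-invariance
checks. Components retained: the smallest number explaining 60% of
variance, capped at 5.

Two per-run statistics are reported. The normalized Euclidean distance
standardizes scores per component and takes each run's median distance to
the other fractions of the same sample — large values point at discordant
runs or unstable samples. The T² statistic is the squared Mahalanobis
distance of the run's scores from a center and covariance pooled across all
runs (reweighted MCD by default; per-sample covariances would be unstable at
15 runs per sample), referred to a χ² with as many degrees of freedom as
retained components; runs with p below α (default 0.01) are flagged. Under a
clean Gaussian null the classical-covariance mode sits at the nominal 1%
flag rate; the MCD mode is slightly anti-null at small run counts
(~1.7% at 200 runs) and calibrates at larger tables (~1% at 1,425 runs), so
the calibration test runs at the study layout.

Identification yields (spectra, peptides, groups per run) decompose by
two-way ANOVA without interaction on a complete sample × fraction layout;
sum-of-squares shares for sample, fraction and residual sum to one exactly.
Reference-sample run acceptance applies three strict bounds: more than
5,000 identified spectra, third-quartile MS2 density above 200, and more
than 40% of identified spectra at charge 2. Instrument-standard (BSA)
thresholds — 10 ppm mass drift, 1e7 intensity, 65% coverage — are recorded
as configuration constants only.

## Variant-peptide vetting

RNA-seq variant calls are filtered with inclusive bounds: SNP quality ≥ 20,
mapping quality ≥ 20, read depth ≥ 3, and for indels gapped reads ≥ 3.
Observed single-amino-acid variants classify by annotation source with the
precedence somatic > COSMIC > dbSNP > novel (mutually exclusive and
exhaustive); lookup keys are protein-level (gene, position, reference
residue, variant residue) to stay independent of genome builds. Isobar
screening digests the reference proteome in silico (cleave after K/R except
before P, up to two missed cleavages, length 6–40 — conventional,
configurable) and indexes peptides by their I→L-collapsed sequence: a
variant peptide that equals a reference peptide after the collapse has
identical mass and is flagged MS-indistinguishable, with the variant's own
source peptide excluded from its matches.

## Synthetic fixtures

The generators produce every input the tests use, with ground truth:

- **PSM streams** over a known peptide–protein map. True proteins emit
  correct identifications (Gumbel scores, location 4, scale 1 by default);
  random matches draw uniformly from the combined target+decoy peptide space
  (Gaussian scores, location 0) so decoy and false-target matches are
  equally frequent — the doubling estimator's assumption, verified as a
  property. Decoys are reversed target peptides under the `XXX_` prefix,
  mirroring every target. Per-protein abundance is lognormal (sigma 1.0 by
  default), shared peptides are planted explicitly (10%) so parsimony is
  non-trivial, and each spectrum is observed by each engine with probability
  0.8. The structural defaults mirror the emulated study layout (95 samples
  × 15 fractions × 3 engines = 4,275 result units); tests pass explicit
  smaller configurations, stated in each test.
- **QC tables**: a rank-3 latent structure plus noise, arbitrary per-column
  units, contiguous sample blocks as batches with optional mean drift, four
  exactly constant columns, and injected outliers shifted by a configured
  number of SDs on a random third of the metrics.
- **Count matrices**: negative-binomial counts (gamma–Poisson, dispersion
  0.05) around lognormal baselines with lognormal size factors; signature
  features carry a planted between-group ratio split symmetrically across
  the two groups, alternating direction. Group sizes default to 16 + 16 and
  the planted ratio to the 32-fold criterion.

What passing tests show — and what they do not: the fixtures exercise the
estimators' assumptions by construction (symmetric decoys, quasi-Poisson
counts, Gaussian metric noise). Real data violate them in ways the suite
cannot detect: engine score distributions are neither Gumbel nor
comparable, decoy symmetry is only approximate for modified peptides,
spectral counts saturate for abundant proteins, and QC metrics drift
continuously rather than by batch means. Results on synthetic data certify
the implementation, not the biology.

## Problem sizes and determinism

Simulation-backed properties run at desk scale, chosen so the full suite
completes in a few minutes on one CPU: calibration loops use 50–200 seeds of
small configurations (tens of proteins, 2–4 samples), the QC null
calibration uses 200 tables at the 95×15 layout, and the tradeoff property
uses 12 fifty-sample datasets. Every stochastic component takes an explicit
integer seed through `numpy.random.default_rng`; a fixed seed reproduces
byte-identical outputs, which the suite asserts.

## Known limitations

- Decoy handling assumes concatenated target–decoy searches with reversed
  sequences; separate-search conventions need the D/T estimator variant.
- The sweep applies spectral-count minima to groups assembled once per
  threshold rather than re-running parsimony per minimum.
- Gene-level rescue prunes at the gene level, so a rescued PSM's protein
  list may retain non-inventory isoforms of an inventory gene.
- The pairwise AUC construction is one defensible reading of an ambiguous
  description; the two-limit behavior (0.5 null, 1.0 perfect) is its
  anchor, not a claim of equivalence to the original analysis.
- mzIdentML/pepXML readers cover only the elements needed to populate PSM
  records and are conveniences, not schema-complete parsers.
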