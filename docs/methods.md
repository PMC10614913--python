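# Methods

## Turnover model

Each protein pool is modeled as a single compartment with first-order
turnover: the fraction of the pool synthesised before the chase (hence
¹⁵N-labeled) that survives t months is e^(−kt), so the fractional abundance
is FA(t) = 100·e^(−kt). No multi-compartment kinetics, re-incorporation of
liberated ¹⁵N, or growth dilution is modeled; a single pool is the simplest
model that produces both long-term label retention and the continued slow
decline between a 6- and a 10-month chase.

The synthetic proteome draws per-protein half-lives from a two-component
log-normal mixture:

| parameter | default | rationale |
| --- | --- | --- |
| fast median half-life | 0.1 month (≈3 days) | typical somatic protein turnover |
| slow (long-lived) median half-life | 12 months | pools that survive a 6-month chase with FA of tens of percent |
| log-sd of both components | 0.7 | broad, realistic spread without mixing the components |
| long-lived mixture weight | 0.15 | a minority long-lived class |
| initial ¹⁵N enrichment | 0.95 | two-generation in-vivo labeling is near-complete but imperfect, and the 0.9 APE gate must be exercisable from both sides |
| chase timepoints | 6 and 10 months | the study design being emulated |

The long-lived ground-truth flag is slow-component membership. With these
defaults the components are cleanly separated at 6 months (fast: FA ≈ 0;
slow: FA ≈ 10–95%), so calling errors reflect the pipeline, not an ambiguous
truth.

## Isotopologue envelopes

Envelopes are aggregated isotopic distributions computed by exact
convolution of per-element isotope distributions (binary exponentiation over
atom counts), with nitrogen's ¹⁵N probability replaced by the enrichment
parameter. Peaks are indexed by total neutron shift and carry the summed
probability and the probability-weighted centroid mass offset. Truncation
keeps the smallest most-probable peak set retaining ≥ 0.999 probability;
this bounds the m/z window set for XIC extraction. Atomic masses and natural
abundances are the AME2020 / IUPAC-CIAAW values hard-coded in
`isopulse.constants`; the chemistry uses the 0.00364 natural ¹⁵N abundance
while the MIMS display baseline is the separately configurable 0.37%
imaging convention.

A brute-force oracle (exhaustive multinomial enumeration of per-element
isotope assignments) validates the convolution to 1e-9 per peak for all
peptides of length ≤ 4 over {G, A, S} at enrichments from natural abundance
to full labeling.

## Synthetic MS1 runs

Each selected tryptic peptide (≥ 6 residues, ≥ 6 nitrogens, up to 5 per
protein) elutes as a Gaussian of 0.2 min FWHM at a uniform-random retention
time in a 75-minute run sampled every 2 s. The light envelope (natural
abundance) carries a fraction 1 − FA/100 of the peptide's total area, the
heavy envelope (at the initial enrichment) FA/100; total areas are
log-normal (σ = 0.5) around 10⁶. Noise is multiplicative log-normal
(σ = 0.1) per centroid plus an additive baseline at 0.5% of the run's
maximum signal intensity, both applied to every emitted centroid. The
generator emulates centroided MS1 only: no MS2, no chimeric interference,
no retention-time drift, no detector saturation. Passing tests therefore
demonstrate correctness of the quantification arithmetic and filter logic
under calibrated noise, not robustness to every artifact of real
acquisitions.

## Quantification

* **Extraction** — per-isotopologue XICs in ±30 ppm windows around the top
  3 light and top 9 heavy isotopologues (heavy envelope computed at the
  configured initial enrichment, default 0.95), charge from the
  identification table. Summed channel traces are divided by the summed
  theoretical probability of the extracted peaks (capture-fraction
  correction) so AR estimates the full pool ratio.
* **Baseline** — per trace, the median of the lowest-decile *detected*
  (positive) intensities, subtracted before integration and regression;
  zeros are treated as missing centroids, not measurements.
* **AR and r** — least-squares slope of heavy on light through the origin
  over scans where both channels exceed twice their baseline, and the
  Pearson correlation of those paired intensities. At least 5 co-eluting
  points are required; otherwise the peptide is routed to singleton
  analysis. The through-origin slope is not exactly reciprocal under
  channel swap when noise is present; a geometric-mean-regression estimator
  (`estimator="gmr"`) is exposed for exactly symmetric behaviour.
* **APE** — the enrichment in [0.0037, 1] whose theoretical envelope
  maximises cosine similarity with the observed heavy isotopologue areas;
  grid step 0.001 with endpoints and step multiples on the grid. Only the
  nitrogen binomial depends on the candidate enrichment, so the
  nitrogen-free sub-envelope is convolved once.
* **Profile score** — Pearson correlation of observed vs theoretical heavy
  envelope intensities clipped to [0, 1]; a constant observation scores 0
  and is flagged. The score and the singleton "threshold score" (cosine
  similarity of the dominant channel's envelope to theory) are
  quantifier-internal metrics defined here; their gate values (0.8, 0.5)
  follow the established filter convention.
* **Singletons** — peptides with fewer than 5 co-eluting points are
  singletons when the dominant/minor integrated area ratio exceeds 5.0 and
  accepted when the envelope score exceeds 0.5. The ratio gate applies to
  the dominant channel whichever it is (a configuration switch restricts it
  to ¹⁴N-dominant only); heavy-dominant singletons carry AR = ∞ (FA 100),
  light-dominant AR = 0.

## Filter cascade and LLP calls

Heavy evidence requires, for regression peptides, r > 0.5 AND APE ≥ 0.9 AND
profile ≥ 0.8; for singletons, the ratio and score gates plus heavy
dominance. Every rejection records the first failing gate. A protein is
long-lived with ≥ 3 passing heavy peptides in tissue mode (the stricter
literal reading "more than three", i.e. ≥ 4, is a configuration away) or
≥ 1 in GeLC/MS mode. Protein FA is the unweighted mean of peptide FAs with
SD (area-weighted mean optional); peptide-level and protein-level summaries
are both emitted where aggregation order matters. Proteins are grouped by
identifier only — no parsimony/razor inference.

## MIMS quantification

Ratio images divide ¹⁵N by ¹⁴N counts per pixel; pixels with fewer than 20
¹⁴N counts (configurable — "low ion counts" has no canonical number) are
masked invalid and excluded from every statistic. Percent above background
is 100·(R/R₀ − 1) with R₀ = 0.37% by default. HSI rendering maps the
clamped percent linearly from blue to magenta with brightness scaled by
total counts; rendering never feeds back into statistics. Mosaics abut
tiles without inter-tile normalization; an optional per-tile attenuation
mask emulates the peripheral yield loss of real fields. Nuclei are
segmented from the median-filtered ³¹P channel by Otsu threshold and a
minimum-area filter. The nuclear/cytoplasmic statistic is the ratio of
ROI-mean ratios (robust to per-pixel division noise; the pixel-wise
alternative is a configuration choice), compared to the hypothetical value
1 by a one-sample t-test. Group tests run on mean ratios R with percent
values reported alongside.

The Poisson image generator draws ¹⁴N counts at a uniform dose (default
10⁴ per pixel) and ¹⁵N at dose × ratio; it does not model detector dead
time, sub-pixel drift, or the edge-yield gradient unless the attenuation
mask is applied.

## Statistics

Two groups: Student's t-test by default (Welch optional). More than two:
one-way ANOVA. Ratio-of-means vs 1: one-sample t-test. Non-parametric
multi-group: Kruskal–Wallis; the post-hoc default is Dunn's rank test with
Holm adjustment, because pairing Kruskal–Wallis with Tukey's HSD is
statistically unconventional — Tukey-on-ranks is nevertheless available to
mirror that convention. Dispersion is SEM; stars are * p<.05, ** p<.01,
*** p<.001. Type-I error of every test is verified at α = 0.05 within
[0.03, 0.07] over 2000 null simulations. FA clustering uses Euclidean
distance and average linkage (unspecified in the source conventions; the
choice is recorded in the result object), with row-mean imputation of
missing entries.

## Numerical choices and degenerate inputs

* Envelope probabilities below 1e-15 are dropped before truncation.
* Empty extraction windows return empty traces with a warning; all-zero
  observations make APE undefined and flag the record.
* Zero-variance groups: ANOVA on identical constants reports F = 0 with a
  warning; a one-sample test at the hypothesised mean reports p = 1.
* All generators are deterministic given (config, seed); the acceptance
  script derives independent sub-seeds below 2³¹ from one master seed.

## Problem sizes

FA-recovery error is measured over the records the pipeline actually
reports: valid quantifications surviving the correlation gate. Co-eluting
peptides occasionally share an m/z window (a light monoisotopic peak landing
in another peptide's heavy window); the resulting distorted ratios carry low
or negative correlation and are exactly what the r > 0.5 filter removes.

The validation experiments use 100-peptide runs for FA recovery, 200
proteins (≈1000 peptides) for LLP operating characteristics, 3600-pixel
regions at dose 10⁴ for MIMS recovery, 20 cells for the nuclear test and
2000 simulations for calibration — sizes at which the Monte-Carlo error of
each check is comfortably below its acceptance band.

## Known limitations

* The quantifier assumes the identification table's retention times and
  charges are correct; no RT alignment or charge-state reconciliation.
* Heavy-envelope extraction assumes the configured initial enrichment; a
  grossly mislabeled pool (true enrichment far from 0.95) would be
  under-captured, which real two-search workflows share.
* FA = 100 exactly for heavy-only singletons; the true value is merely
  > ~83% (the singleton ratio gate), so protein FA means that include
  singletons are biased high — as in the emulated workflow.
* The light/heavy m/z windows of very short, low-nitrogen peptides at high
  charge could in principle overlap; the digest's six-nitrogen minimum for
  synthesised peptides keeps the envelopes disjoint.
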