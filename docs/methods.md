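# Methods

`placentometry` quantifies growth of the mouse placenta from histological
sections: how much of it there is (stereology), how its cells divide or
endoreduplicate (cytometry), how large its cell populations are
(morphometry), and how fetal/placental biometry responds to maternal diet
and fetal sex (cohort statistics). Every estimator is exercised against a
bundled synthetic-data generator with exact ground truth, so the package is
fully testable without any image downloads.

## Stereology

**Composition (Delesse principle).** A rows×cols point grid (default
10×10) is laid over a labelled section field with spacing
`floor(dim/rows)` per axis and a single uniform-random integer translation
in `[0, spacing)` — systematic uniform random sampling, one translation
per field rather than per point. Each point takes the compartment code of
its containing pixel (pixel-centre convention; points on a label boundary
are therefore deterministic and need no tie-break table). Points from all
fields of a conceptus are pooled (the design is 4 fields × 3 sections);
each compartment fraction p gets a binomial standard error
`sqrt(p(1−p)/n)`. When the grid divides the field evenly the estimator is
exactly unbiased under offset enumeration; the test suite checks
unbiasedness to < 0.3 percentage points over 500 random offsets.

**Volume (Cavalieri principle).** Sections are systematically subsampled
(every k-th section from a random start in `[0, k)`), and volume is
`Σ section areas × thickness × k`, reported in mm³. The estimate is exact
for constant-area stacks at k = 1 and is accurate to a few percent for
smooth (parabolic) area profiles at k = 4 with ~10 kept sections.

**Nuclei number.** The study's counting estimator is not fully specified;
this package uses 2-D profile counting with the Abercrombie correction as
a documented stand-in: a nucleus of mean diameter D intersects a section
slab of thickness T with probability proportional to T + D, so the total
is `Σ profiles × V_ref / (Σ areas × (T + D))`. A physical disector is not
implemented because paired disector sections are not part of the design.
D comes from configuration; shrinkage corrections are not applied.

## Cytometry

**Labelling index.** Fraction of K18-positive (trophoblast) nuclei
positive for Ki67 (expressed through G1/S — all cycling cells) or
phospho-histone H3 (late G2/M only). Marker-positive cells without K18 are
endothelium/pericytes/blood and are excluded from numerator and
denominator.

**Cycle length.** `t_total = Ki67 fraction × t_G2M / pHH3 fraction`, with
the G2/M duration defaulting to 0.8 h (typical for mammalian cells). The
formula is implemented literally on fractions in [0, 1]; the CLI accepts
percentages and divides by 100. The ratio is scale-invariant in the two
fractions, and a zero pHH3 fraction yields an undefined (None) estimate
rather than an exception. Doubling time from counts is
`Td = Δt / log2(n1/n0)`, signed (negative for shrinking populations,
infinite for unchanged counts).

**DNA content.** Corrected total nuclear fluorescence is
`CTNF = integrated density − area_px × mean background`; negative values
are clipped to zero with a warning. Mean background is estimated per image
as the median intensity outside all nuclear masks (robust to stray bright
pixels; the study does not state its background procedure, so the median
is this package's documented default, configurable in principle to a
per-nucleus annulus). Ploidy is `2 × CTNF / mean(reference CTNF)` with the
reference being ≥ 10 amniotic epithelial nuclei (diploid, 2C) from the
same slide — per-slide normalisation is enforced, and it makes the
estimate invariant under any global intensity rescaling of the slide. The
reference population's own mean assigned ploidy is exactly 2C by
construction. Ploidy values are reported continuous, not snapped to powers
of two: trophoblast giant cells under- and over-replicate parts of their
genome, so population means like 11.2C are meaningful. Spongiotrophoblast
nuclei are identified by the 80–200 μm² nuclear-area gate that separates
them from glycogen trophoblast.

## Morphometry

Expression area is the pixel census of a binary mask (the stand-in for a
manually traced mRNA-positive region) times pixel area, in mm². Cell
counting thresholds the DAPI channel (Otsu by default; fixed threshold
available), labels connected components (8-connectivity by default,
matching common particle-analysis practice) and keeps components whose
area lies in the half-open gate `[min, max)` μm² — a particle of exactly
`max` is excluded, which is documented and tested. Touching-nuclei
splitting is off by default (the emulated macro does not split); an
optional watershed flag exists. Mean cell size is total area / count, and
is reported missing rather than raising when the count is zero. The
labelling path is verified against a brute-force flood-fill oracle on
small images.

## Cohort statistics

**ANCOVA with backward elimination.** The full model for a weight response
contains the predictors (diet, sex, and placental weight for the fetal
response), all two-way interactions among them, and the covariates
maternal weight and litter size. All predictors are mean-centred before
fitting; centring changes no drop decision (interaction p-values are
invariant to affine shifts of the predictors, which the suite tests) but
makes main-effect coefficients interpretable at average predictor values.
Elimination removes one interaction per step — the largest p-value ≥ α
(0.05), ties broken by term name — and refits; main effects and covariates
are never removed. Rank-deficient designs raise an error naming the
aliased terms. Note that when the diet manipulation also drives maternal
weight (as severe protein restriction does), the diet coefficient
conditional on maternal weight answers a different question than the
marginal diet effect; the bootstrap below targets the marginal model.

**Bootstrap.** Where normality/homoscedasticity are doubtful, regression
coefficients (diet and sex as predictors) are bootstrapped by case
resampling stratified by litter, preserving the litter structure the
design controls for. Default 10 000 resamples. Each coefficient gets a
percentile 95% CI and the two-sided p-value
`2 × min(P(β* ≤ 0), P(β* ≥ 0))` — the centred-percentile construction of
"no difference between groups" (the alternative, permuting group labels,
is not used; this choice is the package's own). Resamples in which a
predictor collapses to one level are redrawn with a cap. The resampled
fits are solved as batched normal equations, so large resample counts are
cheap. Measured operating characteristics (2000 null replicates): the
test's size is 0.056 at 200 cases and 0.053 at 400 cases per dataset at
nominal α = 0.05, and percentile CI coverage for a known coefficient is
~0.94 at 60 cases; the calibration tests simulate 1000 null datasets of
400 cases each.

**ANOVA + Tukey.** Gestational-stage comparisons use one-way ANOVA
followed by Tukey's HSD; homogeneous groups are displayed as compact
letters computed from maximal cliques of the "not significantly
different" graph (brute force — group counts here are ≤ 12). A
Kruskal–Wallis wrapper covers the cases where ANOVA assumptions fail.

**ΔΔCt.** Per gene, `ΔCt = Ct_target − Ct_reference` (reference Hprt1),
`ΔΔCt = ΔCt − mean(ΔCt of controls)`, fold = `2^(−ΔΔCt)`. The control
group's geometric-mean fold is 1 by construction, and the estimate is
invariant to adding a constant to every Ct value. Amplification efficiency
is assumed 1.0 (probes verified near-perfect are not corrected); an
efficiency-corrected variant `(1+E)^(−ΔΔCt)` is available but not the
default. A natural-log `log1p` transform of the fold is emitted alongside
the untransformed values.

## Synthetic-data generator

The generator defines the study conditions the estimators are tested
under; its defaults are the measured values of the system:

- **Label fields** at the E13.5 control labyrinth composition (MBS 17.4%,
  S-TGC 4.0%, SynT 18.4%, FBS 14.7%, endothelium/pericytes 43.6%,
  unknown 1.9%). Pixel quotas are fixed by largest-remainder
  apportionment (realized fractions match targets to one pixel); spatial
  coherence comes from ranking Gaussian-smoothed noise per compartment.
- **Nuclei fields**: exact-pixel-count disks on a shuffled grid (never
  overlapping), true ploidy drawn from a truncated normal with a 2C floor
  (S-TGC default 8.20C ± 2.9, the E16.5 distribution; SpT 6.43C ± 3.0;
  the SpT standard deviation is this package's choice — the study prints
  SpT means without SDs — set between the two printed S-TGC SDs). Note
  the 2C floor shifts the realized mean slightly above the nominal
  parameter when the SD is large relative to the mean; recovery is always
  judged against the realized truth, which is recorded per nucleus.
  Amnion references carry exactly 2C. Total nuclear signal is
  `ploidy × intensity_per_C × lognormal noise` (mean-1, default CV 5% —
  the dominant noise in fluorescence integrals), spread uniformly over
  the nucleus, on a Gaussian-noisy uniform background. Marker flags are
  Bernoulli per cell type (chorion E8.5 defaults: Ki67 0.873, pHH3
  0.070). Nuclear areas per type: SpT in the 80–200 μm² gate, S-TGC
  250–450 μm², amnion 50–80 μm².
- **Section stacks**: parabolic area profile (zero at the poles) scaled so
  the discrete sum equals the requested volume; each section is rendered
  as an exact-count disk, so realized volume differs from the target only
  by per-section pixel rounding (≪ 1%). Defaults: 40 sections × 20 μm,
  subsampled at k = 4.
- **Cohorts**: fetal weight = 1.10 g − 0.10·I(LP) − 0.05·I(F) +
  0.6·(placental − mean) + litter intercept (SD 0.05 g) + noise
  (SD 0.08 g); placental weight 0.095 g with males +0.007 g and LP
  −0.008 g; maternal weight 25 g, 30% lower under LP. Litters alternate
  diet; litter sizes vary ±2 pups so litter size is usable as a
  covariate.

What the generator does **not** emulate: optics (PSF, vignetting, depth
attenuation), chromatin texture, touching/overlapping nuclei,
segmentation error in the "manual" traces, spatially correlated staining
variation, or non-balanced designs. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated noise model,
not robustness to every artefact of real slides.

## Numerical choices and problem sizes

Fixed seeds make every generator byte-identical between runs; the pipeline
manifest hashes all outputs to assert this. Test and demo problem sizes
follow the study design where it states one (200 nuclei + 50 references
per ploidy recovery; 12 pooled 10×10 grids; stacks of 40 × 20 μm sections
sampled every 4th) and are otherwise chosen to keep Monte-Carlo error
well inside the tolerance being checked (500 offsets for grid
unbiasedness; 1000 null datasets for bootstrap size; 500 datasets × 2000
resamples for CI coverage).

## Known limitations

- The nuclei-number estimator is an Abercrombie-corrected profile count;
  absolute counts inherit its assumptions (spherical nuclei of known mean
  diameter, no lost caps, no shrinkage correction).
- The marker-ratio cycle length treats the Ki67 fraction literally as in
  the source formula; whether it should instead enter as a growth-fraction
  correction cannot be decided from the available description, and the
  printed ectoplacental-cone value (14.8 h) is not reproducible from the
  printed E8.5 marker fractions by any reading of the formula (they give
  ≈ 19.5 h).
- The percentile-bootstrap p-value is mildly anti-conservative at small
  n (size ≈ 0.056 at 200 cases); a studentized bootstrap would improve
  this but would no longer be the procedure being emulated.
- Compartment legends, gates and thresholds are configurable but validated
  only for the six-class labyrinth legend and the 80–200 μm² SpT gate used
  throughout.
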