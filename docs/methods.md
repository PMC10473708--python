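# Methods

## Exchange model and percent-exchange normalization

hdxkit works at the peptide-centroid level. In the EX2 regime each
backbone amide exchanges independently with observed rate
`k_obs = k_int / PF` (PF the protection factor), so the deuterium
occupancy of residue *i* after labeling time *t* in a buffer with
deuterium fraction `f_D` is `D_i(t) = f_D * (1 - exp(-k_i t))`. A
uniform back-exchange fraction `b` is lost between quench and
measurement, giving the peptide centroid

```
m_t = m_0 + 1.00628 * (1 - b) * sum_i D_i(t)
m_f = m_0 + 1.00628 * (1 - b) * max_uptake * f_D     (fully-deuterated control)
```

with 1.00628 Da the mass increment per retained deuteron. Percent
exchange `(m_t - m_0)/(m_f - m_0) * 100` then cancels both `f_D` and
`(1 - b)` — the property that makes FD-normalized differential analysis
insensitive to the exact back-exchange level, and which the test suite
asserts across `b ∈ {0, 0.25, 0.49}`.

Undeuterated peptide masses are monoisotopic values from pyteomics.

### Exchangeable-amide bookkeeping

`max_uptake = length - n_term_exclusion - (prolines at positions
n_term_exclusion+1 .. end)`. The default excludes one N-terminal
residue per peptide (its amide deuteron is lost during digestion and
chromatography far faster than the rest); `n_term_exclusion=2` is
available for laboratories using the stricter convention. Position 1 of
the whole construct and prolines never carry an exchangeable amide.
Coordinates are 1-based closed intervals; construct-to-full-protein
numbering is handled by a `residue_offset`.

## Replicate aggregation and repeatability

The design emulated and expected is nested: biological replicates
(independent protein preparations/labelings) each measured in technical
triplicate. Technical injections are averaged within each biological
replicate, biological means are averaged, and dispersion is the SD
across biological means with an n−1 denominator (`n_bio = 3` by
default). For balanced designs the nested mean equals the flat mean; the
SDs differ, which is why the level matters. A `dispersion="technical"`
flag switches to the pooled flat SD for sensitivity analysis; the
biological-level value is primary because the replicate structure the
confidence limit must absorb is biological.

Dataset repeatability is the **unweighted** mean of per-cell SDs over
every peptide × state × exposure cell (no length weighting — the QC
report is a single dataset-level number). Negative uptake values from
noise are retained, not clipped, so these dispersion statistics stay
unbiased; clipping of %EX is available only as an explicit reporting
option.

Back-exchange is estimated from the FD-control deficit:
`BE = 1 - (m_f - m_0) / (max_uptake * f_D * 1.00628)` per peptide,
averaged unweighted across peptides.

## Global confidence limit and classification

The differential analysis uses one dataset-wide threshold rather than
per-peptide tests: `CL = multiplier * sqrt(s_A^2 + s_B^2)` with `s_A`,
`s_B` the two states' repeatabilities in the chosen units (% exchange by
default, Da optionally). The default multiplier 2.32 is the two-sided
98% critical value in the large-sample limit (`Phi^{-1}(0.99) = 2.326`);
`AnalysisConfig.from_confidence` derives the multiplier for other
levels, and users preferring an exact-t convention can pass their own.
With per-dataset repeatabilities of 0.129 and 0.111 Da (2.28% and 2.09%
exchange), the limit evaluates to 0.395 Da (7.18%).

Significance is strict (`|Δ%EX| > CL`); a value exactly at the limit is
not significant. A peptide is stabilized/destabilized when at least
`min_significant_timepoints` exposures (default 1) exceed +CL / fall
below −CL, and flagged *mixed* when both directions reach that
threshold. With state A the wild type, positive Δ%EX = %EX_A − %EX_B
means state B is more protected (stabilized). Per-residue calls are the
plurality label among covering peptides, with ties — including the
one-stabilized-one-destabilized standoff — resolving to unchanged;
contiguous equal-label runs are emitted as regions.

Peptides present in only one state are *reported* in a mismatch listing
and excluded from the differential grid; silent intersection would hide
coverage asymmetry between states.

The Welch two-sample test on biological-replicate %EX means is offered
as an optional AND-criterion next to the global limit ("hybrid"
testing); it never alters the limit-based classification.

### Calibration

By construction the null two-sided exceedance rate of the limit is
`2 * Phi(-2.32) ≈ 2.0%` when the per-cell state-mean noise matches the
repeatability it was built from. The test suite checks this over 25,000
simulated cells (accepted band 1.5–2.7%) and checks recovery: an
implanted 100×-deprotected region at ~0.12 Da replicate noise must be
called destabilized in ≥95 of 100 seeded runs, with spurious calls far
from the region bounded by the per-peptide any-exposure null rate
(1 − 0.98⁵ ≈ 9.6%).

## Synthetic-data generator

The generator emulates a two-state comparison (wild type vs point
mutant) at the scale of a real kinase-domain dataset: a ~348-residue
construct, ~145–150 overlapping peptides, 100% coverage, mean peptide
length ≈ 13, redundancy ≈ 5.5, five exposures (10, 60, 600, 3600,
7200 s), 3 biological × 3 technical replicates, back-exchange ≈ 46–49%.

Defaults and their rationale:

- `f_D = 0.95` — labeling by 20-fold dilution into deuterated buffer
  (19 volumes in 20).
- `b = 0.47` — midpoint of the 46%/49% per-dataset range; per-state
  values can be set where a specific dataset is emulated.
- `noise_tech_da = noise_bio_da = 0.12` — chosen so the expected
  dataset repeatability across n = 3 biological means,
  `E[s] = c4(3) * sqrt(b² + t²/3) ≈ 0.89 × 0.139 ≈ 0.12 Da`, sits in
  the realistic 0.11–0.13 Da band. Biological noise is a per-(peptide,
  replicate) *offset*, not i.i.d. per measurement, so nested
  aggregation is genuinely distinguishable from flat pooling in tests.
- Baseline `log10 k_obs` is drawn from a stated two-component normal
  mixture (fast: N(−1.5, 0.5); slow: N(−3.5, 0.5), equal weights)
  rather than a sequence-dependent intrinsic-rate table: the analysis
  under test consumes centroids only, never intrinsic rates, and the
  mixture spreads uptake curves across the whole 10 s–2 h schedule.
- Back-exchange is a single multiplicative factor common to residues
  and times, matching the dataset-level granularity at which
  back-exchange is reported and estimated.
- Digestion builds a deterministic tiling with ≥2-residue overlaps
  (guaranteeing every amide-bearing residue sits at position ≥2 of some
  peptide — 100% coverage in exchange terms), then adds random peptides
  until the mean per-residue depth reaches the redundancy target.

What the generator does **not** emulate: EX1/bimodal isotope envelopes,
spectral-level simulation, pH/temperature-dependent intrinsic-rate
chemistry, proline isomerization, retention-time or charge-state
effects. Passing tests therefore demonstrate the statistical pipeline's
correctness under EX2 assumptions with Gaussian replicate noise, not
robustness to envelope-level pathologies a real instrument can produce.

## Assay-kinetics utilities

Oxidative-burst series (1-min grid luminescence) are averaged
disc → plant → genotype (genotype SEM across plants; a single plant
reports SEM as missing, not zero). Burst timing fits a four-parameter
logistic `lower + (upper−lower)/(1+exp(−slope(t−midpoint)))` to the
window from the first point through argmax + 5 points; fitting only the
six points at the max would under-determine four parameters, so the
whole rising phase is included (a documented choice; the window is
configurable). The time to half maximum equals the fitted midpoint,
making it invariant to signal rescaling and equivariant under time
shifts. Failed fits are flagged and excluded from plant averages with a
log entry.

The fluorometric standard curve is an ordinary least-squares line
through the dilution points (10 µM, 2-fold steps; a log-log variant is
not needed at these concentrations, where the response is linear);
activity is `(F − intercept)/slope / (protein_mg × minutes)` in
µM·mg⁻¹·min⁻¹, floored at zero below the intercept with a warning.

## Numerical and interface choices

- Exposure units are seconds in files; the CLI accepts minutes behind an
  explicit flag. Fully-deuterated control rows carry the literal token
  `FD` in the exposure column — a sentinel that cannot be mistaken for
  a long exposure.
- All outputs are plain CSV/text with `#`-comment headers recording the
  package version, the seed, and a hash of the scientific configuration;
  a pipeline run is byte-reproducible from config + seed (asserted in
  the tests).
- t = 0 and FD control rows carry technical noise only; controls are
  prepared separately from the biological labeling series.
- Seeds: every stochastic entry point takes an explicit seed; internal
  stages derive child seeds via `numpy.random.SeedSequence.spawn`.
- Problem sizes in the test suite (120-residue recovery runs, 25,000
  null cells, 100 seeded repetitions) are chosen as the smallest scales
  at which the binomial/recovery bands are statistically sharp.

## Known limitations

- No multiple-testing machinery beyond the global-limit / hybrid
  scheme; no EX1 detection; no residue-level rate fitting or
  deconvolution.
- The back-exchange estimate inherits the amide-count convention and
  `f_D`; a mismatch between conventions shifts the estimate by a few
  percentage points.
- `peptide_welch_test` at n = 3 per state has little power; it is a
  guard against pathological single-replicate artifacts, not a
  substitute for the global limit.
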