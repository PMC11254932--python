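# Methods

## Isotope model

All conversions between δ¹⁵N (‰ vs air) and atom% ¹⁵N use the atmospheric
reference ratio R_air = 0.0036765 (0.36630 atom%):

    R = R_air · (δ/1000 + 1),   atom% = 100 · R / (1 + R)

The mapping is strictly increasing and invertible; δ = −1000 ‰ corresponds
to zero ¹⁵N. The ratio is configurable (`IsotopeConstants`) but there is no
reason to change it for nitrogen work.

Tracer rates follow the standard isotope-dilution form: the fraction of the
pool's ¹⁵N that is *excess* over the baseline, divided by the enrichment of
the source medium, times the pool turnover:

* **N₂ fixation** — pool = particulate tissue N (µg → nmol N with
  14.0067 g mol⁻¹); baseline = natural-abundance tissue vials never exposed
  to tracer; medium ≈ 16 atom% ¹⁵N₂. Units nmol N cm⁻² h⁻¹ of leaf.
* **Potential nitrification** — pool = dissolved NO₃⁻ (µM × vial volume,
  24 mL by default, so the vial-level transfer can be normalized to the
  leaf area of the incubated section); baseline = T0 vials; medium
  ≈ 95.9 atom% ¹⁵NH₄⁺ (0.65 µM ambient NH₄⁺ spiked to 20 µM with ≥98 atom%
  tracer gives 94.8–95.8 depending on exact purity; the configured default
  is 95.9). δ¹⁵N-NO₃⁻ measurements mixed with USGS32 (δ = +180 ‰) are
  inverted by amount-weighted mass balance; the inversion is exact for any
  positive split. Units pmol N cm⁻² h⁻¹.
* **N₂ production** — slope of ²⁹N₂ and ³⁰N₂ concentrations between the
  second and third sampling (2 h → 5 h); the first interval is excluded as
  a lag phase. Molecular rates are doubled to N atoms by default
  (`n2_as_molecules=False`); whether such rates are reported per molecule
  or per atom varies across the literature, so the switch is explicit.
* **Nutrient fluxes** — start/end concentration difference, control
  corrected. Uptake is reported positive; the raw signed flux (release
  positive) is kept alongside, so no information is lost to the sign
  convention.

### Significance gate

An enrichment is accepted as tracer uptake only when the excess exceeds
k × SD of the baseline vials, k = 2.5 by default. The SD is the sample SD
of the natural-abundance vials (tissue) or T0 vials (water pools). Two
deliberate consequences:

* a zero baseline SD (noise-free data) passes any positive excess — the
  degenerate case is explicit, not an error;
* with only n = 3 baseline vials the estimated SD is itself noisy
  (2 degrees of freedom), so the realized false-positive rate of the gate
  is ~8 % rather than the ~1.5 % a known SD would give. The pipeline still
  estimates the SD from the vials, because that is what the field protocol
  does; the generator tests assert the idealized rate against the
  *configured* SD.

Non-significant rates propagate into budgets as 0 but keep their raw value
and flag in the rates table.

### Control correction

Control vials contain site water but no leaf, so they have no leaf area to
normalize by. Sample and control rates are therefore computed at the
vial-pool level (nmol h⁻¹), the mean control rate is subtracted, and only
then is the corrected rate divided by the sample's leaf area. The
significance gate is applied to the control-corrected excess.

## Daily budget

Hourly rates are integrated as `light·p + dark·(24−p)` with photoperiod
p = 12 h, scaled to the meadow by the leaf-area index (LAI, cm² leaf per m²
meadow; either given directly or as leaf density × dry weight per leaf ×
specific leaf area), and emitted in mmol N m⁻² d⁻¹. Nitrogen demand is
`(NCP/PQ)/C:N` with PQ = 1 by default. Nitrification appears in the budget
table but is excluded from the net-gain identity: it converts NH₄⁺ to NO₃⁻
within the system rather than adding or removing nitrogen.

Literature daily budgets for this system are printed in mmol N m⁻² d⁻¹ at
magnitudes that cannot be reached from the underlying per-cm² hourly rates
with any physically plausible LAI (the implied LAI would be ~10⁴ m² leaf
per m² meadow). This package does not rescale anything to match: budgets
are whatever rates × LAI give, in mmol by default, with `emit_umol=True`
available because per-area µmol values are the scale the input rates
actually support. The bundled demo parameters (LAI = 5 × 10⁴ cm² m⁻²,
NCP = 150/250 mmol C m⁻² d⁻¹, C:N = 20/22 for ambient/vent) are ordinary
Mediterranean seagrass-meadow values.

## Inference

Treatment contrasts use a two-factor type-II ANOVA because the design is
unbalanced (4 vials with epiphytes, 3 without): type-I SS would depend on
factor order. SS are computed as nested least-squares comparisons with
sum-to-zero coding — SS(A|B), SS(B|A), SS(AB|A,B) — via QR projections,
with F against the full-model residual mean square. On balanced designs
this coincides with the classical decomposition (and with types I and III).
A vectorized many-response path exists for null calibration; 10,000
simulated null responses on the 4/3 design give a type-I error within
±0.01 of the nominal 0.05. Constant responses, empty cells, and saturated
designs raise errors instead of returning undefined statistics.

Normality/homoscedasticity pre-tests are available from scipy directly and
are not wrapped; outlier handling is only via an explicit exclusion list in
the run config, so reruns are reproducible.

## Community statistics

Counts are compositions: CLR transform (log x minus the row mean of log x)
after adding a pseudocount (0.5 by default; 0 is allowed only for
strictly positive tables, where the transform is exactly scale-invariant),
Euclidean distance on CLR rows (Aitchison distance), and one-way PERMANOVA.
The permutation p value uses the (b+1)/(m+1) estimator so p is never 0;
when the number of distinct label arrangements is ≤ 20,000 the sampler is
replaced by full enumeration, which makes tiny designs exact (two fully
separated groups of 3 give p = 1/10, the combinatorial minimum over the 10
distinct splits). Sampled and exact p agree within binomial error as the
permutation count grows.

## Synthetic data

The incubation generator chooses true rates per process × site × light and
inverts the rate equations to produce vial measurements, reproducing the
study design: T0/T1/T2(/T3) destructive sampling, n = 4/3 replicates
with/without epiphytes, n = 3 natural-abundance and no-leaf control vials,
24 mL vials, 6 cm² leaf sections. Default true rates are set to the
study-scale magnitudes (e.g. light N₂ fixation 0.12/0.62 nmol N cm⁻² h⁻¹
ambient/vent; ²⁹N₂ production with no light/dark difference; ³⁰N₂ only at
the vent in the light), except that NO₃⁻/PO₄³⁻ uptake defaults are capped
by vial-pool exhaustion — a 24 mL vial with 1.94 µM NO₃⁻ physically cannot
sustain faster drawdown over 9 h. A dedicated flag
(`dark_fixation_one_hot`) reproduces the qualitative dark result of one
significant replicate out of four.

Measurement noise is multiplicative Gaussian (relative SD, default 5 %,
truncated at zero) applied to measured quantities only, so every estimator
remains exactly unbiased and noise-free data invert exactly. The model
deliberately omits features of real incubations: drift in blanks,
correlated errors within an IRMS run, bottle effects, non-linear tracer
back-flux, and count-table features such as phylogenetic correlation. A
passing recovery test therefore demonstrates correctness of the
calculations, not robustness to every laboratory artifact.

The count-table generator draws per-ASV log-abundances, adds a group shift
to the first k ASVs, softmaxes to a composition, and samples multinomial
counts at log-normal depths; zero effect size gives exchangeable groups,
which is what the PERMANOVA null calibration uses.

## Problem sizes and numerics

Calibration runs use 10,000 null responses (ANOVA), 1,000 count tables ×
199 permutations (PERMANOVA), and 200–500 simulated incubation campaigns
(bias checks) — sizes at which Monte-Carlo error is well below the asserted
tolerances. Baselines need ≥ 2 vials; rate estimates are means over
replicate vials; degenerate inputs (zero duration, inverted time windows,
NOₓ⁻ < NO₂⁻, empty pools, saturated designs) raise typed errors rather than
producing NaN. All randomness flows through explicit integer seeds; there
is no global random state anywhere.

## Known limitations

* The budget stage assumes rates measured on mid-leaf sections scale
  linearly to whole meadows via LAI; leaf-age gradients and self-shading
  are not modeled.
* PERMANOVA is one-way; crossed factors (site × compartment) must be
  tested factor by factor or as combined labels.
* The PNR baseline uses T0 vials per treatment cell; if T0 sampling is
  missing the rate cannot be computed (no fallback to natural abundance).
* δ¹⁵N-NO₃⁻ inputs are taken as already reduced to the sample scale;
  instrument-level corrections (peak-height linearity, Ti-to-sample ratio)
  are upstream of this package.
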