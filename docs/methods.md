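# Methods

## The measurement model

`qfascreen` analyses quantitative fitness analysis (QFA) screens: arrayed
yeast cultures spotted on agar, imaged repeatedly, and summarized per
culture as a timed series of colony intensity readings. Each culture is
modelled as logistic growth,

    G(t) = K · G0 · e^{rt} / (K + G0 · (e^{rt} − 1)),

with carrying capacity `K` (intensity units), growth rate `r` (1/day) and
inoculum density `G0` (intensity units). Measurement noise is
multiplicative: observed intensity = G(t) · e^ε with ε ~ N(0, σ²), because
colony-imaging error scales with signal. Fits therefore minimize least
squares on log intensities.

A fit is converted to two biologically interpretable numbers:

* **MDP** (maximum doubling potential) = log₂(K/G0), the number of
  population doublings from inoculum to saturation (doublings);
* **MDR** (maximum doubling rate) = 1 / t_d where t_d solves G(t_d) = 2·G0;
  in closed form MDR = r / ln[2(K − G0)/(K − 2G0)] (doublings/day), which
  tends to r/ln 2 as K/G0 → ∞.

Fitness is F = MDR × MDP (doublings²/day). It rewards both growing fast
and growing far, and is zero for cultures that never grow.

## Genetic-interaction model

A paired screen measures each gene deletion's fitness in a control
background and in a query-mutation background. Under genetic independence
the query mutation multiplies every strain's fitness by a common factor m,
so in the fitness plot (x = control fitness, y = query fitness) the null is
the line y = m·x through the origin. The genetic interaction strength of a
gene is GIS = F_query − m·F_control; significantly positive GIS marks a
suppressor, negative an enhancer.

The slope m is estimated from per-gene mean fitnesses. The default
estimator is iteratively reweighted least squares through the origin with
Tukey's bisquare (c = 4.685, MAD scale, ≤ 20 iterations, tolerance 1e-8 on
m); since most genes are assumed non-interacting, downweighting outliers
keeps real interactions from biasing m. `lsq_origin` (Σxy/Σx²) is kept as
the transparent non-robust alternative.

Significance per gene is a two-sided Welch t-test of the query replicate
fitnesses against the m-scaled control replicates — the scaling centres the
null on the independence prediction — followed by Benjamini–Hochberg
adjustment across all shared ORFs (default q ≤ 0.05). This replicate-level
test is deliberately assumption-light; it is validated by the false-
discovery-control and planted-effect-recovery properties in the acceptance
suite rather than against any published per-gene q-values. Genes with
fewer than two replicates on either side are reported with missing p/q,
never called, and flagged. Genes absent from either screen are dropped
from slope estimation and scoring and listed by `coverage_report` (absent
rows, not zeros — some deletions are simply missing from knockout
collections).

## Fitness profiles

A gene's profile is its vector of fitness (or GIS) values across screens.
Columns are z-scored per screen (sample sd) before similarity ranking:
screens run at different temperatures and on different scales, and column
standardization makes the normalize-then-rank pipeline exactly invariant to
per-screen affine rescaling. Similarity to a query gene is Pearson
correlation over the screens where both genes are measured
(pairwise-complete, minimum overlap 4 screens by default), or negated RMS
difference for the `euclidean` metric. Positions are 1-based; ties break
lexicographically by ORF, making rankings byte-reproducible.

## Synthetic screens

The generator emulates the study conditions end to end with known ground
truth. Defaults: 1000 genes × 8 replicate cultures per background, 15
timepoints over 5 days, baseline parameters log-normal with K ~ exp
N(ln 0.2, 0.15²), r ~ exp N(ln 3, 0.25²) /day, G0 ~ exp N(ln 0.003, 0.2²)
(inoculum clipped below K/4), multiplicative noise σ = 0.02, query slope
m = 0.5, 5% planted suppressors at effect 1.8 and 5% enhancers at effect
0.5, 2% dead cultures, 16 × 24 plate geometry. These are the scales of a
genome-wide colony screen: a few doublings of dynamic range, percent-level
imaging noise, a strongly sick query background and a minority of genuine
interactions.

Planted effects act on the growth rate r with K and G0 fixed: MDP is then
unchanged and MDR is proportional to r, so a fitness effect of size s maps
exactly (to machine precision, before noise) to r → s·r. This exactness is
what lets the independence invariant F_query = m·F_control hold identically
for unplanted genes and makes slope-recovery tests sharp.

The up-down (UD) treatment — acute high-temperature pulses followed by
recovery — is modelled as a deterministic viability multiplier
`ud_viability_scale` applied to every gene's query-background fitness, not
as temperature-switched kinetics: downstream analysis consumes only
fitness, and ground truth records the effective slope
m × ud_viability_scale so the independence invariant stays exact.

Planted gene counts are floor(fraction × n_genes); suppressors are
assigned before enhancers from a seed-shuffled gene order. Dead cultures
sit at inoculum level (times noise). Gene identifiers are synthetic
ORF-style strings ("YSIM0001C") so real yeast ORF tables drop in
unchanged.

What the generator does **not** emulate: spatial plate effects (edge
colonies, neighbour competition), batch/plate covariates, non-logistic
growth (lags, diauxie), or the SGA mating/selection steps upstream of
spotting. Passing tests therefore demonstrate correctness of the inference
machinery under the stated generative model, not robustness to those
real-data artefacts.

## Numerical choices

* **Fitting.** Trust-region reflective least squares over
  (log K, log r, log G0) with an analytic jacobian; log parameterization
  enforces positivity and makes the fit scale-invariant. Initialization:
  K₀ = max intensity, G0₀ = min intensity, r₀ from the log-linear slope
  over observations between 10% and 90% of max; one retry from
  (2K₀, r₀/2, G0₀/2) before `failed`. Bounds: K ∈ [0.5, 10] × max
  intensity, r ∈ [1e-3, 50]/day, G0 ∈ [0.1 × min, max] intensity. The G0
  upper bound is a box constraint rather than the K-dependent K/2 limit;
  the regime K ≤ 2G0 (doubling impossible under the logistic ceiling) is
  handled downstream by the MDR fallback r/ln 2, with the culture flagged
  `doubling_capped`, and `status="ok"` still requires K > G0. Solver
  tolerances are 1e-12; zero-residual (noiseless) problems converge to
  machine precision regardless.
* **Dead-culture rule.** max intensity < 1.75 × min intensity ⇒ status
  `dead`, fitness 0. The threshold is exposed in configuration; cultures
  with fewer than 4 observations raise an error distinct from dead/failed.
* **Intensity floor.** Intensities are floored at 1e-6 units before the
  log transform.
* **Validation conditions.** The FDR-control, slope-recovery and
  planted-suppressor-recovery checks simulate with dead_fraction = 0:
  dead cultures are genuine fitness differences between backgrounds, not
  null genes, so including them would conflate two failure modes. The
  noisy-recovery checks likewise isolate measurement noise. All other
  checks run with the defaults above.
* **Problem sizes.** Validation uses 100–1000 genes × 4–8 replicates per
  screen (16,000 cultures for the genome-scale runs) and 20 independent
  screen pairs for slope recovery; these sizes give stable pass/fail
  margins while keeping a full validation run to a few minutes.
* **Determinism.** All randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawns; tables are written with fixed
  formats (6 significant digits, "NA" for missing; raw intensities at full
  double precision), so identical config + seed reproduces every table
  byte-identically, and write → read → write is byte-stable.

## Known limitations

* The Welch-test GIS significance is a pragmatic substitute for
  model-based tests used in earlier QFA work; with very few replicates
  (< 4) its p-values are coarse.
* The robust slope assumes interacting genes are a minority; above ~30%
  planted fraction m drifts toward the contaminated bulk.
* Pearson profile similarity needs ≥ 4 shared screens to be meaningful;
  genes measured in fewer conditions are excluded rather than imputed.
* No spatial or batch normalization: systematic plate effects in real data
  would propagate into fitness estimates.
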