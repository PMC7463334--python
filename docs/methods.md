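# Methods

This note records the models implemented, the defaults and why they were
chosen, what the synthetic seascapes do and do not emulate, and the
numerical decisions a maintainer would want written down.

## Environmental descriptors

Each variable is summarised per pixel from its time series. For any
series: the overall mean (AVG), and the highest and lowest
calendar-month climatological means (HM, LM), where a month's
climatology is the mean of all values falling in that calendar month
across years (partial months at series edges included). For daily
series additionally three dispersion statistics: the SD of all daily
values (SD.AVG) and the SDs of daily values within the HM- and LM-months
(SD.HM, SD.LM). The wording "standard deviations associated with the
three averages" admits two readings — SD of daily values within the
extreme months, or SD of that month's yearly means; we implement the
former (it describes within-season variability rather than inter-annual
drift) and flag it here. Five daily variables × 6 + two monthly × 3 +
BAF, depth, population density = 39 columns; alkalinity receives the
full daily six-statistic treatment, which is the only accounting
consistent with that total.

**Alkalinity** is a pointwise polynomial in (SSS − s0) and (SST − t0)
with user-supplied coefficients; the shipped defaults are published
subtropical-zone reference values (see
`src/reefscape/data/alkalinity_subtropical.toml`) and should be replaced
for other water masses.

**Bleaching alert frequency (BAF).** Daily hotspot = max(0, SST − MMM)
with MMM the per-pixel maximum of monthly climatological means (computed
from the supplied series by default; an external climatology can be
passed). The trailing 14-day hotspot sum divided by 7 is the
accumulated heat stress in °C-weeks; a day is alerted when it reaches
4.0. "Accumulated over 2 weeks exceeded 4 °C" is read as ≥ 4 °C-weeks,
the degree-heating-week convention; both window and threshold are
parameters. No minimum-hotspot floor is applied by default (the NOAA
product uses ≥ 1 °C inside its accumulation; `hotspot_floor` exposes
this). BAF only counts days with a full trailing window.

## GEA scan

Per SNP and genotype class, the class indicator is regressed on one
standardized environmental variable plus optional structure covariates
by logistic IRLS (max 100 iterations, log-likelihood tolerance 1e-8);
coefficients are reported back on the original scale. G is the
likelihood-ratio statistic against the covariates-only null; W is the
squared z of the environmental coefficient; both referred to χ²₁.
Separation is declared when a standardized coefficient exceeds 50.
Missing data are dropped listwise per model and the n used is reported.

**Testability rule.** A model is only tested when its response has at
least `min_class_count` (default 10) carriers *and* 10 non-carriers
among complete cases. The χ²₁ reference for G and W is asymptotic; with
~180 individuals, classes with a handful of carriers produce badly
calibrated p-values. Ten events per model is the standard floor for a
one-parameter test. Untestable and degenerate models are reported with
a status and no statistics.

**Multiple testing.** Storey q-values with π₀ estimated on the λ grid
0.05..0.95 (step 0.05), smoothed by a cubic polynomial evaluated at
max λ, clipped to (1/m, 1]; with π₀ fixed at 1 the procedure reduces
exactly to Benjamini–Hochberg (available as `method="bh"`). Correction
batches are per environmental variable: the q-values of one variable's
models never depend on which other variables were scanned. The dual
rule requires q_G < 0.01 and q_W < 0.01; within a SNP the max-G model is
kept, ties broken by lower p_W then variable name, deterministically.

**Structure covariate.** The default is the leading principal axis of
the mean-imputed, centered dosage matrix; an externally computed
discriminant axis can be imported from CSV. A full discriminant
analysis is deliberately not re-implemented: only a scalar axis enters
the models, and the principal axis fills that role on planted two-group
structure with ≥99% sign accuracy (tested).

**Prediction.** An SGEA's probability surface is the inverse-logit of
α + β·env with the structure covariate held at a constant (default its
sample mean, i.e. 0 after centering) — covariate values are undefined at
unsampled reefs. PA is the arithmetic mean over the chosen SGEA subset
(default: all SGEAs of one tagged variable, e.g. BAF for heat stress).

## Connectivity

Daily (u, v) vectors are decomposed by positive scalar projection onto
the eight unit directions (not nearest-direction binning: smooth,
rotation-consistent, and exact for axis-aligned flow) and accumulated
over days. Conductance is each direction's share of the pixel's total
accumulated speed, normalised over all eight physical directions
*before* edges into land or off-grid are removed (so coastal nodes leak
probability, by construction); cost = conductance⁻². No diagonal length
correction is applied by default (`diagonal_scaling` would multiply
diagonal costs by √2; off by default). Least-cost distances are
Dijkstra runs on the sparse directed graph; reef cells map to their
nearest sea pixel within 2 cells (logged), farther cells are rejected.
Current rasters can be resampled to a finer grid before accumulation
(`reefscape.grids.resample`: bilinear on values with nearest-sea fill,
nearest-neighbour on the mask, land re-masked afterwards); the synthetic
experiments run at native resolution.

The connectivity model is OLS of pairwise multi-locus Weir–Cockerham
FST (ratio of sums of the a, b, c components — not mean of per-locus
ratios, which differs; sites with more than 10 genotyped samples) on
sea distance. FST is undirected while sea distance is directed; the
default pairing takes the per-pair **minimum** of the two directed
distances, on the argument that gene flow along the easier direction
dominates homogenization (`mean` is available). Negative FST estimates
are preserved (estimator property) unless clamped. AIC uses the full
Gaussian log-likelihood with the residual variance counted as a
parameter (k = 3), matching mainstream statistical environments so
values are comparable across distance kinds and to published fits.
dFST = a + b·d elementwise, diagonal zero, negative predictions floored
at 0.

## Indices

OCI/ICI/API as in the README, with three recorded choices: the focal
cell's own area is excluded (the indices describe *neighbouring* reefs;
`include_focal` exists for sensitivity); the threshold comparison is
strict (< T, configurable); T defaults to 0.02. T must be judged
against the observed dFST distribution — too small measures only local
connectivity, too large runs past the study area; the synthetic demo's
fitted intercept (~0.013) sits below the default threshold precisely so
that the indices are informative there.

## Synthetic seascapes

The generator emulates: a dominant directional current (default 0.15 m/s
toward ENE) with spatially smooth daily noise of equal magnitude
(mesoscale variability); daily SST with a seasonal sinusoid (baseline
26 °C, amplitude 3 °C, peak late July), a weak latitudinal gradient, and
localized heatwave events (default: centred on the sampling sites,
graded 1–4.5 °C, 35 days, hitting ~60% of years with start days jittered
near the seasonal peak — recurring in the same month every year would
inflate the MMM and erase the BAF signal); companion salinity,
chlorophyll, SPM and PAR series without planted signal; a reef cell per
sea pixel with partial-coverage areas; 12 sites × 15 colonies by
default, matching a realistic regional sampling design.

**Neutral loci.** Per locus, an ancestral frequency p ~ U(0.1, 0.9) and
site frequencies p_i = p + sqrt(2 F p(1−p)) z_i, with z a zero-mean
Gaussian vector whose variogram tracks sea distance,
E[(z_i − z_j)²] ≈ d_ij/d_max, and F = β_sim·d_max, giving expected
pairwise Weir–Cockerham θ ≈ β_sim·d_ij. Least-cost graph distances
(especially after the min-direction collapse, which can violate the
triangle inequality) are generally not conditionally negative definite,
so *no* Gaussian construction can realise that variogram exactly. The
generator therefore embeds the distances by Gower-centred classical MDS
with eigenvalue clipping and rescales the covariance so that the
regression slope of planted expected θ on distance equals β_sim exactly:
the linear *trend* is the planted quantity; pairwise deviations are
structured residuals. Consequences, measured and tested: realized
regression slopes fall within 20% of β_sim, and realized FST at short
distance carries a small positive offset (~0.15·F). β_sim defaults to
0.08/d_max (maximum planted FST 0.08 — realistic regional
differentiation for a broadcast-spawning coral). Frequencies are
clipped to [0.001, 0.999]; genotypes are binomial(2, p_i).

**Adaptive loci.** Per individual, carrying the focal genotype
(coded hom-alt) is Bernoulli(logistic(a + b·env_site)), defaults a = −4,
b = 8 over env spanning [0, 1] (carrier probability 1.8%→98.2% across
the gradient); non-carriers split evenly between the other classes. A
plain-text truth ledger (locus, kind, planted a, b, β_sim) accompanies
every genotype matrix so downstream checks never reverse-engineer the
simulation. All randomness flows from one root seed through named
substreams (currents/sst/genotypes/aux), so stages regenerate
independently and byte-identically.

**What passing tests do not show.** The generator has no linkage
disequilibrium beyond chance, no kinship or inbreeding, no genotyping
error model beyond optional missingness, no environmental
autocorrelation between descriptor families, and its FST~distance
relation is phenomenological, not mechanistic dispersal. Power and
calibration results transfer to real data only to the extent those
simplifications hold.

## Evaluation experiments and problem sizes

The packaged experiments (`reefscape.evaluation`) run at the reference
design (12 sites × 15 colonies, 2,000 loci): null calibration over 50
seeds (~300k fitted models; the dual rule's realized false-positive
rate and the KS uniformity of G p-values on a 1,000-fit subsample —
uniformity is assessed at that scale because the χ²₁ reference is
asymptotic and its ~1% systematic deviation at n = 180, invisible there,
dominates a KS test pooled over 10⁵ fits); power over 50 seeds for
b = 8; slope-recovery coverage over 100 seeds with 100 pairs per seed
(the large-sample regime where the 2-SE interval attains its nominal
~95%); and the least-cost vs Euclidean AIC comparison over 20 seeds with
120-day current records. On one CPU the whole suite runs in under two
minutes; the batched IRLS (shared design matrix across all genotype
responses of one variable) is what makes whole-matrix scans cheap.

## Degenerate inputs and tie-breaks

Zero-variance environments raise; one-class responses and separations
are flagged, never silently dropped. Monomorphic loci contribute
(0,0,0) to FST sums. A pixel with zero accumulated speed keeps its node
with no outgoing edges; unreachable pairs are +inf with a warning.
Greedy LD pruning is first-kept-wins within a per-scaffold window of 50
kept SNPs at r² > 0.3 on pairwise-complete dosage correlation.
Individual missingness filtering precedes SNP filtering. SGEA ties are
broken deterministically as described above.

## Known limitations

Raster I/O is NetCDF/CSV (no GeoTIFF reader); real remote-sensing
retrieval, read alignment/variant calling, and functional annotation of
SGEA neighbourhoods are out of scope — the VCF is taken as given.
The Wald statistic is the scalar df = 1 form on the environmental
coefficient. DAPC itself is not reimplemented (see above). Distances
between reefs assume larvae follow depth-averaged surface currents
summarized over the record; no biophysical larval behaviour.
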