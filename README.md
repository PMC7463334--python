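# reefscape

Seascape genomics for coral reef conservation: a tested Python
implementation of the full chain from remote-sensing-style environmental
descriptors and a genotype–environment association (GEA) scan, through
current-based connectivity modelling, to reef-level conservation indices
(OCI, ICI, API).

## Who this is for

Population and landscape/seascape geneticists who want to (a) detect SNP
genotypes whose frequencies track environmental gradients across a reef
system while controlling for neutral structure, (b) translate ocean
currents into asymmetric "sea distances" and calibrate them against
genetic differentiation, and (c) turn both results into quantitative,
mappable reef prioritization indices in km². A first-class synthetic
seascape generator plants known structure (isolation by sea distance,
logistic genotype–environment links), so every stage can be validated
against ground truth before touching real data.

## The method in brief

**Environmental descriptors.** Each daily variable (SST, salinity,
chlorophyll, current speed, alkalinity estimated from a polynomial in SSS
and SST) yields six per-pixel statistics — overall mean, highest and
lowest calendar-month climatological means (HM, LM), and the SDs of daily
values overall and within the two extreme months; monthly variables (SPM,
PAR) yield the three means. With bleaching alert frequency (BAF), depth
and human population density this is a 39-column table. BAF follows the
degree-heating convention: hotspot = max(0, SST − MMM) where MMM is the
maximum monthly-mean climatology; a day is alerted when the trailing
14-day accumulated hotspot reaches 4 °C-weeks; BAF is the alerted
fraction of days.

**GEA scan.** For each biallelic SNP, each of its three genotype classes
is a binary response regressed on one environmental variable with a
population-structure covariate (leading principal axis of the dosage
matrix, or an imported discriminant axis):

    logit P(genotype) = α + β·env + γ·cov

Support is measured by the likelihood-ratio score G = 2(llᶠᵘˡˡ − llⁿᵘˡˡ)
(null keeps the covariate, drops env) and the Wald score W = (β/se(β))²,
both ~χ²₁. Per environmental variable, p-values are converted to Storey
q-values; a model with q_G < 0.01 **and** q_W < 0.01 is a significant
genotype–environment association (SGEA); a SNP keeps only its best-G
model. Applying each SGEA's inverse-logit across the reef grid and
averaging gives PA — the probability a reef carries the putatively
adaptive genotypes.

**Connectivity.** Daily current vectors are projected (positive part)
onto the eight neighbour directions and accumulated per pixel; each
direction's share of the total is its conductance c, and the move costs
c⁻². Dijkstra on the directed graph gives asymmetric least-cost sea
distances. Pairwise Weir–Cockerham FST (multi-locus ratio of sums, sites
with >10 samples) is regressed on distance — the connectivity model
FST = a + b·d — which then converts the reef-to-reef distance matrix
into directional predicted separations, dFST.

**Indices** (all in km², threshold T = 0.02 on dFST):

    OCI(i) = Σ_{j≠i} area_j · [dFST(i→j) < T]      area reachable FROM i
    ICI(i) = Σ_{j≠i} area_j · [dFST(j→i) < T]      area that can reach i
    API(i) = Σ_{j≠i} area_j · PA_j · [dFST(j→i) < T]   adapted inbound area

## A worked example

```bash
python examples/03_gea_scan.py
```

simulates 12 sites × 15 colonies with 2,000 neutral loci and one adaptive
locus planted at logistic(−4 + 8·env), scans all models and prints:

```
models evaluated: 6003 (5340 testable)
SGEAs at dual q<0.01: 1
              snp genotype  g_score    wald  q_g  q_w
scaffold_21:10000  hom_alt 131.8602 50.8887  0.0  0.0
planted adaptive locus scaffold_21:10000 recovered: True
```

The one retained SGEA is exactly the planted locus; its G and Wald scores
are far beyond the χ²₁ significance bar and no neutral locus survives the
dual q-rule. `examples/04_connectivity.py` prints the companion result
for the connectivity axis (least-cost R² ≈ 0.87 vs Euclidean 0.29, planted
FST-per-distance slope recovered within a few percent), and
`examples/06_full_pipeline.py` runs everything end to end, ending in the
per-reef OCI/ICI/API table. The other examples cover the descriptor
scheme, the generator, and a hand-sized index calculation.

A thin CLI wraps the same library calls:

```bash
reefscape run --out scratch/demo --seed 1          # full pipeline
reefscape indices --dfst dfst.csv --reefs reefs.csv --threshold 0.02 --out idx.csv
```

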