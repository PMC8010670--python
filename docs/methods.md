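# Methods

This note documents the models behind each pipeline stage, the defaults
that matter, what the synthetic generator does and does not emulate, and
the numerical choices made where the design was genuinely open.

## Hashtag demultiplexing

Droplet tag counts are compositional: each droplet's tags are normalized
to proportions, log2-transformed with pseudocount ε = 10⁻⁴, and z-scored
per tag across droplets. "Total read counts for that cell" is taken to be
the droplet's total **HTO** counts (not total library size); the
alternative reading would couple tag calls to RNA depth.

Each tag's distribution is bimodal — background staining versus
tag-positive — and is modeled with a 1-D two-component Gaussian mixture
(EM; deterministic lower/upper-third quantile initialization plus two
seeded random restarts, best lower bound kept; variance floor 10⁻⁶;
non-convergence is an error advising inspection). "Positive" is posterior
of the high-mean component strictly above 0.5 (configurable); a posterior
of exactly the threshold counts as negative, conservative toward empty.
Kind is |positive set|: 0 empty, 1 singlet, 2 doublet, 3 triplet.

Two structural facts shape the design. First, under proportion
normalization an empty droplet with symmetric ambient background is
*indistinguishable from a triplet* — both sit at 1/3 per tag — so empties
must be separated on total counts, which is also what "no sufficient read
counts for any HTO" means operationally: droplets with total HTO counts
below `min_hto_total` (default 10) bypass normalization and are classified
empty. Second, zero tag counts map to log2(ε) ≈ −13.3, far outside the
data scale; the same floor removes these meaningless small-total
proportions from the mixture fits. Both parameters are configurable.

The external donor table (genotype demultiplexing output) assigns each
droplet a donor id, `ambiguous`, or `doublet`; only HTO singlets with a
single donor and ≥ `min_genes_per_cell` (400) detected genes are retained.
The demux report includes the fraction of HTO-empty droplets whose donor
call is ambiguous — empties carry only ambient RNA, so the two methods'
failure sets should overlap heavily.

## Surface-protein stage

CLR is computed per cell across the protein panel with pseudocount 1
(CLR values therefore sum to zero within each cell); the margin is the
interpretation consistent with treating each cell's antibody pool as a
composition. Per-protein positivity reuses the mixture machinery across
cells; a degenerate protein yields all-negative with a warning.

The multiplet rule table is declarative — per rule, all *anchor* markers
positive AND at least one marker of any *forbidden group* positive — with
five rules (anchored on CD19; CD14; CD56; CD3+CD4; CD3+CD8) shipped as
editable YAML. Rules are validated against the panel at load time and the
engine is a pure function of the positivity matrix (idempotent).
Annotation precedence is fixed: CD3+CD4 → CD4 T, CD3+CD8 → CD8 T, CD14 →
monocyte, CD19|CD20 → B, CD56|CD16 → NK, else unassigned; the lineage tie
order is a design choice (T first) since co-positive cases are dominated
by T-cell-containing multiplets already removed by the rules. T cells
positive for both CD45RA and CD45RO get memory state NA with a warning.

## Clustering

Variable features are selected on the concatenated log-normalized RNA and
CLR ADT matrices: loess (span 0.3, a common default) of log10 variance on
log10 mean gives an expected variance per feature; values are standardized
with the observed mean and expected variance, clipped at √n_cells, and
features are ranked by the variance of the clipped values. Zero-variance
features rank last. PCA uses the centered, unit-scaled selected submatrix
with a deterministic sign convention (largest-magnitude loading positive).
The SNN graph uses Euclidean k-NN (k = 20, self included, ties by index),
Jaccard edge weights, and prunes weights ≤ 1/15. Clustering is Leiden
modularity optimization (RB-configuration, resolution 0.8, fixed seed),
with labels renumbered by decreasing cluster size. The prune threshold
and resolution are assumptions exposed in the config. UMAP is not used
anywhere in computed results.

## Differential expression and scoring

Wilcoxon rank-sum, two-sided, tie-corrected (exact for small groups via
scipy), on log-normalized values y = ln(1 + 10⁴·x/T); features must be
detected (nonzero) in ≥ 10% of both groups; BH correction is applied per
contrast (per cell type and condition pair), not globally. Significance
additionally requires |mean log difference| > 0.25: the conventional
reading of the published threshold, since taking "log2(0.25)" literally
(= −2) would make the filter vacuous; the literal value remains reachable
through `de_min_logdiff`.

The inflammation score is the panel share of a cell's normalized
expression, min–max scaled across the scored cells; if all cells tie, all
scores are 0. Gene-set scores are plain per-cell means over the set. The
proprietary 249-gene inflammation panel is always a user-supplied file; a
synthetic stand-in (the generator's monocyte late activation wave, i.e.
its pro-inflammatory arm) is bundled for self-contained runs.

## Trajectory

Cells are embedded on the top PCs (≤ 10) of the differentially induced
feature submatrix. The principal curve alternates lowess smoothing of each
coordinate against the current pseudotime (span 0.6) with re-projection of
all cells onto a 100-knot polyline; it stops when the mean projection
shift falls below 10⁻⁴ of the data scale or after 30 iterations (warning,
last iterate kept — the fit typically oscillates at a scale far below the
state structure). Pseudotime is arc length from the polyline end nearest
the baseline-cell centroid, so baseline cells start at 0. The published
analyses report essentially linear activation trajectories, which makes a
single principal curve the minimal faithful model; its arc-length units
are not comparable to any other tool's internal scaling, so peak windows
are interpreted as fractions of the trajectory, not absolute values.
States are k-means (k = 4, 10 restarts, fixed seed) on the same embedding
— chosen over raw expression space for comparability with the pseudotime —
renamed Baseline/LPS1/LPS2/LPS3 by ascending mean pseudotime. "Uniquely
induced" genes of a state are significant-up versus Baseline in that state
and in no other activated state. Peak times use Nadaraya–Watson smoothing
with a Gaussian kernel of bandwidth 10% of the pseudotime range; constant
profiles return NaN.

## Synthetic experiments

The generator emulates the pooled design: 10 donors × 3 conditions
(baseline, LPS, anti-CD3/CD28), one hashtag per condition, 20k droplets by
default. Droplet categories: 9% empty, 13% cross-condition multiplets
(10% of them triplets, the Poisson co-encapsulation ratio at this loading),
2% cross-donor doublets, 2% biological cross-cell-type doublets (same
condition and donor — the physically interacting pairs the surface rules
target). The biological doublet rate is a free parameter: activation
increases cell–cell interactions but no rate is established, so 2% is a
deliberately exercisable default.

Counts are negative binomial (variance μ + φμ²). RNA: 1,500 genes with
log-normal baseline weights; five cell types (CD4 T 40%, CD8 T 25%,
monocytes 18%, NK 10%, B 7% — blood-typical frequencies) each with 25
constitutive marker genes (5× boost) and a 30-gene activation signature
split into an early wave (Gaussian bump peaking at activation level 0.35)
and a late wave (rising as level²), both up to 7× at amplitude 6. Library
sizes are log-normal around 1,900 UMIs (σ = 0.35), φ = 0.3 — ~850
detected genes per cell, the scale typical of 3′ v2 chemistry PBMC runs;
empty droplets carry ~50 ambient UMIs and thus fail the 400-gene filter.
Activation is a continuous per-cell level: a per-condition/per-type
ceiling (LPS → monocytes 1.0; anti-CD3/CD28 → T 1.0, NK 0.7, B 0.5)
times a uniform draw, making pseudotime recovery well-posed.

ADTs: 39-plex panel; positives mean 500, negatives 5 (the ~100× ratio of
real antibody staining; narrower ratios make CLR dilution in doublets
push single-cell markers below the positivity boundary), ambient 3 in
empties. CD45RA/RO split T cells 50/50 into naive/memory; CD69 turns on
above activation level 0.2, CD25 above 0.5.

HTOs: tag background is cell-bound nonspecific binding (mean 50 per tag
per contained cell); each cell adds `hto_separation` (default 8) × 50 to
its condition's tag; free-antibody ambient is near zero (0.05 per tag), so
empty droplets have near-zero tag totals as in real hashing runs. Tag
counts use their own dispersion (0.05), reflecting the cleaner tag
amplicon libraries; at separation 8 the tag geometry is only ~3 log2 units
wide, so tag noise proportionally narrower than RNA noise is what makes
the published "clearly bimodal per tag" picture hold at this separation.

Ground truth records the *hashing-visible* kind per droplet — the number
of distinct condition tags present (0 empty … 3 triplet) — so a biological
cross-cell-type doublet within one condition is, correctly, a hashing
singlet; its content is carried in `n_cells` and `true_cell_types`. Donor
calls mark multi-donor droplets `doublet`, empties `ambiguous` with
probability 0.85, and cells `ambiguous` at rate 0.02.

What the generator does **not** emulate: ambient RNA contamination in
cell-containing droplets, donor-specific expression variation, batch and
lane effects, UMI saturation, tag-swapping between droplets, and doublet
transcriptome nonadditivity. Passing tests therefore demonstrate that the
pipeline's logic is correct under a faithful stochastic model of the
design, not that it is robust to every artifact of real sequencing data.

## Problem sizes

The default verification run uses 20k droplets (≈ 14.5k analysis cells),
the scale at which the multiplet and empty fractions have tight binomial
intervals; module tests use 4k-droplet experiments and small constructed
matrices with brute-force oracles (exhaustive rank-sum enumeration,
dense PCA/Jaccard/rule evaluation, 2¹⁰ marker-combination enumeration).

## Known limitations

Per-tag mixtures assume bimodality; designs whose conditions are wildly
unbalanced may need a different positivity model. The trajectory module
fits a single non-branching curve. The donor-call table is consumed, not
computed — genotype deconvolution is out of scope. Mixture fits, Leiden
and k-means are seeded; results are reproducible bit-for-bit for a fixed
seed but can shift slightly across seeds.
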