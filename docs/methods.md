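# Methods

This note documents the models and procedures implemented in `cytoflux`,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not demonstrate about real instrument data.

## Data model

An acquisition is an events × channels matrix (`EventTable`) with
per-channel roles: 33 antibody markers, 6 palladium barcode channels
(Pd102–Pd110), 2 iridium DNA channels (Ir191/Ir193), 4 calibration-bead
channels (Ce140 + Eu151/Ho165/Lu175), and the instrument summaries
Event_length, Center and acquisition Time.  Pipeline stages append
per-event annotations (assigned sample, separation, Mahalanobis, bc_neg,
cluster labels); on disk these become `meta_`-prefixed FCS channels so
files remain standard FCS 3.1.

**Panel classification.** The panel declares 21 signaling and 12 identity
markers.  The 13-marker round-1 clustering set (Olig2, CD11b, Fibronectin,
GFAP, CD68, F480, CD45, Ly6C, Sox2, CD40, Galectin-1, Cx3CR1, CD86)
comprises the 12 identity markers plus CD40: CD40 is classed as signaling
because it is analyzed as an activation read-out in the fold-change
time-courses, but it carries enough state information to help separate
lineages in round 1.  CD86 and Galectin-1 are classed as identity.

**Transform.** All statistics and clustering operate on
`asinh(x / 5)`-transformed ion counts.  The cofactor 5 is the community
standard for CyTOF; it is configurable everywhere and recorded in
`sample_meta` whenever applied.

## Synthetic CyTOF generator

Each population defines per-channel lognormal latent log-means/log-SDs;
an event's ion count is Poisson(exp(latent)).  This lognormal × Poisson
model gives realistic zero-inflation at low signal and overdispersion at
high signal.  Default scale is 0.35 (log units).  The catalogue: four
microglial signaling states (baseline; MAPK-high with elevated
pERK/pp38/pRSK/pCREB; pSTAT1-high with elevated pSTAT1/pS6; terminal with
high CD40/CD86/pSTAT3/pNFκB/pSrc and down-regulated Cx3CR1), an
astrocyte-dampened terminal variant (CD40 location reduced ~10-fold),
astrocytes (GFAP/β-catenin/pAkt-high, CD11b−CD45−), fibroblasts
(Fibronectin-high), and low-DNA debris.

Mixing weights over the nine timepoints (0, 0.25, 0.5, 1, 2, 4, 8, 24,
48 h) implement the early-MAPK → mid-pSTAT1 → late-terminal trajectory.
The default numbers (MAPK share 0.73 at 15 min under LPS vs a smaller
burst delayed 15 min under Poly(I:C); pSTAT1 peak shares 0.36 vs 0.63 at
2 h; terminal 48-h shares 0.56 / 0.40 / 0.53 / 0.04 for microglia-LPS /
microglia-PIC / mixed-LPS / mixed-PIC; pERK high-state location set so the
bulk fold-change peak is ≈17× under LPS and ≈4× delayed under Poly(I:C))
are generator parameters chosen to emulate the study conditions the
pipeline is meant to analyze; they are inputs to the tests, not measured
claims about any instrument run.  Mixed cultures carry a 25% astrocyte
compartment (1% residual in microglia-only cultures), 2–4% fibroblasts and
3% debris.

Barcoding sets each sample's 3 positive Pd channels to a lognormal around
`30 × SNR` counts (default SNR 8) and the other 3 to instrument background
(~1 count).  Default barcode keys take codes in complementary pairs so
channel usage stays balanced — required by the robust-range rescaling
below.  Doublets replace a configurable fraction of events by channel-wise
sums of two random cell events (Event_length and Center add); beads are
appended at a configurable fraction of the final total (1/21 emulates a
1:20 spike); smooth multiplicative drift (linear decay or sinusoid) scales
all mass channels, and the exact per-event factor is stored in the ground
truth.  With a fixed seed the simulation is bit-reproducible.

What the generator does **not** emulate: isotopic spillover between
adjacent masses, ion-cloud physics beyond the Event_length/Center
summaries, acquisition-rate artefacts, staining batch effects, and
continuous (rather than discrete-state) signaling heterogeneity.  Passing
tests therefore demonstrate correctness of the algorithms under the stated
statistical model, not robustness to these additional real-data effects.

## Bead normalization

Bead events are auto-gated: positive on all four bead channels (valley
thresholds on the arcsinh scale, quantile fallback), excluding DNA-positive
or broadly antibody-positive events (bead–cell doublets).  Windows of 500
bead events (sliding by half a window; both configurable) give per-channel
raw-scale medians; each window's sensitivity is the least-squares
through-origin slope of its median vector against the run-global baseline
medians.  The through-origin form is deliberate: zero ion counts must map
to zero, so an affine fit is wrong.  Slopes are linearly interpolated
between window-median times, extended to the run boundaries by linear
extrapolation from the edge windows, floored at 0.05, and every mass
channel is divided by the sensitivity at its event time.  Times outside
the fitted span are clamped with a warning.  Window medians are robust to
the ≲1% bead-gate impurity at defaults; the 2% unity-recovery tolerance in
the tests reflects the median sampling noise at 300-event windows.

## Debarcoding

Each Pd channel is arcsinh-transformed and rescaled to [0, 1] by its own
1st–99th percentile span (clipped).  Rescaling puts channels with
different gains on a common footing; a constant channel is a configuration
error.  The candidate code is the top-3 rescaled channels; if it is in the
key the event is assigned, else left unassigned.  Separation = 3rd − 4th
highest rescaled value.  bc_neg is computed on the raw (normalized) scale
— it is a sum of physical ion counts — over the 3 complementary channels.
Mahalanobis distance is computed per assigned group in 6-dim rescaled
space with a ridge of `1e-6 · trace/6` on the covariance; groups below 21
events (the covariance parameter count) get a NaN sentinel.

Default filter: separation ≥ 0.3, Mahalanobis ≤ 30, bc_neg ≤ 15 counts.
The bc_neg ceiling sits well above the singlet bc_neg distribution under
default conditions (99.9th percentile ≈ 10 counts: three background
channels plus worst-case drift correction) while different-code doublets
carry at least one bright positive channel (hundreds of counts).
Same-code doublets are invisible to bc_neg by construction — with k
equally used codes that is ~1/k of doublets — which bounds the achievable
bc_neg recall; the separation and Mahalanobis criteria and the
Event_length gate catch part of that remainder.

## Clean-up gating

Gate order is fixed: debarcode confidence → singlets → viability → Ce140
residual beads → CD11b/CD45 → GFAP-negative (the astrocyte branch replaces
the last two gates with GFAP-positive).  Because the original gates were
drawn manually and their coordinates are not numeric constants, thresholds
default to automatic valley detection with quantile fallbacks:

* KDE with a bandwidth floor of 0.25 asinh units — low Poisson counts are
  discrete, and without the floor integer spikes masquerade as modes;
* a split is accepted only if two peaks ≥ 0.8 asinh units apart exist,
  with the valley density below 0.8× the smaller peak, and the secondary
  peak on the expected side of the dominant mode (above for
  doublet/bead/GFAP shoulders, below for debris and marker-negative
  populations); otherwise the quantile fallback applies.

`resolve_gate` freezes thresholds into concrete specs; resolved gates are
idempotent, and the chain resolves each gate on the events entering it
(re-resolving a quantile gate on its own output would trim again).  The
singlet gate's quantile core is Event_length (1st–95th percentile); Center
trims only when a genuine second mode is present.  Every resolved
threshold is recorded in the gate report, whose in/out counts telescope.

## Two-round clustering

Features are arcsinh-transformed and per-channel z-scaled (the scaling is
recorded; clustering on unscaled transforms is available by flag).  An
unweighted symmetric k-nearest-neighbour graph (k = 15, euclidean — the
same neighbourhood scale as the UMAP) feeds Leiden RB-configuration
modularity optimization at resolution 1.0 by default, deterministic for a
fixed seed; labels are contiguous from 1, largest cluster first.  Since
the original cluster counts (20 and 19) were reached with unpublished
settings, an optional bisection mode tunes the resolution (log-scale
bisection) to a requested cluster count instead of chasing a resolution
value.

Round 1 clusters on the 13 identity markers and computes per-cluster
arcsinh-scale medians.  The exclusion rule flags clusters with low CD11b,
low CD45, or high GFAP: thresholds default to the midpoint of the two
1-D 2-means centers of the cluster medians per channel, applied only when
the centers are ≥ 1 asinh unit apart (otherwise the medians are treated as
unimodal and no cluster is excluded on that channel).  Reasons are
recorded per cluster and inherited by events.  Round 2 re-clusters the
retained events on all markers except CD11b, CD45, GFAP and Olig2
(asserted in code) and stores full-panel median profiles.  UMAP uses
(15, euclidean, local_connectivity 1, 2 components, 1000 epochs) with a
seeded random state.

## Dynamics statistics

Fold changes are ratios of raw-scale means: FC(t) = mean(t) / mean of the
same replicate's t = 0 (vehicle) sample; a transformed-scale option
exists.  The two-way ANOVA is the balanced fixed-effects closed form
(group × time); per-timepoint group contrasts use the pooled residual
variance with df = ab(n−1) and are Šídák-adjusted with m = number of
timepoints.  Šídák is exact under independence and conservative under the
positive correlation induced by the shared MSE; the null simulations
(family-wise error ≈ 4–5% at α = 0.05, n = 3 replicates) confirm control.
Dunnett many-to-one comparisons use the multivariate-t implementation in
scipy; the single-comparison case collapses to the exact two-sided t test.
Means are reported with SEM.

Cluster abundance is the fraction of retained (round-2) events per cluster
within each (condition, stimulus, timepoint, replicate); columns sum to 1.
Cow-plot trajectories divide each cluster's replicate-averaged trajectory
by its own maximum (per-cluster sum normalization available); the ordering
index is the abundance-weighted mean time, ascending, with all-zero
clusters last.  The return-to-baseline statistic is
RMSE = sqrt(mean over clusters of (f₄₈ − f₀)²) on replicate-averaged
fractions.  Terminal-state fractions are reported over the set of clusters
that majority-map to the planted terminal populations: the
astrocyte-dampened terminal state is deliberately distinct molecularly, so
at full resolution it forms its own cluster rather than joining the
microglia-only terminal cluster.

## Problem sizes

Tests and the acceptance script run at reduced but statistically adequate
sizes chosen so every recovery check retains a ≥3σ margin: 20,000 events
for debarcoding accuracy/AUC, ~21,000 (with a 1:20 bead spike) for drift
recovery, three seeds of ~10,000 gated events for clustering recovery, and
an end-to-end study of 4 conditions × 9 timepoints × 2 replicates at 500
events/sample (~26,000 retained events).  The family-wise-error
simulations use 1,000 null runs at n = 3 replicates.

## Known limitations

* FCS support is limited to list-mode float32 (DATATYPE F) 3.0/3.1 files —
  the layout modern mass cytometers and this package write; integer/ASCII
  data types and FCS 2.0 are out of scope.
* Spillover/compensation between adjacent isotopes is not modeled or
  corrected.
* Valley-based auto-thresholds assume reasonably separated modes; heavily
  overlapping populations fall back to quantile rules that should be
  reviewed via the recorded gate report.
* The exclusion rule operates on cluster medians; rare mixed clusters
  below the clustering resolution are inherited wholesale.
* Cross-run (multi-batch) normalization against a reference bead lot is
  not implemented; the pipeline assumes one batch.
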