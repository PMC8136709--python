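# Methods

This note documents the models, parameter choices and numerical decisions
behind `replichron`, and what the synthetic study does and does not show
about real data.

## The simulator

### Replication

Fork geometry is deterministic min-plus: each bin `x` has a population-
median replication time `T(x) = min_i (t_i + |x − x_i| / v)` over the
origins `i` of its chromosome, evaluated at bin-start coordinates on the
fixed 200-bp grid. Population heterogeneity enters analytically: the
fraction of cells that have replicated `x` by time `t` is
`F(x,t) = Φ((t − T(x)) / σ_f)` with firing-time jitter `σ_f`. In the
never-released condition only an escaping minority proceeds, so `F` is
scaled by `escape_fraction`. We chose the analytic population model over
per-cell simulation because it is deterministic, fast, and testable in
closed form (`F = 0.5` exactly at `t = T(x)`; `T` is 1/v-Lipschitz).

### Acetylation

Each bin carries an acetyl fraction in `[0, 1]` governed by first-order
kinetics with three processes:

* a slow background writer (Esa1-like) at rate `k_esa` pushing toward the
  ceiling `a_max`;
* turnover at rate `λ(x)` incorporating unacetylated histones
  (`λ = k_basal` intergenic, plus a transcription-coupled term in gene
  bodies, see below);
* replication: parental histones are split 50/50 between daughters with
  acetylation retained, and new histones are acetylated at deposition with
  probability `p_sas` when the writer is active — so chromatin restarts at
  `A_new = 0.5·A_arr + 0.5·p_sas` (writer on) or `0.5·A_arr` (writer off)
  and then relaxes under `dA/dτ = k_esa(a_max − A) − λA`.

The arrest steady state is the balance of the first two processes,
`A_ss(x) = a_max / (1 + λ(x)/k_esa)`, which makes arrest levels inversely
related to expression, as observed for H4 K16ac. The population value at
any time is the `F`-weighted mixture of arrested and replicated chromatin.

### Transcription-coupled turnover

Two structural choices shape `λ(x)` in gene bodies; both are exposed in the
configuration and both can be switched off, in which case the kinetics
reduce exactly to the constant-rate closed form above:

* **TSS-proximal concentration** (`tss_decay_bp`, default 1500 bp):
  turnover decays exponentially with distance from the TSS in
  transcription orientation. Long genes therefore escape turnover at their
  3' ends, which is why the replication-coupled increase is cleanest in
  long genes and blunted in short ones.
* **Arrest-program relaxation** (`arrest_program_tau`, default 12 min):
  expression is ranked in *arrested* cells, and the arrest transcription
  program dissipates after release. In the model, chromatin replicated at
  time `T` is re-populated under the current program, whose
  transcription-coupled turnover decays as `exp(−t/τ)`; unreplicated
  templates keep the arrest program, so the arrested state stays pinned at
  its balance (and the never-released condition stays flat). Acetylation
  deposited behind early forks in hot genes is stripped while the program
  is still active; only later deposition survives, which shifts the
  half-rise of the top expression quartile measurably later. This
  time-dependence is essential: with any time-invariant per-locus
  kinetics, a decaying deposition pulse always makes the rescaled group
  series rise *earlier*, not later (the exponentially filtered cumulative
  is concave in its argument), so a model without program relaxation
  cannot produce a turnover-caused delay at all.

The turnover amplitude is
`λ = k_basal + λ0 · min(expr/expr_ref, 1) · exp(−d_TSS/ℓ)` with `expr_ref`
the 95th expression percentile. Normalizing by the maximum would make the
rate degenerate under a heavy-tailed (lognormal) abundance distribution —
every gene but one would get a negligible rate.

With the program relaxation active there is no closed form; the linear ODE
with a decaying coefficient is integrated with per-step exponential
updates (0.25-min steps, rates frozen at step midpoints, replication
starts handled at their exact fractional time within a step). Each step is
exact for its frozen rate; against the closed form (program decay
disabled) the stepped trajectories agree to ~1e-4.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `fork_speed` | 1.5 kb/min | bidirectional fork speed |
| `firing_jitter σ_f` | 4 min | population spread of firing |
| firing times | uniform 5–45 min | spans early-to-late S in the 60-min window |
| `p_sas` | 0.75 | P(new histone acetylated at deposition, writer on) |
| `k_esa` | 0.005 /min | background acetylation |
| `k_basal` | 0.02 /min | basal replication-independent turnover |
| `λ0` | 1.0 /min | turnover at the TSS of the hottest genes in arrest |
| `tss_decay_bp` | 1500 bp | e-folding of turnover along the gene body |
| `arrest_program_tau` | 12 min | relaxation of the arrest program |
| `a_max` | 0.8 | ceiling acetyl fraction |
| `escape_fraction` | 0.05 | HU-arrest leakage (NR condition) |
| `spike_fraction` | 0.04 | spike-in chromatin admixture (3–5% range) |
| `read_depth` | 100 /bin | expected coverage per 200-bp bin |
| genome | 2 × 750 kb, origins every 60 kb | ~24 origin domains |

Fork speed, jitter and the kinetic rates are not measured quantities; they
were chosen once so that the 60-minute window spans early-to-late
replication and the study's qualitative phenomenology (rising calibration
factors, ordered quartile half-rises, a 1–3 minute expression delay that a
turnover ablation removes) emerges at realistic noise levels, and they are
all exposed in `SimConfig`.

Expression values are drawn i.i.d. lognormal but *assigned* to gene
positions by a balanced round-robin across replication-timing strata. On a
real genome (~6000 genes across ~300 origin domains) expression and
replication timing decorrelate by sheer numbers; a toy genome with ~24
domains would otherwise carry a seed-dependent timing confound of the same
size as the turnover delay itself. The balancing emulates the
large-genome regime rather than removing a real covariate.

### Observation model

Input coverage is Poisson with mean `read_depth` per bin; IP coverage is
Poisson with mean `read_depth · (A + β)/(A_ref + β)` (`β = 0.05`
non-specific background, `A_ref = a_max`). The spike genome has a constant
acetyl level (0.5) in every sample and contributes `spike_fraction` of the
expected input reads. Because the generator holds per-sample depths fixed,
the calibration factor `k` acts here as a read-out of the global acetyl
trend relative to the constant spike rather than as a correction for
library-size normalization; it consequently amplifies the global trend in
enrichment units, which is harmless to every row-centered, rescaled or
rank-based statistic downstream.

## Analysis decisions

* **Enrichment instead of MACS2.** Track building is a pseudocounted
  IP/input ratio scaled by `k` — a deliberate, documented substitution for
  MACS2, which keeps the stage exactly invertible and testable.
  Pseudocount 0.5 reads/bin, applied symmetrically.
* **"Moving average 2 kB"** is read as the step of the 15-kb window
  (overlapping windows every 2 kb). Terminal windows that would extend
  past the chromosome end are dropped, not truncated, so every window
  averages the same width. Windowing precedes the log2 transform.
* **Detrending** divides by the fitted polynomial (default degree 2;
  subtraction available behind a flag) — division preserves positivity for
  the log2 stage. Division-mode detrending is idempotent on the fitted
  component: means lying exactly on a polynomial of the chosen degree are
  flattened to 1 and stay there; general residuals are reduced, not
  eliminated. The degree and mode are recorded in provenance.
* **Which tracks feed which analysis.** The metaplot series and the
  monotone widening of the origin-proximal region are computed on the
  spike-calibrated course, where the genome-wide rise is the biology being
  measured. The fork-speed growth law is measured on the *detrended*
  heatmap: the global trend otherwise injects time-column offsets into the
  row-centered matrix that lift late-replicating valleys above threshold
  ahead of their time. Detrending is off by default in the pipeline and
  enabled per analysis (`RunConfig.detrend`, CLI `--detrend`).
* **Triangle measurement.** The growth law `width ≈ 2·v·(t − t_fire)` is
  only well-posed around an origin while its region is clear of
  neighbouring domains. Usable timepoints require a ≥13-min lag after
  firing (the 15-kb window support otherwise smears the edges by more than
  the 25% tolerance) and must precede, by ≥8 min, the replication time of
  the inter-domain barrier (the first local maximum of `T(x)` on either
  side). Measurements are pooled over all origins with a usable timepoint
  and summarized by their median.
* **Groupings.** Quartiles are rank-based (equal count, remainder to the
  earliest groups, ties broken by feature id). Length bins are fixed at
  [500,1000), [1000,1500), [1500,2000), ≥2000 bp with <500 bp genes
  excluded. The ARS anchor is the element midpoint; the TSS is the BED
  start for + genes and end−1 for − genes; the first 350 bp of gene bodies
  are excluded in transcription orientation, with partial bins weighted by
  base overlap.
* **Half-rise time** is the earliest time the unit-range-rescaled series
  reaches 0.5, linearly interpolated; it requires a net increase over the
  course and is invariant under affine maps of the series. Rescaling is
  per-series min–max over the whole window including t = 0.
* **Telomere control** uses Spearman rank correlation between firing time
  and `min(position, L − position)`.
* **Coordinates** are 0-based half-open everywhere; bedGraph/BED files are
  written in their native dialect. Binning is fixed-width (200 bp default)
  with length-weighted aggregation; a bin's value is its accumulated
  signal divided by its physical width, so `Σ value·width` equals the
  bedGraph integral exactly and truncated final bins round-trip.

## What the synthetic study does not show

The generator emulates population-level coverage, not reads: no sequence
bias, mappability, fragment-size or MNase digestion structure, no
nucleosome positioning, and no cell-cycle phases beyond the arrest/release
window. Real spike-in calibration also corrects per-sample library scaling
that the generator deliberately holds fixed. Passing tests therefore
demonstrate that the analysis operations are correct and that the method
recovers the phenomenology from data with realistic counting noise — not
that the kinetic parameters are those of real chromatin.

## Numerical notes

* All randomness flows from a single config seed through named
  `SeedSequence` spawns; per-sample rendering seeds are derived by hashing
  (seed, condition, time), and every text artifact is a pure function of
  the configuration (checksums in the run manifest).
* Degenerate inputs: all-zero expression gives a uniform steady state;
  chromosomes shorter than one window contribute zero windows (warning,
  not error); genes shorter than the 5' exclusion are dropped with a log
  entry; a constant series cannot be rescaled and a non-rising series has
  no half-rise — both raise with context.
* Floats are written with 17 significant digits so bedGraph round trips
  are exact.
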