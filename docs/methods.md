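# Methods

This note documents the models, conventions and numerical decisions
behind each stage of `connrep`, and what the synthetic-data tests do and
do not establish about real data.

## Synthetic cohort

The generator emulates a two-session resting-state acquisition at the
parcel level: by default 69 subjects × 2 sessions, TR = 3 s, 120 volumes
per run, 100 parcels.

**Covariance model.** The population inter-parcel correlation matrix is
block-modular: `r_within` (default 0.5) inside each of `n_modules`
(default 5) contiguous modules, `r_between` (default 0.1) elsewhere, unit
diagonal, shrunk minimally toward the identity if ever indefinite.
Subject- and session-specific matrices are drawn hierarchically: each is
a Wishart draw centered on its parent with `df = max(1/sd², P + 2)`
degrees of freedom, rescaled to unit diagonal, so off-diagonal entries
fluctuate around the parent with standard deviation ≈ `subject_sd`
(default 0.05) and `session_sd` (default 0.05) respectively.  `session_sd`
is the knob that drives test–retest variability.  A Wishart draw was
chosen over an additive symmetric perturbation with eigenvalue clipping
because the additive form has spectral norm ~2·sd·√P — about 1.0 at
P = 100 — which exceeds the smallest block-covariance eigenvalues; the
clipped result is then near-singular and the downstream partial
correlations are ill-defined by construction.  The Wishart draw has the
same entrywise scale but is positive definite and well-conditioned by
construction (the achievable entry scale saturates near 1/√P).

**Time series.** White Gaussian noise is given AR(1) temporal structure
per parcel (coefficient 0.4, unit marginal variance) and then spatially
correlated with the Cholesky factor of the session matrix.  AR(1) is the
minimal temporal model that makes band-pass filtering non-trivial; the
lag-0 cross-correlations equal the session matrix exactly, which the
consistency test verifies at T = 10,000 (max error < 0.05).  Series are
scaled to BOLD-like units (baseline 1000, sd 10).

**Nuisance structure.** WM, CSF and a drift signal (smooth AR processes)
are mixed into every parcel with per-parcel loadings ~N(1, 0.3) scaled by
`nuisance_gain` (default 0.5).  The recorded global signal is the parcel
mean plus WM/CSF and unparcellated-tissue components (and a small
independent term): a global signal equal to the *exact* parcel mean would
make post-GSR residuals sum to zero across parcels — an exact rank
deficiency that real whole-brain-mask global signals do not have.

**Motion and spikes.** Motion parameters are mean-reverting random walks
(translation step 0.01 mm, rotation step 2·10⁻⁴ rad, reversion 0.95);
spike-free runs stay far below the FD cutoff.  With probability
`motion_spike_prob` per volume (default 0.02) a coupled artifact is
injected: a persistent 0.6–0.65 mm translation step plus a persistent
intensity level shift of 30 signal-sd on all parcels.  Persistent steps
(rather than transients) make each artifact flag exactly one volume in
both FD and DVARS; successive steps on an axis move its offset back
toward zero so the accumulated excursion respects the 1.5 mm
overall-motion limit.

**What the generator does not emulate:** spatial (voxel-level) structure,
physiological (cardiac/respiratory) waveforms, frequency-dependent
(1/f-like) BOLD spectra, scanner drift nonstationarity, or realistic
between-site variability.  Tests passing on this cohort establish the
correctness and internal consistency of the pipeline machinery, not
empirical claims about any real dataset.

## Quality control

FD_i = |Δdx| + |Δdy| + |Δdz| + 50·(|Δα| + |Δβ| + |Δγ|) with backward
differences and FD₁ = 0; rotations in radians, the 50 mm factor being the
arc-length conversion at an assumed head radius.  DVARS is the RMS
volume-to-volume intensity change across parcels (the package has no
voxel data; DVARS is homogeneous of degree one, so the per-run
mean + 3 SD threshold logic is structurally unaffected).  A volume is bad
iff FD ≥ 0.5 mm or DVARS ≥ its run threshold.

The censoring ladder: (1) overall motion — the range of any translation
column ≥ 1.5 mm or of any rotation column ≥ 1.5° — takes the run
off-study; (2) a run with no bad volumes is used whole; (3) otherwise the
longest contiguous clean interval of at least 5 min (⌈300/TR⌉ volumes) is
used, earliest on ties; (4) otherwise up to 20 bad volumes are scrubbed;
(5) otherwise off-study.  "Overall translation/rotation" as a per-column
range, and the interval-before-scrubbing precedence, are interpretation
choices; the decision function is pure in (FD, DVARS, motion ranges, TR)
and is property-tested against a brute-force interval enumerator.  Per
session the first run is analyzed unless off-study, in which case the
next usable run is taken; subjects without a usable run in each session
are excluded.

## Denoising

Simple set (9): 6 motion parameters, WM, CSF, global signal.  Complex set
(30): 24 motion terms (the 6 parameters, their temporal derivatives,
squares, and squared derivatives), WM and CSF with derivatives, global
signal with derivative.  Derivatives are backward differences with a
leading 0, the same convention as FD.  The 24 + 4 + 2 accounting is the
only split consistent with a 30-column total.

The set is mean-centered and replaced by its principal components, all
components with eigenvalue > 10⁻¹⁰ × the largest being retained — the
purpose is de-collinearization, not dimension reduction, so no variance
cutoff is applied.  The least-squares fit (with intercept — always
included) is estimated on usable volumes only and subtracted at all
volumes.  Band-pass: censored volumes are linearly interpolated from
nearest usable neighbors (edge extension at the boundaries), then a
4th-order Butterworth 0.009–0.1 Hz filter is applied forward-backward
(zero phase); order and band are arguments.  Censored volumes remain
censored downstream.

## Network construction

Pearson correlations on usable volumes, or partial correlations from the
precision matrix Ω = Σ⁻¹ via `partial_ij = −Ω_ij/√(Ω_ii·Ω_jj)`, with no
shrinkage or regularization.  The precision is computed by symmetric
eigendecomposition (guaranteeing a symmetric inverse with positive
diagonal); a covariance with relative smallest eigenvalue ≤ 10⁻¹² is
rejected as numerically singular rather than silently regularized.

**A well-posedness caveat discovered during development:** requiring more
usable volumes than parcels + 1 is necessary but *not sufficient* for
the partial correlation to exist.  Nuisance regression removes up to
K + 1 temporal dimensions, and the 0.009–0.1 Hz band-pass at TR = 3 s
leaves only ≈ 2·BW·T_total ≈ 66 effective temporal degrees of freedom in
a 120-volume run.  With the complex set (31 dimensions) the residual
rank is at most 89, so a 100-parcel covariance is mathematically
singular; even with the simple set the post-filter covariance at 100
parcels is ill-conditioned to the edge of machine precision.
Consequently the package's factorial analyses that cross partial
correlations are demonstrated at parcel counts below the effective rank
(60 parcels in the acceptance script), and partial-correlation cells
that are ill-posed fail loudly with a machine-readable record.

Sign handling: abs (|x|), pos (max(x, 0)), neg (max(−x, 0)).  Weights are
either the sign-handled correlations directly (already in [0, 1]) or the
Fisher route: `Z = √(n − 3 − (p − 2))·atanh(r)` with n the usable-volume
count and p = 2 for Pearson, p = parcel count for partial correlations;
sign handling is applied to Z, then `w = (2Φ(Z) − 1)⁴` with Φ the
standard-normal CDF.  The transform is even in Z, so it must follow the
sign handling; the exponent (4) is an argument.  Binary networks keep the
k = round(d·P(P−1)/2) strongest edges (half-up rounding; cutoff ties
broken toward the smaller (i, j) index, making edge sets deterministic
and nested across densities).  Since |r| → |Z| → w are strictly monotone,
the three representations give identical binary networks — property
tested.

## Graph measures

Conventions follow the standard brain-connectivity-toolbox definitions:
weighted distances on edge lengths 1/w (Dijkstra); binary distances by
BFS; weighted clustering in the Onnela geometric-mean form with weights
rescaled by the network maximum; betweenness by Brandes accumulation
normalized by (P−1)(P−2)/2; nodal efficiency as the global efficiency of
each node's neighbor subgraph.  λ is the mean over finite distances, with
the count of unreachable pairs reported rather than substituted (sparse
binary networks can disconnect).  Global BC is the mean of normalized
nodal BC.  All measures are verified exactly against brute-force path
enumeration on every connected graph with ≤ 5 nodes and 200 random
graphs with ≤ 7 nodes, and weighted routines reduce exactly to binary
ones on unit-weight graphs.

Hub score: +1 each for the top round(0.2·P) by degree/strength and by
betweenness, and the bottom round(0.2·P) by nodal path length and by
clustering (boundary ties broken by node index); hub ⇔ score ≥ 2.

Modularity: Newman's leading-eigenvector algorithm (python-igraph), run
100 times with a random node relabeling per realization (the
implementation does not include a Kernighan–Lin refinement step); the
co-assignment matrix is the fraction of realizations placing two nodes in
the same module.  igraph draws ARPACK start vectors from Python's global
RNG, which is seeded per realization for reproducibility, with a
reseeded retry for occasional ARPACK non-convergence.

Normalization: measure ÷ mean over 30 equivalent random networks — same
node count and exact edge count placed uniformly at random (binary), or
the upper-triangle weight multiset permuted over all pairs (weighted).
Null networks of a graph drawn from the null ensemble itself normalize
to 1 within the sampling band of a single draw,
`3·sd(null)/mean(null)·√(1 + 1/30)` — the correct comparison band, since
the graph under test fluctuates like one draw, not like a mean of 30.

In the pipeline, null seeds derive from (subject, strategy) but not the
session: the binary null depends only on size and density and the
weighted null permutes each session's own weights, so sharing the seed
across sessions is statistically neutral, while guaranteeing that
bit-identical sessions give exactly zero TRT for normalized measures.
Modularity seeds derive from (subject, session), so pSI retains
realization randomness.

## Reproducibility statistics

TRT = 100·|m₂ − m₁|/((m₁ + m₂)/2); Hc is the Dice overlap of hub sets;
pSI_i = (Σ_j P₁(i,j)·P₂(i,j))²/(Σ_j P₁(i,j)·Σ_j P₂(i,j)), computed per
node; the squared numerator is the reading under which identical
deterministic partitions give exactly 1.  0/0 cases (both measures zero;
both hub sets empty) are reported as missing with a warning rather than
forced to 0 or 1.

## Statistical comparison

Because graph-measure TRT values are generally not normally distributed,
strategies are compared with the aligned rank transform: for each effect
of a complete within-subject factorial design, the response minus all
fitted effects except the one of interest (including the additive
subject block) is ranked (average ties) and a balanced factorial ANOVA
with a subject block is run on the ranks; only the effect of interest is
read off.  With S subjects and a complete a×b design the error degrees
of freedom are N − 1 − (S − 1) − Σ effect dof — 204 for 69 subjects in a
2×2 design.  Under a simulated null the per-effect type-I error at
α = 0.05 is nominal (verified at 500 replicates).  Alignment is linear,
so F statistics are invariant to positive affine changes of the response
units — but not to general monotone transforms, since alignment precedes
ranking on the raw scale.  Incomplete subjects (e.g. a failed grid cell)
are dropped listwise with a warning before the ANOVA.  Pairwise
comparisons use the Wilcoxon signed rank test (zero differences dropped,
T+ reported, exact null distribution up to n = 25 and the
continuity-corrected normal approximation beyond); p-values are
Bonferroni-corrected over the four graph measures.

## Analyses

* **1a** (binary): denoising (simple/complex) × correlation
  (Pearson/partial), absolute values, densities 5–40%, one ANOVA per
  density and measure.
* **1b** (weighted): the same two factors × weight scheme (raw vs.
  Fisher-Z/Φ).
* **2** (weighted, simple denoising, raw weights): sign handling
  (abs/pos/neg) × correlation.
* **3**: parcellation granularity, Wilcoxon tests on the session-1
  normalized measures, Pearson only (partial correlations are infeasible
  when the parcel count approaches the usable-volume count).

The analysis ordering is encoded as defaults, not hard-wired: any grid
cell can be run independently.  Every output is deterministic given the
configuration and seed (per-cell seeds are derived by hashing the base
seed with the strategy descriptor).

## Problem sizes in the shipped runs

The acceptance script uses 12 subjects — binary-density and weighted
Pearson quantities at 100 parcels, factorial analyses at 60 parcels (see
the well-posedness caveat above); the test suite exercises cohorts of
3–20 subjects at 20–100 parcels.  These sizes were chosen so a full run
completes in minutes on a single CPU while keeping every qualitative
contrast (density dependence of binary TRT, weighted-vs-binary stability,
correlation-type effects) clearly resolved.

## Known limitations

* The synthetic cohort's session-to-session variance model is a free
  choice, not an estimate from any real dataset; absolute TRT values
  depend on it, and only the qualitative contrasts should be compared
  across settings.
* DVARS on parcel series underestimates voxelwise DVARS heterogeneity.
* The per-run DVARS threshold (mean + 3 SD) flags ~0.1% of clean volumes
  in spike-free runs by construction; this mirrors real-data behavior.
* No OMST or other topological filtering; no ICC/CV reliability metrics;
  no degree-preserving rewiring nulls (the equivalent-random-network
  definition here is uniform edge placement / weight permutation).
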