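# Methods

## The looping formula

The model assumes most transcription happens in factories — clusters of
TF:pol complexes — and that a promoter's firing probability is dominated by
two configurations: direct binding to a factory, and tethering near a
factory through a loop to its nearest appropriate promoter.  For a promoter
*i* bound with affinity ϵ (in kBT) by one of *n* TF:pols, the unlooped
configuration has Boltzmann weight n·e^{βϵ}·(1 − p(l)) and the looped one
n·e^{2βϵ}·p(l) (two TF:pol–TU contacts), where p(l) is the probability that
the intervening segment of length l is looped.  For a confined chromosome
the fractal globule is the relevant polymer state, with p(l) ≈ a/l.
Dividing the weight sum by the (never-computed) partition function gives

    ptrans(i) ∝ b · (1 + c / l(i)),    b = n·e^{βϵ}/Z,   c = (e^{βϵ} − 1)·a.

`boltzmann_ptrans` exposes this derivation term by term and the test suite
verifies the algebraic identity with the reduced formula to 1e-12 relative
error; `ptrans_formula` is the production path.  Only rank orders and ratios
of ptrans are meaningful.

**Variants.**  In the 1-state model all active promoters are equivalent:
`l` is the distance to the nearest active promoter of any class, and `b`,
`c` cancel from the rank order.  In the 3-state model promoters carry class
weights b_g (genic), b_ng (non-genic), b_o (other), and the loop term always
goes to the nearest *genic* promoter — however far, and never to a
non-genic or other one that might be closer.  A promoter with no other genic
promoter on its chromosome keeps only the unlooped term.

**Parameters.**  `c` defaults to 86 kbp (a measured mean chromatin loop
contour length; the rank correlation is insensitive to `c` across tens to
hundreds of kbp).  The class weights default to 13.1 : 3.3 : 1, the ratios
of mean nascent-transcription signal of the three classes on human
chromosome 14; `estimate_state_weights` recomputes them from any binned
signal track as per-class means normalised to the *other* class.  Because a
promoter's signal carries its own loop factor, the estimator optionally
divides each promoter's signal by (1 + c/l_genic) before averaging; without
that correction the estimates are confounded by proximity to genic
promoters.

**Conventions.**  Coordinates are 0-based half-open; a promoter is the
midpoint of its DHS peak; overlap with a segmentation state is ≥ 1 bp with
precedence genic > non-genic > other; distances are centre-to-centre in bp,
intra-chromosomal only; strand is ignored.  Coincident peak midpoints are
merged upstream because the formula diverges at l = 0.  Ranks are
tie-averaged (1 = highest ptrans), which is what the downstream Spearman
comparison expects.

## Evaluation

A reference ranking is built by scoring each promoter with the value of the
3 kbp signal bin containing it (promoters sharing a bin tie).  Agreement is
reported as Spearman's rho with the large-n t-approximation p-value
(a seeded permutation option exists for small n) flagged against a 1e-6
significance threshold, a 10×10 decile confusion matrix (deciles assigned
by rank position, earlier deciles absorbing remainders), and the decile
agreement ratio — same-decile count over the chance expectation n/10, so 10
for identical deciles and ≈ 1 for independent rankings.  Promoters with
zero signal are kept and tie at the bottom rather than being dropped.

## Synthetic data

`synth_chromosome` draws promoter positions from a homogeneous Poisson
process (default mean spacing 48 kbp ≈ one active DHS per 48 kbp, the
density of human chromosome 14) or as a fixed count of uniform order
statistics, with i.i.d. class labels (default split 0.155/0.421/0.424, the
observed genic/non-genic/other proportions).  Positions are kept at least
one signal bin (3 kbp) apart so every promoter owns its evaluation bin;
this is what makes the σ = 0 closed loop exact (rho = 1) rather than
approximate.  `synth_signal` writes b_state·(1 + c/l_genic)·e^ε into each
promoter's bin with ε ~ N(0, σ²) — multiplicative lognormal noise, chosen
as the simplest strictly-positive, read-count-like noise model.  The
generator emulates the *statistical structure* the formula assumes; it does
not emulate read-level artifacts (mappability, GC bias), signal spreading
across bins, or any violation of the looping model itself, so closed-loop
tests demonstrate internal consistency of the pipeline, not performance on
real data.

## The polymer model

Chromatin is a bead-spring chain (1 bead = 3 kbp, diameter σ = 30 nm)
confined in an ellipsoid; TF:pols are free particles.  Active TF:pols are
attracted to TU beads by a truncated-shifted Lennard-Jones potential with
range r_c = 1.8σ and depth ϵ = 7.1/4.4/3.5 kBT for genic/non-genic/other
TUs (2.7 kBT for acetylated open-chromatin beads); the normalisation
N = 1/(1 + 4[(σ/r_c)^12 − (σ/r_c)^6]) ≈ 1.1288 makes the depth exactly ϵ.
All other pairs are purely repulsive (WCA).  Chain connectivity is a
Kremer–Grest FENE spring (K = 30 kBT/σ², R0 = 1.6σ) and a Kratky–Porod
bending term with κ = 3 kBT sets a ≈ 90 nm persistence length; these
standard values are the package's own choice of chain parameters.
Confinement is a harmonic penalty k(u − 1)² outside the ellipsoid surface
(u the normalised ellipsoidal radius squared, k = 10 kBT) — soft, so
transient violations relax rather than abort.  TF:pols switch between
active (binding) and inactive (non-binding) states at constant rates,
default 0.1/τ each way (mean dwell 10 τ), which lets factories turn over.

**Integration.**  Overdamped Langevin (Euler–Maruyama) in reduced units
(kBT = γ = σ = 1, τ = σ²γ/kBT) with dt = 1e-3 τ and a 0.1σ per-step
displacement cap.  A nominally larger step (e.g. 0.01 τ) gives RMS thermal
displacements of 0.14σ per step, which is unstable against the r^{-12}
core in an overdamped scheme; 1e-3 τ with the cap keeps the
trajectory-average potential energy stable to a few percent under dt
halving (asserted in the tests).  A FENE bond reaching R0 raises an error
naming the bond.  Forces use a Verlet neighbour list (skin 0.5σ, rebuilt
every 5 steps) inside a numba kernel; trajectories are bit-reproducible per
seed.

**Observables.**  Residence ptrans of a TU bead = fraction of sampled
frames with ≥ 1 active TF:pol within r_c (the binding criterion is the
interaction range itself).  Clusters are single-linkage components of
active TF:pols at threshold d_cl = r_c, reported for size ≥ 2 with
centroids.  The peripheral fraction is the fraction of points outside the
half-volume ellipsoid (semiaxes × 2^{−1/3}).

**Toy study conditions.**  The cross-validation study runs a 600 kbp toy
chromosome: 200 beads, 10 TU beads (3 genic / 4 non-genic / 3 other,
positions re-drawn per seed), 10 TF:pols, ellipsoid semiaxes equal to the
full-chromosome territory (22.24 : 34.24 : 41.80 σ) scaled by
(200/35784)^{1/3} so bead volume fraction and aspect ratio are preserved.
Each run is 2×10⁵ equilibration steps followed by 3×10⁵ production steps
sampled every 500 (600 frames over 300 τ), across 8 seeds.  The
equilibration length is set so the chain's density profile in the ellipsoid
reaches steady state (monitored through the bead peripheral fraction)
before sampling begins.  At these sizes the 3-state simulation's residence
ranks correlate positively with the 3-state formula (median Spearman rho
≈ 0.6 over seeds) and beat both a label-shuffled null and the 1-state
simulation compared against the same 3-state formula; attractive TUs
produce significantly larger TF:pol clusters than the ϵ = 0 excluded-volume
control.

**What the toy scale does not show.**  Full-chromosome runs report ≈ 88.5%
of clusters in the outer half of the territory volume.  That behaviour does
not survive the scale-down, and the package does not reproduce it: the
peripheral relocation of factories is driven by many dense clusters
spreading apart entropically within a chromosome-filled territory, whereas
the toy system holds roughly one factory at a time, which tracks the
interior of the locally compacted chromatin blob it bridges.  At the study
conditions the chromatin beads (≈ 0.57) and freely diffusing active
TF:pols (≈ 0.63) do sit outward of the uniform null, but cluster centroids
do not (seed-to-seed range ≈ 0.3–0.7, pooled below 0.5) — compounded by
the fact that the centroid of a cluster hugging the strongly curved toy
boundary lies inward of its member particles.  The peripheral-volume
accounting itself is therefore verified definitionally (uniform points
→ 0.5 by construction, surface points → 1, centre → 0), and the 88.5%
figure is explicitly out of desk-scale reach.

## Known limitations

* Only two diagrams: no trans contacts, no double loops, one TF:pol colour.
* Absolute rates are out of reach by construction (Z never computed);
  everything downstream is rank-based.
* The 3-state loop rule (nearest genic promoter, however far) is inherited
  as stated; on chromosomes with very few genic promoters most loop terms
  share one anchor and the formula's discrimination comes mostly from b.
* The simulation's TF:pol copy number, diameter and switching rates are
  model choices, not measured quantities; conclusions drawn from the toy
  study are rank-level and sign-level, not quantitative.
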