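# Methods

## The model

`chromodyn` simulates a chromatin fibre as a bead-spring polymer of M beads
of diameter σ (one bead = 3 kbp ≈ 30 nm) together with n spheres of the same
size representing complexes of transcription factors and RNA polymerase
("TFs").  A subset of beads are transcription units (TUs) carrying
high-affinity binding sites; the rest are euchromatin (weak, non-specific
binding) or heterochromatin (non-binding).  TFs switch stochastically
between an active (binding) and an inactive (inert) state.  Everything
downstream — heterogeneous and bursty transcription, emergent correlation
networks, knockout and deletion phenotypes — emerges from the 3D dynamics
alone; there is no biochemical regulatory network and no fitting to data.

### Interaction potentials

All particle pairs repel through the Weeks–Chandler–Andersen potential

    U_WCA(r) = 4 kBT [ (σ/r)^12 − (σ/r)^6 + 1/4 ],  r < 2^(1/6) σ,

zero beyond the cutoff.  Consecutive beads are joined by FENE springs

    U_FENE(r) = −(Kf R0² / 2) ln[ 1 − (r/R0)² ],

with Kf = 30 kBT/σ² and R0 = 1.6 σ (the Kremer–Grest combination: the
bonded pair also feels WCA).  On chains carrying permanent loops all bonds
are harmonic instead, U = Kh (r − R̄)² with Kh = 100 kBT/σ², R̄ = 1.1 σ for
backbone bonds and R̄ = 1.8 σ for loop bonds (numerical stability of tightly
looped chains).  Chain stiffness is a Kratky–Porod term on consecutive
tangent pairs, U = (kBT ℓp/σ)(1 − cos θ) with ℓp = 3 σ, a relatively
flexible fibre.

TF–chromatin interactions use a Lennard-Jones potential truncated and
shifted to zero at the cutoff r_c.  The pair rule is: active TF + TU →
ε = 8 kBT, r_c = 1.8 σ; active TF + euchromatin → ε = 3 kBT, r_c = 1.8 σ;
every other combination (heterochromatin, or an inactive TF) → ε = kBT,
r_c = 2^(1/6) σ, i.e. purely repulsive.  TF–TF pairs are WCA-repulsive:
clustering in this model is entirely bridging-induced, requiring no
binder–binder attraction.

### Dynamics

Each particle follows the underdamped Langevin equation with m = γ = 1 in
reduced units (σ = kBT = 1), making the Lennard-Jones and Brownian times
coincide; time is measured in τ_B = σ²/D.  Mapping to physical units with
T = 300 K, σ = 30 nm and a nucleoplasm viscosity of 10–100 cP gives
τ_B ≈ 0.6–6 ms.  Under that mapping the switching rate α = 10⁻⁵ τ_B⁻¹ reads
either ~0.001 s⁻¹ (using the slowest mapping) or 0.017–0.17 s⁻¹ (using the
range); the code works purely in τ_B and reports both mappings here without
resolving the discrepancy.

Integration uses a BAOAB splitting of velocity-Verlet: half-kick,
half-drift, an exact Ornstein–Uhlenbeck step (friction + Gaussian noise,
one noise vector per particle per step), half-drift, half-kick, with
Δt = 0.01 τ_B.  BAOAB keeps both configurational averages and the kinetic
temperature accurate at this step size; the test suite verifies
equipartition to 2%, the Boltzmann variance of a stiff harmonic bond to
15%, and the persistence length of a phantom chain.

TF switching is attempted every 100 τ_B (10,000 steps).  An active TF
deactivates with probability α_off·100 and an inactive one activates with
probability α_on·100.  Toy mode uses α_on = α_off = 10⁻⁵ τ_B⁻¹ (half the
TFs active on average); whole-chromosome mode uses α_on = α_off/4 (20%
active on average).

### Transcription read-out

A TU is transcribed at a sampling instant iff at least one **active** TF
centre lies within r_c = 1.8 σ of the bead centre.  Inactive TFs never
count: they are non-binding, and transcription in this model is TF
association.  Activity is the fraction of sampled instants transcribed;
sampling occurs every 100 τ_B, aligned with switching attempts.  In
whole-chromosome mode the same rule can be evaluated for every bead.

## Study conditions and chosen defaults

* **Toy system**: M = 1000 beads (3 Mbp), N = 39 TUs placed uniformly at
  random, 20 switchable TFs.  The TU linear density matches human
  chromosome 22 (~13 TUs/Mbp).
* **Reference fixture**: the TU placement is frozen at one seeded draw.
  The pinned draw contains TUs at beads 905, 907, 930 and 931, so the named
  perturbation experiments (knockout of bead 930; a non-binding island over
  beads 901–940 embedding four active TUs) apply at their published
  coordinates.  Results are representative of arbitrary random placements.
* **Confinement**: toy simulations run in a sphere of radius 25 σ.  This
  gives a chromatin volume fraction of ~0.8% and a TF concentration of
  ~20 nM under the physical mapping — a dilute, nucleoplasm-like
  environment.  Whole-chromosome runs use an ellipsoidal territory sized by
  `ellipsoid_for_territory` for a ~14% volume fraction (default prolate
  2:1:1 axis ratios, configurable).
* **Warm-up**: every run starts cold from a self-avoiding-biased random
  walk, relaxed by 300 τ_B of push-off under a bounded soft-cosine pair
  repulsion U = A(1 + cos πr/r_c), with A ramped from 2 to 50 kBT over five
  sub-phases.  During push-off FENE bonds are temporarily stout harmonic
  springs (rest length σ), so a transiently stretched bond recovers instead
  of diverging; the engine verifies every backbone bond is below 0.95 R0
  (extending the push-off if needed) before enabling the FENE form.
  Push-off is followed by equilibration under the full force field (default
  10³ τ_B before recording), a length chosen from an explicit stationarity
  check: windowed mean activity from a cold start is stationary after
  ~10³ τ_B.
* **Neighbour search**: two Verlet half-lists built in one cell-list pass —
  bead–bead pairs at the WCA cutoff and TF-involving pairs at 1.8 σ — with
  a shared 1.3 σ skin, rebuilt when any particle has moved more than half
  the skin.  Cell-list forces are validated against an O(N²) oracle to
  1e−10 relative error.

## Network inference

Each replicate simulation contributes one observation per TU: its
within-run mean activity.  The Pearson correlation of these per-run
activities across the ensemble, with a two-sided Student t-test
(t = r√((n−2)/(1−r²)), n = number of runs), defines edges: |r| > 0.15 with
p < 10⁻⁶ for the toy system, r > 0.12 (positive only) for whole-chromosome
networks.  This run-level design is internally consistent: r = 0.15 at
n ≈ 1000 runs gives p ≈ 10⁻⁶ and r = 0.12 at n = 800 gives p ≈ 7·10⁻⁴,
exactly the paired thresholds used — whereas within-run sample counts
(≥10³ per run) would give far smaller p at those r.  Constant activities
yield undefined correlations, which are recorded as missing and never form
edges.

Graph statistics: the percolation measure is the fraction of nodes in the
largest connected component; the small-world coefficient is
s = (C/C_rand)/(L/L_rand) against degree-preserving double-edge-swap
randomisations; the degree survival function is fitted by a shifted
maximum-likelihood exponential (rate 1/(mean degree − 1) on nodes of degree
≥ 1) with a KS goodness-of-fit statistic; modularity uses greedy
(Clauset–Newman–Moore) community detection.

## Perturbation analytics

Conditions are compared TU-by-TU with a two-sample, two-sided Student
t-test on per-run activities (equal-variance by default, Welch optional).
No multiple-testing correction is applied internally; significance
thresholds are report-time parameters.  The global "transcriptional
difference" is the Euclidean distance between mean activity vectors; when a
TU has been mutated it is excluded from the distance so the statistic
isolates trans effects (a flag restores inclusion).  Knockout sweeps share
per-run seeds between wild type and mutants for variance reduction.
Deletion analyses report Manhattan series (−log10 p against genomic
position) and QQ series with expected quantiles from uniform order
statistics (k − ½)/n — the normal-theory null in which activity changes are
pure noise.

## Annotation-driven whole-chromosome mode

Beads are 3 kbp bins (0-based, half-open; the last bin may be short).  The
DHS model classifies a bead as TU if its bin overlaps a DNase-hypersensitive
site by ≥1 bp, euchromatin if it overlaps an H3K27ac peak, heterochromatin
otherwise (DHS takes precedence).  The HMM model assigns each bin its
majority-overlap chromHMM state, mapped through a user-supplied state→class
table (ties break to the lower-coordinate interval).  hg19 chromosome sizes
give 35,784 beads for chromosome 14 and 17,102 for chromosome 22; the
diGeorge deletion (chr22:18,912,231–21,465,672, converted at the parser
boundary from 1-based inclusive) removes wild-type beads 6305–7156,
leaving 16,250.

Comparisons against an experimental signal track use mid-ranks, quintile
joint-count heat maps, and Spearman correlation on the unbinned ranks; a
"patch" mode averages both vectors over contiguous all-TU or
all-euchromatin stretches first.  Hi-C-like contact maps count bead pairs
within 3.5 σ (a reporting choice, exposed as a parameter) pooled into
30 kbp bins, optionally restricted to TU-containing anchor bins; the
contact-probability decay exponent is the log–log least-squares slope of
the mean diagonal between 30 kbp and 1.5 Mbp.

## The synthetic annotation generator

`synthetic_annotation_fixture` emulates the whole-chromosome inputs with no
download: bead classes follow a sticky resampling chain (keep the previous
class with probability 1 − 1/L, else redraw from the target mixture), whose
stationary law is exactly the requested class mixture and whose mean patch
length is the requested patchiness; interval tracks (DHS, merged H3K27ac,
super-enhancers) are emitted from the classes; and the signal track is
coupled to a reference activity through a Gaussian copula whose Pearson
parameter ρ = 2 sin(π ρ_s/6) realises the requested Spearman correlation
without bias.  What it does **not** emulate: real peak-width and signal
distributions, replicate structure, mappability artefacts, inter-chromosome
effects.  Tests passing on these fixtures therefore validate the analysis
pipeline (classification, ranking, correlation recovery), not biological
agreement — the latter requires the real BED/bedGraph inputs the readers
consume.

## Scales used by the shipped tests and the reproduction script

Full-scale protocols (1000 runs × 10⁵ τ_B; whole chromosomes × 244–800
runs) are cluster-scale and ship as config files.  The package's own
checks run the same physics at reduced scale, chosen so the tested effect
is well resolved:

* reproduction script: 10 runs × 10⁴ τ_B of production after warm-up
  (the activity–distance anticorrelation stabilises well within this);
* wild-type test ensemble: 10 runs × 5·10³ τ_B;
* clustering comparison: 10 paired seeds × 10³ τ_B;
* percolation trend: 12 paired runs × 10³ τ_B per TF-number condition, with
  CI-scale edge significance (|r| > 0.15, p < 0.05 at n = 12 runs);
* island/knockout sign checks: 10 paired seeds, identical warm-up to the
  wild-type ensemble, compared over identical 1.2·10³ τ_B production
  windows.

At these scales the qualitative effects (clustering, heterogeneity,
anticorrelation, competition release, percolation loss) are reproduced;
quantities tied to long-time averages (absolute activities, full-scale
correlation magnitudes) remain noisier than in the full protocols.

## Known limitations

* One TF species and a homogeneous fibre; multiple factors or heteromorphic
  fibre states are out of scope.
* Loops are permanent harmonic bonds; there is no loop-extrusion dynamics.
* No hydrodynamics, electrostatics, or explicit RNA kinetics; transcription
  is TF proximity.
* The physical time mapping of τ_B (hence of α) spans an order of
  magnitude, as discussed above.
* The small-world coefficient implemented is the standard C/L ratio against
  degree-preserving nulls; other small-world quantifications exist and may
  differ numerically.
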