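# Methods

## The model

`polybridge` simulates a coarse-grained chromatin fiber — a bead-spring
chain, one 30-nm bead per 3 kb by default — together with diffusing
multivalent protein "factors" (30-nm spheres) that bind reversibly to
cognate beads of matching color. No factor–factor or bead–bead attraction
is specified anywhere. Clustering of bound factors nevertheless emerges
from the bridging-induced attraction: a factor bound to several cognate
beads raises their local concentration, which recruits further factors,
which recruit further beads. The clusters are this model's transcription
factories; the loops they gather produce TAD-like enrichment on the contact
map diagonal and, between distant same-color regions, compartment-like
plaid. A bead is scored as transcribed in a frame when a binding-competent
factor of its color lies within 54 nm of its center.

Factors carry a binding-competence flag that switches on and off at
first-order rates (default 1e-5 per Brownian time each way), modelling
phosphorylation cycles; with equal rates half the factors are competent at
stationarity. Equating the default rate with ~0.001 1/s fixes the physical
time mapping tauB ≈ 0.01 s.

## Dynamics and numerics

Particles follow overdamped Langevin (Brownian) dynamics integrated with
the Euler–Maruyama scheme: `x += (D/kT) F dt + noise(2 D dt)`. Diffusion
coefficients scale inversely with diameter (Stokes), with `D = sigma^2/tauB`
for a fiber bead of diameter `sigma`.

Potentials (nm, kT):

* consecutive beads: harmonic bonds, rest length `sigma`, default constant
  185 kT/sigma^2;
* all particle pairs: soft-core repulsion `E0 (1 - r/contact)^2` with
  `E0 = 50 kT` and the force capped at 1 kT/nm, so overlapping particles
  never produce divergent forces;
* competent factor vs cognate bead: a smooth attractive well
  `-eps cos^2((pi/2)(r - contact)/w)` of depth `eps` (default 7 kT, per
  species) and range `w = 1.8 x` bead radius beyond contact (27 nm);
  binding is implicit — "bound" means the center distance is below
  `contact + w` — so valence emerges from sphere geometry rather than a
  bond list;
* optional harmonic-cosine bending stiffness (default 0: flexible fiber)
  and an optional harmonic spherical wall.

**Timestep and stiffness.** For an explicit overdamped update the stiffest
normal mode of a harmonic chain has eigenvalue `4k`, so stability demands
`4 k D dt < 2`. The pair (k = 185 kT/sigma^2, dt = 0.002 tauB) sits at
~1.5 with headroom for contact stiffness, and gives bond-length
fluctuations of sd ≈ 2.2 nm, which keeps bonds below 1.5x their rest
length at ~7 sigma confidence — soft-bond/large-dt combinations that are
common with inertial Langevin integrators oscillate or let bonds stretch
far past that envelope here, which is why both defaults are set together.
The runtime stability check monitors the deterministic drift only
(thermal noise routinely exceeds half a bead diameter in a single step)
and aborts above two bead diameters; with capped pair forces that
threshold is reached only by genuine divergence.

**Noise.** The fused simulation kernel draws uniform variates scaled by
`sqrt(12) * sqrt(2 D dt)` — zero mean, exact variance `2 D dt` — a standard
device in Langevin engines; Euler–Maruyama's weak order is unchanged for
symmetric moment-matched noise, and every equilibrium observable we test
(free-particle MSD, two-particle Boltzmann occupancy) agrees with theory.
The step-level `bd_step` API uses true Gaussian noise. All randomness
(initial conformation, factor placement, competence, switching events,
noise) derives from the single run seed; switching events are pre-sampled
exactly from the two-state Markov chain's geometric dwell times.

**Neighbor search.** A two-level Verlet list: a counting-sort cell grid
rebuilds the full pair list (interaction cutoff + 60-nm outer skin)
whenever any particle has moved half the outer skin; a cheap scan of that
list refreshes a compact near list (cutoff + 30-nm inner skin) that the
per-step force loop consumes. Pair type, contact distance and attraction
depth are resolved at build time; only competence is checked per step.

**Initial conditions.** The fiber grows as a random walk with overlap
rejection inside the confinement sphere; factors are scattered uniformly;
competence is initialized at its stationary probability. Residual overlaps
relax under the capped soft-core forces during equilibration.

**Confinement density.** The default spherical wall encloses the particles
at a 2% volume fraction — a dilute chromatin solution, the regime where
factor co-localization reflects bridging rather than crowding. (At ~10%
packing, chance proximity alone places a large fraction of factors within
the 60-nm cluster cutoff of one another, swamping the signal the clustering
observables are designed to measure.)

## Observables

* **Clusters**: connected components of factors with center distance below
  60 nm (two touching 30-nm spheres with tolerance); "clusters" are
  components of size >= 2.
* **Contact maps**: fraction of (frame, run) observations with bead
  centers within the capture radius, default 54 nm to match the
  transcription criterion (the 50-nm melt-calculation threshold is the
  analytic default; both are parameters). Diagonal zero by convention.
* **TAD strength**: per block, mean intra-block contact frequency divided
  by the mean over pairs straddling the block boundary *at the same
  genomic separation*, pooled with intra-pair weights — the
  separation-matching removes the global distance decay, so a featureless
  map scores 1.
* **Compartment signal**: same matching applied to same-color vs
  different-color pairs of binding beads at separations >= 100 beads.
* **Transcription profiles**: per binding bead, the fraction of
  observations satisfying the 54-nm criterion; ensemble standard errors
  are taken across run-level means, never frames, because frames within a
  run are autocorrelated.
* **Tethered loop**: a freely-jointed ring of 26 x 30-nm segments (77 kbp
  at 3 kb per segment) anchored at one point on a 75-nm sphere, sampled by
  crankshaft Monte Carlo with the sphere as hard excluded volume; the
  visit probability is the fraction of thinned samples within a 30-nm
  shell of the surface. Only ordering properties (anchor > quarter-point >
  midpoint; mirror symmetry) are asserted — absolute visit frequencies
  depend on the discretization.

## The eQTL experiment

Matched wild-type and mutant ensembles (the mutant string differs by one
bead stripped of its colors) are reduced to per-bead, per-run transcription
means. Each binding bead gets a two-sample Gaussian z-test,
`z = (mean_mut - mean_wt) / sqrt(SE_wt^2 + SE_mut^2)`, two-sided, at
alpha = 0.009 per bead with no multiple-testing correction; instead the
report carries the expected-by-chance count `alpha * n_binding_beads`, and
the null is verified directly by re-running the test on random half-splits
of the wild-type arm. Beads with zero variance in both arms carry no
evidence and get p = 1 (flagged). The mutated bead is reported but excluded
from distal-change counts.

### Scaled study conditions

The acceptance-scale experiment uses a 1000-bead string with five colors at
density 0.04 each (~200 binding beads, so alpha x n ≈ 1.8 < 2 expected by
chance), 20 factors per color with default affinity and switching, a 4%
volume-fraction confinement, and 40 runs per arm of 60 tauB equilibration
plus 40 tauB production sampled every 2 tauB; the mutated bead is the
binding bead nearest the string midpoint. These sizes were fixed once,
after a six-run pilot confirmed the mutated-bead loss (wild-type
transcription probability ~0.7, mutant 0.0) and distal different-color
changes, and not revisited. The factor number is a package choice: few
enough that factories compete for factors, many enough that per-bead
transcription probabilities are measurable.

### Other desk-scale protocols

The clustering contrast runs a 500-bead string (20% cognate, 50 factors,
2e6 steps) against a zero-affinity control (5e5 steps — a non-interacting
gas equilibrates almost immediately); demixing uses ten 250k-step runs of a
block-structured two-color string (alternating 50-bead blocks, 20% cognate
within block, 20+20 always-competent factors). TAD insulation uses three
interior fully-colored 50-bead blocks flanked by non-binding blocks
(350 beads, 30 factors — ten per block, enough that every domain nucleates
a factory) over 350k steps; the compartment run alternates fully-colored
pink/green 50-bead blocks (300 beads, 15+15 factors, 300k steps). The
clustering/demixing/contact-map demonstrations switch competence cycling
off (all factors competent); the eQTL experiment keeps the default
switching.

## What the synthetic generators do and do not emulate

Random strings scatter at most one color per bead (annotation-derived
strings may carry several); block strings emulate the domain structure of
real chromatin-state annotations. Real genomes differ in ways these
fixtures deliberately ignore: state domains have broad length
distributions, binding sites have graded affinities, and factor numbers
fluctuate. Passing tests therefore demonstrate the mechanisms — bridging,
demixing, TAD/compartment emergence, omnigenic perturbation spread — not
quantitative agreement with any particular locus. Comparisons against real
Hi-C require external data and are out of scope; the machinery
(`beads_from_track` + contact maps) accepts any BED-style annotation.

## Known limitations and regime notes

* Factories are dynamic but slow: a factor bridging two or three beads sits
  in an effective 14–21 kT well, so factor exchange at the default 7 kT
  affinity happens on timescales far beyond desk-scale runs. Reversibility
  (no irreversible trapping) is asserted in the single-valent regime
  (isolated cognate sites, 5 kT), where unbinding is observable.
* Color demixing presupposes cognate sites separated along the sequence;
  with different colors randomly interleaved at high density, shared chain
  neighborhoods legitimately co-localize different-color factories, and the
  mixed-cluster fraction rises — that is model physics, not an artifact.
* Blocks at the chain ends show weaker TAD insulation than interior blocks
  (an edge effect); block fixtures for insulation measurements flank
  colored blocks with non-binding chromatin.
* The ideal-chain ("melt") contact calculator takes the Kuhn length equal
  to the fiber diameter (20 nm ⇒ 1 kb per segment); this single choice
  reproduces the 0.1/1/10-Mb contact-probability ladder within a factor of
  ~1.4 and the -3/2 decay exactly. The "fraction dimerized" convention
  (molecules vs complexes) matters at the percent level and both are
  reported.
* Hydrodynamic interactions, loop extrusion, CTCF logic and nuclear
  sub-compartments are out of scope.
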