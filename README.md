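# polybridge

Brownian-dynamics simulation of the **bridging-induced attraction**: a
coarse-grained chromatin fiber (bead-spring chain, one 30-nm bead ≈ 3 kb)
plus diffusing multivalent protein "factors" that bind reversibly to
cognate beads of matching color. Although no protein–protein or DNA–DNA
attraction is specified, bound factors cluster spontaneously — a factor
bridging several binding sites concentrates them locally and recruits more
factors. The clusters behave like transcription factories: they stabilize
loops, carve TAD-like blocks and compartment-like plaid into simulated
contact maps, and define a geometric transcription readout (a bead is
"transcribed" when a competent factor of its color is within 54 nm).

The package is for quantitative chromatin biologists and biophysical
modelers who want to explore how factor-mediated clustering couples the
activity of genes sharing a nuclear neighborhood — in particular the
*omnigenic* consequence that abolishing binding at a single site (an
in-silico eQTL) perturbs transcription of many distant, differently
regulated sites.

## What's inside

| module | contents |
| --- | --- |
| `polybridge.model_core` | genome strings (beads with color sets), factor species, synthetic fixtures, eQTL mutations, BED-annotation binning |
| `polybridge.dynamics` | overdamped Langevin engine (numba kernels, implicit binding wells, phosphorylation switching), force/energy reference implementations |
| `polybridge.observables` | factor clusters, contact maps, separation-matched TAD/compartment statistics, 54-nm transcription profiles, tethered-loop Monte Carlo |
| `polybridge.eqtl` | matched wild-type/mutant ensembles, per-bead Gaussian z-tests, expected-by-chance accounting, null split calibration |
| `polybridge.analytics` | closed-form looping numbers: mass-action dimerization, tether-boosted local concentrations, ideal-chain contact probabilities |
| `polybridge.io`, `polybridge.cli` | plain-text formats (BED, TSV, extended-XYZ frames, JSON manifests) and the `polybridge` command |

## The statistics at the core

Free factors at nuclear concentrations barely dimerize: with
dissociation constant `Kd` and total concentration `T`, mass action
(`2M ⇌ D`, `Kd = [M]²/[D]`) gives a dimer fraction of order 1% at
`T = 1 nM`, `Kd = 10⁻⁷ M`. Tethering two factors to nearby sites raises
the local concentration `c` so the pair occupancy `c/(c + Kd)` reaches
~67% at `c = 2×10⁻⁷ M` — binding sites turn loops from rare to common.
On a fiber modeled as an ideal chain with Kuhn segment `b` (20 nm ⇒ 1 kb),
the probability that two loci `N` segments apart lie within capture
radius `r` is the Maxwell integral

    P = erf(a) − (2a/√π) e^(−a²),   a = r √(3 / (2 N b²)),

which decays as `N^(−3/2)`.

The eQTL pipeline reduces each simulation run to per-bead transcription
means and tests each binding bead with a two-sample z-statistic
`z = Δ/√(SE_wt² + SE_mut²)` on run-level means (two-sided Gaussian p,
α = 0.009 per bead, expected false positives `α·n` reported alongside).

## Worked example

```
$ polybridge analytic melt --sep 1e5
contact_probability=0.0204185 (sep=100000 bp, fiber=20.0 nm, 50.0 bp/nm, capture=50.0 nm)

$ polybridge analytic dimer --kd 1e-7 --conc 1e-9 --tether-bp 10000
dimer_fraction[molecules]=0.0192379 (Kd=1e-07 M, total=1e-09 M)
dimer_fraction[complexes]=0.00971237 (Kd=1e-07 M, total=1e-09 M)
local_concentration=1.56701e-06 M at 10000 bp; tethered_occupancy=0.940012
```

Two loci 0.1 Mb apart touch in ~2% of conformations (the 1-Mb and 10-Mb
values are ~6.8×10⁻⁴ and ~2.2×10⁻⁵, the ideal-chain −3/2 ladder); a lone
factor pair at 1 nM is ~1–2% dimerized depending on whether you count
molecules or complexes, while tethering 10 kb apart drives the same pair
to >90% occupancy.

A minimal bridging simulation:

```python
import polybridge as pb
from polybridge.dynamics import confinement_radius_for_volume_fraction
from polybridge.observables import detect_clusters, fraction_bound_in_clusters

string = pb.generate_random_string(500, ["red"], 0.2, seed=1)   # 500 beads, ~100 cognate
species = [pb.FactorSpecies("red", 50)]                          # 50 bridging factors
field = pb.ForceField(
    confinement_radius_nm=confinement_radius_for_volume_fraction(string, species)
)
cfg = pb.SimulationConfig(n_steps=200_000, seed=1,
                          equilibration_steps=100_000, frame_interval=2500)
traj = pb.run_simulation(string, species, field, cfg)
print(sorted(detect_clusters(traj.frames[-1]).sizes.tolist())[::-1][:5])
print(round(fraction_bound_in_clusters(traj), 2))
```

prints

```
[5, 5, 4, 4, 4]
0.94
```

— by 400 Brownian times the fifty factors have condensed into a handful of
clusters (the largest holding 5 factors), and 94% of bound factors sit in a
cluster of at least two, against ~8% for a zero-affinity control.

The same experiment at the command line, end to end:

```
polybridge fixture --n-beads 1000 --colors 5 --density 0.04 --seed 1 --out fx
polybridge eqtl --config eqtl.yaml --mut-bead 500 --runs 40 --alpha 0.009 --out eqtl_out
```

writes a per-bead differential report (`report.tsv`), an up/down summary by
color, and a JSON manifest with every seed needed to reproduce the outputs
bit for bit.

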