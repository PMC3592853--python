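# clustrack

Single-molecule analysis of membrane-protein cluster dynamics in the
plasma membrane, built around the insulin-regulated glucose transporter
GLUT4 in adipocytes. GLUT4 arrives at the cell surface in ~50 nm storage
vesicles and partitions between freely diffusing monomers and elongated
membrane nanodomains ("clusters") that retain it until it dissociates or
is re-internalized. `clustrack` implements the quantitative pipeline for
photoactivated single-molecule TIRF recordings of this system — and a
ground-truthed synthetic-data generator that makes every stage testable
by parameter recovery.

## What it computes

**Motion classification by MSD confidence envelopes.** For free 2D
diffusion the time-averaged mean squared displacement is linear in the
lag,

```
MSD(t) = 4Dt + C,
```

with D the diffusion coefficient and C = 4σ² the localization-noise
offset. Simulated pure random walks with matched track length, D and
noise give per-lag 95% bands for *individual* MSD curves; a trajectory
whose curve runs above the upper bound for five consecutive lags is
*directed*, below the lower bound *confined*, otherwise *free*.
Confinement size follows from the MSD plateau: for positions uniform in
a disc of radius R, plateau = R² + 4σ², so diameter = 2√(plateau − 4σ²).

**Cluster morphology.** Clusters are defined by residency — one
molecule's localizations staying within a diffraction-limited radius for
≥30 frames. Shape comes from second-moment ellipses (semi-axis a = 2√λ
for a uniform ellipse, with σ² subtracted from each covariance
eigenvalue before conversion) and from circularity 4πA/P² of the
region's alpha-shape outline.

**Bleaching-corrected dwell-time kinetics.** A clustered molecule is
lost to the first of three first-order processes, so the observed
exponential loss rate is

```
K(p) = p·K_b + K_d + K_e,
```

where p = t_exp/t_int is the relative exposure. Recording at constant
200 ms exposure with intervals 0.2/0.5/1/2 s (p = 1, 0.4, 0.2, 0.1) and
extrapolating the linear fit to p → 0 removes photobleaching; an
ATP-depletion branch (endocytosis off, K_e = 0) isolates dissociation,
and the difference of intercepts gives the endocytosis rate. The
association rate follows from the cluster/monomer equilibrium, and the
area-conservation relation D_cluster = 2·D_GSV connects cluster size to
the fused vesicle's membrane area.

**Exocytosis.** Fusion events are detected as transient reporter-channel
flashes (fusion-pore opening) and classified as fusion-with-dispersal or
fusion-with-retention from the cargo channel's 1 µm ROI response.

## Worked example

```python
import numpy as np
from clustrack import msd
from clustrack.localize import Trajectory, filter_trajectories, tracks_from_table
from clustrack.sim import make_scenario, make_schedule, simulate_trajectories

scenario = make_scenario("basal", n_molecules=150, seed=5)   # K_d=0.12, K_e=0.57 min⁻¹
schedule = make_schedule(t_exp=0.2, t_int=0.2, n_frames=300)
loc, truth = simulate_trajectories(scenario, schedule, 5)

tracks = filter_trajectories(tracks_from_table(loc), min_points=30)
fit = msd.fit_linear_msd([msd.compute_msd(t) for t in tracks])
classes = msd.classify_tracks(tracks, scenario.d_free, scenario.sigma_loc, seed=42)
fractions = msd.population_fractions([classes])
print(f"pooled D = {fit.d_um2_s:.3f} um^2/s")
print(f"confined fraction = {fractions['confined']['mean']:.2f}")
```

prints

```
pooled D = 0.043 um^2/s
confined fraction = 0.55
```

— the pooled D over *all* tracks is pulled well below the free-monomer
value by the confined population, and about half the trajectories
classify as confined, as expected for the basal state where ~48% of the
transporter sits in clusters. Restricting the fit to the tracks
classified free recovers D = 0.089 µm²/s, the monomer diffusion
coefficient (ground truth 0.092).

The same stages run from the shell:

```
clustrack simulate --preset basal --schedule 200ms/0.5s --frames 600 --seed 7 --out out/
clustrack track out/localizations.csv --min-points 30 --out out/tracks.csv
clustrack classify out/tracks.csv --envelope-reps 1000 --seed 7 --out out/classes.csv
clustrack clusters out/localizations.csv --residency 30 --probe-radius 50 --out out/clusters.csv
clustrack kinetics --preset basal --protocols 0.2,0.5,1,2 --seed 7 --out out/kinetics.json
clustrack run --config run.yaml
```

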