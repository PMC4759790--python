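# burstswitch

Stochastic models of translational bursting in a genetic toggle switch,
spanning the full model hierarchy from individual-molecule simulation to
coarse-grained analytics:

* **Discrete Gillespie engines** — `FM` (mRNA + protein), `GB`
  (geometrically distributed protein bursts), `CB` (constant bursts),
  `NB` (single proteins at a B-fold rate).
* **Diffusion approximation** of the GB model (`DA-GB`): Kramers–Moyal
  drift/diffusion coefficients and an Euler–Maruyama integrator.
* **Piecewise deterministic Markov process** (`PDMP`): three discrete
  mRNA modes with deterministic concentration flow, plus its shot-noise
  limit (`PDMP-SN`) with exponential concentration bursts.
* **First-passage analysis** — Monte-Carlo mean first switching times
  (MFST) to the symmetric boundary x = y for every engine, and a
  finite-difference solver for the shot-noise backward equation on the
  half-plane x > y (self-consistent: no boundary condition imposed).
* **Quasi-potentials** — WKB Hamiltonians for the shot-noise PDMP and
  the diffusion approximation, minimized-action computation by a
  geometric minimum action method, and `exp(-S0/b)` surfaces as
  weak-noise stationary-distribution estimates.
* **Summary statistics** — time-weighted stationary histograms on a
  shared protein-number binning, Jensen–Shannon distances, mode
  detection, and B/K parameter sweeps.
* A **three-way switch** variant (mutual repression plus positive
  autoregulation) is supported by every engine via the `lu_threeway`
  preset.

Two parameter presets ship with the package: `ecoli_table1` (the E. coli
toggle-switch estimates; B = 30 molecules per mRNA, K = 200, so the
concentration-scale mean burst size is b = B/K = 0.15) and
`lu_threeway`.

## Library quick start

```python
import burstswitch as bs

params = bs.get_preset("ecoli_table1")
traj = bs.simulate("GB", params, t_end=100.0, seed=1)

hist_fm = bs.stationary_histogram("FM", params, t_burn=50, t_total=5050, seed=2)
hist_sn = bs.stationary_histogram("PDMP-SN", params, t_burn=50, t_total=5050, seed=3)
print(bs.js_distance(hist_fm, hist_sn))

from burstswitch.first_passage import mfst_monte_carlo, solve_backward_fd
mfst = mfst_monte_carlo("PDMP-SN", params, [(371, 89)], n_rep=500, seed=4)
surface = solve_backward_fd(params, xmax=4.0, n=321, richardson=True)

from burstswitch.wkb import pdmp_hamiltonian, minimize_action
ham = pdmp_hamiltonian(params)
res = minimize_action(ham, (1.855, 0.443), (3.0, 0.25))
```

## Command line

The console script `burstswitch` exposes the main experiments; every
run writes plain tab-separated outputs plus a `manifest.json` echoing
the fully resolved configuration.

```bash
burstswitch simulate --engine GB --preset ecoli_table1 --t-end 100 --seed 1 --outdir out/
burstswitch stationary --engine PDMP-SN --t-total 2000 --outdir out/
burstswitch compare --engines GB,CB,NB --t-total 2000 --outdir out/
burstswitch mfst-mc --engine PDMP-SN --n-rep 200 --outdir out/
burstswitch mfst-fd --n 201 --outdir out/
burstswitch wkb --hamiltonian pdmp --grid-n 9 --outdir out/
burstswitch sweep --axis B --values 5,10,30 --outdir out/
burstswitch fixture trimodal_hist --outdir out/
```

Parameters can also come from a JSON/YAML config file
(`--config params.json`) whose keys match the `ModelParams` fields; a
`preset` key selects a base preset to override.

## Conventions worth knowing

* Time is measured in cell cycles, protein counts in molecules;
  continuous engines work in concentrations x = N/K and are reported on
  the shared 1-molecule binning via N = K·x.
* Histograms are time-weighted (discrete engines exactly, continuous
  engines sampled on a regular time grid), burn-in defaults to 50
  cycles.
* Switching is defined as reach-or-cross: the first time N_Y >= N_X
  (bursts may overshoot the diagonal). Right-censored Monte-Carlo
  replicates are reported separately, never averaged in.
* Identical (seed, parameters, initial condition) triples reproduce
  trajectories bit-for-bit.
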