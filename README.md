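# fbmotility

Agent-based stochastic simulation of single-cell migratory persistence.

Cell trajectories recorded in vitro are rarely the memoryless random walks
that classical motility models assume: the machinery that sustains directed
motion — lamellipodia, adhesion complexes, polarity cues — persists over
finite timescales and correlates successive displacements. `fbmotility`
models an isolated migrating cell as a self-propelled particle whose
displacement noise is **temporally correlated** (an increment process of
fractional Brownian motion, with the Hurst index *H* setting the memory
strength) and whose heading undergoes **angular diffusion** (coefficient
*D<sub>r</sub>*), optionally biased toward an organizing center (strength
*f*<sub>tax</sub>). It is written for biophysicists and modelers who want
to explore how intrinsic memory and reorientation jointly shape
persistence, anomalous diffusion, and responsiveness to guidance cues.

## Model

Position and heading of each cell evolve per timestep Δt as

```
F_m p̂ = γ_s dx/dt − α dW^H/dt            (force balance; p̂ = (cos θ, sin θ))
dθ/dt = sqrt(2 D_r) dW^{H_θ}/dt − f_tax · arccos(v_org · p̂ / ‖v_org‖)
```

where `W^H` is fractional Brownian motion with Hurst index H ∈ (0, 1) —
H = 0.5 is uncorrelated (Wiener) noise, H > 0.5 gives persistent,
positively correlated increments — synthesized exactly per component by
Davies–Harte circulant embedding; the angular noise is white
(H<sub>θ</sub> = 0.5); and the guidance term (zero unless a taxis cue is
configured) rotates the heading toward the organizing center x_org.
Defaults follow the reference protocol: F_m = γ_s = 1, α = 0.25, Δt = 0.1,
1000 steps.

The statistics suite computes, per trajectory and per ensemble:

* persistence factor `PF = ‖x_f − x_0‖ / Σ_i ‖x_{i+1} − x_i‖ ∈ [0, 1]`,
* relative turning angle `θ_R = π − arccos((a² + b² − c²)/2ab) ∈ [0, π]`,
* per-step increment magnitudes and the initial noise–heading alignment,
* ensemble MSD `⟨‖x(t) − x_0‖²⟩` with subsampling and a log–log power-law
  exponent (ballistic = 2, diffusive = 1, super/sub ≷ 1).

See `docs/methods.md` for assumptions, parameter rationale and numerical
choices.

## Worked example

```python
import fbmotility as fm

params = fm.MotilityParams(H=0.75, Dr=0.1, alpha=0.25)
traj = fm.run_simulation(params, seed=7)
stats = fm.trajectory_stats(traj)
print(f"persistence factor : {stats.persistence_factor:.3f}")
print(f"total distance     : {stats.total_distance:.1f}")
print(f"net displacement   : {stats.displacement:.1f}")
print(f"mean increment     : {stats.mean_increment:.4f}")
print(f"mean turning angle : {stats.mean_relative_angle:.4f} rad")
print(f"initial alignment  : {stats.initial_alignment:+.4f}")

ens = [fm.run_simulation(params, seed=s, replicate_id=s) for s in range(100)]
curve = fm.ensemble_msd(ens, sample_size=100, seed=0)
exp = fm.msd_scaling_exponent(curve)
print(f"MSD(100)           : {curve.values[-1]:.0f}")
print(f"MSD exponent       : {exp:.2f} ({fm.classify_diffusion(exp)})")
```

prints

```
persistence factor : 0.291
total distance     : 110.7
net displacement   : 32.3
mean increment     : 0.1107
mean turning angle : 0.4465 rad
initial alignment  : +0.0673
MSD(100)           : 2155
MSD exponent       : 1.40 (superdiffusive)
```

This cell covered 110.7 length units of path but netted only 32.3 (PF 0.29):
moderate correlation (H = 0.75) inflates the mean step above the noise-free
0.1, while even weak reorientation (D<sub>r</sub> = 0.1) erodes
straightness. Over 100 replicates the ensemble MSD grows with exponent
1.40 — faster than diffusive, slower than ballistic — the signature regime
of correlated translational noise competing with angular diffusion.
Deterministic controls (D<sub>r</sub> = 0, α = 0) travel exactly 100 units
in a straight line (PF = 1, MSD ∝ t²).

## Command line

```sh
fbmotility simulate --H 0.75 --Dr 0.1 --seed 7 --out traj.csv
fbmotility metrics  --traj traj.csv --out stats.csv
fbmotility msd      --traj traj.csv --out msd.csv
fbmotility sweep    --preset main --out-dir results/main     # 16 cells x 200 reps
fbmotility sweep    --preset taxis --out-dir results/taxis   # 48 cells x 100 reps
```

Outputs are plain CSV (trajectories: `replicate,step,t,x,y,theta`;
summaries and MSD curves per parameter cell) plus a JSON manifest recording
every parameter and seed; reruns with the same base seed are
byte-identical.

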