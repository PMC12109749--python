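# dnabow

Analysis toolkit for **sharply bent DNA amplifying sensors** ("DNA bows"):
30-bp duplexes held at a ~160° bend, whose mechanical instability amplifies
the effect of stabilising agents such as Mg²⁺ ions.  The package implements
the complete quantitative read-out chain used to characterise these sensors —
structural metrics over (simulated) trajectories, melting-curve melting-point
extraction, and FRET proximity-ratio dose–response — together with a
synthetic bent-duplex generator with known ground truth, so that every
analysis stage is testable without archived MD runs or wet-lab data.

It is aimed at biophysicists and sensor developers who want reproducible,
scriptable versions of these analyses with explicit geometric criteria.

## What it computes

**Trajectory metrics** (duplex: strand B residues 1–30, complement 31–60,
pair *i* = residues (*i*, 61−*i*)):

- **RMSD / RMSF** — least-squares (Kabsch) superposition; RMSF by the
  two-pass procedure: align every frame to the last frame, average, re-align
  to the average, then RMSF_i = √⟨|r_i − ⟨r_i⟩|²⟩.
- **Base-pair distances** — ΔC6 (C6–C6 distance of the paired bases,
  ≈ 6.4 Å in intact B-DNA) and ΔWC (purine N1 to pyrimidine N3, ≈ 2.9 Å),
  with trailing-window per-pair profiles and molecule means.
- **Hydrogen bonds** — geometric detection with donor–acceptor ≤ 3.0 Å,
  D–H⋯A within 20° of linearity, polar atoms N/O/S/F; per-pair counts,
  101-frame smoothing, ⟨N_hb⟩ and its distribution over pairs.
- **Ion shells** — per-species counts within 5 Å of any DNA atom, the net
  shell charge Q5 = 2N_Mg + N_Na − N_Cl, per-ion residence times Tn5, and
  persistent Mg–P contact distances.

**Melting curves** — dA/dT by central differences, then a Gaussian (plus
constant baseline) peak fit; Tm is the fitted centre.

**FRET** — proximity ratio E_PR = F_A / (F_A + F_D) from the acceptor
(670 nm) and donor (570 nm) emission intensities, dose–response tables, and
the cross-method sensitivity metric δ(c) = (Q(c)/Q(0) − 1) × 100%.

**Synthetic generator** — builds a bent B-form duplex of the sensor's
printed sequence (bend angle, rise, twist configurable; Watson–Crick pair
geometry assembled from ideal nucleotide coordinates), then simulates
per-residue Gaussian fluctuations, telegraph-process base-pair opening with
frayed ends, an end-to-end chord constraint emulating the virtual spring
between the C6 atoms of residues 2 and 29, and diffusing Na⁺/Mg²⁺/Cl⁻ ions
with exponential bound residence on phosphates.  All generators are pure
functions of their spec, including the seed.

## Worked example

```python
import numpy as np
from dnabow import (
    TrajectorySimSpec, IonSpec, simulate_trajectory,
    delta_c6, residue_profile, molecule_mean,
    mean_hbonds_per_bp, shell_series,
)

spec = TrajectorySimSpec(
    n_frames=300, dt_ns=0.1,
    ions=(IonSpec("MG", 20, bound_fraction=0.5),
          IonSpec("NA", 10), IonSpec("CL", 10)),
    seed=42,
)
traj, truth = simulate_trajectory(spec)

series = [delta_c6(traj, p) for p in traj.topology.pairs]
print("molecule <dC6>:", round(molecule_mean(residue_profile(series)), 2), "A")
_, nhb = mean_hbonds_per_bp(traj)
print("<Nhb> trailing:", round(nhb, 2))
print("Q5 trailing:", round(shell_series(traj).trailing_means()["Q5"], 1))
```

prints

```
molecule <dC6>: 6.89 A
<Nhb> trailing: 0.59
Q5 trailing: 9.2
```

i.e. under the generator's default (destabilised, frayed-end) condition the
bow sits above the intact-B-DNA ΔC6 of ~6.4 Å, thermal jitter plus base-pair
opening strips it to ~0.6 hydrogen bonds per pair (an intact duplex of this
sequence would show ~2.43), and the bound Mg²⁺ ions neutralise Q5 ≈ 9 of the
duplex's 58 backbone charges.  Dropping the fluctuation amplitudes and open
probabilities (the stabilised, high-Mg²⁺ regime) drives ΔC6 toward 6.4 Å and
⟨N_hb⟩ toward the intact value.

A YAML-driven CLI covers the same stages end to end
(`dnabow generate | analyze-traj | melt | fret | report`); every run writes
a manifest with per-file SHA-256 checksums and is deterministic given
config + seed.

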