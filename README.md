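# vazcycle

Kinetic modelling of the violaxanthin (VAZ) xanthophyll cycle and its role in
non-photochemical quenching (NPQ) and photoprotective memory, in the style of
the *Nannochloropsis oceanica* system.

## The science

Under excess light, photosynthetic organisms dissipate absorbed energy as
heat (NPQ, measured here as the lifetime-based quantity NPQ&tau;).  In
*N. oceanica* this protection is built from two coupled layers:

1. **The xanthophyll cycle.** A pool of violaxanthin (V) is enzymatically
   de-epoxidized via antheraxanthin (A) to zeaxanthin (Z) in high light
   (V &rarr; A &rarr; Z, catalysed by violaxanthin de-epoxidase, VDE) and
   slowly epoxidized back in darkness (Z &rarr; A &rarr; V).  VDE itself
   activates and deactivates with the light, so the pool composition
   integrates the recent light history.
2. **Protein-bound quenching.** A small pool of quenching-competent
   light-harvesting proteins (P, the LHCX1-dependent sites) reversibly binds
   any of the three xanthophylls (P + X &#8652; PX).  In the light, a bound
   complex can convert into an actively quenching conformation
   (PX &#8652; QX) with a xanthophyll-specific equilibrium; in darkness the
   quenching conformation is strictly inaccessible.  Free zeaxanthin itself
   contributes a weak, slow quenching channel ("qZ") with rate ratio
   r<sub>qZ</sub> relative to the protein channel.

NPQ&tau; is the sum of the quencher populations plus the qZ term, in reduced
units where concentrations absorb the (unidentifiable) absolute quenching
rate and fluorescence lifetime:

```
NPQ_tau(t) = Δ[QV] + Δ[QA] + Δ[QZ] + r_qZ · Δ[Z]
```

Because Z both quenches weakly on its own *and* forms the strongest protein
quencher (capacity q<sub>Z</sub> = 0.92, versus 0.28 for A and 0.10 for V),
zeaxanthin left over from an earlier light exposure lets the cell restore
quenching within seconds of re-illumination: a **photoprotective memory**
whose timescale is set by the slow A &rarr; V epoxidation step
(&#8764;1/k<sub>AV</sub> &asymp; 20 min).

The package implements:

- the 12-state mass-action model (`vazcycle.model`) with a numba-compiled
  right-hand side, an adaptive (LSODA) and a fixed-step RK4 integrator, an
  algebraic dark steady state, and genotype knockouts (`vde`, `lhcx1`,
  `vde_lhcx1`);
- observables (`vazcycle.observables`): NPQ&tau; with its channel
  decomposition, fluorescence lifetimes, and HPLC-style pigment totals;
- two-stage constrained fitting with multi-start least squares, pattern
  search and bootstrap uncertainty (`vazcycle.fitting`);
- memory analyses (`vazcycle.memory`): dark-interval recovery scans, the
  memory timescale, the steady-state partition of NPQ&tau; and a quencher
  stoichiometry estimate;
- synthetic data generators and a full parameter-recovery experiment
  (`vazcycle.synth`);
- CSV/YAML I/O and a `vazcycle` command line (`vazcycle.io`,
  `vazcycle.cli`).

## Worked example

```python
import numpy as np
import vazcycle as vz

params = vz.reference_parameters()

# Simulate a light-dark-light sequence and compute NPQ_tau
protocol = vz.parse_protocol("5HL-9D-5HL")
traj = vz.simulate(protocol, params)
trace = vz.npq_trace(traj, params)
for t in (5.0, 14.0, 19.0):
    print(f"NPQ_tau at t = {t:4.1f} min: {np.interp(t, trace.times, trace.npq):.3f}")

# Memory: recovery after a dark interval, and its timescale
scan = vz.recovery_scan(params)
tau = vz.memory_timescale(scan)
print(f"recovery after 9 min dark: {scan.recovery[scan.T_values.tolist().index(9.0)]:.2f}")
print(f"memory timescale: {tau:.1f} min")

# Steady-state partition of NPQ_tau between quenching channels
part = vz.steady_state_partition(params)
print("steady-state partition:",
      ", ".join(f"{k} {100*v:.1f}%" for k, v in part.items()))
```

Output:

```
NPQ_tau at t =  5.0 min: 0.245
NPQ_tau at t = 14.0 min: 0.024
NPQ_tau at t = 19.0 min: 0.486
recovery after 9 min dark: 0.52
memory timescale: 23.2 min
steady-state partition: qE_V 0.2%, qE_A 1.5%, qE_Z 75.2%, qZ 23.0%
```

Note the memory effect: after 9 min of darkness NPQ&tau; has relaxed almost
to zero (0.024), yet the second exposure reaches roughly half of the
first-exposure quenching within its first minute, and ends higher (0.486)
than the first exposure did (0.245) because zeaxanthin kept accumulating.

The same workflows are available from the command line:

```sh
vazcycle simulate --protocol 5HL-9D-5HL --out npq.csv
vazcycle synth    --protocol 5HL-9D-5HL --seed 1 --out data.csv
vazcycle fit      --npq data.csv 5HL-9D-5HL --out fit --bootstrap 200
vazcycle scan-memory --out scan.json
vazcycle partition
vazcycle knockout --genotype vde --protocol 10HL --out vde.csv
```

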