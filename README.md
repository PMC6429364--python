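# mtbinder

Analysis toolkit for the electrostatics-guided association of a dynein
**microtubule-binding domain (MTBD)** with a microtubule segment carrying
the disordered, acidic C-terminal tails of tubulin (**E-hooks**).  It is
aimed at structural/computational biophysicists who want to reproduce this
style of analysis — distance-offset model building, contact statistics,
fluctuation analysis, conformational clustering, MM/GB binding-energy
decomposition and continuum electrostatics — as a tested, scriptable
pipeline, exercised end-to-end on synthetic ensembles with planted,
recoverable statistics.

## What it computes

Given a binder–filament–tail complex (read from PDB/PQR or generated
synthetically) and conformational ensembles (multi-model PDB, DCD, or the
built-in generator):

- **Model building** — extended Cα-trace construction of tail sequences
  (α: `VGVDSVEGEGEEEGEEY`, β: `DATADEQGEFEEEGEEDEA`), rigid transforms,
  the perpendicular-offset protocol d ∈ {0, 5, 15, 25, 35, 45, 55} Å,
  deterministic clash relief, and fixed-pKa ionization at pH 7
  (Asp/Glu −1, Lys/Arg +1, His 0).
- **Contacts** — heavy-atom pair events within 4 Å between tails and
  binder, per frame / per residue / per segment (H1–H6, LH1, LF, flap),
  with percentages `100·count/Σcount` and replicate-mean time series.
- **Fluctuations** — Kabsch superposition, RMSD, per-residue Cα RMSF about
  the ensemble mean, the residue-averaged RMSF
  `RMSF = Σᵢ RMSFᵢ / N_res`, and linear fits of RMSF against offset
  distance and against total contacts.
- **Clustering** — Daura (GROMOS-style) RMSD clustering (cutoffs 2.0 Å
  for the domain, 1.5 Å for tails), top-k populations and representatives,
  and bound/free cross-state RMSD matrices with flagged minima.
- **Energetics** — MM/GB energies `E = E_elec + E_VDW` (Coulomb +
  Still-function generalized Born with HCT radii and Debye screening;
  12-6 Lennard-Jones) and the rigid-body binding protocol
  `ΔE = E_complex − E_MTBD − E_MT` averaged over contact-bearing
  snapshots, with and without tails.
- **Electrostatics** — a finite-difference linearized Poisson–Boltzmann
  solver (2 grids/Å, perfil 70, ε 2/80, I = 0.15 M) with potentials in
  kT/e, surface-potential sampling and field-line tracing.

## Worked example

```python
import numpy as np
from mtbinder import (SyntheticSystemSpec, OffsetProtocol, generate_system,
                      generate_ensemble, offset_binder, build_contact_table,
                      rmsf, fit_linear, ensemble_binding_energy)

spec = SyntheticSystemSpec(n_frames=100, n_runs=3, seed=42)
base = generate_system(spec)          # filament + 4 tails + bound binder
proto = OffsetProtocol()              # z-axis, distances 0..55 A

offsets, contacts, fluct = (0.0, 15.0, 35.0, 55.0), [], []
for d in offsets:
    ens = generate_ensemble(offset_binder(base, proto, d), spec, d)
    contacts.append(build_contact_table(ens, window=0.5).per_frame.mean())
    fluct.append(rmsf(ens).mean_rmsf)
    print(f"offset {d:4.0f} A   mean contacts {contacts[-1]:6.2f}"
          f"   mean RMSF {fluct[-1]:.3f} A")

fit = fit_linear(offsets, fluct)
print(f"RMSF vs offset: slope {fit.slope:.4f} A/A (planted 0.0200),"
      f" r = {fit.r:.3f}")

ens0 = generate_ensemble(base, spec, 0.0)
counts = build_contact_table(ens0, window=0.5).per_frame
idx = np.concatenate([np.where(ens0.run_ids == r)[0][50:]
                      for r in ens0.runs])
e_with = ensemble_binding_energy(ens0, counts, max_snapshots=30,
                                 frame_indices=idx)
e_wo = ensemble_binding_energy(ens0, counts, strip_tails=True,
                               max_snapshots=30, frame_indices=idx)
print(f"dE with tails    {e_with.dE_binding:7.2f} +- {e_with.sd:.2f}")
print(f"dE without tails {e_wo.dE_binding:7.2f} +- {e_wo.sd:.2f}")
```

Output:

```
offset    0 A   mean contacts  24.77   mean RMSF 0.988 A
offset   15 A   mean contacts  11.35   mean RMSF 1.284 A
offset   35 A   mean contacts   2.14   mean RMSF 1.677 A
offset   55 A   mean contacts   0.00   mean RMSF 2.076 A
RMSF vs offset: slope 0.0198 A/A (planted 0.0200), r = 1.000
dE with tails      -1.43 +- 12.17
dE without tails     0.40 +- 0.07
```

Contacts fall monotonically with offset and vanish at the planted 50 Å
threshold; the domain's fluctuation amplitude grows linearly with offset
and the regression recovers the planted gain (0.0198 vs 0.02 Å/Å); and
the mean rigid-body binding energy is favorable only while the tails are
present — stripping them at fixed coordinates flips its sign, the
signature of tail-mediated binding.

A CLI mirrors the library (`mtbinder synth | build | contacts | rmsf |
cluster | energy | pbe | run | report`); `mtbinder run --seed 0 --out
results/` executes the whole pipeline from one YAML/JSON config and writes
TSV tables, a Markdown report and a JSON manifest.

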