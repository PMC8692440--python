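# protrack

Event-by-event proton track-structure Monte Carlo for **arbitrary materials**.

Conventional track-structure codes need the dielectric function of the
target, which is only well measured for liquid water. `protrack` instead
combines two widely available ingredients:

* an analytic nine-parameter model of the singly-differential secondary-
  electron production cross section (per electron shell, with a noble-gas
  analogy for elements lacking a native fit and a generic inner-shell set),
  used to sample *where* ionisations happen and *what* electron they eject;
* a total stopping-power model (relativistic Bethe with Bragg additivity and
  a continuous velocity-proportional low-energy blend), used as the total
  energy budget.

Between ionisations the proton flies freely; the energy lost over a flight
is the stopping-power budget minus the mean ionising contribution
("restricted stopping-power" bookkeeping), so that non-ionising losses are
deposited continuously along the track while every ionisation is an explicit
event: a shell is sampled, its potential is deposited at the collision
point, the ejected electron carries its sampled energy away with
conservation-law emission kinematics, and the electron (and its cascade) is
transported event by event down to 1 eV by a replaceable water-reference
electron engine whose macroscopic cross sections scale with the target's
electron density.

## Layout

| module | what it does |
|---|---|
| `protrack.materials` | material definitions: composition, number density, electron shells, fit-parameter assignment |
| `protrack.rudd_xs` | SDCS evaluation, quadrature, tabulation and inverse-CDF sampling |
| `protrack.stopping` | total stopping power, CSDA ranges |
| `protrack.proton_transport` | free flights, energy bookkeeping, emission kinematics, proton histories |
| `protrack.electron_transport` | batch event-by-event electron cascade engine (1 eV cutoff, density scaling) |
| `protrack.geometry_tallies` | reflective geometries (folding), sphere-lattice lineal-energy, radial-dose, range and spectrum tallies |
| `protrack.cli_benchmarks` | run configs, four canned benchmarks, CLI |

## CLI

```bash
# total stopping power S(E) for any material
protrack stopping --material TEG --out s_teg.csv

# per-shell ionisation cross sections
protrack xs --material water --out xs_water.csv

# run a benchmark from a YAML config (examples in configs/)
protrack run --config configs/lineal_teg_360.yaml --seed 1 --out runs/
```

A run writes `<benchmark>_summary.json` with the tally results and a
provenance block (config, config hash, version). Identical config + seed
give byte-identical summaries; every history uses its own seeded stream, so
results do not depend on execution order.

Materials are either presets (`water`, `TEG`, `helium`) or inline mappings:

```yaml
material:
  name: my-gas
  density: 0.00166        # g/cm^3   (or number_density: molecules/cm^3)
  composition: {C3H8: 0.547, CO2: 0.397, N2: 0.056}   # molar fractions
  # optional per-species shell overrides:
  # shell_overrides:
  #   CO2: [{label: valence, ionisation_potential: 13.78, occupancy: 16,
  #          parameter_set: CO2}]
```

## Known limitation

The secondary-electron engine is a deliberately simple analytic stand-in
(screened-Rutherford elastic, binary-encounter ionisation, lumped
excitation and sub-excitation losses) calibrated against published electron
stopping powers and range anchors. It reproduces energy conservation,
density scaling, the ~20 nm low-energy electron range and the thin-target
spectra, but it under-concentrates the rare multi-keV energy-deposition
clusters that dominate the dose-mean lineal energy: simulated y_D values
land ~30-40% below the published ones (e.g. ~4.4 vs 7.56 keV/um for TEG,
360 nm spheres) and are insensitive to the engine's scattering parameters.
The corresponding acceptance tests are intentionally left failing rather
than loosened; the engine sits behind an interface so a higher-fidelity
electron model can be substituted without touching transport or tallies.
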