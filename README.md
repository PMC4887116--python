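# capsidsim

Stochastic simulation of icosahedral virus capsid self-assembly with
analytical corrections for the effects of the packaged RNA genome.

## The problem

Capsids of many RNA viruses assemble *around* their genome, but kinetic
models of assembly are fitted to in vitro data from purified coat protein
with no RNA present. `capsidsim` bridges that gap for a CCMV-like T=3
capsid (90 coat-protein dimers, assembling at 15.6 µM with exactly one
capsid's worth of subunits and a 100 s window): it computes closed-form
Flory-theory estimates of four RNA contributions and applies them as
multiplicative corrections to the rate constants of a rules-based
discrete-event stochastic simulator, then quantifies how kinetics and
assembly pathways change.

The four contributions, indexed by a 4-digit binary code
(RNA-RNA, Compression, RNA-protein, Concentration):

* **RNA–RNA** — Flory free energy of the confined polyelectrolyte,
  `F_RNA = l²/(Nb²) + vN²/2V` (≈ 208.96 kBT for RNA1), split evenly
  between on- and off-rates;
* **Compression** — confinement entropy `F_conf = Nb²/(R²−(R−D)²)`
  (≈ 119.86 kBT), applied to on-rates;
* **RNA–protein** — adsorption energy `F_ch = −δMr/D` (≈ −456.84 kBT),
  split evenly;
* **Concentration** — local coat enrichment on the RNA coil, on-rates
  × 90/3.1013 ≈ 29.02.

Each whole-capsid free energy F becomes a per-addition equilibrium factor
`K = exp(−F/180)` (180 coat monomers per T=3 shell).

The simulator itself is an exact next-reaction sampler over a lattice-graph
capsid model: fragments occupy slots of the line graph of the truncated
icosahedron (90 dimer slots, pentamer 5-rings and hexamer 6-rings),
associate through symmetry-reduced rigid placements (with implied ring
closure), and dissociate bond by bond. Analytics include mass-fraction
time series, binding-frequency matrices, a simulated light-scattering
proxy, and scans over on/off-rate scaling grids.

## Worked example

The correction table for all 16 effect combinations:

```sh
capsidsim corrections --all
```

```text
code    label           keq_factor  kon_factor  koff_factor
0000    Hollow          1           1           1
0001    Concentration   29.02       29.02       1
0010    RNA-Protein     12.65       3.557       0.2811
0011                    367.2       103.2       0.2811
0100    RNA Compression 0.5138      0.5138      1
...
1111                    59.1        29.69       0.5023
```

(keq_factor multiplies the equilibrium constant of every subunit-addition
step; kon_factor and koff_factor multiply the base on/off rates, with
keq = kon/koff identically. The second table the command prints carries the
underlying free energies: F_RNA ≈ 208.96 kBT, F_conf ≈ 119.86 kBT,
F_ch ≈ −456.84 kBT, weak-confinement radius 428.74 Å, 3.1013 dimers in the
coil volume, effective concentration 452.7 µM.)

Simulate the hollow capsid and the two-positive-effects case, then
summarize:

```sh
capsidsim fixtures --lattice ccmv --preset nucleation --out ccmv.json
capsidsim simulate --ruleset ccmv.json --code 0011 --reps 2 --seed 5 --out-dir runs/0011
capsidsim analyze summary runs/0011
```

```text
seed,max_size,time_to_max,completed
5,90,22.825303482295805,True
6,67,58.86953705096766,False
```

The strong positive corrections (on-rates ×103, off-rates ×0.28) cut both
ways: seed 5 assembles all 90 dimers in 23 s, while seed 6 nucleates too
many growing shells at once and kinetically traps at a 67-mer — the
depleted monomer pool cannot anneal the incompatible partial shells. A
rate-scaling grid scan (`capsidsim grid --ruleset ccmv.json ...`) maps the
wider landscape: assembly is abolished at low-on/high-off scalings, traps
below completion at high-on/low-off scalings, and completes reliably along
a central vein, with time-to-completion falling monotonically as on-rates
grow.

Everything is reproducible: a run's manifest records the base seed, and
identical seeds give byte-identical event logs.

## Layout

```
src/capsidsim/
  corrections.py   Flory-theory free energies -> (K_eq, k_on, k_off) factors
  lattice.py       capsid lattice graphs, rings, symmetry groups
  ruleset.py       bond-class rates, presets, rule-set file schema (JSON)
  engine.py        next-reaction stochastic assembly simulator
  analysis.py      mass fractions, frequency matrices, scattering, grid scans
  eventlog.py      TSV event logs and ensemble manifests
  config.py        YAML run configuration (defaults < file < flags)
  cli.py           capsidsim corrections|fixtures|simulate|analyze|grid
docs/methods.md    model assumptions, parameters, numerical conventions
```

See `docs/methods.md` for the model's assumptions and limitations — in
particular, the fitted base rates of the original CCMV model are not
public, so the shipped rule-set presets are synthetic and only the
qualitative regime structure, not specific published curves, is
reproducible.
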