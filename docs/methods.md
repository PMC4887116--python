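# Methods

`capsidsim` models the self-assembly of an icosahedral virus capsid — the
T=3 shell of cowpea chlorotic mottle virus (CCMV), built from 90 coat-protein
dimers — as a continuous-time Markov jump process over a fixed contact
lattice, and projects how the packaged RNA genome perturbs that process by
rescaling the kinetic rate constants with closed-form polymer-physics
corrections.

## 1. Analytical RNA-effect corrections

The RNA (CCMV RNA1, M = 3171 nt) is treated as a generic polyelectrolyte
confined to a thin shell of thickness D = 1.18 nm against the inner capsid
wall (inner radius R = 10.5 nm). Four separable contributions are computed
in units of kBT:

* **RNA–RNA** (Flory free energy of the confined chain):
  `F_RNA = l²/(N b²) + v N²/(2V)` with Kuhn length b = 2.6 nm (twice the
  1.3 nm persistence length at 1 M monovalent salt), N = M·r/b Kuhn segments
  (r = 0.34 nm per nucleotide), end-to-end distance l = πR (the longest arc
  inside the shell), pervaded volume `V = (4/3)π(R³ − (R−D)³)`, and
  counterion-screened excluded volume v = 3.537 nm³ per segment.
  With the defaults: F_RNA = 0.388 + 208.57 = 208.96 kBT.
* **Compression** (confinement entropy in compression blobs):
  `F_conf = N b²/(R² − (R−D)²)` = 119.86 kBT.
* **RNA–protein** (adsorption of the charged chain on the oppositely charged
  wall): `F_ch = −δ M r/D` = −456.84 kBT with δ = 0.5 kBT per
  nucleotide–protein contact.
* **Concentration** (local coat-protein enrichment on the RNA coil): the
  weak-confinement-regime radius `R₃ = a M^ν` (a = 3.4 Å, ν = 0.6) gives
  R₃ = 428.74 Å; at the bulk concentration c₀ = 15.6 µM the coil volume
  holds 3.1013 dimers, so packing a full capsid's 90 dimers is equivalent to
  multiplying on-rates by 90/3.1013 = 29.02 (an effective 452.7 µM).

Each whole-capsid free energy is converted to a per-addition equilibrium
factor by spreading it over the n = 180 coat monomers of the complete T=3
shell, `K = exp(−F/n)`. RNA–RNA and RNA–protein split their factor evenly
between on- and off-rates (`kon ×= √K`, `koff ÷= √K`); Compression and
Concentration act on on-rates only. The 16 on/off combinations are indexed
by a 4-digit binary code (order: RNA-RNA, Compression, RNA-protein,
Concentration); factors multiply elementwise and satisfy
`keq = kon/koff` identically.

Two internal inconsistencies of the source parameterization are resolved as
follows and surfaced in the API rather than hidden:

* The screened excluded-volume formula (`πb³/48 + 64π λB³ λD²/b²` with
  λB = 0.7 nm, λD = 0.3 nm) evaluates to ≈ 2.07 nm³, not the 3.537 nm³ the
  downstream arithmetic uses. The stored constant 3.537 nm³ is adopted;
  `excluded_volume_eq3` evaluates the literal formula as a labelled
  diagnostic.
* The printed WCR coil volume (3.013 × 10⁸ Å³) is inconsistent with its own
  radius (R₃ = 428.74 Å ⇒ 3.301 × 10⁸ Å³); the radius-derived volume is
  used, which reproduces the downstream dimer count (3.1013) and on-rate
  factor (29.02) exactly.

The 180-monomer divisor is exposed as `distribution_count_n` because its
provenance is only implicit in the e^(F/180) conversions.

## 2. The capsid lattice

The completed capsid is the line graph of the truncated icosahedron: one
node per truncated-icosahedron edge (90 dimer slots), with two slots in
contact when their edges share a vertex. Every slot has 4 contacts; the 12
pentagonal faces become 5-rings of slots (pentamers of dimers) and the 20
hexagonal faces become 6-rings (hexamer motifs). Each contact lies on
exactly one face ring, which assigns it a `pentagon` or `hexagon` bond
class (60 and 120 contacts respectively); each slot lies on exactly two
rings. The 120-element icosahedral symmetry group is lifted analytically
from the icosahedron; under it the slots split into orbits of 60 and 30 —
the same asymmetry as the A/B versus C/C dimer types of the real T=3
lattice, so the graph is deliberately *not* node-transitive. Toy lattices
(3-cycle, K₄, icosahedron skeleton = "dodecahedron" of 12 pentamer slots)
support exact reference calculations and fast scans.

Because the line graph of a cubic polyhedron contains a triangle for every
polyhedron vertex flag, trimers-of-dimers are the smallest closed motifs —
consistent with the prominent trimer intermediates this system is known
for.

## 3. Stochastic assembly engine

State: a well-mixed collection of rigid fragments, each a connected set of
occupied lattice slots with bonds on (a subset of) the lattice contacts it
induces. Free subunits are size-1 assemblies without a committed slot (the
lattice has two slot orbits, so a free dimer must be allowed to enter
either). The simulation volume is fixed by the protocol,
`V = n/(c₀·N_A)` for n subunits at bulk concentration c₀; effect factors
never change the volume, only the rates.

Events:

* **Association** between two fragments: the second fragment is rigidly
  placed by a lattice automorphism so the fragments do not overlap and at
  least one contact joins them; all open contacts inside the merged
  footprint close in the same event (implied ring closure). Geometrically
  equivalent placements (orbits under the anchor's stabilizer; lattice-edge
  orbits for two free subunits) collapse to one event. The propensity of a
  placement is the sum over the contacts it forms of
  `kon(class)·kon_factor/(N_A·V)` — each contact is a distinct site pairing.
* **Dissociation** per existing bond at `koff(class)·koff_factor`. If the
  fragment's bond graph disconnects it splits in two; otherwise the contact
  is merely open.
* **Ring closure**: an open induced contact re-forms at the fast
  unimolecular rate `ring_closure_rate` (default 30 s⁻¹ in the shipped
  presets). This is the model's cooperativity: a doubly-coordinated subunit
  whose bond breaks is usually re-captured before a second bond breaks, so
  effective stability rises steeply with coordination number. Without this
  channel every bond erodes independently, stability is independent of
  coordination, and the 90-subunit protocol invariably stalls in
  multi-nucleus traps.

Scheduling follows the next-reaction method: every event carries an
exponential tentative time sampled once from its propensity
(`t = now − ln(u)/rate`, inverse CDF); the minimum fires; only events whose
participants changed are re-sampled. Bond-only changes (ring openings and
closures) keep the fragment's identity, so the large population of pairwise
association events is left untouched by intra-fragment bond noise — this is
what makes 90-subunit trajectories with 10⁴–10⁵ events tractable. A
trajectory ends at completion (one fragment holds every slot, with every
contact bonded) or at the 100 s protocol limit; a sterically invalid event
would consume its time slot and be discarded, though under these semantics
scheduled events cannot become stale. One seeded RNG stream per trajectory
makes logs bit-reproducible; ensembles derive per-replicate seeds as
`base_seed + index`.

## 4. Base-rate presets

The kinetic constants of the data-fitted CCMV model are not public, so the
shipped rule sets are synthetic. The `nucleation` preset assigns pentagon
contacts `kon = 3×10⁵ M⁻¹s⁻¹, koff = 4 s⁻¹` and divides both hexagon rates
by 5 (slow-forming but long-lived), with `ring_closure_rate = 30 s⁻¹`.
These values were chosen, before freezing the test assertions, so that the
hollow (no-RNA) protocol — 90 subunits, 15.6 µM, 100 s — is
nucleation-limited: reversible small-oligomer churn, then growth gated by
hexamer-stabilized intermediates, completing in roughly 30–70 s in most
trajectories, with occasional runs kinetically trapped below completion.
The cooperativity ratio `ring_closure_rate/koff ≈ 7` makes trimers mortal
(lifetime of seconds) while shell interiors are effectively locked.

Because the base rates are synthetic, only the *structure* of the rate-scan
regime map is meaningful, not the placement of specific RNA-effect codes
within it. In particular, under this preset the all-effects combination
(1111, on-rates ×29.7) lands in the kinetically trapped regime rather than
the fast-completing one; reproducing the published placement would require
the unpublished fitted rates.

## 5. Trajectory analytics

All statistics replay the event log against the size census it implies
(closure and non-splitting dissociation records are census-neutral):

* **Mass fractions**: fraction of subunits in each size s at each event
  time, `s·count_s/n`; rows sum to 1 exactly.
* **Frequency matrix**: entry (i, j) is the fraction of association events
  producing an i-mer in which at least one reactant was a j-mer, pooled
  over an ensemble; each event counts once per involved reactant *size*, so
  entries are frequencies in [0, 1] and occupied rows sum to 2 unless
  equal-size pairings occurred.
* **Scattering proxy**: `Σ_s count_s·s²/n²` — a Rayleigh-like mass-squared
  signal equal to 1 for one complete capsid and 1/n for free subunits. The
  exact experimental light-scattering transform is not restated in the
  source; this proxy preserves the monotone mass-squared character such
  curves require (it rises under every association and falls under every
  splitting dissociation). Ensemble curves are averaged on a logarithmic
  time grid by last-observation-carried-forward.
* **Trajectory summary**: largest size reached and the time of its *first*
  attainment; completion iff the maximum equals the capsid size.
* **Grid scan**: mean max size / mean time-to-max / completion fraction per
  (kon_scale, koff_scale) cell over the 9×6 published scaling grid
  (on: 0.1–500, off: 0.1–5; 54 cells), with optional overlay of the 16
  effect-code points.

## 6. Problem sizes used in the shipped tests

The master-equation comparisons run the 3-subunit triangle toy for 4000
simulated seconds (≥10⁴ events) against the exact 4-state stationary
distribution (states: three free / dimer+free / open trimer / closed
trimer; the dimer gains the third subunit in one double-contact event, so
there is no reversible-open-trimer association path). The regime-map check
runs the full 54-cell grid on the CCMV lattice at 2 replicates per cell
with a 20 s window — a compressed variant of the 100 s protocol chosen as
the package's standard quick-scan configuration; the four regime classes
are insensitive to the window because abolition and trapping establish
themselves within the first seconds while the completion vein is assessed
by completion fraction. Protocol-fidelity checks run the full 90-subunit,
100 s protocol.

## 7. What the synthetic data does and does not show

The generator reproduces the combinatorics of the target shell (90 slots,
pentamer/hexamer motifs, icosahedral symmetry), mass-action kinetics in a
fixed volume, and nucleation-limited versus trapped versus abolished
kinetic regimes. It does not model: explicit 3-D geometry or binding-site
vectors; dimer conformational switching (A/B vs C/C is present only as the
slot-orbit asymmetry); an explicit RNA chain (RNA enters only through the
analytical rate corrections); diffusion; or multi-capsid competition (the
protocol deliberately provides exactly one capsid's worth of subunits).
Passing tests therefore validate the algorithmic machinery and the
analytical corrections, not quantitative agreement with in vitro kinetics,
which would require the unpublished fitted base rates.

## 8. Numerical and degenerate-input conventions

Exponential times use the inverse CDF on u ∈ (0, 1] (`u = 1 − U` from the
RNG's [0, 1) stream), so a rate of 0 yields "never". Heap ties break by
insertion order, which is deterministic. Zero-length chains make the
chain-extensive free energies vanish (their factors → 1); the RNA–RNA
stretch term diverges as M → 0 with l fixed at πR, so that limit is not
claimed. Fragment placements are canonicalized by the lexicographically
smallest automorphism image; rates attach to placements as contact-class
multisets, so canonicalization never changes a propensity. Table-style
output rounds to 4 significant digits for display; all internal arithmetic
is double precision.
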