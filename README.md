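# absb — N-terminal salt bridges in amyloid-beta

`absb` is a Python library for analysing the transient salt bridges that the
arginine at position 5 of the amyloid-beta peptide (Aβ40) forms with its
nearby carboxylate side chains (Asp1, Glu3, Asp7, Glu11) — interactions
implicated in N-terminal compaction of the Aβ monomer and, through their
disruption by Ser8 phosphorylation, in aggregation behaviour relevant to
Alzheimer's disease.  It is written for structural-biology and biophysics
groups who have the corresponding measurements (pressure-series chemical
shifts, conformer ensembles, CEST profiles, conformer energy tables) and
want a tested, reproducible implementation of four analyses:

1. **Pressure coefficients of chemical shifts** (`absb.shift_pressure`).
   Shifts across 1–2000 bar are fitted to a second-order Taylor expansion
   δ(p) = δ₀ + B₁·(p−p₀)/1000 + B₂·((p−p₀)/1000)², p in bar, B₁ in ppm/kbar.
   After subtracting random-coil reference coefficients, the sign of the
   corrected B₁ classifies each residue as pressure-sensitive (positive or
   negative) or random-coil-like (near zero).  Salt bridges are pressure
   labile — electrostriction favours charge separation at high pressure — so
   anomalous B₁ marks candidate electrostatic structure.
2. **Salt-bridge geometry over conformer ensembles** (`absb.saltbridge`).
   Guanidinium–carboxylate pairs are classified per conformer into the three
   canonical interaction modes — *side-on* (bidentate via NH1/NH2), *end-on*
   (bidentate via NE + one NH) and *backside* (monodentate) — from heavy-atom
   N···O contacts (default cutoff 3.5 Å).  The ensemble scanner reports pair
   occupancies and mode breakdowns, the fraction of conformers where one
   arginine bridges two acceptors simultaneously, and Cα–Cα distance
   statistics conditioned on bridge presence (in nm).
3. **Guanidinium rotational exchange by CEST** (`absb.cest`).  The two Nη
   nitrogens swap environments as the guanidinium rotates about Cζ–Nε: a
   two-site symmetric exchange with total rate k_ex (sum of forward and
   backward rates) and shift separation Δω (rad/s).  Saturation profiles are
   simulated by Bloch–McConnell propagation (matrix exponential of the 6+1
   component evolution matrix) and fitted by multi-start nonlinear least
   squares for (k_ex, Δω, centre), with dip detection for major/minor
   exchange species.
4. **Phosphorylation energetics** (`absb.energetics`).  From per-conformer
   energy pairs (Ser8-phosphorylated vs unmodified, in hartrees) it computes
   ΔE per conformer, group means/SDs, and the contrast
   ΔΔE = mean(ΔE_test) − mean(ΔE_control) in hartrees and kJ/mol
   (1 hartree = 2625.4996 kJ/mol); positive ΔΔE means phosphorylation
   destabilises salt-bridged conformers relative to bridge-free ones.

A fifth module, `absb.synthetic`, generates all of these inputs with known
ground truth (planted bridge occupancies, bridge-coupled compaction, known
exchange parameters, configured group energies) and is what the test-suite
recovery checks run on.  `absb.io` holds the CSV/PDB/JSON readers and
writers, and a thin `absb` command line wraps the library.

## Worked example

Scan a 2000-conformer synthetic ensemble with bridges planted at the
reference occupancies (`python examples/salt_bridge_scan.py`):

```
 donor  acceptor  occupancy  side_on  end_on  backside
     5         1     0.0200   0.0200     0.0     0.000
     5         3     0.1015   0.0975     0.0     0.004
     5         7     0.1320   0.1320     0.0     0.000
     5        11     0.0550   0.0550     0.0     0.000

Arg5 bridging Glu3 AND Asp7 simultaneously: 0.40 %
Glu3-Ser8 Calpha distance, bridged conformers:   1.249 +/- 0.049 nm (n=459)
Glu3-Ser8 Calpha distance, unbridged conformers: 1.390 +/- 0.051 nm (n=1541)
```

The recovered occupancies sit within binomial sampling error of the planted
fractions (14 % Asp7, 10 % Glu3, 6 % Glu11, 2 % Asp1, 0.3 % double bridge),
and the bridged sub-ensemble is visibly more compact between Glu3 and Ser8
(1.25 vs 1.39 nm).  The CEST round trip
(`python examples/cest_round_trip.py`) prints

```
fitted k_ex        =   356.00 /s    (truth 356)
fitted delta_omega =  1214.00 rad/s (truth 1214)
fitted center      =    71.00 ppm   (truth 71)
```

i.e. the multi-start fitter recovers the free-arginine exchange parameters
from a noiseless simulated profile to numerical precision.  The other
examples (`pressure_coefficients.py`, `phosphorylation_energetics.py`) cover
the remaining two analyses; each prints a short explanation of its numbers.

The same operations are available from the shell, e.g.:

```bash
absb synth ensemble --seed 17 --n 1000 --out work/
absb saltbridge --ensemble work/ensemble.pdb --donor 5 --acceptors 1,3,7,11 \
     --ca-pairs 3:8,3:10 --out work/scan
absb cest simulate --kex 356 --domega 1214 --center 71 --out work/cest.csv
absb cest fit --profile work/cest.csv --out work/fit.json
```

## Layout

```
src/absb/          shift_pressure, saltbridge, cest, energetics,
                   synthetic, io, cli
examples/          one narrative script per capability
tests/             pytest suite (unit, property and recovery tests)
scripts/           acceptance.py
docs/methods.md    models, assumptions, parameter choices, limitations
```
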