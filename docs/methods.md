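# Methods

This note records the models implemented in `absb`, the assumptions and
defaults behind them, what the synthetic-data generator does and does not
emulate, and the numerical choices a maintainer would want to know about.

## Pressure dependence of chemical shifts

The shift of one nucleus is modelled as a second-order Taylor expansion in
pressure around an ambient expansion point p₀,

δ(p) = δ₀ + B₁·x + B₂·x²,  x = (p − p₀)/1000,

with p and p₀ in bar, so B₁ is ppm/kbar and B₂ ppm/kbar².  Defaults: p₀ =
1 bar; quadratic fit (a linear-only mode with B₂ ≡ 0 exists for sparse
series, since the linear term typically carries most of the response).  The
fit is ordinary least squares on the Vandermonde design; standard errors
come from rss/dof·(XᵀX)⁻¹ and are reported as NaN when the point count
equals the parameter count (exact interpolation — no residual degrees of
freedom).  Duplicate pressures are averaged with a warning.

Random-coil correction is applied to the fitted *coefficients* (subtraction
of per-(residue type, nucleus) reference B₁/B₂), not to the raw shifts; for
polynomial models the two are algebraically identical and coefficient
subtraction is easier to audit.  Both B₁ and B₂ are corrected.  The
reference table is a user-editable CSV; no community-standard set of
pressure coefficients for random-coil peptides ships with the package, so
the default table is empty — every lookup then subtracts zero and sets a
`reference_missing` flag on the record, which propagates into output tables.

Residue classification uses the corrected B₁ with a symmetric threshold:
positive / negative when |B₁| exceeds it, near-zero otherwise.  The default
threshold, 0.2 ppm/kbar, is intended for backbone ¹⁵N coefficients and is
configurable; it has no privileged physical status beyond separating the
clearly structured responses from coil-like ones in typical ¹⁵N data.

Peak-intensity trends (e.g. the Arg5 Hε–Nε peak growing with pressure as a
salt bridge depopulates) are fitted as a straight line in pressure; the
sign label uses a configurable flat tolerance (default 10⁻⁹ intensity
units/kbar, i.e. effectively exact zero).

## Salt-bridge geometry

A contact is a heavy-atom N···O distance ≤ cutoff between a guanidinium
nitrogen (NE, NH1, NH2) and a carboxylate oxygen (OD1/OD2 or OE1/OE2).  The
default cutoff is 3.5 Å, the standard salt-bridge/hydrogen-bond criterion;
hydrogens are never used.  From the 3×2 contact matrix the mode is:

* **side_on** — NH1 and NH2 each contact a *distinct* oxygen (bidentate);
* **end_on** — NE and one NH each contact a distinct oxygen (bidentate);
* **backside** — exactly one nitrogen carries any contact (monodentate);
* **none** — otherwise.

Precedence is side_on > end_on > backside: when several patterns hold the
highest-denticity reading wins, consistent with the bidentate geometries
being the low-energy configurations.  Two consequences worth noting: two
nitrogens sharing one oxygen is *not* bidentate (no distinct oxygens) and
*not* backside (two nitrogens touched), hence `none`; and enlarging the
cutoff can never turn a bridge into no bridge (contacts only grow), which
is tested as a property.

Only side-chain carboxylates partner by default; the C-terminal backbone
carboxylate and the N-terminal ammonium are excluded (configurable for the
former).  Ensembles are exchanged as multi-model PDB; model order defines
the conformer id.  Distances are Å internally; Cα–Cα summaries are reported
in nm.  Occupancy is the fraction of conformers with any mode for a pair;
mode fractions sum to the occupancy; the bidentate fraction is
side_on + end_on and the monodentate fraction is backside.

## CEST model of guanidinium rotation

Rotation about Cζ–Nε exchanges the two Nη environments.  Because the two
states are the same chemical group in two orientations, populations are
exactly ½/½ and the exchange is symmetric; k_ex denotes the **sum** of
forward and backward rates (each direction runs at k_ex/2).  This
convention differs across the CEST literature, so it is stated in every fit
output.

Saturation is modelled by the Bloch–McConnell equations for the six
magnetization components (x, y, z per site) augmented with a constant
component carrying R1 recovery to thermal equilibrium — a 7×7 generator per
offset containing R1, R2, the saturation nutation ω₁ = 2πB₁(sat), the site
offsets centre ± Δω/2 (rad/s, with ppm↔rad/s via the configured ¹⁵N
frequency), and the exchange coupling.  Propagation is `expm(L·T_sat)` from
equilibrium; the intensity is the surviving total z-magnetization, which is
already normalised because the T_sat = 0 reference is exactly 1.  The
multiquantum coherence pathway of the experiment this models is **not**
reproduced; this longitudinal stand-in supports the same two-site
symmetric-exchange analysis (dip structure and the (k_ex, Δω) round trip),
which is what the package needs.  The profile is exactly symmetric about
the centre frequency — a consequence of the equal populations — and this
symmetry is tested to 10⁻¹⁰.

Acquisition parameters are not derivable from profile data alone and
default to B₁(sat) = 25 Hz, T_sat = 0.4 s, R1 = 1.5 s⁻¹, R2 = 30 s⁻¹,
81.1 MHz ¹⁵N (800 MHz ¹H); all are configurable, and the simulate→fit round
trip is valid for any choice because the same fixed parameters enter both
directions.

Fitting is nonlinear least squares (Levenberg–Marquardt through lmfit) over
(k_ex, Δω, centre) with a multi-start grid, default
k_ex ∈ {50, 200, 500, 1000} s⁻¹ × Δω ∈ {500, 1000, 2000} rad/s; the centre
starts at the profile minimum and is bounded by the offset range.  The best
converged start by residual sum of squares wins; every start is logged.
Standard errors are covariance-based; a Monte-Carlo calibration test checks
that the 95 % confidence intervals cover the truth with frequency in
[0.90, 0.99] over 200 noisy replicates (σ = 0.01).  Flat profiles (span
below 10⁻³) are rejected as carrying no exchange information rather than
returning an unidentifiable fit; two-species (salt-bridged minor state)
fitting is deliberately not attempted.

Dip detection runs `scipy.signal.find_peaks` on the negated (optionally
moving-average-smoothed) profile with the depth threshold as prominence;
the deepest dip is labelled major, the rest minor, ordered by depth.

## Phosphorylation energetics

ΔE = E_phos − E_nonphos per conformer (hartrees); group mean ± SD (SD of a
singleton group is NaN, not 0); ΔΔE = mean(ΔE_group) − mean(ΔE_control).
Conversion uses 2625.4996 kJ/mol per hartree (CODATA).  Note that published
tables usually derive the kJ/mol column from *unrounded* hartree contrasts:
0.0346447 hartrees → 90.96 kJ/mol, while the rounded 0.035 × 2625.5 would
give 91.9 — not a bug.  Energies are consumed from tables; no quantum
chemistry is performed.

## Synthetic-data generator

The generator's defaults are the study conditions the analyses are tested
under:

* **Shift tables** — pressures {1, 500, 1000, 1500, 2000} bar; per-residue
  quadratic truths emulating the N-terminal B₁ pattern (positive ≈ +0.5 to
  +0.6 ppm/kbar at Glu3/Glu11/Val12, negative ≈ −0.6 to −0.8 at
  Arg5-His6/His13-His14, near zero at Asp7–Tyr10); Gaussian shift noise
  σ = 0.01 ppm by default (a typical ¹⁵N precision).
* **Ensembles** — the Aβ40 sequence DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVV;
  marginal bridge occupancies Asp7 14 %, Glu3 10 %, Glu11 6 %, Asp1 2 %,
  double (Glu3+Asp7) 0.3 %, modes side-on unless configured (the dominant
  observed mode; the double bridge is side-on to Asp7 plus backside to
  Glu3); bridge-conditional Cα compaction Glu3–Ser8 1.25/1.39 nm and
  Glu3–Tyr10 1.41/1.48 nm (SD 0.05 nm), conditioning on any Glu3- or
  Asp7-bridge.
* **CEST** — k_ex = 356 s⁻¹, Δω = 1214 rad/s, centre 71 ppm (free-arginine
  reference values) with the default acquisition parameters above.
* **Energy tables** — groups (7, −567.268 ± 0.065), (8, −567.291 ± 0.026),
  (12, −567.303 ± 0.023) hartrees for both-bridges / Asp7-only / control.

Bridge draws are a single categorical per conformer (double-bridge category
plus one category per acceptor, with the per-acceptor probability reduced
by the double fraction where it overlaps), so the *marginal* per-pair rates
equal the configured occupancies exactly in expectation while the
double-bridge rate is controlled independently; independent per-pair
Bernoulli draws would make two side-on bridges collide geometrically (one
NH1/NH2 face) and would not conserve the double fraction.  Configurations
where the double fraction exceeds a marginal, or the categories sum above
one, are rejected as infeasible with the conflicting settings named.

Conformers are reduced-atom: a Cα trace from a 3.8 Å-step random walk with
approximate self-avoidance (non-neighbour Cα–Cα ≥ 4 Å, rejection sampling
with capped retries) plus idealised planar guanidinium (N–Cζ 1.33 Å, 120°)
and carboxylate (C–O 1.25 Å, 126°) groups.  Planted acceptors are placed to
realise the requested mode's contact pattern at 2.8–3.2 Å — safely inside
the 3.5 Å cutoff; unplanted carboxylates are kept ≥ 4.5 Å (N···O) from the
guanidinium so no accidental bridges arise, which is what makes the planted
truth label and the geometric classifier agree conformer by conformer (an
equality the tests assert exhaustively).  Bridge-coupled compaction is
imposed by moving the second residue's Cα along the pair axis to a distance
drawn from the conditional normal law; this breaks the two adjacent
backbone step lengths for that residue, an accepted unreality (below).

What the generator does **not** emulate: force-field energetics, realistic
side-chain rotamers or full-atom sterics, chemically complete peptides,
solvent, and any correlation between bridge presence and global chain
dimensions beyond the explicitly planted Cα pairs.  Recovery tests passing
on these ensembles therefore demonstrate that the *analysis* is correct
(classification, counting, conditioning, fitting), not that the generator's
ensembles resemble real Aβ40 ensembles.

All generators take a single integer seed (numpy `default_rng`), are
byte-deterministic under it, and emit a truth sidecar carrying the seed, a
config hash and every planted value.

## Problem sizes and numerical choices

Recovery checks use 5000-conformer ensembles for occupancy targets (binomial
2σ at 14 % ≈ ±1.0 percentage point), 20000 for the 0.3 % double-bridge
fraction (2σ ≈ ±0.077 points), and 2000 for conditional distances (3·SEM ≈
±0.005 nm at n_with ≈ 500); the CEST round trip uses a 60–90 ppm grid at
0.25 ppm.  These sizes make the statistical bounds meaningful while keeping
a full run of suite plus acceptance script in the low minutes on one CPU.
Matrix exponentials are evaluated batched over offsets; the CEST fit
residual is defined in intensity space with no weighting (homoscedastic
noise assumption).  Ties in dip depth are broken by detection order;
degenerate inputs (empty ensembles, flat profiles, empty control groups,
single-point series) raise typed errors rather than returning NaNs, except
where a partition may legitimately be empty (conditional distances report
n = 0 with NaN mean).

## Known limitations

* The salt-bridge mode definitions are contact-pattern rules, not the
  energy-based or angle-resolved definitions used elsewhere; with the 3.5 Å
  heavy-atom cutoff they classify clear geometries correctly but make no
  claim near the cutoff boundary.
* The CEST stand-in ignores the multiquantum pathway, off-resonance
  effects of the hard pulses, and B₁ inhomogeneity; fitted (k_ex, Δω) are
  exchange parameters of the longitudinal model, comparable across data
  analysed the same way.
* The random-coil reference table is empty by default; corrected and raw
  coefficients then coincide and every record is flagged.  Supply a
  measured reference table for quantitative corrected values.
* Pressure-series fitting assumes independent homoscedastic noise across
  pressure points.
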