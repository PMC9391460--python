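# Methods

## Coupled tetramer–dimer–ligand equilibrium

The binding scheme is T ⇌ 2D (K_tet = [D]²/[T], concentration units) with
two successive ligand-binding steps on the dimer, D + L ⇌ DL and
DL + L ⇌ DLL. Protein totals are monomer equivalents throughout, so the
protein balance is 4[T] + 2([D] + [DL] + [DLL]) = P and the ligand balance
[L] + [DL] + 2[DLL] = L_tot.

**Site models.** The default (`macroscopic_equal`) sets both macroscopic
stepwise constants equal, K₁ = K₂ = K_lig — the natural reading of "two
identical, non-overlapping sites on a C₂-symmetric dimer" when the data
resolve only macroscopic steps. The alternative (`intrinsic_statistical`)
treats K_lig as the intrinsic per-site constant of two independent sites
and applies the statistical factors K₁ = K_lig/2, K₂ = 2·K_lig. Both are
first-class options; all headline numbers use the default.

**Observable.** The dose–response signal is modelled as the fraction of
protein monomer units in ligand-bound dimeric species,
f = 2([DL] + [DLL])/P. It is 0 at L_tot = 0, saturates at 1, and is
monotone in total ligand, so the model EC50 (f = ½) is unique. Modelling
the signal as DL-only would change EC50 by ~20% at the default constants;
the DL+DLL convention is used because both bound states alter the dimer's
size/charge/solvation envelope that thermophoresis senses.

**Solver.** At fixed free ligand L the protein balance is a quadratic in
[D] with the stable positive root d = 2P/(2β + √(4β² + 16P/K_tet)),
β = 1 + L/K₁ + L²/(K₁K₂); this form is exact in both the strong-tetramer
and the K_tet → ∞ limits (no catastrophic cancellation). Free ligand is
then located by bracketed Brent root search of the ligand balance on
[0, L_tot] to machine precision — no excess-ligand approximation, although
depletion is negligible at 100 nM protein. Mass balances are verified to
1e−9 relative after every solve; EC50 and K_lig root searches use
bracketed bisection/Brent on [1e−12, 1e4] µM (auto-expanded upward for the
EC50 bracket) with 1e−10 relative tolerance, so the EC50 ↔ K_lig round
trip holds to better than 1e−6.

**Closed-form limit.** With K_tet → ∞ and equal macroscopic constants the
bound fraction is (x + x²)/(1 + x + x²) in x = L_free/K_lig, giving
x = φ = (√5 − 1)/2 at the midpoint. Adding back the exactly-solved ligand
depletion, EC50 = φ·K_lig + ((φ + 2φ²)/4)·P. The test suite checks this to
1e−6; the depletion term matters only when P is comparable to K_lig.

**Error propagation.** K_lig uncertainty is propagated by Monte Carlo:
(EC50, K_tet) drawn from independent Gaussians truncated at zero (the
constants are positive by definition), each draw inverted through the
model, mean/sd/percentile-CI reported. Default 10,000 draws; the seed is
mandatory and results are bit-reproducible. Draws that fail to invert are
dropped; more than 10% failures raises a recorded warning. At
EC50 = 2.5 ± 0.8 µM and K_tet = 1.60 ± 0.32 µM this yields
K_lig ≈ 3.9 ± 1.3 µM.

## MST dose–response models

*Quadratic isotherm* (the "K_D fit"): bound fraction
(F + c + K − √((F + c + K)² − 4Fc))/(2F) at labelled concentration F —
the exact 1:1 solution, valid when titrant and receptor concentrations are
comparable. *Hill model*: f = unbound + (bound − unbound)/(1 + (EC50/c)ⁿ),
n constrained to [0.3, 4] (free by default). *Symmetric two-site model*:
receptor with two identical independent sites of intrinsic K; free ligand
solves its depletion balance exactly and the signal follows the average
site occupancy.

Fits are least squares via `lmfit` (Levenberg–Marquardt), weighted by
per-point standard errors when present (e.g. after replicate merging),
unweighted otherwise. Initialization: plateau levels from the first/last
deciles of the sorted series; the affinity parameter from five log-spaced
multi-starts across the concentration range, keeping the best optimum —
this removes the local-minimum sensitivity the sigmoidal models otherwise
show. Parameter uncertainties come from the fit covariance; the two-site
model additionally profiles the error surface over K and reports the
68.3% interval at Δχ² = 1 with the variance estimated from the residuals
at the optimum (σ² = RSS_min/(n − p)), refining each threshold crossing by
root search. A profile still below threshold at K → 0 yields a lower bound
of 0; one never crossing in the scanned range yields an open upper bound —
matching the wide one-sided intervals this model produces on shallow data.

## Thermal melts

Biphasic denaturation (separate dimer and tetramer transitions) is fitted
as a linear baseline plus two logistic transitions; DSF curves add an
exponential low-temperature term for the dye signal that is maximal near
the start of the ramp and decays with temperature. A logistic rather than
van't Hoff two-state shape is used because only midpoints (Tm), not
enthalpies, are extracted; transition amplitudes are reported but not
interpreted as species fractions. `tm_by_derivative` provides the
model-free cross-check: extrema of the Savitzky–Golay-smoothed first
derivative, signed by the dominant direction of signal change so both
rising (DSF) and falling (CD at 222 nm) conventions work. The two
estimators agree within 2 °C on synthetic curves with widths ≤ 3 °C, and
both are invariant under affine transforms of the signal axis.

## NMR analyses

*pKa*: δ(pH) = (δ_HA + δ_A·10^(pH−pKa))/(1 + 10^(pH−pKa)), single
protonation event, fitted over the 23-point pH 2–13 titration. Both
plateau shifts float by default; a `fix_plateaus` mode pins them to the
end-point spectra instead (this biases pKa by ~0.01 when an end point sits
1% short of its plateau, which is why floating is the default). *CSP*:
combined amide perturbation √(ΔδH² + (0.14·ΔδN)²); the nitrogen weight is
the community default for ¹H–¹⁵N correlation maps and is configurable.
*STD*: effect = I_STD/I₀ with the STD-spectrum intensity stored directly
(avoiding the sign ambiguity of I₀ − I_sat conventions), largest effect
normalized to 100%, amplification factor A_STD = effect × molar excess.

## Contact fingerprints and epitope clustering

A frame's fingerprint sets one bit per topology residue when any ligand
heavy atom is within 4.0 Å of any residue heavy atom (the bit-vector
length follows the input topology — 244 for a 4 × 61-residue tetramer).
Frames contacting fewer than 5 residues are treated as unbound and
dropped. The dimer-of-dimers chain symmetry (Klein four-group: identity,
within-dimer swap, dimer swap, and their product) is handled on the
fingerprints themselves: each is replaced by its lexicographically
smallest image under the group — deterministic, reference-free, and
idempotent, so all four symmetry copies of an epitope collapse to one
canonical form. Epitopes are then flat clusters of the average-linkage
hierarchical clustering of pairwise Jaccard distances, cut at 0.3; the
linkage is configurable (average chosen as the stable default for binary
fingerprints), clusters are ranked by population, and centroids are
per-bit majority fingerprints.

Occupancy grids bin ligand heavy atoms of contact frames onto a 0.5 Å
lattice covering the reference protein's bounding box padded by 5 Å,
auto-expanding (logged) for outliers so total counts always equal the
number of binned (frame, atom) incidences. Frames are least-squares
superposed (Kabsch, protein heavy atoms) onto the reference before
gridding; grids export to OpenDX.

## Permeability calibration

Computed log-permeability scores (from membrane-permeation free-energy
simulations, which are an *input* here, not computed) are mapped to
experimental PAMPA log₁₀(P_eff/P₀), P₀ = 1 cm/s, by ordinary least
squares on the reference set (y-on-x; an errors-in-variables treatment
would need the per-compound score uncertainties of the full reference
panel). Prediction sd combines the calibration residual sd and the
propagated score uncertainty in quadrature. P_eff = 10^y cm/s, classified
as low (< 0.7×10⁻⁶), low-to-medium [0.7–2.1×10⁻⁶], medium
(2.1–4.7×10⁻⁶], or high (> 4.7×10⁻⁶ cm/s); the 2.1–4.7 gap is unnamed in
the usual banding convention and is labelled "medium" here, with band
edges inclusive on the upper side.

## Sequence properties

Average (ProtParam-convention) residue masses plus one water for MW;
ε₂₈₀ = 5500·nTrp + 1490·nTyr + 125·n_cystine. The bundled 68-residue
FASTA is a *synthetic* stand-in for the tetramerization-domain construct
(the natural sequence is published only as a figure): it was constructed
to reproduce the construct's two published sequence-derived constants
(MW 8547 Da, ε₂₈₀ = 19,480 M⁻¹cm⁻¹; 3 Trp, 2 Tyr, no Cys) and has no
biological meaning beyond that validation.

## Synthetic-data generators

Each generator reproduces its assay's canonical design: MST titrations as
16-point serial 1:1 dilutions (self-titration 15 nM–500 µM at 100 nM
labelled protein, 1% span noise, triplicates; ligand titration
0.122–4000 µM, Hill n = 1.2, 2% span noise, triplicates), melts on a
25–95 °C/1 °C grid (CD transitions 48/88 °C; DSF 55/85 °C plus dye
decay), pH titrations with 23 points over pH 2–13, nine-compound
calibration lines (slope 0.269, intercept −5.31 — the line through the
two published score/prediction pairs), and ligand-diffusion trajectories
around a toy four-chain bundle (one heavy atom per residue, 61 per chain)
with three planted epitopes whose axial positions are symmetry-copied
across chains; positional jitter is tuned so that the marginal edge
residues of a ~7-residue footprint flip with ~10% probability,
"unbound" frames are placed far outside the contact cutoff, and planted
labels are returned for recovery assertions. All generators take a
mandatory seed and are bit-reproducible.

What the generators do **not** emulate: MST photophysics and time traces
(inputs are reduced dose–response points), NMR lineshapes and exchange
broadening, real protein geometry (the toy bundle has no side chains, so
contact footprints are cleaner than in a real trajectory), and correlated
noise of any kind. Passing recovery tests therefore demonstrates
correctness of the estimators under the stated noise model, not robustness
to instrument systematics.

## Problem sizes and defaults

Monte-Carlo error propagation defaults to 10,000 draws; tests use
1,000–1,500. Recovery surfaces run 200 seeded replicates for the MST
coverage checks, 200 seeds for pKa bias, and 200-frame trajectories for
clustering. The acceptance script fits one triplicate titration per
stochastic target. These sizes put every sampling error well below the
assertion tolerances.

## Known limitations

The exact supplementary equations behind the published EC50 → K_lig
inversion are not public; under this package's reconstruction (equal
macroscopic constants, DL+DLL observable) the inversion of
EC50 = 2.5 µM at K_tet = 1.60 µM and 100 nM protein gives ≈ 3.9 µM versus
the published 3.75 µM (≈ 4% apart), and the forward EC50 at
K_lig = 3.75 µM gives ≈ 2.40 µM versus 2.5 — consistent within the
experimental uncertainties but not an exact reproduction of the original
algebra. Binding kinetics, heterotropic cooperativity, ITC isotherms, and
the free-energy simulations that produce permeability scores are out of
scope.
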