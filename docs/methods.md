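# Methods

## Scope and intent

`shblab` studies the statistical mechanics of a single short hydrogen bond
(SHB) embedded in an ammonium-rich environment, at the level of a model
Hamiltonian. It is not a force field for any real crystal: the model is
the minimal construction that reproduces, with controllable parameters,
the qualitative and quantitative signatures reported for SHBs in
first-principles simulation work — a low-barrier asymmetric double well
along the proton-transfer coordinate, classical coupling of transfer to
heavy-atom compression and to the rocking of a neighbouring ammonium ion,
and the elimination of all three signatures by nuclear quantum effects
(NQEs). Because the sampler and the analyses are exercised against this
generator, every estimator in the package can be validated against exact
oracles; what passing those tests does *not* show is that the estimators
are robust to features of real trajectory data the generator lacks (see
Limitations).

## Units

Lengths in Å, energies in eV, masses in amu, times in fs, temperatures in
K. k_B = 8.617333262×10⁻⁵ eV/K, ħ = 0.6582119569 eV·fs, and
1 amu·Å²/fs² = 103.6427 eV. All defaults refer to T = 300 K.

## The model Hamiltonian

Coordinates: the SHB proton (longitudinal displacement x from the O–O
midpoint plus a transverse pair yz), the O–O distance R, the ammonium
nitrogen displacement u_N from its lattice site, and four N–H stretch
displacements s_a. The potential is

    V = Δ‡ (x² − x0(R)²)² / x00⁴                (compressible double well)
      + ε x / x00                               (static tilt)
      + ½ k_R (R − R0)²                         (O–O restoring)
      + ½ k_⊥ |yz|²                             (transverse confinement)
      + ½ k_N |u_N + (c/k_N) x ê|²              (presolvation coupling)
      + Σ_a ½ k_NH s_a²                         (N–H stretches)

with x0(R) = x00 + κ (R − R0) and ê the SHB axis.

Two structural choices deserve explanation:

* **Quartic normalization by x00⁴.** Dividing the well mismatch by the
  *fixed* rest separation rather than by x0(R)⁴ makes the barrier at the
  midpoint scale as Δ‡·x0(R)⁴/x00⁴: compression genuinely lowers the
  transfer barrier. Consequences verified in the tests: the classical
  transition state is compressed, |δr| and R correlate positively, and a
  quantum-delocalized proton (which spends its time near the midpoint)
  pulls the *average* O–O distance slightly inward — the expected modest
  quantum strengthening of the bond. With the R-dependent normalization
  the barrier would be R-independent and the quantum ensemble would
  instead expand the bond.

* **Displaced-equilibrium coupling.** Expanding the coupling term gives
  the bilinear c·(u_N·ê)·x plus the counter-term c²x²/(2k_N). The
  counter-term matters: integrating the environment out of the Boltzmann
  distribution then returns *exactly* the bare tilted double well as the
  proton's potential of mean force, so the barrier parameter Δ‡ coincides
  with the barrier a long run recovers by Boltzmann inversion, and the
  coupling strength c can be calibrated against the correlation targets
  without shifting the barrier. Physically this says the ammonium
  equilibrium position tracks the proton ("presolvation") rather than
  exerting an unbalanced mean force.

## Parameters

| name | default | units | meaning / why |
|---|---|---|---|
| `barrier_eV` (Δ‡) | 0.030 | eV | double-well barrier; the reference value for an SHB at R ≈ 2.5 Å, just above k_BT |
| `R0_A` | 2.50 | Å | equilibrium donor–acceptor distance (SHB regime) |
| `x00_A` | 0.20 | Å | well half-separation at R0; calibrated (below) |
| `kappa` | 0.5 | – | well narrowing per Å of compression |
| `kR_eVA2` | 10.0 | eV/Å² | O–O restoring constant → σ_R ≈ 0.05 Å at 300 K |
| `kperp_eVA2` | 8.0 | eV/Å² | transverse proton confinement |
| `asym_eV` (ε) | 0.003 | eV | static tilt; calibrated (below) |
| `c_eVA2` | 1.41 | eV/Å² | proton–rocking coupling; calibrated (below) |
| `kN_eVA2` | 3.0 | eV/Å² | ammonium-site restoring constant → σ_u ≈ 0.09 Å |
| `r_NH0_A` / `k_NH_eVA2` | 1.05 / 30.0 | Å, eV/Å² | N–H bond rest length and stiffness (ħω ≈ 0.35 eV, strongly quantum) |
| `T_K` | 300 | K | thermostat temperature |

Wannier-emission parameters (`WannierEmissionParams`): C–O bond centers at
0.55 ± 0.02 Å from the host oxygen, O–H bond centers at 0.40 ± 0.02 Å
(classical) with an elongation of `slope_vs_dr` = 0.05 Å per Å of proton
sharing and a +0.05 Å shift with σ = 0.04 Å under quantum sampling, lone
pairs at 0.30 ± 0.015 Å. Zero widths are allowed (the noise-free limit is
used for exact classification tests).

### Calibration

Three parameters are not dictated by the reference numbers and were fixed
once, by the scan in `scripts/calibrate_coupling.py`, against four
simultaneous targets: classical Boltzmann-inverted barrier ≈ 30 meV,
classical max |ρ| over SHB-aligned rocking modes ≈ 0.68, quantum (P = 6)
median |ρ| ≤ 0.35, and a single-well quantum δr profile.

* `c_eVA2 = 1.41` follows, to within the Gaussian-response estimate
  ρ = a/√(1+a²) with a = c·σ_x/√(k_N k_B T), from the classical
  correlation target.
* `x00_A = 0.20` (δr wells at ±0.40 Å): at 0.25 the six-bead quantum
  profile retains a ~3 meV double dimple and the quantum correlations
  stay above the target; at 0.20 the zero-point energy (≈ 60 meV against
  a 30 meV barrier) fully symmetrizes the proton.
* `asym_eV = 0.003` sets a clearly visible ~6 meV well asymmetry while
  keeping the *global-minimum* barrier (≈ Δ‡ + ε minus a small entropic
  correction from the R-stiffening of the wells) at ~30 meV.

The spectator-oxygen shell of the fixture (below) is part of the same
calibration: its icosahedral directions are tilted 28° about the lateral
axis so that most rocking-mode pair separations mix axial and transverse
character, which sets the *median* of the correlation spectrum while the
purely SHB-aligned pairs carry the maximum.

## Fixture geometries

`build_pyro_fixture` is a deterministic 22-atom arrangement: the SHB pair
on the x axis at separation R0 with the proton in the donor-side well; one
carbon 1.25 Å from each SHB oxygen (120° from the O–H direction, as in a
carboxylate) for C–O Wannier classification; an ammonium ion (N + four
tetrahedral H at 1.05 Å) offset 3.0 Å laterally from the SHB midpoint and
0.18 Å axially toward the donor — the geometric origin of the donor/
acceptor RDF asymmetry; ten spectator oxygens at 2.85–4.45 Å from N on
tilted icosahedral directions (twelve oxygens in total within 5 Å of N);
two more oxygens beyond 5 Å; a 14 Å cubic cell that keeps minimum image
inert. Oxygen site labels 1–12 are assigned by sorted rest distance from
N; "SHB-aligned" pairs are those whose separation unit vector has
|cos| > 0.8 with the SHB axis.

`build_control_fixture` is the normal-hydrogen-bond control: one donor
nitrogen with five acceptor oxygens at 2.70–2.90 Å (evenly spaced), four
N–H hydrogens at 1.0 Å. It contains no SHB by construction and must
produce zero detections.

## Samplers

Plain Metropolis Monte Carlo; the observables of interest are static
ensemble averages, so no dynamics are claimed (and none should be read
into the pseudo-time axis). The quantum sampler uses the primitive
discretized action

    U = Σ_k Σ_q m_q P/(2 β² ħ²) |r_{q,k} − r_{q,k+1}|²  +  (1/P) Σ_k V(config_k)

with quantized coordinates = proton (3D) and the four N–H stretches (mass
m_H each), and classical coordinates (R, u_N) entering every bead
identically (mixed quantum–classical convention). No staging or
normal-mode transforms: at P = 6–8 the primitive chain mixes adequately.

Move mix per sweep: single-bead displacements (proton, stretches),
whole-chain translations (keep the centroid mobile), classical R and u_N
displacements, and a proton **mirror move** (x_k → −x_k for all beads with
u_N,x → −u_N,x). The mirror move is a symmetric involution, so plain
Metropolis acceptance — only the tilt term changes — preserves detailed
balance; it removes the slow well-hopping mode that would otherwise
dominate the correlation time of the double well. Step sizes are tuned
toward 40% acceptance in 100-sweep windows during burn-in (default 10% of
the run, mirroring a discarded equilibration period) and then frozen;
production acceptance outside [0.05, 0.95] triggers a warning, not an
error. Sampling is bit-reproducible given (seed, config, parameters).
The recorded pseudo-time step is 0.5 fs per sweep (times `record_every`),
which gives the 50 fs analysis blocks a definite meaning in sweeps.

Validation: the bead-averaged ⟨x²⟩ of a harmonic chain is checked at 1%
against the exact finite-P value from inverting the ring-polymer precision
matrix (`harmonic_pimc_oracle`; P = 64 agrees with the
(ħ/2mω)·coth(βħω/2) closed form at 2%), and the frozen-environment proton
marginal is checked by a χ² test against direct quadrature of
exp(−V_1D/k_BT) at α = 0.01.

## Analysis conventions

* **SHB detection** uses an O–O cutoff of 2.60 Å (above the nominal
  2.5 Å ceiling, so thermally stretched frames are kept) with a bridging
  hydrogen within 1.80 Å of both oxygens; the donor is the oxygen nearer
  the proton, ties to the lower index. Detection is done once on the
  time-averaged structure and the triple is then tracked, keeping the δr
  sign convention pinned to one donor through transfer events.
* **Quantum δr** is bead-pooled (the proton's quantum distribution is a
  bead statistic); the per-frame bead mean is used only where one value
  per frame set is required, i.e. when correlating against the
  bead-shared classical environment coordinates.
* **Free-energy profiles**: 81 bins over [−0.8, 0.8] Å; empty bins are
  NaN (undefined, never zero); gauge fixed to min F = 0. Block errors use
  contiguous 50 fs blocks and the delta method σ_F = k_BT·σ_p/(p√N_b).
* **Barrier/minima**: strict local minima of the 3-bin median-smoothed
  profile with a 1 meV prominence floor (sparse tail bins would otherwise
  register as minima); barrier = profile maximum between the two deepest
  minima measured from the global minimum; asymmetry = their depth
  difference. The smoothing and the floor are the documented tie-breaking
  devices for noisy double wells.
* **Correlations** use the population (1/n) covariance convention; signed
  ρ is stored, |ρ| summarized. The 66 pair series d_i,j are never
  materialized (covariance algebra on the 12 site series).
* **RDFs** normalize by shell volume 4πr²dr and the others' number
  density; r_max is capped at half the shortest cell edge.
* **N–H distribution**: the four nearest hydrogens to N per frame, with a
  1.6 Å sanity cutoff — generous because quantum stretch excursions
  legitimately exceed a covalent-bond cutoff of 1.3 Å at P = 6.
* **Wannier classification** is by direction cosine to the bonded
  partners (C within 1.45 Å required; H within 1.3 Å optional), not by
  distance thresholds, because the quantum outward shift moves O–H bond
  centers into the lone-pair distance range. When the proton sits near
  the midpoint both oxygens fall within the hydrogen cutoff and may carry
  an O–H label — the operational reading of partial covalency. Histogram
  modes use 0.01 Å bins with 3-bin mean smoothing; ties resolve to the
  larger raw count, then the lower center.

## Problem sizes

The packaged analyses and checks run at desk scale: 6×10⁵ classical
sweeps (5.4×10⁵ recorded frames), 2.3×10⁵ quantum sweeps at P = 6
recorded every other sweep (≥10⁵ bead sets), ~10⁴ recorded frames for the
Wannier pipeline, and 3×10⁶ sweeps per harmonic oracle check. With the
numba-compiled kernels a full regeneration of every headline quantity
takes a few minutes on one CPU.

## What the generator does and does not emulate

Emulated: the double-well/single-well classical-vs-quantum contrast at
~30 meV barrier scale; compression gating of transfer; an asymmetric
environment with RDF asymmetry between the two SHB oxygens; rocking-mode
correlations up to |ρ| ≈ 0.68 classically and their quantum suppression;
quantum N–H broadening and O–O compression; four Wannier centers per
oxygen with a quantum outward shift of the O–H pair.

Not emulated: real crystal periodicity with multiple interacting SHBs;
anharmonic N–H chemistry (no dissociation, harmonic stretches — the N–H
distribution is symmetric about its rest length by construction);
genuine time correlation (Monte Carlo pseudo-time only, so block errors
measure sampler, not physical, correlation); electronic structure (the
Wannier stage is distributional, not a wavefunction localization);
thermostat physics (plain PIMC replaces generalized-Langevin bead
thermostats, so finite-P convergence is slower than in the thermostatted
reference setups — P = 6 here relies on the calibrated well geometry).

## Known limitations

* The finite-P primitive action underconverges the most quantum modes
  (βħω ≈ 13 for the N–H stretch): quantum N–H widths are qualitatively,
  not quantitatively, converged at P = 6.
* `barrier_and_asymmetry` measures from the global minimum; for strongly
  tilted wells the escape barrier from the shallow side (Δ‡ − ε) is the
  smaller and physically rate-limiting one.
* The mirror move exploits the near-symmetry of the model potential; for
  strongly asymmetric variants (ε ≫ k_BT) its acceptance vanishes and
  well-hopping slows accordingly.
* Only orthorhombic cells are supported throughout.
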