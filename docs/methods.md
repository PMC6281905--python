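# Methods

## Scope and model

`esterkin` post-processes electronic-structure results for the
rate-determining step of As/P ester hydrolysis: associative (Sₙ2-like)
attack of a water nucleophile on the central atom, through a
pentacoordinated trigonal-bipyramidal transition state, with first-order
kinetics.  Only this step is modelled; leaving-group departure, the
pentacovalent intermediate's onward chemistry, solvation models and the
quantum-chemical energy evaluation itself are outside the package.  Energies
supplied to the package are assumed to already include whatever solvation
treatment the upstream calculation used.

Units are fixed: Å for lengths, kcal/mol for energies, K for temperature,
cal/(mol·K) for entropy.  Hartree input is accepted only with an explicit
unit tag at the activation-strain boundary.  Physical constants come from
scipy's CODATA 2018 tables; the derived conversion 1 cm⁻¹ =
2.85914×10⁻³ kcal/mol and the 298 K Eyring prefactor k_BT/h =
6.2093×10¹² s⁻¹ follow from them.

## Kinetics

The Eyring equation k(T) = (k_B·T)/(h·c°)·exp(−ΔG‡/RT) is used with a
transmission coefficient of 1 and a dimensionless standard-state factor
c° = 1 (a hook allows other values, but the default reproduces the published
convention).  T = 298 K is the default analysis temperature.  Rates are kept
as natural-log values internally: at ΔG‡ ≈ 44 kcal/mol the rate is
~10⁻²⁰ s⁻¹, and log-space arithmetic keeps the forward/inverse pair exact to
1e-10 relative across at least 60 orders of magnitude (property-tested).
Stability ratios are plain rate quotients; a ratio below 1 warns that the
arguments are swapped rather than failing.

## RRHO thermochemistry

Ideal-gas rigid-rotor harmonic-oscillator corrections at 1 atm:
Sackur–Tetrode translational entropy, classical rotation from the principal
moments of inertia (linear and monatomic species handled; the symmetry
number defaults to 1 and is configurable), harmonic vibrations over real
modes only.  A transition state must carry exactly one imaginary mode
(encoded as a negative wavenumber) and that mode is excluded from every
statistical sum.  No quasi-harmonic floor is applied to low frequencies —
the harmonic partition function is evaluated as supplied, the simplest
defensible choice when the upstream protocol specifies nothing else.  The
reported Gibbs correction satisfies G_corr = H_corr − T·S exactly by
construction, and H_corr includes ZPE, thermal internal energy and the RT
(PV) term.

## Activation strain

ΔE‡_act = ΔE‡_dist + ΔE‡_int with the separated relaxed fragments
(ester + water) as the reactant reference.  A pre-reaction-complex reference
is accepted only when annotated; the resulting deviation from additivity is
reported, never silently absorbed.  Fragment order never affects results.

## Structure handling

XYZ parsing/writing is internal (8-decimal output, so round-trips are exact
to well below 1e-6 Å); the PDB ATOM/HETATM subset goes through biotite, with
the element column taking precedence over the atom-name heuristic.  Internal
atom indices are 0-based; PDB/XYZ serials are 1-based and preserved on
write.  Bond perception is distance-based: i–j bonded iff
d ≤ 1.15·(r_cov(i)+r_cov(j)) with Cordero covalent radii embedded as data.
The reaction centre is the As/P atom bonded to the most oxygens; ties break
to the lowest serial and are flagged ambiguous (a pyro-type ester, where the
centre and the leaving-group phosphorus both carry four oxygens, is the
canonical ambiguous case).

Classification walks the bridging oxygens away from the centre: one bridge
is a monoester, two a diester; phosphorus beyond the bridge gives the
O-P-R pattern (class 1A), carbon gives O-C-R (1B for monoesters, 2 for
diesters).  The anionic state is read from the declared net charge (−1 mono,
−2 di); other charges are rejected rather than guessed.

Torsions follow the IUPAC convention: the signed value is unchanged when the
four atoms are read from either end, and negated by mirror reflection.

## QM/MM partitioning

The two-layer partition rule admits as cut bonds only non-polar bonds
between two sp³ carbons (sp³ is topological: exactly four neighbours) whose
endpoints both lie more than `min_graph_distance` (default 4) bonds from the
reaction centre.  Because a layer boundary may only pass through eligible
bonds, the minimal QM region is exactly the connected component of the
centre after deleting all eligible bonds — any smaller region would sever an
ineligible bond.  This closed-form construction is verified against
brute-force cut-set enumeration on small graphs in the test suite.  Each cut
is saturated with a hydrogen link atom at 1.09 Å along the severed bond axis
(no g-factor scaling).  With no eligible bond the whole system becomes the
QM layer with a warning, not an error.  The MM layer is marked frozen in the
manifest, matching the usual practice of constraining the outer region of a
strand model.

## Superposition

Kabsch least-squares rigid alignment via SVD with the determinant
correction, so the rotation is always proper.  Correspondence is explicit;
the helper pairs atoms on (chain, residue number, atom name) and excludes
hydrogens by default, since crystal references usually lack them.  Fewer
than three pairs or a collinear pair set is a degeneracy error.  Validation
against an external crystal reference requires downloading that structure,
so the shipped tests exercise the identical route on synthetic strands with
constructed ground truth (exact recovery of applied rigid transforms; RMSD
bounded by applied noise) instead of asserting any literature RMSD.

## Synthetic data: what it emulates, and what it does not

The generators stand in for the outputs of a QM/MM workflow:

* **Ideal esters / TS pairs** place the centre, bridging oxygen(s) and O_p at
  the published reactant and TS bond lengths and angles for each
  (central atom, class, anionic state) combination; all other atoms carry a
  uniform ±0.01 Å jitter so perception and classification run on
  non-idealised coordinates.  Where the published class-2 rows are mutually
  inconsistent at the last printed digit, the bond lengths and the
  O3′–E–O5′ angle are placed exactly and the O3′–O5′ distance is derived
  (it agrees with the printed value to <0.01 Å).  TS structures are
  5-coordinate with the water oxygen axial (E–O_w at 1.90 Å for P, 2.00 Å
  for As, inside the bond-perception cutoff) and carry exactly one imaginary
  mode.
* **Fragment-energy sets** realise prescribed distortion/interaction targets.
  Targets are quantised to a 2⁻²⁰ kcal/mol grid and equilibrium energies are
  integer-valued, which keeps every derived sum exactly representable —
  recovery by the analysis code is therefore bit-exact, not approximate.
  The default per-species targets reproduce the qualitative published
  pattern (phosphorus esters deform more in the TS than arsenate esters;
  dianionic more than monoanionic); their absolute magnitudes are
  illustrative, since the published decomposition is only available as a
  figure.
* **Thermo species** draw random frequencies and solve for the TS electronic
  energy using a closed-form RRHO evaluation written independently of the
  thermochemistry module, so the prescribed ΔG‡ is recovered through the
  full analysis path to ~1e-11 kcal/mol.
* **Mock strands** are simplified sugar–phosphate single strands
  (O5′–C5′–C4′(–C1′–base placeholder)–C3′–O3′ with explicit hydrogens,
  bridging P/As with two free oxygens) whose declared bond topology is also
  reproduced exactly by distance-based perception on the jittered
  coordinates.

None of these are physically realistic force-field structures: vibrational
spectra are uniform draws, base stacking and electrostatics are absent, and
strand geometry is a zig-zag, not a helix.  Passing tests therefore
demonstrate correctness of the analysis operations and their invariants on
known ground truth — not the accuracy of any electronic-structure protocol
on real nucleic acids.

## Numerical choices

* Bond-perception scale 1.15; linear-rotor threshold 1e-6 amu·Å² on the
  smallest principal moment; Kabsch collinearity detected by centred-matrix
  rank at tolerance 1e-8.
* Consistency between a supplied rate and a supplied ΔG‡ is enforced to
  0.05 kcal/mol (configurable); contradictions are errors, not warnings.
* Reported tables render lengths/angles to 2 decimals and rates in
  scientific notation at 2–3 significant figures, matching how such values
  are printed.
* Problem sizes in the shipped tests (25–65-atom fixtures, 1000-seed
  property sweeps, 10⁴ random rigid transforms) were chosen so the whole
  suite runs in seconds while still exercising every invariant.

## Known limitations

* No anharmonic, hindered-rotor or quasi-harmonic corrections; no tunnelling
  or variational refinement of the TST rate.
* No bond-order perception, protonation-state assignment or force-field
  typing; the MM layer is only partitioned and tagged, never evaluated.
* Coordinate sets distributed as PDF documents must be extracted by the
  user to XYZ/PDB before analysis; multi-model PDB and mmCIF are
  unsupported.
* The classifier covers mono- and diesters with O-P-R / O-C-R bridges;
  triesters and mixed patterns are rejected explicitly.
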