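# Methods

## Model

The aggregate is treated in the Heitler–London limit: pigment wave
functions do not overlap, so the singly-excited manifold of N pigments is
spanned by N product states and the electronic problem reduces to the
N×N Frenkel Hamiltonian with site energies ε_m on the diagonal and
pairwise couplings H_ml off it.  Two-exciton states, exciton–phonon
coupling and transfer dynamics are outside the model.

Couplings use the point-dipole approximation with the dipole placed at
the central Zn atom (inter-pigment distance is therefore the Zn–Zn
distance).  This is adequate when inter-pigment separations are large
compared with the transition-density extent and the dominant interaction
is electrostatic; it degrades for closely stacked, strongly overlapping
pigments, where transition-density-cube or transition-charge methods
would be needed (deliberately not implemented).

Solvent screening multiplies the coupling by
f(R) = A·e^(−βR) + f0 (defaults A = 2.68, β = 0.27 Å⁻¹, f0 = 0.54,
appropriate for ε ≈ 2).  A `literal` variant f = A·e^(−βR + f0) is also
available; it decays to zero at large R, which is unphysical for a
dielectric (screening should tend to a constant 1/ε-like factor), so
`additive` is the default whenever screening is enabled and `off`
(f ≡ 1) is used for vacuum calculations.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| dipole magnitude | 5.00 (vacuum), 6.18 (solvent) | D | Qy transition dipole along N21→N23 |
| mean site energy | 1.973 | eV | Qy excitation of a monomer in the aggregate (628 nm) |
| site-energy sd | 0 | eV | optional Gaussian static disorder, seeded |
| σ (broadening) | 0.0248 | eV | inhomogeneous Gaussian width (~200 cm⁻¹) |
| A, β, f0 | 2.68, 0.27 Å⁻¹, 0.54 | — | screening factor for ε ≈ 2 |
| truncation | 0.14 | meV | |H1j| threshold fixing directional extents |
| calibration target | −80 | meV | nearest stacking-neighbor coupling |
| slip | 5.0 | Å | in-plane offset of consecutive layers |
| in-plane spacings | 14.0 / 13.0 | Å | along-dipole / perpendicular lattice constants |

σ is interpreted in eV: every energy entering the Gaussian exponent is
in eV, and 0.0248 eV is a physically sensible inhomogeneous width for
these aggregates.  The 1/(4πε₀) prefactor (0.6241509 eV·Å³/D²) and the
conversions hc = 1239.842 eV·nm and 8065.544 cm⁻¹/eV are frozen from
CODATA constants in one module so all emitted energies, wavelengths and
wavenumbers are mutually consistent.

## Synthetic lattice

No aggregate coordinates are published for this system, so the builder
generates them: one monomer template (either a real structure from an
XYZ file with an explicit Zn/N21–N24 role map, or an ideal toy skeleton)
repeated by rigid translation on a three-direction lattice.  Monomers
are never rotated — the model is a parallel stack — so every site has
the same dipole vector.  Site ordering is deterministic (direction 3
fastest) and static disorder is drawn from a seeded generator in site
order, making every run bit-reproducible; changing the seed changes only
site energies, never positions.

Direction roles: direction 1 translates along the dipole axis
(head-to-tail, orientation factor κ = −2, negative coupling), direction 2
in-plane perpendicular to it (side-by-side, κ = +1, positive coupling —
the H-aggregate direction), direction 3 stacks layers normal to the ring
with an in-plane slip along the dipole ("stepped" layering).  The slip
matters: an unslipped stack couples side-by-side (positive), whereas a
5 Å slip at ~3.3 Å vertical spacing gives κ < 0 and hence the negative,
J-type stacking coupling these aggregates are known for.  Because the
cumulative translation scales slip and rise together, couplings along
the stacking chain still decay exactly as 1/j³.

Rather than guessing distances, the stacking spacing is calibrated by a
bracketed scalar root-find (Brent) so that the nearest
stacking-direction coupling equals a target (−80 meV for the 5.00 D
vacuum dipole), reproducing it to 1e-6 eV; the calibrated spacing puts
the Zn–Zn stacking distance at 5.98 Å, inside the 6–7 Å range reported
for chlorosomal stacks.  If the target's sign is unattainable for the
chosen arrangement (e.g. a negative target with zero slip) the
calibration fails loudly and reports the attainable coupling range.  The
in-plane lattice constants (14 and 13 Å) were chosen once as realistic
macrocycle-plus-ligand packing distances; with the 0.14 meV truncation
threshold they give directional interaction extents of 4 (along-dipole),
3 (perpendicular) and 8 (stacking) neighbors on 24-site chains.

The named size presets Zn12 (4×1×3), Zn24 (4×1×6), Zn36 (4×1×9),
Zn72 (4×2×9) and Zn108 (4×3×9) share one template and one set of
translation vectors and differ only in counts.

What the generator does *not* emulate: rotational or reverse-parallel
(antiparallel) packing, curvature (tubular/spiral chlorosome
morphologies), correlated or dynamic disorder, and per-site energies
from an electronic-structure method.  Passing tests therefore certify
the exciton machinery and the qualitative J/H size phenomenology on an
idealized lattice, not quantitative peak positions of any real
aggregate: simulated peaks here (e.g. 690.7 → 707.5 → 711.4 nm for
Zn12 → Zn24 → Zn36) show the correct red-shift-and-saturate /
blue-shift-on-in-plane-extension pattern, with magnitudes specific to
the calibrated synthetic geometry.

## Numerics

* DOOP is computed from exactly two bonds and one included angle, not a
  least-squares ring-plane fit; cos(θ/2) is evaluated via the half-angle
  identity √((1+cos θ)/2), which is exact at θ = 180° and guarantees a
  nonnegative result for θ ≤ 180°.
* The coupling matrix is assembled pair-by-pair with the scalar kernel
  (N ≤ a few hundred; ~6k pairs at N = 108), keeping it trivially equal
  to a brute-force double loop.  The kernel parenthesizes its projection
  product so H_ml = H_lm holds exactly in floating point.
* Diagonalization is dense `eigh`; eigenvalues ascend.  Degenerate
  subspaces may return in any orthonormal basis — all downstream
  observables (dipole strengths, spectra) are invariant under
  orthonormal remixing within a degenerate block.
* The spectrum uses a 2000-point uniform energy grid covering all
  eigenvalues ± 5σ; the peak is refined off-grid by a parabolic fit
  through the grid maximum and its two neighbors (grid-halving moves
  the refined peak by < 0.1 nm).  The photon-energy prefactor E in A(E)
  is retained; it shifts a narrow line by only ~σ²/E.
* Unit conversions are linear among eV/meV/cm⁻¹ (signed values allowed,
  so shifts and couplings convert directly) and via λ = hc/E for
  wavelengths (positive values only).
* Peak wavelengths are reported at full precision and rounded to 1 nm
  in human-readable summaries.

## Design choices

* Atom roles (Zn, N21–N24) are assigned only through an explicit index
  map supplied by the user, never inferred from element symbols: the
  four nitrogens are chemically distinct and silent misassignment would
  corrupt the dipole axis.
* The dipole sign convention is N21→N23 uniformly; observables are
  invariant under a global sign flip.
* The second-quantized ladder-operator formalism is represented
  implicitly by the eigenvector coefficient matrix; no operator objects.
* The CLI (`doop`, `build`, `couplings`, `calibrate`, `spectrum`,
  `size-series`) is a thin layer over the library; every run writes a
  JSON report echoing the fully resolved configuration, from which the
  run can be reproduced bit-for-bit (only the timestamp differs).

## Known limitations

* Point dipoles at the Zn position overestimate couplings at short
  range and ignore transition-density shape.
* Uniform site energies by default; real aggregates have site-to-site
  variation that the normal-disorder option only caricatures.
* The absolute simulated peak positions depend on the synthetic lattice
  geometry (slip and in-plane spacings), which real structural data
  would constrain but this package does not possess.
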