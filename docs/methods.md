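# Methods

## The model

`chemion` implements a deliberately minimal, topology-first quantum-chemical
picture of singly bound molecules.  A molecule is a set of **Euler vertices**
— central atoms, hydrogen ligands, and lone-pair positions ("loves") — and
every constructible chart satisfies the Euler rule

    #vtx = #chp + 1,

where a chemion pair (#chp) is a shared valence-electron pair: one per bond,
one per lone pair.  Each vertex carries exactly **one spherical Slater
orbital** n_val·s, with n_val the periodic-table row (1 for H; 2 for C, N, O,
F and their lone pairs; 3 for Si, P, S, Cl and theirs) and default exponent

    ζ_V = Z_val(V) / n_val(V),

with Z_val the periodic-table column.  Lone pairs sit one Bohr radius
(0.529177249 Å) from their parent atom at an unoccupied tetrahedron slot and
carry the parent's valence shell but no nuclear charge.

Geometries are ideal tetrahedra: the one bond angle arccos(−1/3) ≈ 109.471°,
the one dihedral 2π/3 = 120°, and bond lengths from a configurable table
(defaults are standard covalent lengths, e.g. C–C 1.54 Å, C–H 1.09 Å; the
model is symbolic, not an empirical-geometry refinement).  Internal units are
atomic (bohr, hartree); I/O is in ångström via 1 bohr = 0.529177249 Å.

### Chemion ensembles and proportional charges

Electrons are treated as ensemble-localized "chemions": a computation always
refers to a **chemion ensemble** ε — the full molecule's 2·#chp valence
electrons, or a single bond's pair (#chp = 1).  The nuclear frame seen by an
ensemble is rescaled proportionally,

    Z_prop(C) = Z_val(C) · 2·#chp(ε) / Σ_D Z_val(D),

so Σ_C Z_prop(C) = 2·#chp(ε) always: the ensemble is electrically neutral
against its own nuclear background.  The ensemble energy is
E_0 = E_nucl(ε) + E_chem(ε) with E_nucl the pairwise Coulomb sum of the
proportional point charges and E_chem the lowest full-CI eigenvalue (singlet
or triplet, the singlet winning ties).

This is a *known modelling fiction*: localizing electron subsets violates
antisymmetry across ensembles, and distinct ensembles of the same molecule
are not additive.  The package therefore reports **per-bond** torsion
potentials only and never sums ensemble energies into one molecular total.

## Integrals

The four vertex-integral families are overlaps S, kinetic energies K,
nuclear attractions U(·,·,C), and two-chemion repulsions R (chemists'
notation, stored dense with full 8-fold permutational symmetry; bases never
exceed ~20 vertices).

Each normalized node-less Slater radial function r^(n−1)e^(−ζr) is expanded
in 1–6 spherical Gaussian primitives by a variable-projection least-squares
fit at ζ = 1 (Gauss–Legendre quadrature on [0, 25] bohr, exponents
parameterized as an increasing ladder with minimum neighbour ratio 1.3 to
exclude degenerate local minima), scaled exactly to any ζ by α → αζ²,
c → cζ^(3/2), and renormalized to unit self-overlap.  All integrals are then
analytic over the primitives (Boys function F₀ via erf), so three- and
four-center integrals are exact within the fit.  At order 6 the two-center
1s–1s overlap at 1.4 bohr is accurate to ~3·10⁻⁷; one-center kinetic and
attraction moments to ~2·10⁻⁴ relative — the truncation of the expansion,
not of the integral formulas.  Closed-form two-center Slater integrals serve
as independent oracles in the test suite only.

An optional `two-center-only` mode zeroes repulsion entries spanning more
than two distinct centers and attraction entries whose nucleus is foreign to
both orbital centers.  It is one *interpretive* reading of restricting the
picture to two-center repulsion integrals, is off by default, and is not
used by any default pipeline.

## Vertex condensation and the fragment bank

A fragment's orbitals can be replaced by one **recursion orbital**, their
normalized sum φ_ω = N_ω Σ_p φ_p with N_ω = (Σ_pq S_pq)^(−1/2).  Condensing
any integral family is the normalized double (or quadruple) sum of precursor
blocks — implemented as a congruence with the aggregation matrix T[p, g] =
N_g.  Because condensation is linear, condensed blocks equal direct
integrals over the explicitly summed orbital to machine precision (tested
against an independent multi-center primitive evaluator).

One subtlety is documented rather than hidden: renormalization happens at
*every* level, so a nested (level-2) recursion orbital is a **weighted** sum
of anchors — weight N₂·N₁(group) — not the plain renormalized sum.  The
recursion is associative in the correct sense (two-level condensation equals
the one-shot congruence with composite weights), and the tests assert
exactly that.

Condensed blocks, and converged Fock matrices, live in a **fragment bank**
(HDF5): one group per key, keyed by a hash of element sequence, bond-length
table, exponent rule, torsion values rounded to 1e-9 rad, evaluation mode,
expansion order, level, ensemble label, and the fragment's internal geometry
(pairwise distances rounded to 1e-9 bohr — rigid-motion invariant, exactly
like the integrals themselves).  A Fock block is only ever reused under an
identical key ("available"); any mismatch returns a "not available" signal
and triggers a fresh build.  float64 blocks round-trip bit-identically.

### Integral budgets

Growing a chain by one CH₂ adds 4 vertices: the new chart has a = 3n+8
vertices of which the reused precursor covers b = 3n+4.  Fresh raw entries
per prolongation step are therefore a²−b² overlaps and kinetics, ≤ a³−b³
attractions (the nucleus axis shrinks when lone pairs are present), and
a⁴−b⁴ repulsions; the anchor chart itself costs 5², 5², ≤5³, 5⁴.  With a−b
= 4 constant, the difference-of-powers factorizations make the per-step cost
linear in n.  The scanner's bank-miss accounting reproduces these counts
exactly (integer equality, asserted in the tests).

## RHF

The Roothaan equations F C = S C E are solved by symmetric orthogonalization
(scipy's generalized symmetric eigensolver), eigenvalues ascending, column
phases fixed by making the largest-magnitude coefficient positive.  The
closed-shell density D = 2 Σ_o^{#chp} C_o C_oᵀ is iterated with the RMS
density criterion

    σ(i) = { #vtx⁻² Σ_mn [D_mn(i) − D_mn(i−1)]² }^(1/2) < tol.

Defaults: core (D = 0) initial guess, 200 iteration cap, optional linear
density damping (0.3 recommended for the monofocals, which otherwise
oscillate), documented threshold 1e-4 for standalone SCF and 1e-8 whenever
the orbitals feed CI (the looser value leaves Brillouin residuals too large
for clean CI cross-checks).  Non-convergence returns a flagged state, never
an exception.  E_0^RHF is computed both as ½ Σ D(H+F) and from the
orbital-sum expression; the two agree to 1e-10 in the tests.

## Full CI

Since #vtx = #chp + 1, a converged reference leaves exactly **one virtual
orbital r**.  The full many-chemion space is then the reference Ψ₀, the
singles Ψ_a^r, the paired doubles Ψ_aa^rr and the unpaired doubles Ψ_ab^rr:

    #sing = (#chp+1)(#chp+2)/2,      #trip = (#chp+1)·#chp/2.

Both symmetric blocks are assembled from closed formulas over the MO
integrals (J_ab = (aa|bb), K_ab = (ab|ba), orbital energies ε_k, and
generalized Fock sums F^m_kl = h_kl + Σ_{n≠m}[2(kl|nn) − (kn|nl)], the sum
running over all orbitals except m), with √2 factors on the couplings
between the reference/paired and singly-excited configurations.  Basis
ordering is fixed (reference, singles ascending, paired doubles ascending,
unpaired doubles ascending pairs) so stored matrices are deterministic.

Every element class was cross-checked against an independent Slater–Condon
determinant construction (exact coefficient fitting over random symmetric
integral tensors).  Closed-form tables for this configuration basis
circulate with a few internally inconsistent coefficients; the forms
implemented here are the determinant-consistent ones, specifically:

* shared-pair doubles coupling ⟨Ψ_ab^rr|H|Ψ_bc^rr⟩ =
  −F^r_uv − 2(uv|rr) + (ur|rv) + (uv|ss) + (us|sv)
  (s the shared, u, v the unique occupied indices — symmetric in u ↔ v);
* triplet corrections relative to the singlet elements: −2K_ar (singles
  diagonal), −2(ar|rb) (singles coupling), −2K_ab (doubles diagonal) —
  i.e. the standard exchange splittings, not twice them;
* the shared-pair triplet coupling orient·(−S + 2(us|sv)), where the
  orientation sign is the phase convention of the antisymmetric triplet pair
  label (³Ψ_ba = −³Ψ_ab), not a formula change.

With these forms the union of the singlet and triplet block spectra equals
the M_S = 0 determinant-FCI spectrum to ~1e-13 for #chp ≤ 5 (the M_S = ±1
triplet blocks are identical by spin symmetry and are not stored).  The
`chemion validate` report states this explicitly.  The determinant route
(`chemion.detci`) diagonalizes S² first and projects H into each spin
eigenspace, so degenerate eigenvalues cannot leak between sectors; it shares
no code with the closed-formula blocks it arbitrates.

## Torsion scans and recursive growth

The shape question is reduced to one-dimensional problems: for the chain
H–(CH2)n–X only one torsion is varied at a time.  The potential at each grid
point is the **chain-bond ensemble** energy — the varied bond's single
chemion pair (#chp = 1) in the condensed two-vertex basis (proximal methyl
fragment vs distal rest), with that ensemble's proportional charges and full
nuclear repulsion.  Grids are uniform and half-open on [0, 2π) (default 24
points; the curve is periodic, no duplicated endpoint); the minimizing grid
point is reported with ties broken toward the smallest τ, plus a separate
three-point parabolic refinement.

`aufbau_polymerize` grows the chain one CH₂ per step at the methyl end: the
newest backbone bond is scanned, earlier optima stay frozen (each shifting
one bond further down the chain), and the distal fragment's integral block —
whose internal geometry is unchanged by the bond rotation — is served from
the bank.  On a cold bank the fragment block is computed standalone, stored,
and *then* consumed through the same reuse path, so cold and warm runs
produce bit-identical curves.

The model produces small torsional barriers even for axially symmetric
molecules (F₂, Cl₂, FCl): lone pairs occupy discrete tetrahedron slots, so
the basis breaks axial symmetry.  This is a known artifact of the picture,
kept (and tested) as such.

## Parameters that matter

| parameter | default | units | notes |
|---|---|---|---|
| expansion order | 6 | primitives/orbital | 3–4 suffices for topology/symmetry work; 6 for integral accuracy |
| ζ rule | Z_val/n_val | 1/bohr | screening-free ratio rule; exponent optimization is out of scope |
| bond lengths | covalent table | Å | overridable per pair in the molecule spec |
| lone-pair distance | 1 | bohr | fixed by the model |
| SCF σ threshold | 1e-4 / 1e-8 | — | standalone / CI-feeding |
| SCF damping | 0 (scan), 0.3 (monofocals) | — | plain iteration oscillates for chp = 4 ensembles |
| grid size | 24 | points | 15° spacing; tests use 6–12 on ethane-sized systems |
| bank torsion rounding | 1e-9 | rad | part of the reuse key |

## What the built-in inputs do and do not emulate

All test inputs are generated from the standard-tetrahedral builder: ideal
angles, fixed bond lengths, no relaxation.  Passing tests therefore
demonstrate the *topological and algebraic* behaviour of the method —
counts, invariances, variational structure, reuse correctness — not
agreement with experimental conformer energetics.  Real molecules have
non-ideal angles, stretched bonds and substituent-dependent exponents, none
of which the generator varies; barrier heights from this model are
qualitative by construction.

## Numerical choices and degenerate inputs

* Overlap matrices with smallest eigenvalue < 1e-8 raise a named
  linear-dependence error; nothing is silently regularized.
* Coincident nuclei are rejected in the nuclear-repulsion sum.
* Degenerate singlet/triplet ground states (|ΔE| < 1e-9) are reported as
  "degenerate" rather than silently resolved.
* Eigensolver phases, CSF ordering, and grid tie-breaks are all fixed, so
  every pipeline is run-to-run deterministic (asserted byte-for-byte on
  curve CSVs).
* The Boys function uses the series limit below t = 1e-13 to avoid 0/0.

## Known limitations

* No p or d orbitals, no multiple-ζ bases, no multiple bonds, aromatic
  rings, or hydrogen bridges — the picture is deliberately irreducible.
* Ensemble energies are not additive; no total molecular energy across
  bonds is defined or reported.
* No gradients and no global multi-torsion optimization; the sequential
  one-bond scheme is the method, not an approximation to be converged.
* The `two-center-only` mode is an interpretive restriction and is not the
  default evaluation path.
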