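# Methods

## The conversion model

SHELXL defines a refinement entirely through its instruction file: cell and
wavelength (`CELL`), symmetry by the coordinates of the general position
(`LATT`/`SYMM`) rather than a space-group symbol, element bookkeeping
(`SFAC`/`UNIT`), restraints, and atom records in fractional coordinates.
`shelxbridge` treats the conversion as a sequence of well-defined
sub-problems with exact or closed-form solutions wherever possible, and
confines every heuristic to an explicitly named, overridable parameter.

### Symmetry

Each of the 65 Sohncke space groups (plus the alternative settings that
occur in deposited files: hexagonal vs. primitive rhombohedral axes for
the R groups, short and non-standard monoclinic spellings) is stored as a
minimal set of generator triplets in a plain-text package data file.  The
full operator set is the breadth-first closure of the generators under
composition, with translations reduced mod 1 and modulo the
lattice-centering translations, using integer matrices and rational
translations so that group membership is exact, never a floating-point
comparison.  The `LATT` magnitude encodes the centering
(P=1, I=2, R=3, F=4, A=5, B=6, C=7), always with a negative sign since all
Sohncke groups are non-centrosymmetric; centering translations and the
identity are implied by `LATT` and never written as `SYMM` cards.

The stored generator table was cross-checked, setting by setting, against
gemmi's space-group tables (operator sets compared modulo centering, and
general-position multiplicities compared directly); the test suite repeats
that comparison on every run.  The emission order of `SYMM` cards —
breadth-first over generator products, identity first — is fixed but
arbitrary; SHELX attaches no meaning to the order.

### Coordinate and displacement-parameter transforms

The orthogonalization matrix follows the PDB convention (a along x, b in
the x–y plane), because that is the convention under which the input
coordinates are defined.  Fractional coordinates are M⁻¹·x.  Anisotropic
tensors arrive as Cartesian U×10⁴ (`ANISOU` records, which take precedence
over the B-factor column when both are present) and leave in the
CIF/SHELX convention U_ij = (M⁻¹ U M⁻ᵀ)_ij / (a*_i a*_j).  This transform
preserves the equivalent isotropic U and positive definiteness; both are
verified numerically over random cells.  Isotropic B becomes U = B/8π².
Output precision is six decimals for coordinates and five for U values and
occupancies, matching customary SHELX card precision.

### Identifier normalization

Chain remapping replaces an illegal chain character with the first unused
identifier in the fixed order A–Z, a–z, 0–9, blank; the mapping is reported
and more than 63 distinct chains is a hard error.  Renumbering leaves a
chain untouched when its numbering is already legal (no insertion codes,
all numbers within [−999, 9999], no duplicates); otherwise the chain is
renumbered sequentially from its first residue's number (or from 1 when
that itself is out of range), which preserves relative order and changes
as little as possible.  Insertion-code removal therefore shifts all
downstream residues rather than inventing negative numbers.  A chain
longer than the 10 999 representable numbers cannot be renumbered and is
an error.

### Restraints

The restraint library ships as package data: per residue type, the heavy-
atom bond graph with distance targets and esds in the style of the
Engh & Huber amino-acid values, sp² centres, and specific angle targets
where 109.5°/120° defaults would be wrong (rings, backbone).  1,3-distance
targets are derived from the angle targets by the law of cosines on the two
bounding bond targets, because SHELX restrains distances, not angles.
A small set of common crystallization-buffer ligands (GOL, EDO, SO4, PO4,
ACT) is included as a static auxiliary library; it is a synthetic stand-in
for the much larger server-generated libraries used in production
pipelines, and unknown residues simply produce a "not restrained" warning
rather than an error — intentional for heavy atoms at high resolution.

Disulfide detection pairs cysteine SG atoms whose separation lies in
[1.8, 2.5] Å, greedy nearest-first so each SG joins at most one bridge and
the result is independent of atom order; a detected bridge adds a DFIX
2.031 Å restraint and suppresses the thiol hydrogen rule.  Chain breaks
are declared where consecutive CA atoms are more than 4.5 Å apart — the
standard continuity heuristic — and every resulting segment gets its own
termini: ammonium hydrogens (HFIX 33) at the N terminus, carboxylate
targets for C-terminal residues carrying OXT.  Both thresholds are
function arguments, overridable per run.

Peptide planarity is one FLAT restraint per link covering CA(i), C(i),
O(i), N(i+1), CA(i+1), esd 0.1; no torsion restraint is applied, so a
cis/trans interconversion remains possible when the data demand it.
Cross-link 1,2/1,3 distance restraints (C–N and its flanking 1,3 pairs)
are not emitted; the FLAT restraint holds the link geometry in practice
and the omission is documented here as a known limitation.

### Scattering and dispersion

The element table is exactly the first 98 elements; atoms whose element
(from columns 77–78, with name-column inference as fallback) is not among
them abort the conversion naming the offending atom.  `UNIT` counts are
occupancy sums over the asymmetric unit multiplied by the operator count
and centering multiplicity.  Dispersion values come from an embedded
synthetic tabulation (`dispersion_synthetic.json`): per element, nodes of
(λ, f′, f′′, μ) spanning 0.2–3.0 Å with an extra node at the K edge (L3
for the heaviest elements).  Between nodes f′ is interpolated linearly in
log λ (it changes sign near edges), f′′ and μ log–log.  The magnitudes are
indicative power laws with the qualitatively correct edge behaviour
(f′ dipping strongly negative at the edge, f′′ dropping across it), not
measured coefficients; they exist to produce well-formed `DISP` cards and
are trivially overridden by hand-edited `SFAC`/`DISP` instructions, which
SHELXL always honours.  `DISP` cards are emitted for elements heavier than
oxygen when an X-ray wavelength is known; wavelengths under 0.1 Å are
classified as electron diffraction and suppress dispersion cards entirely.
Neutron data need a user-inserted `NEUT` card; the `.ins` carries a
commented reminder.

### Reflection data

The `_refln` loop is parsed with gemmi's CIF reader.  Intensities with
sigmas are preferred, amplitudes the fallback; anomalous-only data
(I+/I− columns) are accepted when both branches and their sigmas are
present and are written as +h and −h records.  Missing sigmas or a single
Friedel branch make the loop unusable.  Status codes map f → batch −1,
o → batch absent; all others are dropped and counted in the run report.
On output, values always carry an explicit decimal point (the decimal
position defines how SHELX reads the field), using the fewest decimals
that represent the value and degrading precision only when the 8-column
field would otherwise overflow; indices beyond ±999 cannot be represented
and abort with the reflection identified.  Working reflections are written
with a blank batch field ("+1 or absent" are equivalent and both are
accepted on read-back).

### Document assembly

Card order is fixed: TITL, CELL (wavelength first; Cu Kα 1.54184 Å assumed
with a commented note when no wavelength is known), ZERR (esds 0 when the
PDB provides none), LATT, contiguous SYMM block, SFAC, UNIT, DISP, the
always-active RIGU and XNPD 0.01 with commented ANIS/DELU/SIMU, a
commented conventional refinement template (CGLS 10, LIST 6 — a package
convention, activated by the user), restraint and hydrogen-rule cards,
WGHT/FVAR, residue blocks, HKLF, END.  Untied occupancies are coded
10 + q; a two-conformer altLoc group becomes PART 1/PART 2 with
occupancies tied to one fresh free variable (codes 21.0/−21.0 for free
variable 2); groups with three or more conformers keep their deposited
occupancies untied.  Lines longer than 78 characters wrap with the "="
continuation.  A grammar checker validates the finished document (single
CELL/ZERR/LATT/SFAC/UNIT/HKLF, SYMM contiguity, SFAC indices in range,
residue-scoped cards referencing existing residue names) before anything
is written.

## The synthetic-fixture generator

Test inputs are generated, not stored.  A fixture is an extended
(φ = ψ = ω = 180°) polypeptide built by natural-extension placement with
bond lengths and angles from the restraint library, an OXT on the last
residue, four waters by default, per-atom B factors of 15 ± 3 Å²
(waters 25 ± 5), occupancy 1, placed in a stated cell and space group
(default 30 × 24 × 20 Å, P 1, Cu Kα).  Side chains are placed from the
bond graph with deterministic staggered torsions, which leaves
five-membered and fused rings only approximately closed — fixtures
exercise identifier handling, symmetry, transforms and formats, not
side-chain geometry, and passing tests say nothing about refinement
behaviour on real data.  Reflection loops contain a requested number of
distinct (h, k, l) within the resolution limit (default 1.8 Å), lognormal
positive intensities, σ = 0.05·I + 1, and an exact rounded count of
free-R flags at the requested fraction (default 5%).  Defect injections
reproduce one deposit pathology each: an all-digit residue name, element
"X", a second coordinate model, a sigma-less reflection loop, an
out-of-range index.  The default sizes (two residues, 120 reflections for
the worked example; 10 000 reflections for the format sweep; 1 000 random
cells for the transform sweep) were chosen as the smallest sets that
exercise every code path convincingly.

## Numerical choices and degenerate inputs

Cell angles must lie in (0°, 180°) and combinations with non-positive
metric volume are rejected as singular.  Operator closure beyond 192
elements (the largest possible group order) aborts as divergent, which
catches malformed generator input.  Coordinate round-trips are verified to
1e-8 Å and equivalent-isotropic-U preservation to 1e-10 relative — both
far above the achieved ~1e-13 but stated as contracts.  Ties in disulfide
pairing (equal distances) break on atom identity to stay deterministic.
Empty reflection loops yield an empty intensity-kind set (HKLF 4).

## Known limitations

* No mmCIF coordinate input, NMR ensembles, or nucleic-acid/metal
  restraint libraries.
* The auxiliary ligand library is a five-residue synthetic stand-in.
* Dispersion magnitudes are indicative, not tabulated measurements.
* No cross-residue distance restraints (see above); no NCS restraints.
* MTZ reflection files are out of scope (convert externally first).
* The fetcher hits the live archives only when invoked with an accession
  code; every test runs offline through injected streams.
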