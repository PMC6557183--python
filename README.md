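# shelxbridge

Macromolecular crystal structures are deposited in PDB format with
Cartesian coordinates, isotropic B factors and free-form identifiers, while
the small-molecule refinement program SHELXL expects a `.ins` instruction
file — fractional coordinates, CIF-convention anisotropic `U_ij`,
general-position symmetry operators instead of a space-group name, strict
identifier rules — paired with a fixed-format `.hkl` reflection file.
`shelxbridge` is the bridge: it reads a PDB coordinate file plus an mmCIF
`_refln` loop and writes a complete, refinement-ready `.ins`/`.hkl` pair.
It is aimed at crystallographers who want SHELXL's least-squares standard
uncertainties, free variables and disorder handling for well-diffracting
protein structures without reformatting anything by hand.

## What the conversion does

* **Identifiers** — SHELX chain identifiers are one of 63 characters
  (A–Z, a–z, 0–9, blank; case sensitive); anything else is deterministically
  remapped. Residue numbers must lie in [−999, 9999] with no insertion
  codes, so decorated or out-of-range numbering is resolved by sequential
  renumbering that preserves order. All-digit residue names (legal in the
  PDB, ambiguous in SHELX) are flagged — renamed interactively, or warned
  about and kept in automated mode.
* **Symmetry** — a dictionary of symmetry generators for the 65 Sohncke
  space groups (the only groups chiral molecules can adopt), in standard
  and alternative settings, expanded to the full operator set by iterative
  multiplication with exact rational arithmetic, and emitted as
  `LATT`/`SYMM` cards. For example, R3 on hexagonal axes becomes
  `LATT -3` / `SYMM -Y, X-Y, Z` / `SYMM -X+Y, -X, Z`, and on primitive
  rhombohedral axes `LATT -1` / `SYMM Z, X, Y` / `SYMM Y, Z, X`.
* **Transforms** — Cartesian → fractional coordinates through the standard
  PDB orthogonalization matrix M (a ∥ x, b in the x–y plane):
  x_frac = M⁻¹ x_cart; B → U = B/8π²; Cartesian ADP tensors to the
  CIF/SHELX convention via U* = M⁻¹ U M⁻ᵀ, U_ij = U*_ij/(a*_i a*_j).
* **Stereochemistry** — Engh–Huber-style 1,2 (`DFIX`) and 1,3 (`DANG`)
  distance restraints per residue type (1,3 targets from angle targets by
  the law of cosines), peptide planarity by `FLAT` (no torsion restraint,
  so cis/trans flips stay possible), geometric detection of disulfide
  bridges (SG–SG within 1.8–2.5 Å, restrained to 2.031 Å) and of chain
  termini and breaks.
* **Hydrogens** — riding-model `HFIX` codes per residue, written as
  `REM` comments the user activates later; parents missing from the model
  are moved to active `HFIX 0` placeholders so hydrogen generation cannot
  fail on incomplete side chains.
* **Scattering** — `SFAC`/`UNIT` bookkeeping over the 98 elements SHELX
  knows (anything else, such as the placeholder element `X`, is a hard
  error), `DISP` cards with f′, f′′ and μ interpolated from an embedded
  tabulation, in-house anode wavelength snapping, and the rule that data
  at wavelengths below 0.1 Å are electron diffraction (no dispersion
  cards).
* **Reflections** — the `_refln` loop is read (intensities preferred,
  amplitudes as fallback; incomplete loops — missing sigmas, or I+ without
  I− — are rejected) and written in the 28/32-column fixed format
  `HHHHKKKKLLLLRRRRRRRRSSSSSSSSBBBB`, batch −1 marking free-R reflections,
  terminated by an all-zero record, with the matching `HKLF 4`/`HKLF 3`
  card in the `.ins`.
* **Displacement-parameter safety** — `RIGU` and `XNPD 0.01` are always
  written active; `ANIS`, `DELU`, `SIMU` are offered as comments.

## Worked example

The package ships a synthetic-fixture generator, so the whole pipeline can
be exercised without any deposited data:

```python
from shelxbridge import FixtureSpec, generate_fixture
from shelxbridge.pipeline import RunConfig, run, print_report

spec = FixtureSpec(sequence="GV", space_group="P 21 21 21", seed=42,
                   n_reflections=120, free_fraction=0.05)
pdb_text, cif_text = generate_fixture(spec)
open("gv.pdb", "w").write(pdb_text)
open("gv.cif", "w").write(cif_text)
report = run(RunConfig(pdb_path="gv.pdb", hkl_path="gv.cif",
                       output_basename="gv"))
print_report(report)
```

prints

```
WROTE   gv.ins
WROTE   gv.hkl
```

and the start of `gv.ins` reads

```
TITL synthetic fixture
CELL 1.54184 30.0000 24.0000 20.0000 90.000 90.000 90.000
ZERR 1 0.0000 0.0000 0.0000 0.000 0.000 0.000
LATT -1
SYMM -X+1/2, -Y, Z+1/2
SYMM X+1/2, -Y+1/2, -Z
SYMM -X, Y+1/2, -Z+1/2
SFAC C N O
UNIT 28 8 28
```

— the Gly–Val dipeptide's 7 carbons, 2 nitrogens and 7 oxygens multiplied
by the four symmetry operators of P2₁2₁2₁, followed by the restraint,
hydrogen-rule and residue blocks and a final `HKLF 4`. The matching
`gv.hkl` holds 120 reflections (6 of them flagged −1 for free-R
cross-validation) and the `0 0 0` terminator.

The same conversion runs from the shell:

```
shelxbridge gv.pdb --hkl gv.cif -o gv
```

A 4-character accession code instead of a path fetches the entry (and its
reflection data, when available) from the public archive or, with
`--redo`, from PDB_REDO.

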