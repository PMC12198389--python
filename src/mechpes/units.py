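"""Unit conversion constants.

The package works in Hartree atomic units internally (hartree, bohr) and in
the units practitioners report at its boundaries: Å for coordinates,
kcal mol⁻¹ for energies and barriers, nN for pulling forces and N m⁻¹ for
the uniaxial-compression force constant.

All constants derive from CODATA 2018:

* 1 hartree  = 4.3597447222071e-18 J  = 627.5095 kcal mol⁻¹
* 1 bohr     = 0.529177210903 Å
* 1 hartree/bohr  = 4.3597e-18 / 0.5292e-10 N = 82.387 nN
* 1 N m⁻¹ in hartree/bohr² = a0² / Eh = 6.42306e-4
"""

HARTREE_J = 4.3597447222071e-18
BOHR_M = 0.529177210903e-10
AVOGADRO = 6.02214076e23
CAL_J = 4.184  # thermochemical calorie

BOHR_TO_ANGSTROM = BOHR_M * 1e10
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM

HARTREE_TO_KCALMOL = HARTREE_J * AVOGADRO / (CAL_J * 1000.0)  # 627.5095
KCALMOL_TO_HARTREE = 1.0 / HARTREE_TO_KCALMOL

# force: 1 hartree/bohr expressed in nanonewton (≈ 82.387 nN)
HARTREE_PER_BOHR_NN = HARTREE_J / BOHR_M * 1e9
NN_TO_AU_FORCE = 1.0 / HARTREE_PER_BOHR_NN

# spring constant: 1 N m⁻¹ expressed in hartree/bohr² (≈ 6.42306e-4)
NEWTON_PER_METER_TO_AU = BOHR_M**2 / HARTREE_J
AU_TO_NEWTON_PER_METER = 1.0 / NEWTON_PER_METER_TO_AU
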