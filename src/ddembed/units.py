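"""Unit conventions and conversion constants.

Everything inside the package is in Hartree atomic units: lengths in
bohr, charges in units of the elementary charge, energies in hartree,
dipoles in e*bohr, quadrupoles in e*bohr^2, polarizabilities in bohr^3.
File inputs in angstrom are converted on read.
"""

BOHR_PER_ANGSTROM = 1.8897259886
ANGSTROM_PER_BOHR = 1.0 / BOHR_PER_ANGSTROM

#: Default probe radius used for the solvent accessible surface (angstrom).
DEFAULT_PROBE_RADIUS_ANG = 1.4

#: Scaling applied to Bondi van der Waals radii when building the cavity.
DEFAULT_RADIUS_SCALE = 1.1
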