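"""Unit system and physical constants.

The whole package works in the "academic" MD unit system:

=============  ==========
quantity       unit
=============  ==========
length         angstrom (A)
time           picosecond (ps)
mass           atomic mass unit (amu, g/mol)
energy         kcal/mol
temperature    kelvin
charge         elementary charge (e)
=============  ==========

The derived kinetic-energy unit amu * A^2 / ps^2 equals 10 J/mol, so one
kcal/mol is 418.4 amu * A^2 / ps^2; forces returned in kcal/(mol*A) must be
multiplied by :data:`KCAL_TO_AKMA` before dividing by a mass in amu to obtain
an acceleration in A/ps^2.
"""

#: Boltzmann constant, kcal/(mol*K).
KB = 0.0019872041

#: kcal/mol expressed in amu * A^2 / ps^2 (the integrator's native energy unit).
KCAL_TO_AKMA = 418.4

#: Coulomb prefactor: q1*q2/r with q in e and r in A gives kcal/mol after
#: multiplying by this constant (dielectric = 1).
COULOMB_CONSTANT = 332.0636

#: Per-bead soft-sphere repulsion is clamped at this energy (kcal/mol) so the
#: potential stays finite at bead centers; the force is zero on the clamped
#: plateau.
REPULSION_CAP = 1.0e3
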