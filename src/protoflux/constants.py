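"""Physical constants and unit conventions.

Units used throughout the package:

* energy        kcal/mol
* temperature   K
* concentration mM (1 mM = 1e-3 mol/L)
* potential     mV
* length        A (angstrom) for molecular geometry, nm for vesicles
* time          s
* electric field MV/cm

Sign conventions (fixed repo-wide):

* membrane potential  ``delta_psi = psi_in - psi_out``
* proton-motive free energy ``pmf`` is the free energy of moving one proton
  from the vesicle interior to the exterior.
"""

# gas constant, kcal mol^-1 K^-1
R_KCAL = 1.9872041e-3

# Faraday constant expressed as kcal mol^-1 V^-1 (= 96485.332 J mol^-1 V^-1 / 4184)
F_KCAL_PER_V = 23.060548

# Boltzmann constant / Planck constant, K^-1 s^-1  (k_B/h)
KB_OVER_H = 1.380649e-23 / 6.62607015e-34

# Avogadro constant, mol^-1
N_AVOGADRO = 6.02214076e23

# Coulomb constant for two elementary charges in vacuum,
# kcal mol^-1 A e^-2  (e^2/(4 pi eps0) expressed in kcal/mol at 1 A)
COULOMB_KCAL_A = 332.06371

# 1 kcal/mol per elementary charge per angstrom, expressed in MV/cm.
# 1 kcal/mol = 0.0433641 eV, so 1 kcal/(mol e A) = 0.0433641 V/A = 4.33641 MV/cm
KCAL_PER_MOL_E_A_IN_MV_CM = 4.3364103

# default assay temperature (37 C)
T_DEFAULT = 310.15

LN10 = 2.302585092994046


def rt(temperature: float = T_DEFAULT) -> float:
    """Thermal energy R*T in kcal/mol."""
    return R_KCAL * temperature
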