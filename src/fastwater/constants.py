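"""Physical constants and reference data, in GROMACS-style units.

Units used package-wide: masses in g/mol, lengths in nm, times in ps
(frame spacing, lag times) or ns (rates, relaxation times), integration
time steps in fs, energies in kJ/mol, temperatures in K.
"""

#: Boltzmann constant, kJ/(mol K).
KB = 0.0083144621

#: Self-interaction lattice constant of the periodic (cubic) Ewald sum,
#: used in the Yeh-Hummer finite-size correction of diffusion coefficients.
YEH_HUMMER_XI = 2.837297

#: Conversion factor from the internal viscosity unit kJ ns mol^-1 nm^-3
#: to Pa s (1 kJ/mol = 1.66053906892e-21 J, 1 nm^3 = 1e-27 m^3, 1 ns = 1e-9 s).
ETA_INTERNAL_TO_PA_S = 1.66053906892e-3

# Reference (unmodified) 3-site water site masses, g/mol.
TIP3P_M_O = 15.9994
TIP3P_M_H = 1.008
TIP3P_M_TOT = TIP3P_M_O + 2.0 * TIP3P_M_H  # 18.0154

# Finite-size-corrected self-diffusion coefficients D_inf (nm^2/ns) of neat
# water at 310 K reported for the original model (TIP3P), the repartition-only
# variant (TIP3P-R, m_r = 4, m_tot = 18.0154) and the fast water model
# (TIP3P-F, m_r = 4, m_tot = 1.116).  Reference inputs for ratio analyses.
REFERENCE_D_INFINITY = {
    "TIP3P": 7.053,
    "TIP3P-R": 6.125,
    "TIP3P-F": 23.648,
}

# Rigid 3-site water geometry (nm, degrees): O-H bond length and H-O-H angle.
WATER_OH_BOND = 0.09572
WATER_HOH_ANGLE = 104.52
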