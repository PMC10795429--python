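"""Physical constants used throughout the transport engine.

All energies are in MeV, lengths in mm unless a name says otherwise.
A single authoritative set of values lives here; nothing else in the
package redefines them.
"""

# Rest energies (MeV)
M_P = 938.272  # proton
M_E = 0.511    # electron

#: Avogadro constant (1/mol)
N_A = 6.02214076e23

#: Speed of light (mm/ns); only ratios of it appear in the physics.
C_MM_NS = 299.792458

#: Momentum-to-curvature conversion: a proton with momentum pc (MeV) in a
#: field B (T) follows a circle of radius pc / (QC * B) millimetres.
QC = 0.299792  # MeV / (T * mm)

#: 4 pi N_A r_e^2 m_e c^2 — the Bethe-Bloch prefactor K (MeV cm^2 / mol).
K_BETHE = 0.307075

#: Classical electron radius (cm), for independent cross-checks.
R_E_CM = 2.8179403262e-13
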