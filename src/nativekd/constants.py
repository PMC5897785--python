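"""Physical constants and reference masses for the RNase A titration system.

All masses are average (not monoisotopic) masses in daltons, matching how
intact-protein m/z ladders are computed on low-resolution instruments.
"""

#: Mass of a proton, Da. Used as the charging mass for [M+zH]^z+ ions.
PROTON_MASS = 1.00728

#: Mass of a hydrogen atom, Da. Alternative charging-mass convention; the
#: difference from the proton is invisible at 1-decimal m/z rounding.
HYDROGEN_MASS = 1.00794

#: Nominal mass of one phosphate (Pi) adduct, Da. The +98 Da series seen on
#: free and ligand-bound RNase A ions is conventionally assigned as H3PO4.
PI_ADDUCT_MASS = 98.0

#: Average neutral mass of bovine pancreatic RNase A, Da, as implied by the
#: published singly-protonated value [M+H]+ = 13,682.3 used to build the
#: predicted m/z ladders in this work.
RNASE_A_MASS = 13682.3 - PROTON_MASS

#: Average mass of RNase A computed from the PDB 1RTA sequence, Da. This is
#: the value quoted with the sample-preparation table. It differs from
#: RNASE_A_MASS by ~9 Da; the two are deliberately kept as separate named
#: constants because the source material does not reconcile them.
RNASE_A_MASS_1RTA = 13690.3

#: Average mass of the pentadeoxycytidine ligand dC5 (sequence CCCCC), Da.
DC5_MASS = 1383.9

#: Average mass of the dC2AC2 ligand (sequence CCACC), Da.
DC2AC2_MASS = 1408.0

#: Total protein concentration in every titration sample, mol/L.
P0_MOLAR = 40.9e-6

#: Ligand concentrations of the titration design, mol/L.
TITRATION_L0_MOLAR = (0.0, 5e-6, 10e-6, 20e-6, 40e-6)

#: Acquired full-scan m/z range of the ion-trap instrument.
SCAN_RANGE = (1500.0, 1950.0)

#: Integration-window padding beyond the extreme ladder m/z values, Th.
DEFAULT_HALF_WIDTH = 0.5
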