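"""Physical constants and unit conventions.

Units used throughout the package: lengths in dm, areas in dm^2, volumes in
dm^3 (litres), concentrations in M (mol/L), time in s.  The scaled vesicle
volume ``Omega`` is dimensionless: Avogadro's number times the litre volume,
i.e. the volume expressed as "number of molecules at 1 M".
"""

#: Avogadro's constant, mol^-1.
N_A = 6.02214e23

#: Permeability of ribose through an oleic-acid bilayer, dm^2 s^-1 mol^-1.
#: Used as the reference for the dimensionless per-species multipliers.
D_RIBOSE = 2.65e8

#: Lipid bilayer thickness, dm.
BILAYER_THICKNESS = 4e-8

#: Reduced surface below which an osmotically tense vesicle bursts.
PHI_BURST = 0.9

#: Maximum reactant (or product) molecularity of an elementary step.
MAX_ORDER = 3
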