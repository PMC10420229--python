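"""Turn solvation free energies into solvent/water partition coefficients.

logP = -(dG_solv - dG_water) / (R T ln 10): each 1.36 kcal/mol by which a
solvent beats water corresponds to one log10 unit of preference.
"""

import pandas as pd

from micellocalc import PhysicalConstants, logp_matrix

const = PhysicalConstants()  # 298.15 K
print(f"RT ln10 = {const.rt_ln10:.5f} kcal/mol")

# a tiny solvation panel (kcal/mol): water + two alcohols
solvation = pd.DataFrame(
    {
        "water": [-6.62, -9.01, -5.30],
        "propan-1-ol": [-8.10, -9.55, -7.95],
        "methanol": [-7.45, -9.40, -6.80],
    },
    index=["phenol-like", "polar-probe", "apolar-probe"],
)
logp = logp_matrix(solvation, const)
print("\nsolvent/water logP:")
print(logp.round(3).to_string())

# Positive entries mean the compound prefers the organic solvent over
# water; the apolar probe shows the largest propan-1-ol/water logP, as a
# hydrophobic solute should.
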