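"""Annotate residues with SASA and salt bridges; classify sensors.

SASA is Shrake-Rupley with a 1.4 A probe and Bondi-type radii; salt
bridges use a 3.2 A O-N distance cutoff.  Sensors are classified as
binding-groove, surface (SASA > 70 A^2) or buried.
"""

import math

from icnet import annotate_structure, classify_sensors, sasa
from icnet.annotate import Structure, StructureResidue
import numpy as np

# a single isolated carbon: SASA equals the analytic sphere 4*pi*(1.7+1.4)^2
lone = Structure([StructureResidue(1, "ALA", "A", ["C1"], np.zeros((1, 3)),
                                   ["C"])])
print(f"isolated carbon SASA: {sasa(lone)[1]:.2f} A^2 "
      f"(analytic {4 * math.pi * 3.1 ** 2:.2f})")

from icnet import generate_toy_complex

complex = generate_toy_complex(n_protein=12, n_guide=3, seed=9)
table = annotate_structure(complex)
print(table.head(8).to_string(index=False))

sensors = [2, 5, 9]
out = classify_sensors(sensors, table, groove={9}, sasa_threshold=70.0)
print(out.to_string(index=False))
print("groove membership wins; then SASA > 70 A^2 marks surface sensors")
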