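"""Simulate a screen for the study compounds and normalize it.

Builds the triplicate rotated-row plate design for the 19 drugs and 4
counterions, then normalizes every continuous readout against its in-plate
vehicle-control median and pools binary incidences across replicates.
"""

import numpy as np

import phenobar as pb

records = pb.study_compound_table()
compounds = pb.experimental_drugs(records) + pb.experimental_counterions(records)
print(f"simulating {len(compounds)} compounds "
      f"({len(compounds) - 4} drugs + 4 counterions)")

wells = pb.simulate_screen(compounds, seed=1)
print(f"{len(wells)} wells; 24 animals per concentration "
      f"(3 plates x 8 wells)")

normalized = pb.normalize_screen(wells)
ser = [r.value for r in normalized
       if r.chemical_id == "SER" and r.endpoint == "speed_blue2"
       and r.concentration == 100.0]
print(f"SER @ 100 uM, speed_blue2: median {np.median(ser):.1f}% change "
      f"(n={len(ser)} animals)")
# A strongly negative percent change means the drug slowed the animals under
# blue light relative to the vehicle controls on the same plate.
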