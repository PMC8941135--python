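"""Identify LC-MS features against an authentic-standard library.

A feature is identified when its m/z is within 5 ppm OR 0.001 Da of a
library adduct AND its RT within 0.5 min of the standard; a matching
MS/MS spectrum raises the score to 3, a mismatch vetoes the call.
"""

from exoflux import (
    CompoundRecord,
    Polarity,
    SpectralLibrary,
    assign_identification,
    default_adducts,
)

library = SpectralLibrary(records=[
    CompoundRecord(name="trehalose", neutral_mass=342.1162,
                   adducts=default_adducts(342.1162), reference_rt=7.4,
                   msms=[(85.0284, 0.6), (127.0390, 1.0), (163.0601, 0.4)]),
    CompoundRecord(name="adenine", neutral_mass=135.0545,
                   adducts=default_adducts(135.0545), reference_rt=4.9,
                   msms=[(92.0244, 0.3), (119.0352, 1.0)]),
])

cases = [
    # (label, observed m/z, RT, observed MS/MS)
    ("on-target with matching MS/MS", 343.1236, 7.5,
     [(85.0284, 0.55), (127.0390, 1.0), (163.0601, 0.38)]),
    ("on-target, no MS/MS acquired", 343.1236, 7.5, None),
    ("mass ok but RT off by 1 min", 343.1236, 8.4, None),
    ("on-target but mismatching MS/MS", 343.1236, 7.5, [(201.0, 1.0)]),
]

for label, mz, rt, msms in cases:
    ident = assign_identification(
        "feat", mz, rt, Polarity.positive, library, observed_msms=msms
    )
    print(f"{label:36s} -> compound={ident.compound!s:10s} score={ident.score} "
          f"level={ident.msi_level.value} ({ident.reason})")

print("\nScore 3 = mass+RT+MS/MS match (MSI level 1 plus spectrum); score 2 = "
      "mass+RT (level 1); a mismatching spectrum invalidates the identification.")
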