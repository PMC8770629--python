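"""Generate synthetic head phantoms and a simulated patient cohort.

Each phantom is a head-like axial slice (skull ring, brain, two crescent
temporalis-like muscles) with an exact ground-truth mask; the cohort
carries sex-specific muscle cross-sectional areas (CSA) and survival times
from a proportional-hazards model.
"""

import numpy as np

from temporalis.phantom import CohortSpec, PhantomSpec, generate_phantom, simulate_cohort

spec = PhantomSpec(image_size=128, pixel_spacing_mm=1.5, seed=0)
for i in range(3):
    s = generate_phantom(spec, i)
    print(
        f"phantom {i}: image {s.image.shape} at {s.image.spacing[0]} mm, "
        f"true CSA left/right = {s.true_left_area_mm2:.0f}/{s.true_right_area_mm2:.0f} mm²"
    )
# The true areas are exact pixel counts × pixel area: they are what a
# perfect segmentation should recover downstream.

cohort = simulate_cohort(CohortSpec(n_patients=45, seed=1))
csa = np.array([p.csa_mm2 for p in cohort])
events = sum(p.event for p in cohort)
print(
    f"\ncohort: n=45, mean CSA {csa.mean():.0f} mm², {events} deaths observed, "
    f"{45 - events} censored"
)
# Defaults are calibrated to a glioblastoma cohort: ~76% male, male/female
# CSA 607/472 mm², median survival ~18 months, protective high-CSA effect.
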