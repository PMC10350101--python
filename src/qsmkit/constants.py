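"""Physical constants and display conventions used across the pipeline."""

import numpy as np

#: Reduced proton gyromagnetic ratio, Hz per tesla.
GAMMA_HZ_PER_T = 42.577478e6

#: Proton gyromagnetic ratio in angular units, rad s^-1 T^-1.
GAMMA_RAD_PER_T_S = 2.0 * np.pi * GAMMA_HZ_PER_T

#: Fat-water chemical shift, ppm.
FAT_WATER_SHIFT_PPM = 3.5

#: Grayscale display window for healthy-brain susceptibility maps, ppm.
DISPLAY_WINDOW_PPM = (-0.2, 0.2)

#: Reference T1 of white matter / deep gray matter (seconds) by field strength (T).
T1_PRESETS_S = {1.5: 0.650, 3.0: 0.850, 7.0: 1.220}

#: Reference T2* of the putamen (seconds) by field strength (T).
T2STAR_PRESETS_S = {1.5: 0.055, 3.0: 0.030, 7.0: 0.016}
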