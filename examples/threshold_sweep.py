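"""Compare candidate lower ADC thresholds for marrow involvement.

The disease band keeps voxels with adc_lower < ADC <= 2.0e-3 mm^2/s.
This sweep measures tDV at the three candidate lower cuts (0.45, 0.55,
0.65 x10^-3) on a phantom whose lesions straddle them, showing how the
choice trades sensitivity to mildly infiltrated marrow against
false-positive normal tissue.
"""

import numpy as np

from tdvpipe import threshold_sweep
from tdvpipe.synthdata import Lesion, PhantomSpec, generate_phantom

lesions = [
    Lesion(center=(32, 32, 25), adc=0.5e-3,
           s0=1000.0 * np.exp(-(1.0e-3 - 0.5e-3) * 999)),
    Lesion(center=(32, 32, 60), adc=0.6e-3,
           s0=1000.0 * np.exp(-(1.0e-3 - 0.6e-3) * 999)),
    Lesion(center=(32, 32, 95), adc=0.7e-3,
           s0=1000.0 * np.exp(-(1.0e-3 - 0.7e-3) * 999)),
]
study = generate_phantom(PhantomSpec(lesions=lesions))
table = threshold_sweep([study])

for _, row in table.iterrows():
    print(f"adc_lower = {row.adc_lower * 1e3:.2f} x10^-3 mm^2/s -> "
          f"tDV = {row.tdv_ml:.1f} ml")
# Each raise of the cut drops the lesions whose ADC now falls below it,
# so measured tumour burden decreases monotonically.
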