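"""Fit the IVIM biexponential model to lumbar-marrow ROI signal.

Generates a 9-b-value spinal DWI phantom whose marrow carries a
perfusion fraction f = 0.247 (D* = 20e-3, D = 0.35e-3 mm^2/s), averages
the signal over an L1-L3-style rectangular ROI and fits
S(b)/S(0) = f exp(-b D*) + (1-f) exp(-b D) by the segmented strategy.
"""

from tdvpipe import fit_ivim, roi_mean_signal
from tdvpipe.ff_quant import DWI_ROI_AREA_BOUNDS_MM2, RectRoi
from tdvpipe.synthdata import (IvimParams, PhantomSpec, SPINAL_B_VALUES,
                               generate_phantom)

spec = PhantomSpec(pattern="normal", lesions=[], b_values=SPINAL_B_VALUES,
                   ivim=IvimParams(f=0.247, dstar=20.0e-3))
study = generate_phantom(spec)

roi = RectRoi(plane="coronal", slice_index=32, corner=(27, 40),
              extent=(10, 12))
signal = roi_mean_signal(study.dwi, roi, area_bounds=DWI_ROI_AREA_BOUNDS_MM2)
fit = fit_ivim(signal.b_value.to_numpy(), signal.mean_signal.to_numpy())

print(f"perfusion fraction f : {fit.f:.3f}   (true 0.247)")
print(f"pseudodiffusion D*   : {fit.dstar * 1e3:.2f} x10^-3 mm^2/s "
      f"(true 20.00)")
print(f"tissue diffusion D   : {fit.d * 1e3:.3f} x10^-3 mm^2/s (true 0.350)")
print(f"converged: {fit.converged}, rss = {fit.rss:.2e}")
# f is the capillary (pseudodiffusion) signal fraction; a fit within 1%
# of truth on noiseless data validates the segmented fitting strategy.
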