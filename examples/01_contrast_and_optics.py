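"""Contrast measures, retinal adaptation, and the modeled eye optics.

Prints the Michelson and RMS contrast of simple patterns, the Naka-Rushton
light-adaptation curve, and the acceptance/interommatidial angles implied by
the Gaussian-blur-plus-decimation front end.
"""

import numpy as np

from emdlobula import (
    acceptance_angle,
    interommatidial_angle,
    make_dot_texture,
    michelson_contrast,
    naka_rushton,
    rms_contrast,
)

tex = make_dot_texture((64, 64), dot_size_px=8, contrast=0.8, i0=0.5, seed=0)
print(f"80% dot texture -> block luminances {tex.min():.2f}/{tex.max():.2f}, "
      f"measured Michelson contrast {michelson_contrast(tex.max(), tex.min()):.2f}")
print(f"RMS contrast of the same texture: {rms_contrast(tex):.2f}")

for i in (0.1, 1.0, 10.0, 100.0):
    print(f"Naka-Rushton (mean 1.0, mu 0.7): I={i:>6.1f} -> I'={naka_rushton(np.array([i]), 1.0)[0]:.3f}")

for dpp in (0.33, 0.39):
    rho = acceptance_angle(3.5, dpp)
    phi = interommatidial_angle(6, dpp)
    print(f"at {dpp}°/px: acceptance angle Δρ = {rho:.1f}°, interommatidial angle Δϕ = {phi:.1f}°")
# Δρ is the FWHM of a photoreceptor's spatial sensitivity; Δϕ the spacing of
# the sampling lattice the EMD array lives on.
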