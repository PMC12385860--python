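"""Recover a known misalignment between the CTU and unenhanced volumes.

The unenhanced phantom is rendered through a rigid transform (patient
motion); registering it back to the CTU by cross-correlation gradient
descent should invert that transform to sub-millimetre accuracy.
"""

import dataclasses

import numpy as np

import focusctu as f
from focusctu.register import RegistrationOptions

spec = f.default_spec("small")
center = tuple(n * s / 2 for n, s in zip(spec.shape, spec.spacing))
truth = f.AffineTransform.from_rigid(
    rotation_deg=(0, 0, 5.0), translation=(6.0, -4.0, 8.0), center=center
)
out = f.generate_phantom(dataclasses.replace(spec, misalignment=truth))

result = f.register(out.ctu, out.unenhanced, RegistrationOptions(model="rigid"))
print(f"cross-correlation: {result.metric_at_identity:.4f} (identity) "
      f"-> {result.metric_value:.4f} (registered)")

residual = result.transform.compose(out.misalignment)
print(f"residual translation at volume center: "
      f"{np.linalg.norm(residual.displacement_at(center)):.3f} mm")
print(f"residual rotation: {residual.rotation_angle_deg():.3f} deg")
# Residuals well below 1 mm / 1 degree mean the masked unenhanced volume
# lines up voxel-for-voxel with the CTU before the focused mask is applied.
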