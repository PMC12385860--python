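"""Build focused-view masks on a phantom with an unopacified ureter gap.

Method 1 shows only segmented voxels, method 2 adds a 10 mm boundary,
method 3 additionally bridges the ureter gap with a straight path dilated
by 20 mm — so the gap region stays viewable while incidental findings
outside the tract remain hidden.
"""

import numpy as np

import focusctu as f
from focusctu.focusview import FocusedViewConfig

spec = f.random_spec(seed=11, n_gaps=1, gap_length_range=(28.0, 28.0))
out = f.generate_phantom(spec)

cfg = FocusedViewConfig()  # method 3, 10 mm boundary, 20 mm bridge radius
m1 = f.method1_mask(out.observed)
m2 = f.method2_mask(out.observed, cfg.boundary_mm)
m3 = f.method3_mask(out.observed, cfg)
print(f"mask voxels: method1 {m1.sum()}, method2 {m2.sum()}, method3 {m3.sum()}")

bridged, segments = f.bridge_components(out.observed, cfg)
for seg in segments:
    print(f"bridge segment: {np.round(seg.start_mm, 1)} -> {np.round(seg.end_mm, 1)} mm "
          f"(length {seg.length_mm:.1f} mm)")

# visibility of the true anatomy under each mask (4-point reader scale)
for name, mask in (("method 1", m1), ("method 2", m2), ("method 3", m3)):
    rep = f.organ_coverage(out.truth, mask,
                           ureter_side=out.ureter_side,
                           ureter_arclength=out.ureter_arclength)
    gap_side = spec.gaps[0].side
    ureter = rep.instances[f"ureter_{gap_side}"]
    print(f"{name}: {gap_side} ureter coverage {ureter.coverage:.3f} "
          f"(score {ureter.score4}/4)")

conc = f.concealment_check(out.incidental_mask, m3)
print(f"incidental findings hidden: {conc.hidden_fraction:.0%} (all: {conc.all_hidden})")
# Method 3 restores full ureter visibility (score 4) that methods 1-2 lose
# at the gap, while the lesions stay 100% concealed.
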