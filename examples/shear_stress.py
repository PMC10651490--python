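"""Shear stress on interstitial cell surfaces from porous-media theory.

Evaluates the Kozeny-Carman permeability and Darcy shear stress over the
study's biophysical input ranges and prints the resulting envelope.
"""

import ifshear as ifs

r = ifs.shear_stress_envelope()  # defaults: u 0.4-0.6 μm/s, K 4.5-5.5,
                                 # area 0.0083-0.18 μm², ε 0.2, μ 0.8 mPa·s

print(f"Darcy permeability range : {r.kp_range[0]:.3g} - {r.kp_range[1]:.3g} m^2")
print(f"Shear stress envelope    : {r.tau_min:.3f} - {r.tau_max:.3f} Pa")
print(f"  minimum at area {r.corner_min['area'] * 1e12:.4g} um^2, "
      f"u {r.corner_min['u'] * 1e6:.2g} um/s, K {r.corner_min['kozeny_k']}")
print(f"  maximum at area {r.corner_max['area'] * 1e12:.4g} um^2, "
      f"u {r.corner_max['u'] * 1e6:.2g} um/s, K {r.corner_max['kozeny_k']}")
print("\nThe envelope is the span of shear stresses a cell lining the")
print("interstitial space experiences during head-motion-driven flow;")
print("sub-pascal values of this size modulate mechanosensitive signalling.")
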