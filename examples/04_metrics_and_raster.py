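"""Regional morphometry, Murray-exponent recovery and rasterisation.

Branch statistics are reported for the macula, optic-disc and peripheral
regions, the Murray exponent is re-fitted from the grown radii, and the
network is embedded in an OCT-A-like image grid (6.3 µm axial, 21 µm
lateral) for an en-face projection.
"""

import retvasc as rv

net, domain, params, _ = rv.generate_retina(seed=7, preset="mini")

metrics = rv.compute_branch_metrics(net, domain)
print("per-region branch statistics:")
print(metrics.per_region.round(2))

exponent, estimates, skipped = rv.fit_murray_exponent(net)
print(f"\nconfigured Murray exponent: {params['murray_exponent']:.3f}")
print(f"recovered median exponent:  {exponent:.3f} "
      f"({len(estimates)} bifurcations, {skipped} degenerate skipped)")

vol = rv.rasterize_network(net, lateral_um=21.0, axial_um=6.3)
enface = rv.enface_projection(vol)
print(f"\nvolume shape {vol.data.shape}, "
      f"{int((vol.data > 0).sum())} vessel voxels")
print(f"en-face image {enface.shape}, "
      f"vessel area fraction {float((enface > 0).mean()):.3f}")
vol.save_tiff("mini_retina.tiff")
print("wrote mini_retina.tiff")
# The recovered exponent matches the value the generator sampled because
# radii are maintained Murray-consistently at every bifurcation.
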