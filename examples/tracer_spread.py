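"""Contrast-agent spread between serial CT-like scans -> flow velocity.

Simulates a pre/post scan pair in which the tracer bolus spreads twice as
far along y, segments the tracer against the air reference (>= 1.02 x air
intensity), measures per-axis extents and converts the fold-change into
an interstitial flow-velocity estimate.
"""

import ifshear as ifs

pair = ifs.generate_tracer_volume(
    pre_spread_sd=[0.3, 0.3, 0.3], post_spread_sd=[0.3, 0.6, 0.3], seed=1
)
pre = ifs.measure_spread(ifs.segment_tracer(pair.pre, pair.air_roi))
post = ifs.measure_spread(ifs.segment_tracer(pair.post, pair.air_roi))
fold = ifs.spread_fold_change(pre, post)

for ax, name in enumerate("xyz"):
    print(f"{name}: pre {pre.extent[ax]:.2f} mm -> post {post.extent[ax]:.2f} mm "
          f"(fold {fold[ax]:.2f})")

est = ifs.estimate_flow_velocity(baseline_u=0.2, fold_range=(2.0, 3.0))
print(f"\nflow velocity from a 2-3x spread enhancement over the 0.2 um/s")
print(f"sedentary baseline: {est.u_range[0]:.2f} - {est.u_range[1]:.2f} um/s")
print("Only the axis with enhanced spread shows a fold above 1; the fold")
print("range scales the literature baseline into the in-vivo flow estimate.")
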