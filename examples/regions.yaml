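# Metric regions for the c52v_point example: the point target sits on
# axis at r = r0 + 30 mm = 79.57 mm from the center of curvature.
points:
  - {x_mm: 0.0, z_mm: 79.57, search_radius_mm: 3.0}
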