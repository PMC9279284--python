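# SYNTHETIC class-area table (km² of natural lake surface per stratum).
#
# The true per-stratum lake areas live in a supplementary dataset that is not
# redistributed here.  These stand-in areas were constructed to satisfy the
# published aggregate constraints — global natural lake area 2.67e6 km²
# (HydroLAKES), humid-tropical-forest lake area ~2.4% of the total
# (7.4 Tg C yr⁻¹ / 113.5 g C m⁻² yr⁻¹ ≈ 65,200 km²), and an area-weighted
# mean burial near 29.7 g m⁻² yr⁻¹ — and are labelled synthetic for that
# reason.  Replace with measured areas for real upscaling.
areas_km2:
  Humid tropical forest: 65200
  Other tropical/subtropical: 0        # no burial data available
  Temperate forest: 400000
  Boreal forest: 1000000
  Other mid-latitude: 30000
  Subpolar and polar: 1000000
  Deserts: 0                           # no burial data available
  Cold anthropic: 100000
  Moderate anthropic: 40000
  Warm anthropic: 34800
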