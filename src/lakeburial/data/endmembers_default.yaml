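# Endmember boxes for sedimentary organic-matter sources in (d13C, C:N) space.
#
# LITERATURE-INFORMED ASSUMPTIONS.  Bulk-OM source fields for tropical
# floodplain systems: algae are N-rich (low C:N), vascular C3 plants are
# N-poor (high C:N) with depleted d13C, C4 grasses are enriched in 13C,
# and C3-derived soil organic matter sits at intermediate C:N.  Exact box
# boundaries vary between compilations; these defaults are drawn so the
# four boxes are pairwise disjoint.  Override for other systems.
#
# d13c in permil vs VPDB; cn is the molar C:N ratio.
endmembers:
  phytoplankton:
    d13c: [-33.0, -26.0]
    cn: [4.0, 8.0]
  C3 soil:
    d13c: [-28.0, -24.0]
    cn: [8.5, 14.0]
  C3 plants:
    d13c: [-33.0, -26.0]
    cn: [14.5, 40.0]
  C4 plants:
    d13c: [-16.0, -10.0]
    cn: [8.5, 40.0]
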