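"""Build the scanner geometry and inspect its derived dimensions.

The annulus is specified by bore radius, facet apothem and facet count; the
facet width and maximum outer radius follow from the regular-polygon cross
section and should reproduce the as-built 18.2 mm facets and 8.2 cm OD.
"""

from annpet import ScannerGeometry

g = ScannerGeometry()
a = g.annulus
print(f"facets:            {a.n_facets}")
print(f"facet width:       {a.facet_width:.2f} mm   (as built: 18.2 mm)")
print(f"outer diameter:    {2 * a.max_outer_radius / 10:.2f} cm (as built: 8.2 cm)")
print(f"min thickness:     {a.facet_apothem - a.inner_radius:.1f} mm")
print(f"partners of facet 0: {sorted(g.coincidence_partners(0))}")
print(f"unique coincidence facet pairs: {len(g.partner_pairs())}")

facet, u, v, depth, inside = g.locate_point([35.0, 0.0, 0.0])
print(f"point (35,0,0) mm -> facet {facet}, depth {depth:.1f} mm from the bore")
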