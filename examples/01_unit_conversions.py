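"""Convert reported cell dimensions into volumes (μm³).

Microscopy papers report cell size as cross-sectional area, diameter, or
length × width; all analyses need volumes. Spherical shapes cover the
area/diameter cases and a prolate spheroid covers elongated cells.
"""

from karyoscale import prolate_spheroid_volume, volume_from_area, volume_from_diameter

area = 100.0  # μm², e.g. a projected yeast cross-section
print(f"area {area} μm²        -> sphere volume {volume_from_area(area):8.2f} μm³")

diameter = 10.0  # μm, e.g. an erythrocyte-scale cell
print(f"diameter {diameter} μm      -> sphere volume {volume_from_diameter(diameter):8.2f} μm³")

length, width = 10.0, 4.0  # μm, an elongated flagellate
v = prolate_spheroid_volume(length, width)
print(f"length×width {length}×{width} μm -> prolate spheroid volume {v:8.2f} μm³")

# The numbers are the exact closed forms (4/3)π(√(A/π))³, (4/3)π(D/2)³ and
# (4/3)π(L/2)(W/2)²; feeding the matching diameter through either spherical
# route gives identical volumes.
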