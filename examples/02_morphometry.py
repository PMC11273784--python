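"""Morphometry of a single synthetic sac against its neck-plane annotation.

Prints the standard rupture-risk geometry indices: sac height, neck width,
AR = height/neck, SR = height/parent diameter, surface area, volume and S/V.
"""

from hemocloud import assemble_geometric_parameters
from hemocloud.geometry import ar_high_risk
from hemocloud.synthetic import make_sac_mesh

# a slender sac: 3 x 3 mm equatorial radii, 6 mm dome axis, 1.8 mm neck radius
mesh, neck_plane = make_sac_mesh(
    a=3.0, b=3.0, c=6.0, neck_radius=1.8, parent_diameter=3.5,
    rings=48, segments=48,
)
rec = assemble_geometric_parameters(mesh, neck_plane, parent_diameter=3.5)

print(f"sac height          {rec.sac_height:7.3f} mm")
print(f"neck width          {rec.neck_width:7.3f} mm")
print(f"aspect ratio (AR)   {rec.aspect_ratio:7.3f}   "
      f"({'high-risk regime, AR > 1.6' if ar_high_risk(rec.aspect_ratio) else 'below the 1.6 threshold'})")
print(f"size ratio (SR)     {rec.size_ratio:7.3f}")
print(f"surface area        {rec.surface_area:7.2f} mm^2")
print(f"volume              {rec.volume:7.2f} mm^3")
print(f"S/V                 {rec.sv_ratio:7.3f} 1/mm")
print("\nAR above ~1.6 is the conventional high-risk regime for rupture;")
print("S/V rises for slender sacs, another reported discriminator.")
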