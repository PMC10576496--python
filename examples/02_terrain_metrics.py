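"""Compute the five structural-complexity metrics for one colony DEM.

Surface rugosity (3-D over planform area), fractal dimension from the
1-32 cm surface-area curve, and per-cell slope / planform curvature /
profile curvature summarised over the raster.
"""

from reefstruct import ColonyParams, colony_metrics, gen_colony

raster, mask = gen_colony(ColonyParams(seed=7))
mset = colony_metrics(raster, colony_id="demo")

print(f"planform area:    {mset.planform_area:.4f} m^2")
print(f"geodesic area:    {mset.geodesic_area:.4f} m^2")
print(f"surface rugosity: {mset.surface_rugosity:.3f}  (1 = perfectly flat)")
print(f"fractal D:        {mset.fractal.d:.3f}  (2 = flat ... 3 = space-filling)")
print(f"  log-log R^2:    {mset.fractal.r_squared:.4f} "
      f"(fractal flag: {mset.fractal.is_fractal})")
print(f"median slope:     {mset.slope_stats.median:.1f} deg "
      f"(IQR {mset.slope_stats.iqr:.1f})")
print(f"profile curv IQR: {mset.profile_curv_stats.iqr:.1f}")
print(f"planform curv IQR:{mset.planform_curv_stats.iqr:.1f}")
# Real A. palmata colonies show rugosity ~2.6-4.8 and D ~2.3-2.5 at this scale.
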