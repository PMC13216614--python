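"""Build the 642-cell equal-area hexagonal analysis grid.

Aperture-4 icosahedral grid at resolution 3: 10*4^3 + 2 = 642 cells of
~800,000 km^2 each (12 pentagons), the spatial unit of the global analysis.
"""
import numpy as np

from oceangap.geogrid import assign_cell, build_grid

grid = build_grid(3)
areas = np.array([c.area_km2 for c in grid.cells])
pent = np.array([c.is_pentagon for c in grid.cells])
print(f"cells: {len(grid)}  (pentagons: {pent.sum()})")
print(f"mean cell area: {areas.mean():,.0f} km^2")
print(f"hexagon area spread: {(areas[~pent].max() - areas[~pent].min()):.2e} km^2")
cid = assign_cell(grid, -36.8, 174.7)       # off northern New Zealand
c = grid.cells[cid]
print(f"point (-36.8, 174.7) falls in cell {cid} centred at "
      f"({c.center[0]:.1f}, {c.center[1]:.1f})")
grid.to_geojson("grid_642.geojson")
print("cell polygons written to grid_642.geojson")
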