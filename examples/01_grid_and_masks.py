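"""Hierarchical grid design and DMD mask export.

Divides a 2172x1653 um field of view (at 1 um per camera pixel) into a
3x3 grid, subdivides the center cell twice, and rasterizes a selection
of leaves to DMD pattern masks.
"""

from pathlib import Path

import optomap as om

out = Path("scratch/examples")
out.mkdir(parents=True, exist_ok=True)

grid = om.grid_create((0, 0, 2172, 1653), 3, 3)
print("3x3 cell size:", grid.cell_dimensions_um("0.0", 1.0), "um")

grid.subdivide("0.4", 3, 3)          # one more level in the center
print("subdivided cell size:", grid.cell_dimensions_um("0.4.0", 1.0), "um")

grid.subdivide("0.4.4", 3, 3)        # and once more
print("twice-subdivided cell size:", grid.cell_dimensions_um("0.4.4.0", 1.0), "um")

# merge two adjacent fine cells back into one wider region
merged = grid.merge(["0.4.4.0", "0.4.4.1"])
print("merged cell size:", grid.cell_dimensions_um(merged.id, 1.0), "um")

# export a few leaves as DMD masks through a full-field calibration
transform = om.CalibrationTransform.uniform_scale(grid.bounds,
                                                  om.DEFAULT_DMD_SHAPE)
masks = grid.export(["0.0", "0.4.0", merged.id], grouped=False,
                    transform=transform)
for m in masks:
    print(f"mask {m.id}: {m.n_on} mirrors ON")
om.geometry.save_masks(masks, out / "masks.tif", transform=transform)
print("wrote", out / "masks.tif")

# Each printed size is the physical footprint one stimulus will cover;
# the ON counts are how many DMD micromirrors illuminate each region.
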