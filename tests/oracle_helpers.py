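"""Independent brute-force oracles for the geometric operations.

These deliberately avoid the package's code paths: the overlap oracle
rasterizes each geometry onto a fine pixel grid by point-in-rectangle
arithmetic (fixtures are grid-aligned axis-parallel rectangles, so the
rasterization is exact) and declares a pair overlapping iff any pixel is
covered by both.
"""

import numpy as np

RES = 0.01  # km, oracle pixel size


def rect_mask(bounds, extent, res=RES):
    """Boolean pixel mask of an axis-aligned rectangle over the extent.

    Pixels are res x res with centers at offsets of res/2; a pixel belongs
    to the rectangle iff its center lies strictly inside.
    """
    x0, y0, x1, y1 = extent
    nx = int(round((x1 - x0) / res))
    ny = int(round((y1 - y0) / res))
    cx = x0 + (np.arange(nx) + 0.5) * res
    cy = y0 + (np.arange(ny) + 0.5) * res
    bx0, by0, bx1, by1 = bounds
    mx = (cx > bx0) & (cx < bx1)
    my = (cy > by0) & (cy < by1)
    return np.outer(mx, my)


def brute_force_overlap_pairs(ranges, pas, extent, res=RES):
    """All (pa_id, species_id) pairs with positive-area overlap, by pixels."""
    range_masks = {r.species_id: rect_mask(r.geometry.bounds, extent, res)
                   for r in ranges}
    pairs = set()
    for p in pas:
        pmask = rect_mask(p.geometry.bounds, extent, res)
        for sid, rmask in range_masks.items():
            if np.any(pmask & rmask):
                pairs.add((p.pa_id, sid))
    return pairs


def brute_force_cell_counts(ranges, xll, yll, cell, n_rows, n_cols):
    """Per-cell counts of overlapping ranges by direct rectangle arithmetic."""
    counts = np.zeros((n_rows, n_cols), dtype=int)
    for row in range(n_rows):
        for col in range(n_cols):
            cx0 = xll + col * cell
            cy1 = yll + (n_rows - row) * cell
            cy0 = cy1 - cell
            cx1 = cx0 + cell
            for r in ranges:
                bx0, by0, bx1, by1 = r.geometry.bounds
                if min(cx1, bx1) > max(cx0, bx0) and min(cy1, by1) > max(cy0, by0):
                    counts[row, col] += 1
    return counts


def random_grid_aligned_fixture(rng, n_ranges, n_pas, extent=(0, 0, 3, 3),
                                step=0.05):
    """Random axis-aligned squares with corners on a coarse grid.

    Corner coordinates are multiples of ``step`` (a multiple of the oracle
    pixel size), so rasterized decisions at RES resolution are exact.
    """
    from shapely.geometry import box

    from pagap import ProtectedArea, SpeciesRange

    x0, y0, x1, y1 = extent
    nsteps = int(round((x1 - x0) / step))

    def rand_box():
        # corners computed as units*step in one multiplication each, so two
        # squares sharing a grid line get bitwise-equal coordinates
        su = int(rng.integers(1, max(2, nsteps // 3)))
        ou = int(rng.integers(0, nsteps - su + 1))
        ov = int(rng.integers(0, nsteps - su + 1))
        return box(x0 + ou * step, y0 + ov * step,
                   x0 + (ou + su) * step, y0 + (ov + su) * step)

    ranges = []
    for i in range(n_ranges):
        g = rand_box()
        ranges.append(SpeciesRange(f"s{i}", "amphibia", g, g.area, "LC"))
    pas = []
    for i in range(n_pas):
        g = rand_box()
        pas.append(ProtectedArea(f"p{i}", g, area_km2=g.area,
                                 terrestrial_area_km2=g.area))
    return ranges, pas
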