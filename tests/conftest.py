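import numpy as np
import pytest
from hypothesis import settings

import vitimap as vm

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def template():
    return vm.default_template()


@pytest.fixture(scope="session")
def simple_scene():
    """One clean fluorescent patch on a synthetic face."""
    spec = vm.SceneSpec(seed=11,
                        patches=(vm.PatchSpec(center=(200.0, 300.0),
                                              radii=(18.0, 14.0)),))
    image, gt, session = vm.generate_scene(spec)
    return image, gt, session


# --- brute-force oracles, deliberately independent of the implementation ---

def bf_point_in_polygon(px, py, verts):
    """Even-odd rule with inclusive boundary, one point at a time."""
    n = len(verts)
    inside = False
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        seg = max(((x2 - x1) ** 2 + (y2 - y1) ** 2) ** 0.5, 1.0)
        cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
        if (abs(cross) <= 1e-9 * seg
                and min(x1, x2) - 1e-9 <= px <= max(x1, x2) + 1e-9
                and min(y1, y2) - 1e-9 <= py <= max(y1, y2) + 1e-9):
            return True
        if (y1 > py) != (y2 > py):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < xint:
                inside = not inside
    return inside


def bf_rasterize(verts, height, width):
    out = np.zeros((height, width), dtype=bool)
    for y in range(height):
        for x in range(width):
            out[y, x] = bf_point_in_polygon(float(x), float(y), verts)
    return out


def bf_detect(filtered, roi_vertex_lists, t):
    """Loop-over-everything reimplementation of the adaptive detection."""
    h, w = filtered.shape
    out = np.zeros((h, w), dtype=bool)
    for verts in roi_vertex_lists:
        region = bf_rasterize(verts, h, w)
        mx = filtered[region].max()
        if mx == 0.0 and t != 0.0:
            continue
        for y in range(h):
            for x in range(w):
                if region[y, x] and filtered[y, x] >= t * mx:
                    out[y, x] = True
    return out
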