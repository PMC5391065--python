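"""Independent brute-force oracles used to check the library's geometry.

Each oracle reaches its answer by a different route than the implementation
it checks (bisection instead of quadratic roots, per-element fsum instead of
vectorised reductions) so agreement is evidence, not tautology.
"""

import math

import numpy as np


def chord_march_oracle(points: np.ndarray, link: float):
    """March a chain of rigid links along a polyline by scan-and-bisect.

    Walks the polyline point by point until the distance from the current
    node first reaches ``link``, then bisects within that sub-segment.
    Returns (nodes, n_full_links). Independent of the quadratic-root
    marcher in the library.
    """
    pts = np.asarray(points, float)
    nodes = [pts[0]]
    i = 1
    while True:
        cur = nodes[-1]
        while i < len(pts) and np.linalg.norm(pts[i] - cur) < link:
            i += 1
        if i >= len(pts):
            break
        a, b = pts[i - 1], pts[i]
        lo, hi = 0.0, 1.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if np.linalg.norm(a + mid * (b - a) - cur) < link:
                lo = mid
            else:
                hi = mid
        nodes.append(a + hi * (b - a))
    return np.array(nodes), len(nodes) - 1


def extendible_R_oracle(points: np.ndarray, link: float) -> float:
    """Extendible-chain rugosity from the scan-and-bisect marcher."""
    pts = np.asarray(points, float)
    nodes, n_full = chord_march_oracle(pts, link)
    draped = n_full * link + float(np.linalg.norm(pts[-1] - nodes[-1]))
    undraped = float(np.linalg.norm(pts[-1] - pts[0]))
    return draped / undraped


def fixed_R_oracle(points: np.ndarray, link: float, chain: float) -> float:
    """Fixed-length-chain rugosity from the scan-and-bisect marcher."""
    n_links = int(math.floor(chain / link + 1e-9))
    nodes, n_full = chord_march_oracle(np.asarray(points, float), link)
    if n_full < n_links:
        raise ValueError("oracle chain runs off the contour")
    end = nodes[n_links]
    return (n_links * link) / float(np.linalg.norm(end - nodes[0]))


def quilt_area_oracle(heights: np.ndarray, spacing: float) -> float:
    """Cell-by-cell quilt area with explicit cross products and fsum."""
    ny, nx = heights.shape
    areas = []
    for j in range(ny - 1):
        for i in range(nx - 1):
            z = heights[j:j + 2, i:i + 2]
            if not np.isfinite(z).all():
                continue
            sw = (i * spacing, j * spacing, z[0, 0])
            se = ((i + 1) * spacing, j * spacing, z[0, 1])
            ne = ((i + 1) * spacing, (j + 1) * spacing, z[1, 1])
            nw = (i * spacing, (j + 1) * spacing, z[1, 0])
            for tri in ((sw, se, ne), (sw, ne, nw)):
                areas.append(_tri_area(*tri))
    return math.fsum(areas)


def _tri_area(p, q, r):
    ux, uy, uz = (q[0] - p[0], q[1] - p[1], q[2] - p[2])
    vx, vy, vz = (r[0] - p[0], r[1] - p[1], r[2] - p[2])
    cx, cy, cz = (uy * vz - uz * vy, uz * vx - ux * vz, ux * vy - uy * vx)
    return 0.5 * math.sqrt(cx * cx + cy * cy + cz * cz)


def resultant_oracle(triangles: np.ndarray) -> tuple[float, int]:
    """(R1, i) by per-triangle float arithmetic with fsum accumulation."""
    sx, sy, sz = [], [], []
    for tri in np.asarray(triangles, float):
        p, q, r = tri
        ux, uy, uz = q - p
        vx, vy, vz = r - p
        nx_ = uy * vz - uz * vy
        ny_ = uz * vx - ux * vz
        nz_ = ux * vy - uy * vx
        norm = math.sqrt(nx_ * nx_ + ny_ * ny_ + nz_ * nz_)
        if norm == 0.0:
            continue
        cx, cy, cz = nx_ / norm, ny_ / norm, nz_ / norm
        if cz < 0:
            cx, cy, cz = -cx, -cy, -cz
        sx.append(cx)
        sy.append(cy)
        sz.append(cz)
    R1 = math.sqrt(math.fsum(sx) ** 2 + math.fsum(sy) ** 2
                   + math.fsum(sz) ** 2)
    return R1, len(sx)


def semicircle_polyline(radius: float, n: int, y: float = 0.0,
                        x0: float = 0.0) -> np.ndarray:
    """Semicircular arc in the X-Z plane sampled at n+1 equal-arc points:
    from (x0, y, 0) over the top to (x0 + 2r, y, 0)."""
    theta = np.linspace(np.pi, 0.0, n + 1)
    x = x0 + radius * (1.0 + np.cos(theta))
    z = radius * np.sin(theta)
    return np.column_stack([x, np.full(n + 1, y), z])


def sinusoid_polyline(side: float, amplitude: float, wavelength: float,
                      n: int, y: float = 0.0) -> np.ndarray:
    x = np.linspace(0.0, side, n + 1)
    z = amplitude * np.sin(2 * np.pi * x / wavelength)
    return np.column_stack([x, np.full(n + 1, y), z])
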