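"""Deterministic synthetic networks for calibrating and testing the metrics.

Every generator returns a :class:`VesselNetwork` whose statistics are known
in closed form (grids, parallel lines, T/Y junction sets) or by construction
(homogeneous Poisson segment fields, half-plane voids), so each analysis
routine has an independent oracle.
"""

from __future__ import annotations

import numpy as np

from .network import VesselNetwork

__all__ = ["generate_fixture"]

_KINDS = ("poisson-segments", "grid", "parallel-lines", "T-junction-set",
          "Y-fork-set", "half-plane-void")


def generate_fixture(kind: str, params: dict | None = None, seed: int = 0) -> VesselNetwork:
    """Build a synthetic network of the given ``kind``.

    Parameters per kind (all lengths um):

    - poisson-segments: box (side, default 2000), intensity (segments per
      um^2), seg_length (fixed) or mean_seg_length (exponential), random
      orientations; a homogeneous Poisson field with alpha = 0.5.
    - grid: spacing, extent -- square lattice of horizontal+vertical lines.
    - parallel-lines: n_lines, spacing, length -- perfectly nematic.
    - T-junction-set: n, arm -- disjoint T shapes (every branch node lateral).
    - Y-fork-set: n, arm -- disjoint symmetric 120-deg Ys (every node a fork).
    - half-plane-void: like poisson-segments but all mass at y > 0 (the lower
      half-plane is empty).
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind not in _KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {_KINDS}")

    if kind in ("poisson-segments", "half-plane-void"):
        side = params.get("side", 2000.0)
        intensity = params.get("intensity", 5e-5)
        n = rng.poisson(intensity * side * side)
        centers = rng.uniform(0.0, side, (n, 2))
        if kind == "half-plane-void":
            centers[:, 1] = np.abs(centers[:, 1] - side / 2) + side / 2
        if "seg_length" in params:
            lens = np.full(n, float(params["seg_length"]))
        else:
            lens = rng.exponential(params.get("mean_seg_length", 50.0), n)
        angs = rng.uniform(0.0, np.pi, n)
        d = 0.5 * lens[:, None] * np.stack([np.cos(angs), np.sin(angs)], axis=1)
        coords = np.empty((2 * n, 2))
        coords[0::2] = centers - d
        coords[1::2] = centers + d
        edges = np.stack([np.arange(0, 2 * n, 2), np.arange(1, 2 * n, 2)], axis=1)
        return VesselNetwork.from_arrays(coords, edges)

    if kind == "grid":
        spacing = params.get("spacing", 100.0)
        extent = params.get("extent", 1000.0)
        k = int(round(extent / spacing))
        xs = np.arange(k + 1) * spacing
        net = VesselNetwork()
        idx = {}
        for i, x in enumerate(xs):
            for j, y in enumerate(xs):
                idx[i, j] = net.add_node((x, y))
        for i in range(k + 1):
            for j in range(k + 1):
                if i < k:
                    net.add_segment(idx[i, j], idx[i + 1, j])
                if j < k:
                    net.add_segment(idx[i, j], idx[i, j + 1])
        return net

    if kind == "parallel-lines":
        n_lines = params.get("n_lines", 10)
        spacing = params.get("spacing", 100.0)
        length = params.get("length", 1000.0)
        net = VesselNetwork()
        for i in range(n_lines):
            a = net.add_node((0.0, i * spacing))
            b = net.add_node((length, i * spacing))
            net.add_segment(a, b)
        return net

    # junction sets: disjoint motifs on a coarse lattice
    n = params.get("n", 5)
    arm = params.get("arm", 50.0)
    pitch = 4.0 * arm
    net = VesselNetwork()
    for i in range(n):
        cx, cy = (i % 10) * pitch, (i // 10) * pitch
        c = net.add_node((cx, cy))
        if kind == "T-junction-set":
            ends = [(cx - arm, cy), (cx + arm, cy), (cx, cy + arm)]
        else:  # Y-fork-set: 120 deg apart
            angs = np.array([90.0, 210.0, 330.0]) * np.pi / 180.0
            ends = [(cx + arm * np.cos(a), cy + arm * np.sin(a)) for a in angs]
        for e in ends:
            net.add_segment(c, net.add_node(e))
    return net
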