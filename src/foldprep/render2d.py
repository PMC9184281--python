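"""Lightweight pseudo-3D structure rendering and MSA plot data.

Instead of a 3D renderer, the backbone trace is drawn as 2D line segments
sorted by depth (painter's algorithm) and shaded by depth, which fakes a 3D
impression while staying vector-graphics friendly.  This module produces the
resolution-independent segment data; the matplotlib drawing layer is a thin
convenience on top.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .msa import GAP_CODE, Msa, encode_rows, query_identity

__all__ = [
    "Segment",
    "SegmentList",
    "ribbon_segments",
    "msa_coverage_plot_data",
    "read_ca_coords",
    "plot_segments",
]

#: shade assigned to the farthest segment; nearest gets 1.0
SHADE_MIN = 0.5


@dataclass
class Segment:
    start: Tuple[float, float]
    end: Tuple[float, float]
    depth: float
    shade: float
    color: float  # scalar color value; meaning depends on color_mode


@dataclass
class SegmentList:
    segments: List[Segment]
    color_mode: str

    def __iter__(self):
        return iter(self.segments)

    def __len__(self):
        return len(self.segments)

    def to_json(self) -> str:
        return json.dumps({
            "color_mode": self.color_mode,
            "segments": [asdict(s) for s in self.segments],
        })

    @classmethod
    def from_json(cls, text: str) -> "SegmentList":
        d = json.loads(text)
        return cls(
            segments=[
                Segment(tuple(s["start"]), tuple(s["end"]), s["depth"],
                        s["shade"], s["color"])
                for s in d["segments"]
            ],
            color_mode=d["color_mode"],
        )


def _chain_of(index: int, partition: Optional[Sequence[Tuple[int, int]]]) -> int:
    if partition is None:
        return 0
    for k, (start, end) in enumerate(partition):
        if start <= index < end:
            return k
    raise ValueError(f"residue {index} not covered by the chain partition")


def ribbon_segments(
    coords: np.ndarray,
    view: Optional[np.ndarray] = None,
    color_mode: str = "index",
    metric: Optional[Sequence[float]] = None,
    chain_partition: Optional[Sequence[Tuple[int, int]]] = None,
) -> SegmentList:
    """Project a CA trace into depth-sorted, depth-shaded 2D segments.

    ``coords`` is N×3; ``view`` an optional 3×3 rotation applied first.
    Consecutive residues become one segment each (chain boundaries from
    ``chain_partition`` break the trace); segments are sorted ascending by
    mean transformed z (farthest drawn first) with a stable sort, and shade
    maps z linearly from SHADE_MIN (farthest) to 1.0 (nearest).

    Colors: ``index`` — residue position normalised to [0, 1] (N to C
    terminus); ``metric`` — mean of the supplied per-residue values over the
    segment's endpoints (e.g. pLDDT); ``chain`` — chain id of the segment.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 2:
        raise ValueError("need at least two 3D coordinates")
    if color_mode == "metric" and metric is None:
        raise ValueError("color_mode 'metric' needs per-residue metric values")
    if view is not None:
        coords = coords @ np.asarray(view, dtype=float).T
    n = coords.shape[0]

    raw: List[Segment] = []
    for i in range(n - 1):
        ci, cj = _chain_of(i, chain_partition), _chain_of(i + 1, chain_partition)
        if ci != cj:
            continue
        depth = float((coords[i, 2] + coords[i + 1, 2]) / 2.0)
        if color_mode == "index":
            color = i / max(n - 2, 1)
        elif color_mode == "metric":
            color = float((metric[i] + metric[i + 1]) / 2.0)
        elif color_mode == "chain":
            color = float(ci)
        else:
            raise ValueError(f"unknown color_mode {color_mode!r}")
        raw.append(Segment((float(coords[i, 0]), float(coords[i, 1])),
                           (float(coords[i + 1, 0]), float(coords[i + 1, 1])),
                           depth, 0.0, color))
    if not raw:
        raise ValueError("no segments (all residue pairs cross chain breaks)")

    depths = np.array([s.depth for s in raw])
    lo, hi = float(depths.min()), float(depths.max())
    span = hi - lo
    for s in raw:
        s.shade = 1.0 if span == 0 else SHADE_MIN + (1.0 - SHADE_MIN) * (s.depth - lo) / span
    order = np.argsort(depths, kind="stable")
    return SegmentList(segments=[raw[i] for i in order], color_mode=color_mode)


def msa_coverage_plot_data(msa: Msa) -> dict:
    """Depth-and-diversity plot data for an MSA.

    Returns per-query-column counts of rows carrying a residue (coverage)
    and per-row query identity with rows ordered most-similar first, which is
    the layout of the standard MSA coverage figure.
    """
    codes = encode_rows(msa.rows)
    coverage = (codes != GAP_CODE).sum(axis=0)
    identities = [query_identity(row, msa.query) for row in msa.rows]
    order = sorted(range(len(identities)), key=lambda i: (-identities[i], i))
    return {
        "coverage": coverage.astype(int).tolist(),
        "row_order": order,
        "row_identity": [identities[i] for i in order],
        "n_rows": len(msa),
        "query_length": msa.query_length,
    }


def read_ca_coords(path) -> Tuple[np.ndarray, List[Tuple[int, int]]]:
    """CA-trace coordinates and chain partition from a PDB file."""
    from Bio.PDB import PDBParser

    structure = PDBParser(QUIET=True).get_structure("model", path)
    coords: List[List[float]] = []
    partition: List[Tuple[int, int]] = []
    model = next(structure.get_models())
    for chain in model:
        start = len(coords)
        for residue in chain:
            if "CA" in residue:
                coords.append(residue["CA"].coord.tolist())
        if len(coords) > start:
            partition.append((start, len(coords)))
    return np.asarray(coords, dtype=float), partition


def plot_segments(segments: SegmentList, ax=None, cmap: str = "viridis",
                  linewidth: float = 2.0):
    """Draw a segment list with matplotlib (thin, untested convenience)."""
    import matplotlib.pyplot as plt
    from matplotlib.collections import LineCollection
    import matplotlib.cm as cm
    from matplotlib.colors import Normalize

    if ax is None:
        _, ax = plt.subplots()
    colors = np.array([s.color for s in segments])
    norm = Normalize(colors.min(), colors.max()) if colors.size else None
    mapper = cm.get_cmap(cmap)
    rgba = []
    for s in segments:
        c = np.array(mapper(norm(s.color))) if norm else np.array([0.2, 0.2, 0.2, 1.0])
        c[:3] *= s.shade
        rgba.append(c)
    lc = LineCollection([[s.start, s.end] for s in segments], colors=rgba,
                        linewidths=linewidth)
    ax.add_collection(lc)
    ax.autoscale()
    ax.set_aspect("equal")
    ax.axis("off")
    return ax
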