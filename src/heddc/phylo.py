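"""Distance-based trees from normalized tandem-repeat distance matrices."""

from __future__ import annotations

import io
import logging

import numpy as np
import skbio
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .matrix import DistanceMatrix

logger = logging.getLogger(__name__)


def _skbio_dm(dm: DistanceMatrix, which: str) -> skbio.DistanceMatrix:
    mat = np.array(
        [[float(x) for x in row] for row in getattr(dm, which)], dtype=float
    )
    return skbio.DistanceMatrix(mat, ids=list(dm.ids))


def neighbor_joining(dm: DistanceMatrix, which: str = "normalized") -> str:
    """Neighbor-joining tree as Newick text (negative branches clamped to 0)."""
    if len(dm.ids) < 3:
        raise ValueError(
            "neighbor joining needs at least 3 taxa; write the distance "
            "matrix directly instead"
        )
    sdm = _skbio_dm(dm, which)
    tree = skbio.tree.nj(sdm)  # clamps negative branch lengths by default
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            logger.warning("clamping negative branch length %g", node.length)
            node.length = 0.0
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def upgma(dm: DistanceMatrix, which: str = "normalized") -> str:
    """UPGMA (average-linkage, ultrametric) tree as Newick text."""
    if len(dm.ids) < 3:
        raise ValueError("UPGMA needs at least 3 taxa")
    mat = np.array(
        [[float(x) for x in row] for row in getattr(dm, which)], dtype=float
    )
    Z = hierarchy.average(squareform(mat, checks=False))
    root = hierarchy.to_tree(Z)

    def newick(node, parent_height: float) -> str:
        height = node.dist / 2  # ultrametric node height
        length = parent_height - height
        if node.is_leaf():
            return f"{dm.ids[node.id]}:{length:.10g}"
        left = newick(node.left, height)
        right = newick(node.right, height)
        return f"({left},{right}):{length:.10g}"

    h = root.dist / 2
    return f"({newick(root.left, h)},{newick(root.right, h)});"


def write_newick(newick: str, path) -> None:
    with open(path, "w") as fh:
        fh.write(newick.rstrip() + ("\n" if not newick.endswith("\n") else ""))
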