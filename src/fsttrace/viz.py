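"""Integrated representations of population structure.

The pairwise-F_ST distance matrix describes the *current* structure
(NJ tree, classical MDS); the population-specific F_ST values describe
each population's deviation from the common ancestral pool and are
overlaid as a red (smallest F_ST, i.e. most ancestral) to blue (largest)
color gradient on the tree, the MDS plot, a dot chart with ±2×SE
whiskers, and a sampling-location map whose yellow edges connect
populations with pairwise F_ST below a connectivity threshold
(default 0.02 ≈ 49 island-model migrants per generation).

Every plotted quantity is also written as a TSV "plot data" file so the
figures can be checked on data rather than pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .estimators import PairwiseFstMatrix, PopSpecificFstResult

__all__ = [
    "MdsResult",
    "classical_mds",
    "nj_tree",
    "fst_colors",
    "connectivity_edges",
    "render_outputs",
]


@dataclass
class MdsResult:
    """Classical MDS (principal coordinates) embedding.

    ``contributions[k-1]`` is the cumulative contribution ratio
    C_k = sum_{j<=k} lambda_j+ / sum_j lambda_j+, computed over positive
    eigenvalues only (negative eigenvalues are treated as 0).
    """

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    contributions: np.ndarray

    def axis_contribution(self, k: int) -> float:
        """Marginal contribution of axis k (1-based), as a fraction."""
        c = self.contributions
        return float(c[k - 1] - (c[k - 2] if k >= 2 else 0.0))


def classical_mds(d: np.ndarray, k: Optional[int] = None) -> MdsResult:
    """Classical (Torgerson) MDS of a distance matrix.

    Double-centers -0.5 * J D^2 J, eigendecomposes, and scales the
    eigenvectors of the positive eigenvalues by their square roots.
    ``k`` caps the returned axes (default: all axes with positive
    eigenvalue).
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    pos = np.clip(w, 0.0, None)
    total = pos.sum()
    if total <= 0:
        contributions = np.ones(n)
        coords = np.zeros((n, 1))
        return MdsResult(coords, w, contributions)
    contributions = np.cumsum(pos) / total
    n_pos = int((w > 1e-12 * w.max()).sum())
    k_out = n_pos if k is None else min(k, n)
    coords = v[:, :k_out] * np.sqrt(pos[:k_out])
    return MdsResult(coords, w, contributions)


def nj_tree(d: np.ndarray, labels: Sequence[str]):
    """Neighbor-joining tree from a distance matrix.

    Returns an unrooted ``skbio.TreeNode``.  Negative branch lengths
    are retained but flagged with a warning.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj as _nj

    d = np.asarray(d, dtype=float)
    if d.shape[0] < 3:
        raise ValueError("neighbor joining needs at least three populations")
    tree = _nj(DistanceMatrix(d, ids=list(labels)), neg_as_zero=False)
    if any(n.length is not None and n.length < 0 for n in tree.traverse()):
        warnings.warn("NJ tree contains negative branch lengths")
    return tree


def fst_colors(values: np.ndarray) -> np.ndarray:
    """Standardize F_ST values and map them to an rgb gradient.

    F'_ST = (F_ST - min) / (max - min); color = (1 - F', 0, F'), so the
    smallest value is pure red and the largest pure blue.  A degenerate
    (constant) range maps everything to red with a warning.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one value")
    span = np.nanmax(v) - np.nanmin(v)
    if span <= 0 or not np.isfinite(span):
        warnings.warn("degenerate F_ST range; all populations colored red")
        f = np.zeros_like(v)
    else:
        f = (v - np.nanmin(v)) / span
    return np.column_stack([1.0 - f, np.zeros_like(f), f])


def connectivity_edges(pw, threshold: float = 0.02) -> list[tuple[int, int]]:
    """Undirected edges between populations with pairwise F_ST < threshold."""
    values = pw.values if isinstance(pw, PairwiseFstMatrix) else np.asarray(pw)
    k = values.shape[0]
    return [
        (i, j)
        for i in range(k)
        for j in range(i + 1, k)
        if np.isfinite(values[i, j]) and values[i, j] < threshold
    ]


def _unrooted_layout(tree):
    """Equal-angle layout for an unrooted tree -> {leaf/node id: (x, y)}."""
    leaves = list(tree.tips())
    n_leaves = len(leaves)
    coords = {}
    lines = []

    def count_tips(node):
        return 1 if node.is_tip() else sum(count_tips(c) for c in node.children)

    def place(node, x, y, angle_lo, angle_hi):
        coords[id(node)] = (x, y, node)
        lo = angle_lo
        for child in node.children:
            tips = count_tips(child)
            wedge = (angle_hi - angle_lo) * tips / max(count_tips(node), 1)
            mid = lo + wedge / 2.0
            length = child.length or 0.0
            cx = x + length * np.cos(mid)
            cy = y + length * np.sin(mid)
            lines.append(((x, y), (cx, cy)))
            place(child, cx, cy, lo, lo + wedge)
            lo += wedge
    place(tree, 0.0, 0.0, 0.0, 2.0 * np.pi)
    return coords, lines


def render_outputs(outdir, psfst: PopSpecificFstResult,
                   pairwise: PairwiseFstMatrix,
                   coords: Optional[pd.DataFrame] = None,
                   threshold: float = 0.02,
                   prefix: str = "fst",
                   formats: Sequence[str] = ("png",)) -> dict[str, Path]:
    """Write the four integrated figures plus their plot-data files.

    Outputs: (a) map of sampling points colored by population-specific
    F_ST with yellow connectivity edges, (b) sorted dot chart with ±2×SE
    whiskers, (c) NJ tree, (d) MDS scatter with axis contributions in
    the labels; the tree is also exported as Newick and every plotted
    table as TSV.  ``coords`` needs columns population/lon/lat; a
    population without coordinates is dropped from the map with a
    warning.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pops = list(psfst.populations)
    if pops != list(pairwise.populations):
        raise ValueError("population sets of the two estimates differ")
    written: dict[str, Path] = {}

    def save(fig, stem):
        for fmt in formats:
            p = outdir / f"{prefix}_{stem}.{fmt}"
            fig.savefig(p, dpi=150, bbox_inches="tight")
            written[f"{stem}.{fmt}"] = p
        plt.close(fig)

    def tsv(df, stem):
        p = outdir / f"{prefix}_{stem}.tsv"
        df.to_csv(p, sep="\t", index=False)
        written[f"{stem}.tsv"] = p

    colors = fst_colors(psfst.fst)
    dist = pairwise.distances()
    edges = connectivity_edges(pairwise, threshold)

    # population-specific F_ST table + pairwise matrix
    tsv(psfst.to_dataframe(), "popspecific")
    pw_df = pairwise.to_dataframe().reset_index().rename(columns={"index": "population"})
    tsv(pw_df, "pairwise")

    # (a) map
    if coords is not None:
        cmap = coords.set_index("population")
        have = [p for p in pops if p in cmap.index]
        missing = sorted(set(pops) - set(have))
        if missing:
            warnings.warn(f"no coordinates for populations {missing}; omitted from map")
        lon = cmap.loc[have, "lon"].to_numpy(dtype=float)
        lat = cmap.loc[have, "lat"].to_numpy(dtype=float)
        idx = {p: i for i, p in enumerate(pops)}
        fig, ax = plt.subplots(figsize=(7, 6))
        edge_rows = []
        for i, j in edges:
            pi, pj = pops[i], pops[j]
            if pi in have and pj in have:
                xi, yi = cmap.loc[pi, ["lon", "lat"]].astype(float)
                xj, yj = cmap.loc[pj, ["lon", "lat"]].astype(float)
                ax.plot([xi, xj], [yi, yj], color="gold", lw=1.2, zorder=1)
                edge_rows.append((pi, pj, pairwise.values[i, j]))
        ax.scatter(lon, lat, c=colors[[idx[p] for p in have]], s=60,
                   edgecolor="k", lw=0.4, zorder=2)
        for p, x, y in zip(have, lon, lat):
            ax.annotate(p, (x, y), fontsize=6, xytext=(2, 2),
                        textcoords="offset points")
        ax.set_xlabel("longitude")
        ax.set_ylabel("latitude")
        ax.set_title(f"population-specific $F_{{ST}}$ (red = smallest); "
                     f"edges: pairwise $F_{{ST}}$ < {threshold:g}")
        save(fig, "map")
        tsv(pd.DataFrame({"population": have, "lon": lon, "lat": lat,
                          "fst": [psfst.fst[idx[p]] for p in have]}),
            "map_points")
        tsv(pd.DataFrame(edge_rows, columns=["pop_i", "pop_j", "pairwise_fst"]),
            "map_edges")

    # (b) dot chart, sorted, whiskers at +-2 SE
    order = np.argsort(psfst.fst)
    se = psfst.se if psfst.se is not None else np.zeros(len(pops))
    fig, ax = plt.subplots(figsize=(5, 0.28 * len(pops) + 1))
    y = np.arange(len(pops))
    ax.errorbar(psfst.fst[order], y, xerr=2.0 * se[order], fmt="none",
                ecolor="gray", elinewidth=1)
    ax.scatter(psfst.fst[order], y, c=colors[order], s=40, edgecolor="k",
               lw=0.4, zorder=3)
    ax.set_yticks(y, [pops[i] for i in order], fontsize=6)
    ax.set_xlabel("population-specific $F_{ST}$ (±2×SE)")
    save(fig, "dotchart")
    tsv(pd.DataFrame({"population": [pops[i] for i in order],
                      "fst": psfst.fst[order], "se": se[order],
                      "whisker_halfwidth": 2.0 * se[order]}),
        "dotchart")

    # (c) NJ tree
    tree = nj_tree(dist, pops)
    nwk = outdir / f"{prefix}_tree.nwk"
    tree.write(str(nwk))
    written["tree.nwk"] = nwk
    node_coords, lines = _unrooted_layout(tree)
    fig, ax = plt.subplots(figsize=(7, 7))
    for (x1, y1), (x2, y2) in lines:
        ax.plot([x1, x2], [y1, y2], color="gray", lw=1)
    cidx = {p: i for i, p in enumerate(pops)}
    for _, (x, y, node) in node_coords.items():
        if node.is_tip():
            ax.text(x, y, node.name, fontsize=7,
                    color=tuple(colors[cidx[node.name]]))
    ax.set_axis_off()
    ax.set_title("NJ tree of pairwise $F_{ST}$, leaves colored by "
                 "population-specific $F_{ST}$")
    save(fig, "njtree")

    # (d) MDS
    mds = classical_mds(dist)
    c1 = mds.axis_contribution(1) * 100.0
    c2 = mds.axis_contribution(2) * 100.0 if mds.coordinates.shape[1] > 1 else 0.0
    xy = mds.coordinates
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(xy[:, 0], xy[:, 1] if xy.shape[1] > 1 else np.zeros(len(pops)),
               c=colors, s=50, edgecolor="k", lw=0.4)
    for i, p in enumerate(pops):
        ax.annotate(p, (xy[i, 0], xy[i, 1] if xy.shape[1] > 1 else 0.0),
                    fontsize=6, xytext=(2, 2), textcoords="offset points")
    ax.set_xlabel(f"MDS axis 1 ({c1:.0f}%)")
    ax.set_ylabel(f"MDS axis 2 ({c2:.0f}%)")
    save(fig, "mds")
    mds_df = pd.DataFrame({"population": pops, "axis1": xy[:, 0]})
    if xy.shape[1] > 1:
        mds_df["axis2"] = xy[:, 1]
    mds_df["fst"] = psfst.fst
    tsv(mds_df, "mds")
    return written
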