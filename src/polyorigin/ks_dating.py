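"""Ks-distribution modeling, peak extraction and molecular dating.

Synonymous substitutions per synonymous site (Ks) between gene pairs act
as a proxy clock: the mode ("peak") of the Ks distribution over many gene
pairs estimates the divergence of a species pair or of the homeolog sets
within a polyploid genome.  Dating proceeds two ways:

* *linear calibration* — ``age = Ks_peak * age_cal / Ks_cal`` against a
  known split (default: the Solanum-Nicotiana split, Ks = 0.279 at
  29.5 Mya);
* *UPGMA* — average-linkage clustering of the symmetric Ks-peak matrix
  into an ultrametric tree (node height = merge distance / 2), whose
  heights are then rescaled so a calibration node sits at a known age.

Densities use a Gaussian kernel with the normal-reference (Silverman)
bandwidth; Ks values above ``ks_max`` (default 2.0) are discarded before
estimation as a saturation guard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import gaussian_kde

from .errors import InsufficientDataError, PolyOriginError
from .scenario import CALIBRATION_AGE_MYA, canonical_pair

__all__ = [
    "DensityCurve",
    "KsPeak",
    "estimate_ks_density",
    "find_ks_peak",
    "calibrate_dates",
    "CalibratedTree",
    "upgma_tree",
    "date_upgma_nodes",
]


@dataclass
class DensityCurve:
    """Kernel density estimate on an even grid over [0, ks_max]."""

    grid: np.ndarray
    density: np.ndarray
    n_samples: int
    bandwidth: float

    @property
    def spacing(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def estimate_ks_density(
    samples, ks_max: float = 2.0, grid_points: int = 512, bw_method="silverman"
) -> DensityCurve:
    """Gaussian KDE of a Ks sample, truncated to (0, ks_max].

    Requires >= 10 usable samples after truncation.  The curve is
    renormalized so it integrates to 1 over the grid (trapezoid rule),
    compensating for kernel mass leaking below zero.  A zero-variance
    sample degenerates to a point mass at the nearest grid point.
    """
    samples = np.asarray(samples, dtype=float)
    usable = samples[(samples > 0) & (samples <= ks_max)]
    if usable.size < 10:
        raise InsufficientDataError(
            f"only {usable.size} Ks values in (0, {ks_max}]; >= 10 required"
        )
    grid = np.linspace(0.0, ks_max, grid_points)
    if np.std(usable) == 0:
        density = np.zeros(grid_points)
        idx = int(np.argmin(np.abs(grid - usable[0])))
        density[idx] = 1.0 / (grid[1] - grid[0])
        return DensityCurve(grid, density, int(usable.size), 0.0)
    kde = gaussian_kde(usable, bw_method=bw_method)
    density = kde(grid)
    area = np.trapezoid(density, grid)
    density = density / area
    bandwidth = float(kde.factor * np.std(usable, ddof=1))
    return DensityCurve(grid, density, int(usable.size), bandwidth)


@dataclass
class KsPeak:
    """A located density mode; ``at_boundary`` flags a search-range edge hit."""

    value: float
    at_boundary: bool

    def __float__(self) -> float:
        return self.value


def find_ks_peak(curve: DensityCurve, search_range=(0.01, None)) -> KsPeak:
    """Global argmax of the density within ``search_range`` (which.max semantics)."""
    lo, hi = search_range
    if hi is None:
        hi = float(curve.grid[-1])
    mask = (curve.grid >= lo) & (curve.grid <= hi)
    if not mask.any():
        raise PolyOriginError(f"empty search range {search_range}")
    idx_local = int(np.argmax(curve.density[mask]))
    idx_all = np.nonzero(mask)[0][idx_local]
    first, last = np.nonzero(mask)[0][[0, -1]]
    return KsPeak(value=float(curve.grid[idx_all]), at_boundary=idx_all in (first, last))


def calibrate_dates(
    peaks: dict, calibration_pair, calibration_age: float = CALIBRATION_AGE_MYA
) -> dict:
    """Linear dating: ``age = Ks * calibration_age / Ks_calibration``.

    ``peaks`` maps unordered species pairs to peak Ks values.  The
    calibration pair must be present with Ks > 0; its age is reproduced
    exactly and all other ages scale linearly.
    """
    canon = {canonical_pair(*k): float(v) for k, v in peaks.items()}
    cal = canonical_pair(*calibration_pair)
    if cal not in canon:
        raise PolyOriginError(f"calibration pair {cal} not in peak table")
    ks_cal = canon[cal]
    if ks_cal <= 0:
        raise PolyOriginError(f"calibration Ks must be > 0, got {ks_cal}")
    factor = calibration_age / ks_cal
    return {pair: ks * factor for pair, ks in canon.items()}


def read_ks_table(path) -> pd.DataFrame:
    """Read a ``species_a<TAB>species_b<TAB>ks`` table."""
    df = pd.read_csv(path, sep="\t")
    required = {"species_a", "species_b", "ks"}
    if not required <= set(df.columns):
        raise PolyOriginError(f"Ks table must have columns {sorted(required)}")
    return df


def write_ks_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def peaks_from_table(
    df: pd.DataFrame,
    ks_max: float = 2.0,
    grid_points: int = 512,
    search_range=(0.01, None),
) -> dict:
    """Per-pair Ks peaks: KDE + argmax for every species pair in the table."""
    peaks = {}
    for (a, b), sub in df.groupby(["species_a", "species_b"]):
        curve = estimate_ks_density(sub["ks"].to_numpy(), ks_max, grid_points)
        peaks[canonical_pair(a, b)] = find_ks_peak(curve, search_range)
    return peaks


# ---------------------------------------------------------------------------
# UPGMA


@dataclass
class _CNode:
    height: float
    children: list
    taxon: str | None = None

    def leaves(self):
        if self.taxon is not None:
            yield self
        else:
            for child in self.children:
                yield from child.leaves()


@dataclass
class CalibratedTree:
    """Ultrametric tree with node heights in Ks units or Mya."""

    root: _CNode
    units: str = "ks"
    calibration: tuple | None = None  # (calibration node, age)

    def leaf_names(self) -> list:
        return sorted(leaf.taxon for leaf in self.root.leaves())

    def _mrca(self, a: str, b: str) -> _CNode:
        node = self.root
        while True:
            nxt = None
            for child in node.children:
                names = {leaf.taxon for leaf in child.leaves()}
                if a in names and b in names:
                    nxt = child
                    break
            if nxt is None:
                return node
            node = nxt

    def height_of(self, a: str, b: str) -> float:
        """Height (units) of the MRCA of two taxa; a==b gives 0."""
        if a == b:
            return 0.0
        return self._mrca(a, b).height

    def root_height(self) -> float:
        return self.root.height

    def rescaled(self, factor: float, units: str, calibration=None) -> "CalibratedTree":
        def scale(node: _CNode) -> _CNode:
            return _CNode(
                height=node.height * factor,
                children=[scale(c) for c in node.children],
                taxon=node.taxon,
            )

        return CalibratedTree(root=scale(self.root), units=units, calibration=calibration)

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        def depths(node, acc):
            if node.taxon is not None:
                yield acc
            for child in node.children:
                yield from depths(child, acc + (node.height - child.height))

        ds = list(depths(self.root, 0.0))
        return max(ds) - min(ds) <= tol

    def newick(self, fmt: str = "%.6g") -> str:
        def render(node: _CNode, parent_height: float) -> str:
            length = fmt % (parent_height - node.height)
            if node.taxon is not None:
                return f"{node.taxon}:{length}"
            inner = ",".join(render(c, node.height) for c in node.children)
            return f"({inner}):{length}"

        inner = ",".join(render(c, self.root.height) for c in self.root.children)
        return f"({inner});"


def upgma_tree(distance_matrix, taxa) -> CalibratedTree:
    """Average-linkage (UPGMA) tree from a symmetric distance matrix.

    Node heights equal merge distance / 2, so the tree reproduces any
    additive ultrametric input exactly.  Raises on asymmetry beyond 1e-9.
    """
    d = np.asarray(distance_matrix, dtype=float)
    taxa = list(taxa)
    if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(taxa):
        raise PolyOriginError("distance matrix must be square and match taxa")
    if len(taxa) < 2:
        raise PolyOriginError("UPGMA requires >= 2 taxa")
    if np.max(np.abs(d - d.T)) > 1e-9:
        raise PolyOriginError("distance matrix asymmetric beyond 1e-9")
    if np.any(d < 0):
        raise PolyOriginError("distance matrix must be non-negative")
    sym = (d + d.T) / 2.0
    np.fill_diagonal(sym, 0.0)
    z = linkage(squareform(sym, checks=False), method="average")
    nodes = [_CNode(height=0.0, children=[], taxon=t) for t in taxa]
    for left, right, dist, _ in z:
        nodes.append(
            _CNode(
                height=float(dist) / 2.0,
                children=[nodes[int(left)], nodes[int(right)]],
            )
        )
    return CalibratedTree(root=nodes[-1], units="ks")


def date_upgma_nodes(
    tree: CalibratedTree, calibration_node, calibration_age: float = CALIBRATION_AGE_MYA
) -> CalibratedTree:
    """Rescale all heights so the calibration node sits at ``calibration_age``.

    ``calibration_node`` is either the string ``"root"`` or a pair of taxon
    names whose MRCA anchors the calibration.  Idempotent: re-dating an
    already-dated tree with the same calibration leaves it unchanged.
    """
    if calibration_node == "root":
        h = tree.root_height()
    else:
        a, b = calibration_node
        h = tree.height_of(a, b)
    if h <= 0:
        raise PolyOriginError("calibration node height must be > 0")
    return tree.rescaled(
        factor=calibration_age / h,
        units="mya",
        calibration=(calibration_node, calibration_age),
    )
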