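"""Self-organizing map for clustering learning contexts.

A rectangular grid of model vectors m_i is fitted to n-dimensional data.
The best-matching unit (BMU) for an input x is the model with the smallest
Euclidean distance; online updates move every model toward x in proportion
to a decreasing learning rate alpha(t) and a Gaussian neighborhood kernel
h_ci(t) centered on the BMU:

    m_i(t+1) = m_i(t) + alpha(t) * h_ci(t) * [x - m_i(t)]

Batch fitting replaces each model by the kernel-weighted mean of the data
means of the Voronoi cells:

    m_i = sum_j n_j h_ji x_bar_j / sum_j n_j h_ji

With the kernel shrunk to a delta this is exactly a k-means (Lloyd) step,
so delta-kernel batch fixed points coincide with k-means centroids.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["SomGrid", "bmu", "update_online", "fit_batch"]


@dataclass
class SomGrid:
    """Grid state: (rows x cols) model vectors plus schedules.

    alpha0     initial learning rate in [0, 1]; decays linearly to 0 over
               ``t_max`` online steps (alpha(t) = alpha0 * (1 - t/t_max)).
    sigma0     initial neighborhood width in grid-distance units; decays
               linearly to ``sigma_min``.  sigma -> 0 gives a delta kernel
               (h = 1 only at the BMU itself).
    """

    rows: int
    cols: int
    dim: int
    seed: int = 0
    alpha0: float = 0.5
    sigma0: float = 1.0
    sigma_min: float = 1e-3
    t_max: int = 1000
    weights: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one unit")
        if not (0.0 <= self.alpha0 <= 1.0):
            raise ValueError("alpha0 must lie in [0, 1]")
        if self.weights is None:
            rng = np.random.default_rng(self.seed)
            self.weights = rng.uniform(0.0, 1.0, size=(self.rows * self.cols, self.dim))
        else:
            self.weights = np.asarray(self.weights, dtype=float).reshape(
                self.rows * self.cols, self.dim
            )
        rr, cc = np.meshgrid(np.arange(self.rows), np.arange(self.cols), indexing="ij")
        self._grid_pos = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)

    @property
    def n_units(self) -> int:
        return self.rows * self.cols

    def alpha(self, t: int) -> float:
        return max(0.0, self.alpha0 * (1.0 - t / self.t_max))

    def sigma(self, t: int) -> float:
        return max(self.sigma_min, self.sigma0 * (1.0 - t / self.t_max))

    def kernel(self, center: int, sigma: float) -> np.ndarray:
        """Gaussian neighborhood over grid distance; exactly 1 at the BMU."""
        d2 = ((self._grid_pos - self._grid_pos[center]) ** 2).sum(axis=1)
        if sigma <= 0:
            out = np.zeros(self.n_units)
            out[center] = 1.0
            return out
        return np.exp(-d2 / (2.0 * sigma**2))

    def quantization_error(self, data: np.ndarray) -> float:
        data = np.atleast_2d(np.asarray(data, dtype=float))
        dists = np.linalg.norm(data[:, None, :] - self.weights[None, :, :], axis=2)
        return float(dists.min(axis=1).mean())

    def to_json(self, path) -> None:
        doc = {
            "rows": self.rows, "cols": self.cols, "dim": self.dim,
            "seed": self.seed, "alpha0": self.alpha0, "sigma0": self.sigma0,
            "sigma_min": self.sigma_min, "t_max": self.t_max,
            "weights": self.weights.ravel().tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SomGrid":
        with open(path) as fh:
            doc = json.load(fh)
        weights = np.asarray(doc.pop("weights"), dtype=float)
        return cls(**doc, weights=weights)


def bmu(grid: SomGrid, x) -> int:
    """Index of the best-matching unit; ties break to the lowest index."""
    if grid.n_units == 0:
        raise ValueError("empty grid")
    x = np.asarray(x, dtype=float)
    if x.shape != (grid.dim,):
        raise ValueError(f"input must have dimension {grid.dim}")
    dists = np.linalg.norm(grid.weights - x[None, :], axis=1)
    return int(np.argmin(dists))


def update_online(grid: SomGrid, x, t: int) -> SomGrid:
    """One online step at schedule time t (in place; returns the grid)."""
    x = np.asarray(x, dtype=float)
    c = bmu(grid, x)
    a = grid.alpha(t)
    if a == 0.0:
        return grid
    h = grid.kernel(c, grid.sigma(t))
    grid.weights += a * h[:, None] * (x[None, :] - grid.weights)
    return grid


def fit_batch(
    grid: SomGrid,
    data,
    epochs: int = 10,
    sigma: float | None = None,
    shrink: bool = True,
) -> list[float]:
    """Batch-fit the grid; returns the per-epoch quantization-error trace.

    ``sigma`` fixes the kernel width for every epoch; otherwise the width
    shrinks linearly from sigma0 to sigma_min across epochs (when
    ``shrink``).  A unit whose kernel mass is zero (empty cells only)
    keeps its model vector unchanged.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.size == 0:
        raise ValueError("data must be non-empty")
    trace: list[float] = []
    for epoch in range(epochs):
        if sigma is not None:
            width = sigma
        elif shrink and epochs > 1:
            width = grid.sigma0 + (grid.sigma_min - grid.sigma0) * epoch / (epochs - 1)
        else:
            width = grid.sigma0
        # Voronoi assignment
        dists = np.linalg.norm(data[:, None, :] - grid.weights[None, :, :], axis=2)
        cells = np.argmin(dists, axis=1)
        counts = np.bincount(cells, minlength=grid.n_units).astype(float)
        sums = np.zeros_like(grid.weights)
        np.add.at(sums, cells, data)
        means = np.divide(sums, counts[:, None], out=np.zeros_like(sums), where=counts[:, None] > 0)
        # kernel-weighted combination of cell means
        H = np.stack([grid.kernel(i, width) for i in range(grid.n_units)])  # h[i, j]
        mass = H @ counts
        numer = H @ (counts[:, None] * means)
        keep = mass <= 0
        new_weights = np.where(
            keep[:, None], grid.weights, numer / np.where(mass[:, None] > 0, mass[:, None], 1.0)
        )
        grid.weights = new_weights
        trace.append(grid.quantization_error(data))
    return trace
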