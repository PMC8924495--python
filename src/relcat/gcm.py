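"""Generalized Context Model (GCM) for the non-arbitrary similarity pathway.

Exemplars live as points in an attention-weighted Minkowski space.
Similarity of a probe x to a stored exemplar j decays exponentially with
distance,

    s(x, j) = exp(-c * (sum_k w_k |y_xk - y_jk|^r)^(q/r)),

and the evidence for a category is the summed similarity over that
category's exemplars.  Choice follows the biased-choice rule

    P(A | x) = beta_A * eta_xA / sum_M beta_M * eta_xM,

with a category-specific bias in every term of the denominator and any
number of categories M >= 2.  Coordinates are inputs (an MDS solution or
measured dimensions); no scaling or fitting is performed here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ExemplarSpace", "summed_similarity", "choice_probability"]


@dataclass
class ExemplarSpace:
    """Exemplar memory plus the GCM parameters.

    coords     (n_exemplars, D) coordinates y_jk.
    categories length-n category label per exemplar.
    weights    attention weights w_k; normalized to sum to 1.
    c          sensitivity (> 0): how sharply similarity falls with distance.
    r          Minkowski order: 1 city-block, 2 Euclidean.
    q          similarity shape: 1 exponential, 2 Gaussian.
    biases     response bias beta per category (>= 0, default 1).
    """

    coords: np.ndarray
    categories: list[str]
    weights: np.ndarray | None = None
    c: float = 1.0
    r: int = 2
    q: int = 1
    biases: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2:
            raise ValueError("coords must be (n_exemplars, D)")
        n, d = self.coords.shape
        if len(self.categories) != n:
            raise ValueError("one category label per exemplar required")
        if self.weights is None:
            self.weights = np.full(d, 1.0 / d)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (d,) or np.any(self.weights < 0):
            raise ValueError("weights must be length-D and non-negative")
        total = self.weights.sum()
        if total <= 0:
            raise ValueError("weights must not all be zero")
        self.weights = self.weights / total
        if self.c <= 0:
            raise ValueError("sensitivity c must be > 0")
        if self.r not in (1, 2) or self.q not in (1, 2):
            raise ValueError("r and q must each be 1 or 2")
        for cat in set(self.categories):
            self.biases.setdefault(cat, 1.0)
        for cat, beta in self.biases.items():
            if beta < 0:
                raise ValueError(f"bias for {cat!r} must be >= 0")
            if cat not in self.categories:
                raise ValueError(f"bias refers to unknown category {cat!r}")

    @property
    def category_names(self) -> list[str]:
        return sorted(set(self.categories))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **params) -> "ExemplarSpace":
        """Build from a table with columns id, category, dim1..dimD."""
        dims = [c for c in df.columns if c not in ("id", "category")]
        return cls(coords=df[dims].to_numpy(float), categories=list(df["category"]), **params)

    @classmethod
    def from_csv(cls, path, **params) -> "ExemplarSpace":
        return cls.from_frame(pd.read_csv(path), **params)


def _distances(space: ExemplarSpace, probe: np.ndarray) -> np.ndarray:
    diffs = np.abs(space.coords - probe[None, :])
    inner = (space.weights[None, :] * diffs ** space.r).sum(axis=1)
    return inner ** (1.0 / space.r)


def summed_similarity(space: ExemplarSpace, probe_coords, category: str) -> float:
    """Summed similarity eta of the probe to one category's exemplars."""
    probe = np.asarray(probe_coords, dtype=float)
    if probe.shape != (space.coords.shape[1],):
        raise ValueError("probe dimensionality must match the exemplar space")
    if category not in space.categories:
        raise KeyError(f"unknown category {category!r}")
    mask = np.array([cat == category for cat in space.categories])
    dist = _distances(space, probe)[mask]
    return float(np.exp(-space.c * dist ** space.q).sum())


def choice_probability(space: ExemplarSpace, probe_coords) -> dict[str, float]:
    """Bias-weighted choice probabilities over all categories (sum to 1).

    When every bias-weighted similarity is zero (e.g. an extremely distant
    probe at large c) the response is uniform, with a warning.
    """
    names = space.category_names
    if len(names) < 2:
        raise ValueError("choice requires >= 2 categories")
    evidence = np.array(
        [space.biases[cat] * summed_similarity(space, probe_coords, cat) for cat in names]
    )
    total = evidence.sum()
    if total == 0.0:
        warnings.warn("all bias-weighted similarities are zero; uniform fallback")
        return {cat: 1.0 / len(names) for cat in names}
    return {cat: float(ev / total) for cat, ev in zip(names, evidence)}
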