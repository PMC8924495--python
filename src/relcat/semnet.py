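"""Semantic network with representation and relation input layers.

The architecture follows the parallel-distributed-processing semantic
network family: a context-independent *representation* layer is driven by a
one-hot concept input, a *relation* input injects the relational-frame
context further downstream (into the second hidden block when there is
one), and a sigmoid attribute layer reads the result out:

    h1 = sigmoid(Wc @ concept + b1)
    h2 = sigmoid(W2 @ h1 + Wr @ relation + b2)
    ...
    out = sigmoid(Wo @ h_last + bo)

Two trainers are provided over the same weights:

* plain stochastic backpropagation on the mean squared-error cost
  C = (1/n) sum_x C_x, and
* a predictive-coding relaxation with purely local (Hebbian) updates:
  value nodes v_l relax to a fixed point of
  dv_l ∝ -eps_l + W_{l+1}^T (eps_{l+1} * f'(z_{l+1})) with the input and
  target layers clamped, after which each weight moves by
  (error node) x (presynaptic activity) — which approximates the exact
  backprop gradient to high precision.

A binned plug-in mutual-information diagnostic quantifies how much input
and output information each layer carries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SemNet",
    "PredictiveState",
    "TripleCorpus",
    "response_probability",
    "bayes_posterior",
    "discrete_mutual_information",
    "discrete_entropy",
    "layer_mutual_information",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def sigmoid_prime(z: np.ndarray) -> np.ndarray:
    s = sigmoid(z)
    return s * (1.0 - s)


def response_probability(o_k, theta: float):
    """Logistic response rule P_k = 1 / (1 + e^{-theta * O_k}).

    Maps an output activation to a response probability; strictly
    increasing in O_k, with theta > 0 a positive scaling parameter.
    """
    if theta <= 0:
        raise ValueError("theta must be > 0")
    return 1.0 / (1.0 + np.exp(-theta * np.asarray(o_k, dtype=float)))


def bayes_posterior(p_e_given_h: float, p_h: float, p_e: float) -> float:
    """P(H|E) = P(E|H) P(H) / P(E)."""
    if p_e <= 0:
        raise ValueError("P(E) must be > 0")
    return p_e_given_h * p_h / p_e


# ---------------------------------------------------------------------------
# Corpus encoding
# ---------------------------------------------------------------------------

@dataclass
class TripleCorpus:
    """One-hot encoded (concept, relation-context, attribute) corpus.

    Target vectors are multi-hot, aggregated per (concept, relation) pair:
    every attribute the corpus asserts for that pair is on.  A row counts
    as correctly produced when its own attribute's output unit exceeds 0.5.
    """

    concepts: list[str]
    relations: list[str]
    attributes: list[str]
    X_concept: np.ndarray
    X_relation: np.ndarray
    Y: np.ndarray
    row_attr: np.ndarray  # attribute index of each row

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TripleCorpus":
        concepts = sorted(df["concept"].unique())
        relations = sorted(df["relation"].unique())
        attributes = sorted(df["attribute"].unique())
        ci = {c: i for i, c in enumerate(concepts)}
        ri = {r: i for i, r in enumerate(relations)}
        ai = {a: i for i, a in enumerate(attributes)}
        n = len(df)
        Xc = np.zeros((n, len(concepts)))
        Xr = np.zeros((n, len(relations)))
        row_attr = np.zeros(n, dtype=int)
        # aggregate multi-hot targets per (concept, relation)
        pair_targets: dict[tuple[int, int], np.ndarray] = {}
        rows = list(zip(df["concept"], df["relation"], df["attribute"]))
        for concept, relation, attribute in rows:
            key = (ci[concept], ri[relation])
            vec = pair_targets.setdefault(key, np.zeros(len(attributes)))
            vec[ai[attribute]] = 1.0
        Y = np.zeros((n, len(attributes)))
        for idx, (concept, relation, attribute) in enumerate(rows):
            Xc[idx, ci[concept]] = 1.0
            Xr[idx, ri[relation]] = 1.0
            Y[idx] = pair_targets[(ci[concept], ri[relation])]
            row_attr[idx] = ai[attribute]
        return cls(concepts, relations, attributes, Xc, Xr, Y, row_attr)


# ---------------------------------------------------------------------------
# The network
# ---------------------------------------------------------------------------

@dataclass
class PredictiveState:
    """Relaxed value and error nodes of one predictive-coding inference."""

    values: list[np.ndarray]
    errors: list[np.ndarray]
    converged: bool
    residual: float
    iterations: int


class SemNet:
    """Layered semantic network with an optional relation input block."""

    def __init__(
        self,
        n_concepts: int,
        hidden_sizes: tuple[int, ...] | list[int],
        n_attributes: int,
        n_relations: int = 0,
        seed: int = 0,
        init_scale: float = 0.1,
        activation: str = "sigmoid",
    ) -> None:
        if not hidden_sizes and activation == "sigmoid" and n_relations:
            raise ValueError("relation input requires at least one hidden layer")
        self.n_concepts = n_concepts
        self.n_relations = n_relations
        self.hidden_sizes = tuple(hidden_sizes)
        self.n_attributes = n_attributes
        self.activation = activation
        self.seed = seed
        # relation input feeds the second hidden block when present, so the
        # first hidden block stays a context-independent representation.
        self.rel_inject = 2 if len(self.hidden_sizes) >= 2 else 1
        sizes = [n_concepts, *self.hidden_sizes, n_attributes]
        self.sizes = sizes
        rng = np.random.default_rng(seed)
        self.W = [
            rng.uniform(-init_scale, init_scale, size=(sizes[i + 1], sizes[i]))
            for i in range(len(sizes) - 1)
        ]
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        if n_relations:
            inject_size = sizes[self.rel_inject]
            self.Wr = rng.uniform(-init_scale, init_scale, size=(inject_size, n_relations))
        else:
            self.Wr = None

    # -- activations ------------------------------------------------------
    def _f(self, z: np.ndarray) -> np.ndarray:
        return z if self.activation == "linear" else sigmoid(z)

    def _fprime(self, z: np.ndarray) -> np.ndarray:
        return np.ones_like(z) if self.activation == "linear" else sigmoid_prime(z)

    @property
    def n_layers(self) -> int:
        return len(self.W)

    def _preactivation(self, layer: int, prev: np.ndarray, relation: np.ndarray | None) -> np.ndarray:
        z = prev @ self.W[layer].T + self.b[layer]
        if self.Wr is not None and layer + 1 == self.rel_inject and relation is not None:
            z = z + relation @ self.Wr.T
        return z

    def forward(self, concept, relation=None, return_all: bool = False):
        """Deterministic forward pass; outputs in (0, 1) under sigmoid."""
        a = np.atleast_2d(np.asarray(concept, dtype=float))
        squeeze = np.asarray(concept).ndim == 1
        if a.shape[1] != self.n_concepts:
            raise ValueError(f"concept input must have {self.n_concepts} units")
        rel = None
        if self.Wr is not None:
            if relation is None:
                rel = np.zeros((a.shape[0], self.n_relations))
            else:
                rel = np.atleast_2d(np.asarray(relation, dtype=float))
                if rel.shape[1] != self.n_relations:
                    raise ValueError(f"relation input must have {self.n_relations} units")
        acts, zs = [a], []
        for layer in range(self.n_layers):
            z = self._preactivation(layer, acts[-1], rel)
            zs.append(z)
            acts.append(self._f(z))
        if return_all:
            return acts, zs
        out = acts[-1]
        return out[0] if squeeze else out

    # -- backpropagation --------------------------------------------------
    def gradients(self, concept, relation, target, flat_spot: float = 0.0):
        """Gradients of C = (1/n) sum ½||o - t||² wrt W, b, Wr.

        ``flat_spot`` adds Fahlman's constant to the output-layer sigmoid
        derivative (0 = exact gradient).  Training uses a small positive
        value so saturated output units with wrong targets keep learning;
        analyses that need the true gradient leave it at 0.
        """
        acts, zs = self.forward(concept, relation, return_all=True)
        t = np.atleast_2d(np.asarray(target, dtype=float))
        n = t.shape[0]
        delta = (acts[-1] - t) * (self._fprime(zs[-1]) + flat_spot)
        gW = [np.zeros_like(w) for w in self.W]
        gb = [np.zeros_like(b) for b in self.b]
        gWr = None if self.Wr is None else np.zeros_like(self.Wr)
        rel = None
        if self.Wr is not None:
            rel = np.atleast_2d(np.asarray(relation, dtype=float)) if relation is not None else np.zeros((n, self.n_relations))
        for layer in range(self.n_layers - 1, -1, -1):
            gW[layer] = delta.T @ acts[layer] / n
            gb[layer] = delta.mean(axis=0)
            if gWr is not None and layer + 1 == self.rel_inject:
                gWr = delta.T @ rel / n
            if layer > 0:
                delta = (delta @ self.W[layer]) * self._fprime(zs[layer - 1])
        return gW, gb, gWr

    def loss(self, concept, relation, target) -> float:
        out = np.atleast_2d(self.forward(concept, relation))
        t = np.atleast_2d(np.asarray(target, dtype=float))
        return float(0.5 * np.sum((out - t) ** 2) / t.shape[0])

    def train_backprop(
        self,
        corpus: TripleCorpus,
        epochs: int,
        lr: float = 0.5,
        seed: int = 0,
        batch_size: int | None = None,
        flat_spot: float = 0.1,
    ) -> list[float]:
        """Mini-batch gradient descent; returns the per-epoch loss trace."""
        if epochs < 1:
            raise ValueError("epochs must be >= 1")
        rng = np.random.default_rng(seed)
        n = corpus.X_concept.shape[0]
        batch = batch_size or n
        trace = []
        for _ in range(epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch):
                idx = order[start : start + batch]
                gW, gb, gWr = self.gradients(
                    corpus.X_concept[idx], corpus.X_relation[idx], corpus.Y[idx],
                    flat_spot=flat_spot,
                )
                for layer in range(self.n_layers):
                    self.W[layer] -= lr * gW[layer]
                    self.b[layer] -= lr * gb[layer]
                if gWr is not None:
                    self.Wr -= lr * gWr
            epoch_loss = self.loss(corpus.X_concept, corpus.X_relation, corpus.Y)
            if not np.isfinite(epoch_loss):
                raise FloatingPointError("training diverged (non-finite loss)")
            trace.append(epoch_loss)
        return trace

    def accuracy(self, corpus: TripleCorpus, threshold: float = 0.5) -> float:
        """Fraction of rows whose own attribute unit exceeds the threshold."""
        out = np.atleast_2d(self.forward(corpus.X_concept, corpus.X_relation))
        hits = out[np.arange(len(corpus.row_attr)), corpus.row_attr] > threshold
        return float(hits.mean())

    # -- predictive coding -------------------------------------------------
    def relax(
        self,
        concept,
        relation,
        target,
        step: float = 0.1,
        max_iter: int = 500,
        tol: float = 1e-6,
    ) -> PredictiveState:
        """Relax value nodes to the predictive-coding fixed point.

        Input layer clamped to the concept vector, output layer clamped to
        the target; hidden value nodes follow
        dv_l = -eps_l + W_{l+1}^T (eps_{l+1} * f'(z_{l+1})).
        Non-convergence logs a warning and returns the current state.
        """
        x = np.atleast_2d(np.asarray(concept, dtype=float))
        t = np.atleast_2d(np.asarray(target, dtype=float))
        rel = None
        if self.Wr is not None:
            rel = (
                np.atleast_2d(np.asarray(relation, dtype=float))
                if relation is not None
                else np.zeros((x.shape[0], self.n_relations))
            )
        acts, _ = self.forward(x, rel, return_all=True)
        values = [a.copy() for a in acts]
        values[-1] = t.copy()
        residual = np.inf
        it = 0
        for it in range(1, max_iter + 1):
            zs = [self._preactivation(layer, values[layer], rel) for layer in range(self.n_layers)]
            errors = [np.zeros_like(values[0])] + [
                values[layer + 1] - self._f(zs[layer]) for layer in range(self.n_layers)
            ]
            residual = 0.0
            for layer in range(1, self.n_layers):  # hidden layers only
                back = (errors[layer + 1] * self._fprime(zs[layer])) @ self.W[layer]
                dv = -errors[layer] + back
                values[layer] = values[layer] + step * dv
                residual = max(residual, float(np.abs(dv).max(initial=0.0)))
            if residual < tol:
                break
        converged = residual < tol
        if not converged:
            logger.warning(
                "predictive-coding relaxation stopped at residual %.3g after %d iterations",
                residual, it,
            )
        zs = [self._preactivation(layer, values[layer], rel) for layer in range(self.n_layers)]
        errors = [np.zeros_like(values[0])] + [
            values[layer + 1] - self._f(zs[layer]) for layer in range(self.n_layers)
        ]
        return PredictiveState(values=values, errors=errors, converged=converged, residual=residual, iterations=it)


    def pc_updates(self, concept, relation, target, state: PredictiveState | None = None, **relax_kwargs):
        """Local Hebbian weight updates at the relaxed state.

        Delta W_l = (eps_{l+1} * f'(z_l)) x (presynaptic v_l); the
        direction that *descends* the squared-error cost, comparable 1:1
        with ``-gradients(...)``.
        """
        if state is None:
            state = self.relax(concept, relation, target, **relax_kwargs)
        x = np.atleast_2d(np.asarray(concept, dtype=float))
        n = x.shape[0]
        rel = None
        if self.Wr is not None:
            rel = (
                np.atleast_2d(np.asarray(relation, dtype=float))
                if relation is not None
                else np.zeros((n, self.n_relations))
            )
        dW, db = [], []
        dWr = None
        for layer in range(self.n_layers):
            z = self._preactivation(layer, state.values[layer], rel)
            local = state.errors[layer + 1] * self._fprime(z)
            dW.append(local.T @ state.values[layer] / n)
            db.append(local.mean(axis=0))
            if self.Wr is not None and layer + 1 == self.rel_inject:
                dWr = local.T @ rel / n
        return dW, db, dWr

    def train_predictive_coding(
        self,
        corpus: TripleCorpus,
        epochs: int,
        lr: float = 0.5,
        seed: int = 0,
        batch_size: int | None = None,
        relax_step: float = 0.2,
        relax_iter: int = 200,
        relax_tol: float = 1e-6,
    ) -> list[float]:
        """Train with relaxation + local updates; returns the loss trace."""
        if epochs < 1:
            raise ValueError("epochs must be >= 1")
        rng = np.random.default_rng(seed)
        n = corpus.X_concept.shape[0]
        batch = batch_size or n
        trace = []
        for _ in range(epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch):
                idx = order[start : start + batch]
                dW, db, dWr = self.pc_updates(
                    corpus.X_concept[idx], corpus.X_relation[idx], corpus.Y[idx],
                    step=relax_step, max_iter=relax_iter, tol=relax_tol,
                )
                for layer in range(self.n_layers):
                    self.W[layer] += lr * dW[layer]
                    self.b[layer] += lr * db[layer]
                if dWr is not None:
                    self.Wr += lr * dWr
            epoch_loss = self.loss(corpus.X_concept, corpus.X_relation, corpus.Y)
            if not np.isfinite(epoch_loss):
                raise FloatingPointError("training diverged (non-finite loss)")
            trace.append(epoch_loss)
        return trace

    # -- embeddings & checkpoints -----------------------------------------
    def concept_embeddings(self, layer: int = 1) -> np.ndarray:
        """Hidden representation of each concept one-hot (relation silent)."""
        eye = np.eye(self.n_concepts)
        acts, _ = self.forward(eye, None, return_all=True)
        return acts[layer]

    def knowledge_profiles(self, corpus: "TripleCorpus", threshold: float = 0.5) -> np.ndarray:
        """Asserted-knowledge profile of every concept.

        For each (concept, relation) pair present in the corpus, the output
        activations are averaged and thresholded, giving the attribute set
        the trained network asserts in that relational context.  Profiles
        are the per-relation blocks concatenated; unobserved blocks stay
        zero and feature columns that are zero for every concept (which
        carry no rank information) are dropped.  Row i belongs to
        ``corpus.concepts[i]``.
        """
        out = np.atleast_2d(self.forward(corpus.X_concept, corpus.X_relation))
        cidx = corpus.X_concept.argmax(axis=1)
        ridx = corpus.X_relation.argmax(axis=1)
        n_c, n_r, n_a = len(corpus.concepts), len(corpus.relations), len(corpus.attributes)
        profiles = np.zeros((n_c, n_r * n_a))
        for i in range(n_c):
            for r in range(n_r):
                mask = (cidx == i) & (ridx == r)
                if mask.any():
                    block = (out[mask].mean(axis=0) > threshold).astype(float)
                    profiles[i, r * n_a : (r + 1) * n_a] = block
        return profiles[:, profiles.any(axis=0)]

    def to_dict(self) -> dict:
        return {
            "n_concepts": self.n_concepts,
            "n_relations": self.n_relations,
            "hidden_sizes": list(self.hidden_sizes),
            "n_attributes": self.n_attributes,
            "activation": self.activation,
            "seed": self.seed,
            "W": [w.ravel().tolist() for w in self.W],
            "b": [b.tolist() for b in self.b],
            "Wr": None if self.Wr is None else self.Wr.ravel().tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, doc: dict) -> "SemNet":
        net = cls(
            n_concepts=doc["n_concepts"],
            hidden_sizes=tuple(doc["hidden_sizes"]),
            n_attributes=doc["n_attributes"],
            n_relations=doc["n_relations"],
            seed=doc.get("seed", 0),
            activation=doc.get("activation", "sigmoid"),
        )
        for layer, flat in enumerate(doc["W"]):
            net.W[layer] = np.asarray(flat, dtype=float).reshape(net.W[layer].shape)
        for layer, flat in enumerate(doc["b"]):
            net.b[layer] = np.asarray(flat, dtype=float)
        if doc.get("Wr") is not None:
            net.Wr = np.asarray(doc["Wr"], dtype=float).reshape(net.Wr.shape)
        return net

    @classmethod
    def from_json(cls, path) -> "SemNet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Mutual information diagnostics
# ---------------------------------------------------------------------------

def discrete_entropy(symbols) -> float:
    """Plug-in entropy (bits) of a sequence of hashable symbols."""
    _, counts = np.unique(np.asarray(symbols, dtype=object), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def discrete_mutual_information(xs, ys) -> float:
    """Plug-in I(X;Y) in bits from paired symbol sequences."""
    xs = [str(x) for x in xs]
    ys = [str(y) for y in ys]
    joint = [f"{x}|{y}" for x, y in zip(xs, ys)]
    return discrete_entropy(xs) + discrete_entropy(ys) - discrete_entropy(joint)


def _bin_layer(acts: np.ndarray, n_bins: int) -> list[str]:
    lo = acts.min(axis=0)
    hi = acts.max(axis=0)
    span = hi - lo
    constant = span <= 0
    if constant.all():
        logger.info("layer is constant across the corpus; MI is 0 by construction")
    width = np.where(constant, 1.0, span / n_bins)
    bins = np.clip(((acts - lo) / width).astype(int), 0, n_bins - 1)
    bins[:, constant] = 0
    return ["/".join(map(str, row)) for row in bins]


def layer_mutual_information(
    model: SemNet, corpus: TripleCorpus, layer_index: int, n_bins: int = 8
) -> tuple[float, float]:
    """Binned plug-in estimates of I(input; layer) and I(layer; target).

    Each unit is discretized into ``n_bins`` equal-width bins over its
    observed range and the layer symbol is the tuple of bin indices; the
    input symbol is the (concept, relation) pattern and the target symbol
    the multi-hot attribute vector.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    acts, _ = model.forward(corpus.X_concept, corpus.X_relation, return_all=True)
    layer = np.atleast_2d(acts[layer_index])
    layer_syms = _bin_layer(layer, n_bins)
    input_syms = [
        "/".join(map(str, np.concatenate([c, r]).astype(int)))
        for c, r in zip(corpus.X_concept, corpus.X_relation)
    ]
    target_syms = ["/".join(map(str, y.astype(int))) for y in corpus.Y]
    return (
        discrete_mutual_information(input_syms, layer_syms),
        discrete_mutual_information(layer_syms, target_syms),
    )
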