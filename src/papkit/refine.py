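"""Segmentation-mask refinement.

A candidate mask is expanded and contracted to form a three-variant set
(contracted, current, expanded).  The image intensities along each variant's
contour are flattened into a fixed-length zero-padded vector; the three
vectors form a 3×L token matrix fed to a single-head self-attention module
followed by a two-layer fully connected head that scores the candidate as a
positive (well-placed) mask or not.  Refinement resizes a negative candidate
one voxel at a time, keeping the better-scoring of the dilated and eroded
variants, until the classifier accepts it or an iteration bound is hit, in
which case the best-scoring mask seen (including the input) is returned.

The classifier is a small pure-numpy network trained by full-batch gradient
descent with momentum — deliberately simple so that training is bit-for-bit
reproducible from a seed.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volio import Volume

#: Fixed contour-vector length (zero padding / truncation).
CONTOUR_LEN = 2048

#: Intensity scale applied to HU values before the network.
_HU_SCALE = 1.0 / 1000.0

_CROSS = ndimage.generate_binary_structure(3, 1)  # six-connected


def _ball(radius: int) -> np.ndarray:
    ax = np.arange(-radius, radius + 1)
    return (ax[:, None, None] ** 2 + ax[None, :, None] ** 2
            + ax[None, None, :] ** 2) <= radius ** 2


@dataclass
class MaskVariantSet:
    """Contracted ⊆ current ⊆ expanded triple with the step used."""

    current: np.ndarray
    expanded: np.ndarray
    contracted: np.ndarray
    step: int
    contraction_fallback: bool = False


def make_variants(mask: np.ndarray, step: int = 1) -> MaskVariantSet:
    """Expand and contract a mask by a ball of ``step`` voxels.

    If the contraction empties the mask, the contracted variant falls back
    to the current mask (flagged, with a warning).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    ball = _ball(step)
    expanded = ndimage.binary_dilation(mask, structure=ball)
    contracted = ndimage.binary_erosion(mask, structure=ball)
    fallback = False
    if not contracted.any():
        warnings.warn("contraction emptied the mask; using the current mask "
                      "as the contracted variant", stacklevel=2)
        contracted = mask.copy()
        fallback = True
    return MaskVariantSet(current=mask, expanded=expanded,
                          contracted=contracted, step=step,
                          contraction_fallback=fallback)


@dataclass
class ContourFeatureVector:
    """Fixed-length contour-intensity vector."""

    values: np.ndarray
    raw_length: int
    truncated: bool = False


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Interior boundary: mask voxels with >= 1 six-connected non-mask
    neighbour.  Neighbours beyond the array border count as mask, so the
    grid edge itself never manufactures contour (a 3x3 square in a
    single-slice grid has the expected 8 boundary voxels)."""
    eroded = ndimage.binary_erosion(mask, structure=_CROSS, border_value=1)
    return mask & ~eroded


def contour_intensities(vol: Volume, mask: np.ndarray,
                        length: int = CONTOUR_LEN) -> ContourFeatureVector:
    """Image intensities along the mask contour, as one ordered vector.

    Within each axial slice boundary voxels are ordered by angle around the
    slice's boundary centroid (radius, then index, break residual ties);
    slices are concatenated in index order; the result is zero-padded or
    truncated to ``length``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if mask.shape != vol.shape:
        raise ValueError("mask not aligned with volume")
    bnd = boundary_voxels(mask)
    chunks = []
    for k in range(mask.shape[2]):
        idx = np.argwhere(bnd[:, :, k])
        if len(idx) == 0:
            continue
        center = idx.mean(axis=0)
        delta = idx - center
        ang = np.arctan2(delta[:, 1], delta[:, 0])
        rad = np.hypot(delta[:, 0], delta[:, 1])
        order = np.lexsort((idx[:, 1], idx[:, 0], rad, ang))
        ordered = idx[order]
        chunks.append(vol.data[ordered[:, 0], ordered[:, 1], k])
    seq = np.concatenate(chunks).astype(np.float64)
    raw = seq.size
    truncated = raw > length
    out = np.zeros(length, dtype=np.float64)
    out[:min(raw, length)] = seq[:length]
    return ContourFeatureVector(values=out, raw_length=raw, truncated=truncated)


def assemble_input(variants: MaskVariantSet, vol: Volume,
                   length: int = CONTOUR_LEN) -> np.ndarray:
    """3×L token matrix: contour vectors of (contracted, current, expanded)."""
    rows = [contour_intensities(vol, m, length=length).values
            for m in (variants.contracted, variants.current, variants.expanded)]
    return np.stack(rows, axis=0)


# ---------------------------------------------------------------------------
# classifier


@dataclass
class MaskClassifier:
    """Single-head self-attention over 3 variant tokens + 2-layer MLP head."""

    weights: dict
    length: int = CONTOUR_LEN
    threshold: float = 0.5
    seed: int = 0
    train_accuracy: float | None = None
    history: list = field(default_factory=list)

    # -- persistence -------------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "length": self.length, "threshold": self.threshold,
            "seed": self.seed, "train_accuracy": self.train_accuracy,
            "weights": {k: v.tolist() for k, v in self.weights.items()},
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "MaskClassifier":
        payload = json.loads(text)
        weights = {k: np.asarray(v, dtype=np.float64)
                   for k, v in payload["weights"].items()}
        return cls(weights=weights, length=payload["length"],
                   threshold=payload["threshold"], seed=payload["seed"],
                   train_accuracy=payload.get("train_accuracy"))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "MaskClassifier":
        with open(path) as fh:
            return cls.from_json(fh.read())


def _init_weights(length: int, d: int, m: int, seed: int) -> dict:
    rng = np.random.default_rng(seed)
    return {
        "We": rng.normal(0, 1 / math.sqrt(length), (length, d)),
        "be": np.zeros(d),
        "Wq": rng.normal(0, 1 / math.sqrt(d), (d, d)),
        "Wk": rng.normal(0, 1 / math.sqrt(d), (d, d)),
        "Wv": rng.normal(0, 1 / math.sqrt(d), (d, d)),
        "W1": rng.normal(0, 1 / math.sqrt(d), (d, m)),
        "b1": np.zeros(m),
        "W2": rng.normal(0, 0.01 / math.sqrt(m), (m, 1)),
        "b2": np.zeros(1),
    }


def _forward(w: dict, X: np.ndarray, cache: bool = False):
    """X: (N, 3, L) scaled inputs -> probabilities (N,)."""
    d = w["We"].shape[1]
    E = X @ w["We"] + w["be"]                     # (N,3,d)
    Q = E @ w["Wq"]
    K = E @ w["Wk"]
    V = E @ w["Wv"]
    S = np.einsum("ntd,nsd->nts", Q, K) / math.sqrt(d)
    S = S - S.max(axis=-1, keepdims=True)
    A = np.exp(S)
    A = A / A.sum(axis=-1, keepdims=True)         # (N,3,3)
    Z = np.einsum("nts,nsd->ntd", A, V)
    h = Z.mean(axis=1)                            # (N,d)
    pre = h @ w["W1"] + w["b1"]
    u = np.maximum(pre, 0.0)                      # (N,m)
    logit = (u @ w["W2"]).ravel() + w["b2"][0]
    prob = 1.0 / (1.0 + np.exp(-logit))
    if not cache:
        return prob
    return prob, {"E": E, "Q": Q, "K": K, "V": V, "A": A, "h": h,
                  "u": u, "pre": pre, "logit": logit}


def _backward(w: dict, X: np.ndarray, y: np.ndarray, prob: np.ndarray,
              c: dict) -> dict:
    N = X.shape[0]
    d = w["We"].shape[1]
    g = {}
    dlogit = (prob - y) / N                                     # (N,)
    g["W2"] = c["u"].T @ dlogit[:, None]
    g["b2"] = np.array([dlogit.sum()])
    du = np.outer(dlogit, w["W2"].ravel()) * (c["pre"] > 0)     # (N,m)
    g["W1"] = c["h"].T @ du
    g["b1"] = du.sum(axis=0)
    dh = du @ w["W1"].T                                         # (N,d)
    dZ = np.repeat(dh[:, None, :], 3, axis=1) / 3.0             # (N,3,d)
    dA = np.einsum("ntd,nsd->nts", dZ, c["V"])
    dV = np.einsum("nts,ntd->nsd", c["A"], dZ)
    inner = (c["A"] * dA).sum(axis=-1, keepdims=True)
    dS = c["A"] * (dA - inner) / math.sqrt(d)
    dQ = np.einsum("nts,nsd->ntd", dS, c["K"])
    dK = np.einsum("nts,ntd->nsd", dS, c["Q"])
    g["Wq"] = np.einsum("nti,ntj->ij", c["E"], dQ)
    g["Wk"] = np.einsum("nti,ntj->ij", c["E"], dK)
    g["Wv"] = np.einsum("nti,ntj->ij", c["E"], dV)
    dE = dQ @ w["Wq"].T + dK @ w["Wk"].T + dV @ w["Wv"].T
    g["We"] = np.einsum("nti,ntj->ij", X, dE)
    g["be"] = dE.sum(axis=(0, 1))
    return g


def bce_loss(prob: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-(y * np.log(prob + eps)
                   + (1 - y) * np.log(1 - prob + eps)).mean())


def train_classifier(positives, negatives, seed: int = 0,
                     length: int = CONTOUR_LEN, embed_dim: int = 64,
                     hidden_dim: int = 32, lr: float = 0.1,
                     momentum: float = 0.9, n_iter: int = 400,
                     threshold: float = 0.5) -> MaskClassifier:
    """Train the positive-mask classifier.

    ``positives`` / ``negatives`` are lists of (Volume, mask) pairs; each
    sample's own variant triplet forms its 3×L input.  Binary cross-entropy
    is minimized by full-batch gradient descent with momentum; given a seed
    the trained weights are bit-for-bit reproducible.
    """
    if not positives or not negatives:
        raise ValueError("both classes must be non-empty")
    X, y = [], []
    for label, group in ((1.0, positives), (0.0, negatives)):
        for vol, mask in group:
            variants = make_variants(mask, step=1)
            X.append(assemble_input(variants, vol, length=length) * _HU_SCALE)
            y.append(label)
    X = np.stack(X)
    y = np.asarray(y)
    w = _init_weights(length, embed_dim, hidden_dim, seed)
    vel = {k: np.zeros_like(v) for k, v in w.items()}
    history = []
    for _ in range(n_iter):
        prob, cache = _forward(w, X, cache=True)
        history.append(bce_loss(prob, y))
        g = _backward(w, X, y, prob, cache)
        for k in w:
            vel[k] = momentum * vel[k] - lr * g[k]
            w[k] = w[k] + vel[k]
    prob = _forward(w, X)
    acc = float(((prob >= threshold) == (y == 1)).mean())
    return MaskClassifier(weights=w, length=length, threshold=threshold,
                          seed=seed, train_accuracy=acc, history=history)


def score_mask(clf: MaskClassifier, vol: Volume, mask: np.ndarray) -> float:
    """Score one candidate mask in [0, 1] using its own variant triplet."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    variants = make_variants(mask, step=1)
    X = assemble_input(variants, vol, length=clf.length)[None] * _HU_SCALE
    return float(_forward(clf.weights, X)[0])


def refine_mask(clf: MaskClassifier, vol: Volume, mask: np.ndarray,
                max_iter: int = 10) -> tuple[np.ndarray, int, float]:
    """Resize a candidate mask until the classifier accepts it.

    A positive input is returned unchanged with 0 iterations.  Otherwise
    each iteration scores the 1-voxel dilated and 1-voxel eroded candidates
    and keeps the higher-scoring one; the loop stops at a positive score or
    after ``max_iter`` iterations, returning the best-scoring mask seen
    (the input included).  An emptied candidate branch is pruned.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    score = score_mask(clf, vol, mask)
    if score >= clf.threshold or max_iter == 0:
        return mask, 0, score
    best_mask, best_score = mask, score
    current = mask
    ball = _ball(1)
    iterations = 0
    for _ in range(max_iter):
        candidates = []
        grown = ndimage.binary_dilation(current, structure=ball)
        if grown.any():
            candidates.append(grown)
        shrunk = ndimage.binary_erosion(current, structure=ball)
        if shrunk.any():
            candidates.append(shrunk)
        if not candidates:
            break
        scored = [(score_mask(clf, vol, c), c) for c in candidates]
        scored.sort(key=lambda t: -t[0])
        s, current = scored[0]
        iterations += 1
        if s > best_score:
            best_mask, best_score = current, s
        if s >= clf.threshold:
            return current, iterations, s
    return best_mask, iterations, best_score
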