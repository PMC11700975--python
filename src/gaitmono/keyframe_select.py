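"""Representative-frame selection by density-peak clustering over kNN.

Each frame is described by a feature vector (here: its flattened,
centroid-removed joint coordinates).  Two scores are computed per frame:

* local density    rho_i = exp(-(1/k) * sum_{x_j in kNN(x_i)} |x_i - x_j|^2),
* centre score     delta_i = min_{j: rho_j > rho_i} |x_i - x_j|   if such j
  exists, else max_j |x_i - x_j|.

Frames maximizing gamma_i = rho_i * delta_i are simultaneously in dense
regions and far from denser frames — the density-peak criterion for
cluster exemplars.  Note the printed asymmetry: squared distances inside
the density exponent, plain Euclidean distances in the centre score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .errors import ParameterError
from .pose_model import PoseSequence


@dataclass
class DensityScores:
    """Per-frame DPC-kNN scores."""

    rho: np.ndarray
    delta: np.ndarray
    k: int

    @property
    def gamma(self) -> np.ndarray:
        """Selection score: product of density and centre score."""
        return self.rho * self.delta


def _pairwise(features: np.ndarray) -> np.ndarray:
    features = np.asarray(features, dtype=float)
    if features.ndim == 1:
        features = features[:, None]
    if features.ndim != 2:
        raise ParameterError("features must be a (frames, dims) array")
    if not np.isfinite(features).all():
        raise ParameterError("descriptors must be finite")
    if len(features) < 2:
        raise ParameterError("need at least 2 frames")
    return squareform(pdist(features))


def local_density(features: np.ndarray, k: int) -> np.ndarray:
    """Local density per frame from its k nearest other frames."""
    dist = _pairwise(features)
    n = len(dist)
    if not 1 <= k <= n - 1:
        raise ParameterError(f"k must be in [1, {n - 1}], got {k}")
    # drop self-distance (always 0, always first after partition of column i)
    sq = dist ** 2
    np.fill_diagonal(sq, np.inf)
    knn_sq = np.partition(sq, k - 1, axis=1)[:, :k]
    return np.exp(-knn_sq.mean(axis=1))


def center_score(features: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Distance to the nearest denser frame (or to the farthest frame)."""
    dist = _pairwise(features)
    rho = np.asarray(rho, dtype=float)
    if rho.shape != (len(dist),):
        raise ParameterError("rho length does not match feature count")
    delta = np.empty(len(dist))
    for i in range(len(dist)):
        denser = rho > rho[i]
        if denser.any():
            delta[i] = dist[i, denser].min()
        else:
            delta[i] = dist[i].max()
    return delta


def density_scores(features: np.ndarray, k: int) -> DensityScores:
    rho = local_density(features, k)
    return DensityScores(rho=rho, delta=center_score(features, rho), k=k)


def frame_descriptors(seq: PoseSequence) -> np.ndarray:
    """Flattened joint coordinates per frame, centroid-removed per axis.

    Removing the per-frame centroid makes the descriptor a pose-shape
    signature, invariant to the walker's forward translation; coordinates
    are scaled to unit overall RMS so the density exponent is well
    conditioned for millimetre inputs.
    """
    x = seq.coords - seq.coords.mean(axis=1, keepdims=True)
    flat = x.reshape(seq.n_frames, -1)
    scale = np.sqrt(np.mean(flat ** 2))
    return flat / scale if scale > 0 else flat


def select_keyframes(seq: PoseSequence, m: int, k: int | None = None) -> np.ndarray:
    """Indices of the ``m`` most representative frames, sorted ascending.

    ``k`` defaults to ceil(sqrt(F)).  Ties in gamma break toward the lower
    frame index so the output is deterministic.
    """
    F = seq.n_frames
    if not 1 <= m <= F:
        raise ParameterError(f"m must be in [1, {F}], got {m}")
    if k is None:
        k = math.ceil(math.sqrt(F))
    scores = density_scores(frame_descriptors(seq), k)
    order = np.lexsort((np.arange(F), -scores.gamma))
    return np.sort(order[:m])
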