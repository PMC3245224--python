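"""Episode similarity: plug-in mutual information with offset alignment.

The mutual information I(X, Y) = sum p(x, y) log p(x, y) / (p(x) p(y)) is
estimated by the histogram plug-in: each vector is binned into equal-width
bins spanning its own range, the joint distribution is the normalised 2-D
histogram, and empty cells contribute zero.  The logarithm base defaults to
2, so values are in bits; the base only rescales.

Episodes generally have unequal lengths.  The shorter episode is slid
across the longer one and the metric is evaluated at every contiguous
offset; the maximum over offsets is the similarity.  Bin edges are recomputed
per aligned slice so every offset is scored on the same footing.

A Pearson-correlation metric with the same alignment scheme is provided for
contrast with correlation-based cycle networks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateInputError
from .segmentation import Episode

__all__ = ["MiConfig", "SimilarityMatrix", "mutual_information",
           "aligned_similarity", "similarity_matrix"]

_METRICS = ("mutual_information", "pearson")


@dataclass(frozen=True)
class MiConfig:
    """Similarity-estimation settings.

    n_bins : int or None
        Histogram bins per axis.  ``None`` selects ``floor(sqrt(L))``
        clamped to [8, 32] (and to at most L // 2), with L the alignment
        length.
    log_base : float
        Logarithm base; 2 gives bits.
    metric : str
        ``"mutual_information"`` or ``"pearson"``.
    """

    n_bins: int | None = None
    log_base: float = 2.0
    metric: str = "mutual_information"

    def __post_init__(self):
        if self.n_bins is not None and self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if not self.log_base > 1:
            raise ValueError("log_base must be > 1")
        if self.metric not in _METRICS:
            raise ValueError(f"metric must be one of {_METRICS}")

    def resolve_bins(self, length: int) -> int:
        if self.n_bins is not None:
            return self.n_bins
        b = min(max(8, int(np.sqrt(length))), 32)
        return max(2, min(b, length // 2))


@dataclass
class SimilarityMatrix:
    """Symmetric episode-pair similarity with a zero diagonal."""

    values: np.ndarray
    metric: str = "mutual_information"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        self.values = v

    @property
    def size(self) -> int:
        return self.values.shape[0]

    def __getitem__(self, key):
        return self.values[key]

    def offdiagonal(self) -> np.ndarray:
        """Upper-triangle entries (each pair once), for distribution studies."""
        iu = np.triu_indices(self.size, k=1)
        return self.values[iu]


def _bin_indices(v: np.ndarray, nb: int) -> np.ndarray:
    lo = v.min()
    span = v.max() - lo
    if span == 0:
        raise DegenerateInputError("constant vector has zero range; MI undefined")
    idx = ((v - lo) * (nb / span)).astype(np.intp)
    return np.minimum(idx, nb - 1)


def _binned_mi(x: np.ndarray, y: np.ndarray, nb: int, log_base: float) -> float:
    """Plug-in MI from an nb x nb joint histogram; hot path, kept allocation-lean."""
    n = x.size
    ix = _bin_indices(x, nb)
    iy = _bin_indices(y, nb)
    joint = np.bincount(ix * nb + iy, minlength=nb * nb).astype(float).reshape(nb, nb)
    rows = joint.sum(axis=1)
    cols = joint.sum(axis=0)
    r, c = joint.nonzero()
    cell = joint[r, c]
    mi = float(np.sum(cell * np.log(cell * n / (rows[r] * cols[c])))) / n
    return mi / np.log(log_base)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd @ xd) * (yd @ yd))
    if denom == 0:
        raise DegenerateInputError("constant vector; correlation undefined")
    return float((xd @ yd) / denom)


def mutual_information(x, y, cfg: MiConfig | None = None) -> float:
    """Plug-in mutual information of two equal-length vectors.

    Equal-width bins span each vector's own range, so the estimate is exactly
    invariant under affine rescaling of either input.  Requires
    ``len(x) >= 2 * n_bins`` so cells are not absurdly undersampled.
    """
    cfg = cfg or MiConfig()
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    nb = cfg.resolve_bins(x.size)
    if x.size < 2 * nb:
        raise ValueError(f"need at least 2*n_bins={2 * nb} samples, got {x.size}")
    return _binned_mi(x, y, nb, cfg.log_base)


def _metric_fn(cfg: MiConfig):
    if cfg.metric == "pearson":
        return lambda a, b: _pearson(a, b)
    log_base = cfg.log_base

    def mi(a, b):
        nb = cfg.resolve_bins(a.size)
        return _binned_mi(a, b, nb, log_base)

    return mi


def _episode_values(e) -> np.ndarray:
    if isinstance(e, Episode):
        return e.values
    return np.asarray(e, dtype=float).ravel()


def aligned_similarity(e_i, e_j, cfg: MiConfig | None = None) -> float:
    """Offset-maximised similarity of two (possibly unequal-length) episodes.

    With L the shorter length, the metric is evaluated on every contiguous
    length-L window of the longer episode against the shorter one, and the
    maximum over offsets is returned.  Equal lengths reduce to the single
    offset-0 evaluation.
    """
    cfg = cfg or MiConfig()
    a = _episode_values(e_i)
    b = _episode_values(e_j)
    if a.size == 0 or b.size == 0:
        raise ValueError("episodes must be non-empty")
    short, long_ = (a, b) if a.size <= b.size else (b, a)
    L = short.size
    fn = _metric_fn(cfg)
    best = -np.inf
    for off in range(long_.size - L + 1):
        v = fn(long_[off:off + L], short)
        if v > best:
            best = v
    return best


def similarity_matrix(episodes, cfg: MiConfig | None = None) -> SimilarityMatrix:
    """Pairwise aligned similarity of all episodes; zero diagonal.

    Each unordered pair is computed once and mirrored.  The diagonal is
    forced to zero by convention so self-pairs never enter the network
    construction.
    """
    cfg = cfg or MiConfig()
    vals = [_episode_values(e) for e in episodes]
    n = len(vals)
    if n < 2:
        raise ValueError("need at least 2 episodes")
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = aligned_similarity(vals[i], vals[j], cfg)
    return SimilarityMatrix(S, metric=cfg.metric)
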