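"""scikit-learn-compatible transformers over the library.

The image -> diagram -> vector chain is transform-shaped, so these wrappers
expose it to sklearn pipelines and model selection: each transformer is
stateless in the statistical sense (``fit`` only validates and records input
metadata) and ``transform`` maps a sequence of greyscale images, or of
persistence-pair lists, to the next representation.

Example
-------
>>> from sklearn.pipeline import make_pipeline
>>> pipe = make_pipeline(CubicalPersistence("BW"), LandscapeVectorizer(dim=0))
>>> X = pipe.fit_transform(list_of_images)   # (n_images, n_layers * grid)
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import cubical, duality, feature_maps, summaries
from .image_prep import to_greyscale

__all__ = [
    "Greyscaler",
    "CubicalPersistence",
    "BettiCurveVectorizer",
    "LandscapeVectorizer",
    "ADVExtractor",
    "FeatureMapVectorizer",
]


def _as_image_list(X):
    if isinstance(X, np.ndarray) and X.ndim in (3, 4):
        return list(X)
    return list(X)


class Greyscaler(TransformerMixin, BaseEstimator):
    """CCIR-601 greyscale conversion; greyscale input passes through."""

    def fit(self, X, y=None):
        self.n_features_in_ = len(_as_image_list(X))
        return self

    def transform(self, X):
        return [to_greyscale(img) for img in _as_image_list(X)]


class CubicalPersistence(TransformerMixin, BaseEstimator):
    """Images -> lists of persistence pairs for one filtration direction."""

    def __init__(self, direction: str = "BW", representatives: bool = True):
        self.direction = direction
        self.representatives = representatives

    def fit(self, X, y=None):
        if self.direction.upper() not in ("BW", "WB"):
            raise ValueError(f"direction must be 'BW' or 'WB', got {self.direction!r}")
        self.n_features_in_ = len(_as_image_list(X))
        return self

    def transform(self, X):
        return [
            cubical.persistence(
                cubical.build_filtration(img, self.direction),
                representatives=self.representatives,
            )
            for img in _as_image_list(X)
        ]


class BettiCurveVectorizer(TransformerMixin, BaseEstimator):
    """Pair lists -> (n_samples, 256) Betti-curve vectors for one dimension."""

    def __init__(self, dim: int = 0):
        self.dim = dim

    def fit(self, X, y=None):
        self.n_features_in_ = len(X)
        return self

    def transform(self, X):
        return np.array([summaries.betti_curve(pairs, self.dim) for pairs in X], dtype=float)


class LandscapeVectorizer(TransformerMixin, BaseEstimator):
    """Pair lists -> flattened fixed-depth landscape vectors.

    Landscapes are truncated or zero-padded to ``n_layers`` layers so the
    output is rectangular: shape (n_samples, n_layers * 511).
    """

    def __init__(self, dim: int = 0, n_layers: int = 5,
                 min_persistence: float = summaries.DEFAULT_MIN_PERSISTENCE):
        self.dim = dim
        self.n_layers = n_layers
        self.min_persistence = min_persistence

    def fit(self, X, y=None):
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        self.n_features_in_ = len(X)
        return self

    def transform(self, X):
        g = summaries.LANDSCAPE_GRID.size
        out = np.zeros((len(X), self.n_layers * g))
        for i, pairs in enumerate(X):
            ls = summaries.landscape(pairs, self.dim, self.min_persistence)
            k = min(ls.n_layers, self.n_layers)
            if k:
                out[i, : k * g] = ls.layers[:k].ravel()
        return out


class ADVExtractor(TransformerMixin, BaseEstimator):
    """Images -> (n_samples, 2) array of [ADV_BW, ADV_WB]."""

    def fit(self, X, y=None):
        self.n_features_in_ = len(_as_image_list(X))
        return self

    def transform(self, X):
        out = []
        for img in _as_image_list(X):
            r = duality.adv(img)
            out.append([r.adv_bw, r.adv_wb])
        return np.array(out)


class FeatureMapVectorizer(TransformerMixin, BaseEstimator):
    """Images -> flattened composite feature-map grids.

    Runs both filtrations, builds the per-window descriptor map for each, and
    combines them; all images must share one shape so the grids align.
    """

    def __init__(self, kind: str = "density", window: int = feature_maps.DEFAULT_WINDOW):
        self.kind = kind
        self.window = window

    def fit(self, X, y=None):
        imgs = _as_image_list(X)
        shapes = {np.asarray(i).shape for i in imgs}
        if len(shapes) > 1:
            raise ValueError(f"all images must share one shape, got {shapes}")
        self.image_shape_ = shapes.pop() if shapes else None
        self.n_features_in_ = len(imgs)
        return self

    def transform(self, X):
        out = []
        for img in _as_image_list(X):
            shape = np.asarray(img).shape
            maps = {}
            for d in ("BW", "WB"):
                pairs = cubical.persistence(cubical.build_filtration(img, d))
                maps[d] = feature_maps.feature_map(pairs, shape, self.kind, self.window)
            comp = feature_maps.composite_map(maps["BW"], maps["WB"])
            out.append(comp.grid.ravel())
        return np.array(out)
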