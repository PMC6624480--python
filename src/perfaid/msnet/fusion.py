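"""Late fusion of the two stream classifiers with a linear SVM.

Each stream emits a 2-component softmax score per patch; the fusion model
is a linear SVM on the concatenated 4-dimensional score vector, fitted on
a held-out split of the training patches so the hyperplane is not tuned on
scores the streams have already overfitted.
"""

from __future__ import annotations

import numpy as np
from sklearn.svm import LinearSVC

from ..preprocess import DegenerateInputError

__all__ = ["fuse_svm", "apply_fusion"]


def _stack_scores(spatial_scores: np.ndarray, temporal_scores: np.ndarray) -> np.ndarray:
    s = np.asarray(spatial_scores, dtype=float)
    t = np.asarray(temporal_scores, dtype=float)
    if s.shape != t.shape or s.ndim != 2 or s.shape[1] != 2:
        raise ValueError("stream scores must both be (N, 2)")
    for name, arr in (("spatial", s), ("temporal", t)):
        if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-4):
            raise ValueError(f"{name} scores are not softmax-normalized")
    return np.hstack([s, t])


def fuse_svm(
    spatial_scores: np.ndarray,
    temporal_scores: np.ndarray,
    labels: np.ndarray,
    c: float = 1.0,
) -> LinearSVC:
    """Fit the linear-SVM fusion layer on paired stream softmax scores."""
    x = _stack_scores(spatial_scores, temporal_scores)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise DegenerateInputError("fusion fit requires both classes")
    svm = LinearSVC(C=c, random_state=0)
    svm.fit(x, y)
    return svm


def apply_fusion(
    model: LinearSVC, spatial_scores: np.ndarray, temporal_scores: np.ndarray
) -> np.ndarray:
    """Fused binary decision per sample (sign of the learned hyperplane)."""
    return model.predict(_stack_scores(spatial_scores, temporal_scores)).astype(np.int64)
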