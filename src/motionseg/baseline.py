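"""Probabilistic-atlas baseline segmenter.

A deliberately simple comparison method in the spirit of classical
atlas-driven pipelines: a per-voxel label-frequency atlas built from training
masks, combined with a per-class Gaussian intensity model, segmented by
maximum posterior.  It serves as the second "method" in the reliability
comparisons; it is a synthetic stand-in authored by this package, not a
re-implementation of any external tool.
"""

from __future__ import annotations

import numpy as np

from .core_io import LabelMask, LabelScheme, Volume


class AtlasSegmenter:
    """Voxelwise argmax of log prior(label | position) + log N(intensity)."""

    def __init__(self, prior_smoothing: float = 0.5, min_sd: float = 1e-3) -> None:
        self.prior_smoothing = prior_smoothing
        self.min_sd = min_sd
        self.classes_: np.ndarray | None = None

    def fit(self, pairs: list[tuple[Volume, LabelMask]]) -> "AtlasSegmenter":
        if not pairs:
            raise ValueError("need at least one training pair")
        shape = pairs[0][0].shape
        labels_all = np.stack([m.labels for _, m in pairs])
        self.classes_ = np.unique(labels_all)
        self.scheme_: LabelScheme = pairs[0][1].scheme
        counts = np.zeros((len(self.classes_),) + shape, dtype=np.float32)
        mu = np.zeros(len(self.classes_))
        var = np.zeros(len(self.classes_))
        for ci, c in enumerate(self.classes_):
            sel = labels_all == c
            counts[ci] = sel.sum(axis=0)
            vals = np.concatenate(
                [np.asarray(v.data)[m.labels == c] for v, m in pairs]
            )
            mu[ci] = vals.mean()
            var[ci] = max(vals.var(), self.min_sd**2)
        prior = counts + self.prior_smoothing
        self.log_prior_ = np.log(prior / prior.sum(axis=0, keepdims=True))
        self.mu_, self.var_ = mu, var
        return self

    def predict(self, v: Volume) -> LabelMask:
        if self.classes_ is None:
            raise RuntimeError("fit the segmenter first")
        x = np.asarray(v.data, dtype=np.float64)
        if x.shape != self.log_prior_.shape[1:]:
            raise ValueError("volume shape differs from the atlas shape")
        best_score = np.full(x.shape, -np.inf)
        best_label = np.zeros(x.shape, dtype=np.int32)
        for ci, c in enumerate(self.classes_):
            ll = (
                self.log_prior_[ci]
                - 0.5 * (x - self.mu_[ci]) ** 2 / self.var_[ci]
                - 0.5 * np.log(self.var_[ci])
            )
            better = ll > best_score
            best_score[better] = ll[better]
            best_label[better] = c
        return LabelMask(labels=best_label, scheme=self.scheme_)
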