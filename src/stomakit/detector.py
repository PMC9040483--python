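"""High-level stomata counter with a scikit-learn estimator interface.

``StomataCounter.fit`` takes annotated images, builds the disk training
set, fits the PCA basis and all nine learners, and tunes the fusion
stage by Nelder–Mead on held-in probability maps.  ``predict`` returns a
:class:`~stomakit.fusion.DetectionSet` per image; ``score`` is the
detection F1 against provided annotations.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import ensemble, fusion
from .features import DiskSpec, features_at_points, fit_pca
from .synthetic import AnnotationSet

logger = logging.getLogger(__name__)

__all__ = ["RadialFFTTransformer", "StomataCounter"]


class RadialFFTTransformer(BaseEstimator, TransformerMixin):
    """Stateless transformer: disk patches → flattened circular-FFT features.

    ``X`` is an (n, side, side) stack of square disk patches.
    """

    def __init__(self, diameter_px: int = 80, n_rings: int = 40,
                 angles_per_ring: int = 64, harmonics_kept: int = 8):
        self.diameter_px = diameter_px
        self.n_rings = n_rings
        self.angles_per_ring = angles_per_ring
        self.harmonics_kept = harmonics_kept

    def _spec(self) -> DiskSpec:
        return DiskSpec(
            diameter_px=self.diameter_px,
            n_rings=self.n_rings,
            angles_per_ring=self.angles_per_ring,
            harmonics_kept=self.harmonics_kept,
        )

    def fit(self, X=None, y=None):
        self.n_features_out_ = self._spec().n_features
        return self

    def transform(self, X) -> np.ndarray:
        from .features import circular_fft

        spec = self._spec()
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        return np.stack([circular_fft(patch, spec).flatten() for patch in X])


class StomataCounter(BaseEstimator):
    """End-to-end detector: circular-FFT/PCA features, nine-learner
    probability-map ensemble, MCC-tuned fusion, peak detection.

    Parameters mirror the pipeline stages; fitted state carries a
    trailing underscore (``basis_``, ``learners_``, ``fusion_params_``).
    """

    def __init__(
        self,
        diameter_px: int = 80,
        n_rings: int = 40,
        angles_per_ring: int = 64,
        harmonics_kept: int = 8,
        variance_target: float = 0.95,
        learner_kinds: tuple[str, ...] = ensemble.LEARNER_KINDS,
        negatives_per_positive: int = 3,
        stride_px: int = 2,
        match_radius_px: float = 20.0,
        min_separation_px: float = 12.0,
        tune_images: int = 6,
        tune_max_iter: int = 120,
        encoding: str = "weighted",
        seed: int = 0,
    ):
        self.diameter_px = diameter_px
        self.n_rings = n_rings
        self.angles_per_ring = angles_per_ring
        self.harmonics_kept = harmonics_kept
        self.variance_target = variance_target
        self.learner_kinds = learner_kinds
        self.negatives_per_positive = negatives_per_positive
        self.stride_px = stride_px
        self.match_radius_px = match_radius_px
        self.min_separation_px = min_separation_px
        self.tune_images = tune_images
        self.tune_max_iter = tune_max_iter
        self.encoding = encoding
        self.seed = seed

    def _disk_spec(self) -> DiskSpec:
        return DiskSpec(
            diameter_px=self.diameter_px,
            n_rings=self.n_rings,
            angles_per_ring=self.angles_per_ring,
            harmonics_kept=self.harmonics_kept,
        )

    # ------------------------------------------------------------------
    def fit(self, images: dict[str, np.ndarray], annotations: dict[str, AnnotationSet]):
        spec = self._disk_spec()
        raw = ensemble.build_training_set(
            images,
            annotations,
            negatives_per_positive=self.negatives_per_positive,
            spec=spec,
            basis=None,
            seed=self.seed,
            encoding=self.encoding,
        )
        self.basis_ = fit_pca(raw.X, variance_target=self.variance_target)
        from .features import project

        training = ensemble.TrainingSet(
            X=project(raw.X, self.basis_), y=raw.y, provenance=raw.provenance, seed=raw.seed
        )
        self.learners_ = {}
        for kind in self.learner_kinds:
            logger.info("training learner %s", kind)
            self.learners_[kind] = ensemble.train_learner(kind, training)

        tune_ids = sorted(images)[: self.tune_images]
        maps_per_image, truths = [], []
        for image_id in tune_ids:
            if image_id not in annotations or len(annotations[image_id]) == 0:
                continue
            logger.info("probability maps for tuning image %s", image_id)
            maps_per_image.append(self._maps(images[image_id]))
            truths.append(annotations[image_id])
        init = fusion.FusionParams(
            weights=np.full(len(self.learner_kinds), 1.0 / len(self.learner_kinds)),
            min_separation_px=self.min_separation_px,
        )
        self.fusion_params_, self.tuned_mcc_ = fusion.tune_fusion(
            maps_per_image,
            truths,
            init=init,
            max_iter=self.tune_max_iter,
            match_radius_px=self.match_radius_px,
        )
        logger.info(
            "tuned fusion: sigma=%.2f threshold=%.3f mean MCC=%.3f",
            self.fusion_params_.smooth_sigma_px,
            self.fusion_params_.height_threshold,
            self.tuned_mcc_,
        )
        return self

    def _maps(self, image: np.ndarray) -> list[np.ndarray]:
        # one shared feature pass for all nine learners
        maps = ensemble.predict_maps(
            self.learners_, image, spec=self._disk_spec(), basis=self.basis_,
            stride_px=self.stride_px, encoding=self.encoding,
        )
        return [maps[kind] for kind in self.learner_kinds]

    def predict_map(self, image: np.ndarray) -> np.ndarray:
        """Fused, smoothed probability map for one image."""
        fused = fusion.combine_maps(self._maps(image), self.fusion_params_.weights)
        return fusion.smooth_map(fused, self.fusion_params_.smooth_sigma_px)

    def predict_one(self, image: np.ndarray) -> fusion.DetectionSet:
        fused = fusion.combine_maps(self._maps(image), self.fusion_params_.weights)
        det = fusion.detect_stomata(fused, self.fusion_params_)
        return fusion.flag_close_pairs(det, self.fusion_params_.min_separation_px * 2)

    def predict(self, images: dict[str, np.ndarray]) -> dict[str, fusion.DetectionSet]:
        return {image_id: self.predict_one(images[image_id]) for image_id in sorted(images)}

    def score(
        self, images: dict[str, np.ndarray], annotations: dict[str, AnnotationSet]
    ) -> float:
        """Pooled detection F1 over the given images."""
        tp = fp = fn = 0
        for image_id, det in self.predict(images).items():
            counts = fusion.match_points(det, annotations[image_id], self.match_radius_px)
            tp += counts.TP
            fp += counts.FP
            fn += counts.FN
        if tp == 0:
            return 0.0
        return 2 * tp / (2 * tp + fp + fn)
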