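"""Scikit-learn style estimators wrapping the segmentation pipeline.

``VesselSegmenter`` is the end-to-end per-pixel classifier: ``fit``
configures the symmetric (bar) and asymmetric (half-bar) B-COSFIRE filters
from drawn prototypes, ``transform`` returns continuous vessel-likelihood
maps, and ``predict`` returns binary vessel masks after thresholding and
artifact removal.  ``GridSearchOptimizer`` searches the three thresholding
parameters over labelled images and exposes the winning combination.

Both follow the sklearn contract (``get_params``/``set_params``, fitted
attributes with a trailing underscore) and therefore compose with
``sklearn.base.clone`` and pipeline utilities.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from . import core, metrics, optimizer, postprocess, preprocess
from .dog_bank import DoGSpec
from .raster_io import DatasetItem


def _as_item(x) -> DatasetItem:
    if isinstance(x, DatasetItem):
        return x
    return DatasetItem(image=np.asarray(x, dtype=np.float64), identifier="array")


class VesselSegmenter(BaseEstimator):
    """Trainable B-COSFIRE vessel segmenter.

    Parameters
    ----------
    preprocessing_threshold : fraction of each DoG map's maximum below which
        responses are suppressed before combination (searched over 0.1-0.6).
    filter_threshold : binarization level as an integer percent of the
        response maximum (searched over 25-50).
    artifact_size : minimum component area (px) surviving postprocessing.
    removal_algorithm : one of ``component_filter``, ``kmedian``,
        ``bw_clearance``.
    sigma, rho_max : DoG scale and outermost tuple radius of the symmetric
        (vessel-interior) filter.
    sigma_asym, rho_max_asym : same for the asymmetric (vessel-ending) filter.
    rho_step : radial spacing of the configured tuples.
    sigma0, alpha : blur growth law sigma' = sigma0 + alpha * rho.
    n_orientations : rotation-bank size (12 = 15 degree steps for the bar).
    asym_weight : weight of the asymmetric response in the combined map.
    invert : invert intensities first (for bright-vessel inputs).
    """

    def __init__(
        self,
        preprocessing_threshold: float = 0.3,
        filter_threshold: int = 30,
        artifact_size: int = 0,
        removal_algorithm: str = "component_filter",
        hole_size: int | None = None,
        sigma: float = 2.4,
        rho_max: float = 8.0,
        sigma_asym: float = 1.8,
        rho_max_asym: float = 12.0,
        rho_step: float = 2.0,
        sigma0: float = 0.5,
        alpha: float = 0.1,
        n_orientations: int = 12,
        asym_weight: float = 0.5,
        invert: bool = False,
        prototype_width: float | None = None,
    ) -> None:
        self.preprocessing_threshold = preprocessing_threshold
        self.filter_threshold = filter_threshold
        self.artifact_size = artifact_size
        self.removal_algorithm = removal_algorithm
        self.hole_size = hole_size
        self.sigma = sigma
        self.rho_max = rho_max
        self.sigma_asym = sigma_asym
        self.rho_max_asym = rho_max_asym
        self.rho_step = rho_step
        self.sigma0 = sigma0
        self.alpha = alpha
        self.n_orientations = n_orientations
        self.asym_weight = asym_weight
        self.invert = invert
        self.prototype_width = prototype_width

    # -- configuration -------------------------------------------------------

    def _rho_list(self, rho_max: float) -> list[float]:
        n = int(math.floor(rho_max / self.rho_step + 1e-9))
        return [self.rho_step * i for i in range(n + 1)]

    def fit(self, X=None, y=None) -> "VesselSegmenter":
        """Configure the bar and half-bar filters from drawn prototypes.

        The prototypes are synthetic (a vertical bar and half bar of width
        ~2 sigma); no training data is consumed, which is why ``X`` and ``y``
        are optional and ignored.
        """
        blur = core.BlurParams(sigma0=self.sigma0, alpha=self.alpha)
        # each filter sees a prototype matched to its own DoG scale (a bar of
        # width ~2 sigma); a mismatched width splits the circle maxima into
        # the two edge ridges of the bar
        width_sym = (
            self.prototype_width
            if self.prototype_width is not None
            else 2.0 * self.sigma
        )
        width_asym = (
            self.prototype_width
            if self.prototype_width is not None
            else 2.0 * self.sigma_asym
        )
        size = 2 * int(math.ceil(self.rho_max_asym + 6 * self.sigma)) + 21

        bar = core.bar_prototype(size=size, width=width_sym, half=False)
        self.symmetric_filter_ = core.configure_filter(
            bar, self._rho_list(self.rho_max), DoGSpec(self.sigma), symmetric=True, blur=blur
        )
        half = core.bar_prototype(size=size, width=width_asym, half=True)
        self.asymmetric_filter_ = core.configure_filter(
            half,
            self._rho_list(self.rho_max_asym),
            DoGSpec(self.sigma_asym),
            symmetric=False,
            blur=blur,
        )
        self.symmetric_bank_ = core.RotationBank(
            self.symmetric_filter_, n_orientations=self.n_orientations
        )
        self.asymmetric_bank_ = core.RotationBank(
            self.asymmetric_filter_, n_orientations=self.n_orientations
        )
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "symmetric_bank_"):
            raise RuntimeError("this VesselSegmenter instance is not fitted yet")

    # -- inference -----------------------------------------------------------

    def response(
        self,
        image: np.ndarray,
        fov: np.ndarray | None = None,
        preprocessing_threshold: float | None = None,
    ) -> np.ndarray:
        """Continuous vessel-likelihood map of one image.

        The green channel is extracted from color input, intensities outside
        the FOV are replaced by the nearest inside value before filtering,
        and the response is zeroed outside the FOV afterwards.
        """
        self._check_fitted()
        p = (
            self.preprocessing_threshold
            if preprocessing_threshold is None
            else preprocessing_threshold
        )
        gray = preprocess.extract_green(np.asarray(image, dtype=np.float64))
        if self.invert:
            gray = 1.0 - gray
        gray = preprocess.fill_outside_fov(gray, fov)
        resp = core.segment_response(
            gray,
            self.symmetric_bank_,
            self.asymmetric_bank_,
            prep=p,
            asym_weight=self.asym_weight,
        )
        if fov is not None:
            resp = np.where(np.asarray(fov) > 0, resp, 0.0)
        return resp

    def _params(self) -> postprocess.SegmentationParams:
        return postprocess.SegmentationParams(
            preprocessing_threshold=self.preprocessing_threshold,
            filter_threshold=self.filter_threshold,
            artifact_size=self.artifact_size,
            removal_algorithm=self.removal_algorithm,
            hole_size=self.hole_size,
        )

    def transform(self, X: Sequence) -> list[np.ndarray]:
        """Vessel-likelihood maps for a sequence of images or dataset items."""
        items = [_as_item(x) for x in X]
        return [self.response(it.image, it.fov_mask) for it in items]

    def predict_mask(self, response: np.ndarray) -> np.ndarray:
        """Binarize a response map and remove background artifacts."""
        params = self._params()
        return postprocess.remove_artifacts(
            postprocess.binarize(response, params.filter_threshold), params
        )

    def predict(self, X: Sequence) -> list[np.ndarray]:
        """Binary vessel masks for a sequence of images or dataset items."""
        return [self.predict_mask(r) for r in self.transform(X)]

    def score(self, X: Sequence, y: Sequence[np.ndarray] | None = None) -> float:
        """Aggregate pixel accuracy over items (counts summed, then derived)."""
        items = [_as_item(x) for x in X]
        gts = y if y is not None else [it.gt_mask for it in items]
        total = metrics.ConfusionCounts(0, 0, 0, 0)
        for item, gt in zip(items, gts):
            if gt is None:
                raise ValueError(f"item '{item.identifier}' has no ground truth")
            mask = self.predict_mask(self.response(item.image, item.fov_mask))
            total = total + metrics.confusion(mask, gt, item.fov_mask)
        return metrics.derive_metrics(total).accuracy

    def evaluate(self, items: Sequence[DatasetItem]) -> metrics.EvaluationResult:
        """Aggregate evaluation (Se/Sp/Acc and AUC) over dataset items."""
        total = metrics.ConfusionCounts(0, 0, 0, 0)
        responses, gts, fovs = [], [], []
        for item in items:
            if item.gt_mask is None:
                raise ValueError(f"item '{item.identifier}' has no ground truth")
            resp = self.response(item.image, item.fov_mask)
            mask = self.predict_mask(resp)
            total = total + metrics.confusion(mask, item.gt_mask, item.fov_mask)
            responses.append(resp)
            gts.append(item.gt_mask)
            fovs.append(
                item.fov_mask
                if item.fov_mask is not None
                else np.ones_like(item.gt_mask)
            )
        pooled_resp = np.concatenate([r[f > 0] for r, f in zip(responses, fovs)])
        pooled_gt = np.concatenate([g[f > 0] for g, f in zip(gts, fovs)])
        auc_value = metrics.auc(pooled_resp[None, :], pooled_gt[None, :])
        return metrics.derive_metrics(total, auc=auc_value)


class GridSearchOptimizer(BaseEstimator):
    """Exhaustive search of the thresholding parameters on labelled images.

    ``fit`` evaluates every grid combination on the supplied items (vessel
    responses cached per preprocessing threshold) and selects the best record
    by accuracy, with sensitivity / specificity / smallest-parameter
    tie-breaks.  Fitted attributes: ``records_``, ``best_record_``,
    ``best_params_``, ``best_estimator_``.
    """

    def __init__(
        self,
        grid: optimizer.ParameterGrid | None = None,
        segmenter: VesselSegmenter | None = None,
    ) -> None:
        self.grid = grid
        self.segmenter = segmenter

    def fit(self, X: Sequence[DatasetItem], y=None) -> "GridSearchOptimizer":
        grid = self.grid if self.grid is not None else optimizer.ParameterGrid()
        base = self.segmenter if self.segmenter is not None else VesselSegmenter()
        worker = VesselSegmenter(**base.get_params()).fit()

        def response_fn(item: DatasetItem, prep: float) -> np.ndarray:
            return worker.response(item.image, item.fov_mask, preprocessing_threshold=prep)

        self.records_ = optimizer.run_grid(list(X), grid, response_fn)
        self.best_record_ = optimizer.select_best(self.records_)
        p = self.best_record_.params
        self.best_params_ = {
            "preprocessing_threshold": p.preprocessing_threshold,
            "filter_threshold": p.filter_threshold,
            "artifact_size": p.artifact_size,
            "removal_algorithm": p.removal_algorithm,
        }
        self.best_estimator_ = VesselSegmenter(
            **{**worker.get_params(), **self.best_params_}
        ).fit()
        return self

    def predict(self, X: Sequence) -> list[np.ndarray]:
        if not hasattr(self, "best_estimator_"):
            raise RuntimeError("this GridSearchOptimizer instance is not fitted yet")
        return self.best_estimator_.predict(X)
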