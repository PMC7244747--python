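"""Scikit-learn-style estimators for the reconstruction methods.

The classical reconstructors are transform-shaped (sinogram in, image out;
``fit`` is a no-op kept for pipeline compatibility), while the learned
reconstructor is fit/predict-shaped.  All follow the scikit-learn estimator
protocol: constructor arguments are hyperparameters stored verbatim,
``get_params``/``set_params`` work through :class:`sklearn.base.BaseEstimator`,
and fitted state lives in trailing-underscore attributes.

Input convention: X is a list (or array) of sinograms as
:class:`~paxel.simulate.SensorTimeSeries`, or for the learned estimator the
approach-specific prepared inputs; outputs are stacked (n, H, W) images.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from paxel import interp as _interp
from paxel import tv as _tv
from paxel.nn import fdunet as _fd
from paxel.simulate import SensorTimeSeries, time_reversal

__all__ = ["TimeReversalReconstructor", "TVReconstructor", "FDUNetReconstructor"]


def _as_series_list(X) -> list[SensorTimeSeries]:
    if isinstance(X, SensorTimeSeries):
        return [X]
    out = list(X)
    if not out or not all(isinstance(s, SensorTimeSeries) for s in out):
        raise ValueError("X must be a SensorTimeSeries or a sequence of them")
    return out


class TimeReversalReconstructor(TransformerMixin, BaseEstimator):
    """Time-reversal reconstruction of each sinogram."""

    def __init__(self, normalize_output: bool = True):
        self.normalize_output = normalize_output

    def fit(self, X=None, y=None):
        self.n_features_in_ = 0
        return self

    def transform(self, X) -> np.ndarray:
        series = _as_series_list(X)
        return np.stack([
            time_reversal(s, normalize_output=self.normalize_output) for s in series])


class TVReconstructor(TransformerMixin, BaseEstimator):
    """TV-regularized iterative (FISTA) reconstruction of each sinogram.

    ``lambda_reg`` may be absolute or, when ``lambda_relative`` is true,
    a fraction of ||A'y||_inf per sinogram (a scale-free parameterization).
    """

    def __init__(self, lambda_reg: float = 1e-2, lambda_relative: bool = True,
                 max_iters: int = 50, tol: float = 1e-5, nonneg: bool = True,
                 prox_iters: int = 20, normalize_output: bool = True):
        self.lambda_reg = lambda_reg
        self.lambda_relative = lambda_relative
        self.max_iters = max_iters
        self.tol = tol
        self.nonneg = nonneg
        self.prox_iters = prox_iters
        self.normalize_output = normalize_output

    def fit(self, X=None, y=None):
        self.n_features_in_ = 0
        return self

    def transform(self, X) -> np.ndarray:
        series = _as_series_list(X)
        out = []
        self.traces_ = []
        for s in series:
            lam = self.lambda_reg
            if self.lambda_relative:
                from paxel.simulate import TimeConfig, apply_adjoint
                tcfg = TimeConfig(dt=s.dt, n_steps=s.n_steps)
                lam = lam * float(np.abs(apply_adjoint(s, tcfg=tcfg)).max())
            cfg = _tv.IterativeConfig(lambda_reg=lam, max_iters=self.max_iters,
                                      tol=self.tol, nonneg=self.nonneg,
                                      prox_iters=self.prox_iters)
            img, trace = _tv.reconstruct_tv(s, cfg)
            if self.normalize_output and img.max() > 0:
                img = img / img.max()
            out.append(img)
            self.traces_.append(trace)
        return np.stack(out)


class FDUNetReconstructor(BaseEstimator):
    """FD-UNet learned reconstruction (Post-DL, Pixel-DL or mDirect-DL).

    ``fit(X, y)`` takes approach-specific inputs X -- (n, H, W) time-reversal
    images for ``postdl``, (n, N, H, W) pixel volumes for ``pixeldl``,
    (n, H, W) resampled sinograms for ``mdirectdl`` -- and (n, H, W) ground
    truths in [0, 1].  ``predict(X)`` returns (n, H, W) reconstructions.
    """

    def __init__(self, approach: str = "pixeldl", growth_rate_init: int = 4,
                 features_init: int = 16, levels: int = 2,
                 dense_layers_per_block: int = 2, learning_rate: float = 1e-3,
                 batch_size: int = 3, epochs: int = 10, seed: int = 0):
        self.approach = approach
        self.growth_rate_init = growth_rate_init
        self.features_init = features_init
        self.levels = levels
        self.dense_layers_per_block = dense_layers_per_block
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.seed = seed

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if self.approach == "pixeldl":
            if X.ndim != 4:
                raise ValueError("pixeldl expects (n, N, H, W) pixel volumes")
            return X
        if X.ndim != 3:
            raise ValueError(f"{self.approach} expects (n, H, W) inputs")
        return X[:, None]

    def fit(self, X, y):
        Xp = self._prepare(X)
        y = np.asarray(y, dtype=np.float32)
        in_ch = Xp.shape[1]
        spec = _fd.FDUNetSpec(
            in_channels=in_ch, growth_rate_init=self.growth_rate_init,
            features_init=self.features_init, levels=self.levels,
            dense_layers_per_block=self.dense_layers_per_block,
            residual=(self.approach == "postdl"))
        self.model_ = _fd.build_fdunet(spec, seed=self.seed, approach=self.approach)
        cfg = _fd.TrainConfig(learning_rate=self.learning_rate,
                              batch_size=self.batch_size, epochs=self.epochs,
                              seed=self.seed, scale_preset="desk")
        _fd.train(self.model_, Xp, y, cfg)
        self.loss_history_ = list(self.model_.loss_history)
        self.n_features_in_ = in_ch
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("FDUNetReconstructor is not fitted")
        Xp = self._prepare(X)
        if self.approach == "postdl":
            return np.stack([_fd.predict_postdl(self.model_, im[0]) for im in Xp])
        if self.approach == "pixeldl":
            return np.stack([
                _fd.predict_pixeldl(self.model_, v.transpose(1, 2, 0)) for v in Xp])
        return np.stack([_fd.predict_mdirect(self.model_, im[0]) for im in Xp])

    def score(self, X, y) -> float:
        """Mean PSNR (dB) of predictions against ground truths."""
        from paxel.metrics import psnr
        preds = self.predict(X)
        vals = [psnr(p, t) for p, t in zip(preds, np.asarray(y, dtype=np.float64))]
        finite = [v for v in vals if np.isfinite(v)]
        return float(np.mean(finite)) if finite else float("inf")
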