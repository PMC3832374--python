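"""Inverse problems: baseline normalisation, AIF extraction, voxel-wise 2CFM
fitting and monoexponential clearance fitting.

The two nonlinear fits are exposed as scikit-learn style estimators:

* :class:`TwoCompartmentFiltrationModel` — fits the two-compartment
  filtration model independently to each row of a curve matrix
  ``X (n_curves, n_times)`` and exposes the fitted parameter table,
  per-curve residual sums of squares and convergence flags as trailing
  underscore attributes;
* :class:`MonoexponentialClearanceModel` — a regressor over time that
  estimates skin background, amplitude and elimination half-life from a
  transcutaneous fluorescence trace.

The spec-level operations (:func:`fit_voxel`, :func:`fit_map`,
:func:`fit_clearance`) are thin wrappers over these estimators, so the
same code path serves both the pipeline and sklearn composition
(``get_params``/``set_params``, cloning, grid search).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .io_types import (
    Aif,
    ClearanceFit,
    DegenerateFitError,
    DynamicSeries,
    NOT_FITTED,
    PARAM_NAMES,
    ParamMaps,
    RoiMask,
    TwoCfmParams,
    ValidationError,
)
from .pk_models import monoexp_signal, twocfm_concentration

__all__ = [
    "baseline_normalize",
    "extract_aif",
    "TwoCompartmentFiltrationModel",
    "MonoexponentialClearanceModel",
    "fit_voxel",
    "fit_map",
    "fit_clearance",
]


# --------------------------------------------------------------------------
# signal preprocessing
# --------------------------------------------------------------------------

def baseline_normalize(series: DynamicSeries) -> DynamicSeries:
    """Subtract each voxel's mean pre-contrast signal from its time course.

    Under the linear signal-concentration assumption the result is the
    concentration proxy used by all kinetic fitting.  The mean of the
    output over the baseline window is zero per voxel by construction.
    """
    if series.n_baseline >= series.n_volumes:
        raise ValidationError("n_baseline must be smaller than the series")
    base = series.data[..., : series.n_baseline].mean(axis=-1, keepdims=True)
    return DynamicSeries(series.data - base, series.times, series.voxel_dims,
                         series.n_baseline)


def extract_aif(series: DynamicSeries, mask: RoiMask) -> Aif:
    """Spatial mean of the (baseline-normalised) series over the aorta ROI."""
    mask.check_grid(series)
    sel = mask.require_nonempty("aorta")
    return Aif(series.times, series.data[sel, :].mean(axis=0))


# --------------------------------------------------------------------------
# voxel-wise 2CFM fitting
# --------------------------------------------------------------------------

#: deterministic multi-start initialisations (F_P, V_P, F_T, T_T) spanning
#: low, medium and high flow regimes; voxel curves are noisy and a single
#: start is routinely caught by local minima in T_T
_STARTS = (
    (20.0, 5.0, 5.0, 60.0),
    (150.0, 20.0, 50.0, 120.0),
    (350.0, 50.0, 150.0, 300.0),
)


class TwoCompartmentFiltrationModel(BaseEstimator):
    """Voxel-wise bounded least-squares fit of the 2CFM.

    Parameters
    ----------
    aif
        Baseline-normalised arterial input function.
    times
        Acquisition times in seconds (uniform grid).
    bounds_F_P, bounds_F_T
        Physiologic flow envelopes, ml/100 ml/min.
    bounds_V_P
        Plasma volume envelope, ml/100 ml.
    bounds_T_T
        Tubular transit-time envelope, seconds.
    delay_grid
        Candidate bolus-arrival delays in seconds; the delay is selected by
        grid search (best residual), the four continuous parameters by
        bounded trust-region least squares from ``n_starts`` deterministic
        initial points.
    variant
        ``"4param"`` fits (F_P, V_P, F_T, T_T); ``"3param"`` freezes
        ``T_T = inf`` (no tubular outflow over the acquisition window).
    n_starts
        How many of the deterministic starts to use (1-3).
    early_stop_rtol
        If a start reaches ``RSS < early_stop_rtol * ||curve||^2`` the
        remaining starts and delays are skipped (exact-interpolation
        shortcut for noise-free data).

    Attributes
    ----------
    params_ : ndarray, shape (n_curves, 5)
        Fitted (F_P, V_P, F_T, T_T, delay) per curve.
    chi2_ : ndarray, shape (n_curves,)
        Residual sum of squares (signal units squared).
    converged_ : ndarray of bool, shape (n_curves,)
        False where the optimiser failed; such curves carry NaN parameters.
    """

    def __init__(self, aif=None, times=None,
                 bounds_F_P=(0.0, 500.0), bounds_V_P=(0.1, 100.0),
                 bounds_F_T=(0.0, 300.0), bounds_T_T=(1.0, 600.0),
                 delay_grid=(0.0, 2.5, 5.0, 7.5, 10.0),
                 variant="4param", n_starts=3, early_stop_rtol=1e-12):
        self.aif = aif
        self.times = times
        self.bounds_F_P = bounds_F_P
        self.bounds_V_P = bounds_V_P
        self.bounds_F_T = bounds_F_T
        self.bounds_T_T = bounds_T_T
        self.delay_grid = delay_grid
        self.variant = variant
        self.n_starts = n_starts
        self.early_stop_rtol = early_stop_rtol

    # -- internals ---------------------------------------------------------

    def _model(self, theta: np.ndarray, delay: float,
               times: np.ndarray) -> np.ndarray:
        if self.variant == "3param":
            F_P, V_P, F_T = theta
            T_T = np.inf
        else:
            F_P, V_P, F_T, T_T = theta
        p = TwoCfmParams(F_P=F_P, V_P=V_P, F_T=F_T, T_T=T_T, delay=delay)
        return twocfm_concentration(p, self.aif, times)

    def _fit_single(self, curve: np.ndarray, times: np.ndarray):
        lo = [self.bounds_F_P[0], self.bounds_V_P[0], self.bounds_F_T[0]]
        hi = [self.bounds_F_P[1], self.bounds_V_P[1], self.bounds_F_T[1]]
        scale = [100.0, 10.0, 50.0]
        if self.variant != "3param":
            lo.append(self.bounds_T_T[0])
            hi.append(self.bounds_T_T[1])
            scale.append(100.0)
        lo, hi = np.array(lo), np.array(hi)
        norm2 = float(np.dot(curve, curve))
        stop_cost = 0.5 * self.early_stop_rtol * norm2

        best = None
        for delay in self.delay_grid:
            for start in _STARTS[: self.n_starts]:
                x0 = np.clip(np.array(start[: len(lo)]), lo, hi)

                def resid(theta, _delay=delay):
                    return self._model(theta, _delay, times) - curve

                try:
                    res = least_squares(resid, x0, bounds=(lo, hi),
                                        x_scale=scale, method="trf")
                except Exception:
                    continue
                if best is None or res.cost < best[0].cost:
                    best = (res, delay)
                if best[0].cost <= stop_cost:
                    break
            if best is not None and best[0].cost <= stop_cost:
                break

        if best is None or not np.all(np.isfinite(best[0].x)):
            return np.full(5, np.nan), np.nan, False
        res, delay = best
        theta = res.x
        if self.variant == "3param":
            out = np.array([theta[0], theta[1], theta[2], np.inf, delay])
        else:
            out = np.array([theta[0], theta[1], theta[2], theta[3], delay])
        return out, 2.0 * res.cost, True   # res.cost = RSS / 2

    # -- sklearn surface ---------------------------------------------------

    def fit(self, X, y=None):
        """Fit every row of ``X (n_curves, n_times)`` independently."""
        if self.aif is None or self.times is None:
            raise ValidationError("aif and times must be set before fitting")
        times = np.asarray(self.times, dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(times):
            raise ValidationError(
                f"curves have {X.shape[1]} samples but times has {len(times)}")
        n = X.shape[0]
        self.params_ = np.empty((n, 5))
        self.chi2_ = np.empty(n)
        self.converged_ = np.empty(n, dtype=bool)
        for i in range(n):
            p, c, ok = self._fit_single(X[i], times)
            self.params_[i], self.chi2_[i], self.converged_[i] = p, c, ok
        return self

    def predict(self, X=None):
        """Model curves at the fitted optima (``X`` is ignored; rows match fit)."""
        times = np.asarray(self.times, dtype=float)
        out = np.full((len(self.params_), len(times)), np.nan)
        for i, (row, ok) in enumerate(zip(self.params_, self.converged_)):
            if ok:
                p = TwoCfmParams(F_P=row[0], V_P=row[1], F_T=row[2],
                                 T_T=row[3], delay=row[4])
                out[i] = twocfm_concentration(p, self.aif, times)
        return out


def fit_voxel(curve, aif: Aif, times, config=None) -> tuple[TwoCfmParams, float]:
    """Fit one tissue curve; returns the parameters and the chi2 (RSS).

    ``config`` is a dict of :class:`TwoCompartmentFiltrationModel` keyword
    arguments (bounds, ``delay_grid``, ``variant``, ``n_starts``).
    Non-convergence raises nothing here; it surfaces as NaN parameters —
    map-level fitting downgrades such voxels to the not-fitted sentinel.
    """
    est = TwoCompartmentFiltrationModel(aif=aif, times=times, **(config or {}))
    est.fit(np.atleast_2d(curve))
    row = est.params_[0]
    if not est.converged_[0]:
        return None, np.nan
    return (TwoCfmParams(F_P=row[0], V_P=row[1], F_T=row[2], T_T=row[3],
                         delay=row[4]),
            float(est.chi2_[0]))


def fit_map(series: DynamicSeries, mask: RoiMask, aif: Aif,
            config=None, roles=None) -> ParamMaps:
    """Voxel-wise 2CFM fit over the kidney labels of ``mask``.

    ``series`` must already be baseline-normalised.  ``roles`` defaults to
    every declared kidney role (``cortex_*`` and ``medulla``).  Voxels
    where the optimiser fails carry the not-fitted sentinel and are
    excluded from ``fitted_mask``.
    """
    mask.check_grid(series)
    if roles is None:
        roles = [r for r in mask.label_map
                 if r.startswith("cortex") or r == "medulla"]
    sel = np.zeros(series.spatial_shape, dtype=bool)
    for role in roles:
        sel |= mask.voxels(role)
    if not sel.any():
        raise ValidationError("no kidney voxels to fit")

    est = TwoCompartmentFiltrationModel(aif=aif, times=series.times,
                                        **(config or {}))
    est.fit(series.data[sel, :])

    maps = {name: np.full(series.spatial_shape, NOT_FITTED)
            for name in PARAM_NAMES}
    chi2 = np.full(series.spatial_shape, NOT_FITTED)
    fitted = np.zeros(series.spatial_shape, dtype=bool)
    idx = np.where(sel)
    for j, name in enumerate(PARAM_NAMES):
        col = np.where(est.converged_, est.params_[:, j], NOT_FITTED)
        maps[name][idx] = col
    chi2[idx] = np.where(est.converged_, est.chi2_, NOT_FITTED)
    fitted[idx] = est.converged_
    return ParamMaps(maps, chi2=chi2, fitted_mask=fitted)


# --------------------------------------------------------------------------
# fluorescence clearance fitting
# --------------------------------------------------------------------------

class MonoexponentialClearanceModel(BaseEstimator, RegressorMixin):
    """One-compartment fit of a transcutaneous fluorescence trace.

    The skin background is the mean signal over the pre-injection window;
    the elimination phase ``A * 2^(-t/(60 t_half))`` is fitted by bounded
    least squares to the background-subtracted signal over a window
    starting ``fit_lag_s`` seconds after the (smoothed) peak — late enough
    to exclude the distribution phase, whose kinetics the one-compartment
    model does not describe.

    Parameters
    ----------
    background_window
        ``(t0, t1)`` seconds; ``None`` uses the trace's own window.
    fit_lag_s
        Seconds between the signal peak and the start of the fit window.
    smooth_s
        Width (seconds) of the moving average used only to locate the peak.

    Attributes
    ----------
    background_, amplitude_, t_half_min_, fit_window_, residual_rms_
        Fitted quantities; ``clearance_fit_`` bundles them as a
        :class:`~renogfr.io_types.ClearanceFit`.
    """

    def __init__(self, background_window=None, fit_lag_s=300.0, smooth_s=30.0):
        self.background_window = background_window
        self.fit_lag_s = fit_lag_s
        self.smooth_s = smooth_s

    def fit(self, X, y):
        times = np.asarray(X, dtype=float).reshape(-1)
        signal = np.asarray(y, dtype=float).reshape(-1)
        if times.shape != signal.shape:
            raise ValidationError("times and signal must have equal length")
        window = self.background_window or (times[0], times[0] + 60.0)
        bg_sel = (times >= window[0]) & (times < window[1])
        if not bg_sel.any():
            raise ValidationError("background window contains no samples")
        background = float(signal[bg_sel].mean())
        net = signal - background

        # locate the peak on a lightly smoothed copy (robust to 1 Hz noise)
        w = max(1, int(round(self.smooth_s)))
        kernel = np.ones(w) / w
        smooth = np.convolve(net, kernel, mode="same")
        i_peak = int(np.argmax(smooth))
        t_start = times[i_peak] + self.fit_lag_s
        fit_sel = times >= t_start
        if fit_sel.sum() < 10:
            raise DegenerateFitError("fit window too short after the peak")
        t_fit, y_fit = times[fit_sel], net[fit_sel]

        # degeneracy screen: the tail must be positive and decaying
        if y_fit.max() <= 0:
            raise DegenerateFitError("background-subtracted tail is not positive")
        slope = np.polyfit(t_fit, y_fit, 1)[0]
        if slope >= 0:
            raise DegenerateFitError("background-subtracted tail does not decay")

        # log-linear initialisation on the positive part of the tail
        pos = y_fit > 0
        coef = np.polyfit(t_fit[pos], np.log(y_fit[pos]), 1)
        lam0 = max(-coef[0], 1e-7)                  # 1/s
        a0 = float(np.exp(coef[1] - coef[0] * t_fit[0]))
        t0 = float(t_fit[0])

        def resid(theta):
            a, lam = theta
            return a * np.exp(-lam * (t_fit - t0)) - y_fit

        res = least_squares(resid, [max(a0, 1e-9), lam0],
                            bounds=([0.0, 1e-9], [np.inf, np.inf]),
                            x_scale=[max(a0, 1.0), max(lam0, 1e-6)])
        a_hat, lam_hat = res.x
        t_half_min = float(np.log(2.0) / lam_hat / 60.0)
        rms = float(np.sqrt(np.mean(res.fun ** 2)))

        self.background_ = background
        self.amplitude_ = float(a_hat)
        self.t_half_min_ = t_half_min
        self.fit_window_ = (t0, float(t_fit[-1]))
        self.residual_rms_ = rms
        self.clearance_fit_ = ClearanceFit(
            background=background, amplitude=float(a_hat), t_half=t_half_min,
            fit_window=self.fit_window_, residual_rms=rms)
        return self

    def predict(self, X):
        """Evaluate the fitted model (background + elimination branch)."""
        return monoexp_signal(self.clearance_fit_,
                              np.asarray(X, dtype=float).reshape(-1))


def fit_clearance(trace, config=None) -> ClearanceFit:
    """Fit the one-compartment clearance model to a fluorescence trace.

    ``config`` is a dict of :class:`MonoexponentialClearanceModel` keyword
    arguments.  The background window defaults to the trace's own
    (protocol: first minute, pre-injection).
    """
    cfg = dict(config or {})
    cfg.setdefault("background_window", tuple(trace.background_window))
    est = MonoexponentialClearanceModel(**cfg)
    est.fit(trace.times, trace.signal)
    return est.clearance_fit_
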