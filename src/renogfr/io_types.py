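"""Domain types, unit conventions and file I/O for the dual-modality GFR pipeline.

Conventions used throughout the package:

* time is stored in **seconds**;
* flows (plasma flow ``F_P``, tubular flow ``F_T``) are stored in the renal
  reporting unit **ml/100 ml/min** and converted to fractional per-second
  rates only at model-evaluation boundaries (:func:`flow_to_per_second`);
* volume fractions (``V_P``) are in **ml/100 ml**, transit times in seconds;
* image arrays are indexed ``(x, y, z[, t])`` with 0-based voxel coordinates,
  voxel dimensions in mm; masks must share the dynamic grid exactly — no
  resampling is performed anywhere;
* CSV files are comma-separated, UTF-8, header row, ``.`` decimal separator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "DimensionalityError",
    "DegenerateFitError",
    "ConfigError",
    "DynamicSeries",
    "RoiMask",
    "Aif",
    "TwoCfmParams",
    "ParamMaps",
    "FluorescenceTrace",
    "ClearanceFit",
    "GfrResult",
    "ComparisonStats",
    "flow_to_per_second",
    "flow_to_per_minute_per100",
    "read_dynamic_series",
    "write_dynamic_series",
    "read_roi_mask",
    "write_roi_mask",
    "write_param_maps",
    "read_param_maps",
    "read_fluorescence_trace",
    "write_fluorescence_trace",
    "load_reference_gfr_table",
    "load_reference_group_means",
    "NOT_FITTED",
]

#: Sentinel stored in parameter maps for voxels where no fit was attempted or
#: where the optimiser failed; distinct from a genuine value of 0.
NOT_FITTED = np.nan

ROLES = ("background", "aorta", "cortex_left", "cortex_right", "medulla", "pelvis")


class ValidationError(ValueError):
    """Input violates a documented precondition or type invariant."""


class DimensionalityError(ValidationError):
    """An image has the wrong number of dimensions."""


class DegenerateFitError(ValidationError):
    """The data cannot support the requested fit (e.g. constant trace)."""


class ConfigError(ValueError):
    """A run configuration is missing or malformed."""


# --------------------------------------------------------------------------
# unit helpers
# --------------------------------------------------------------------------

def flow_to_per_second(flow_ml_100ml_min: float | np.ndarray) -> float | np.ndarray:
    """Convert a flow in ml/100 ml/min to a fractional rate in 1/s."""
    return flow_ml_100ml_min / 100.0 / 60.0


def flow_to_per_minute_per100(rate_per_s: float | np.ndarray) -> float | np.ndarray:
    """Inverse of :func:`flow_to_per_second` (exact round trip)."""
    return rate_per_s * 60.0 * 100.0


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class DynamicSeries:
    """A 4D dynamic contrast-enhanced acquisition.

    Parameters
    ----------
    data
        Signal intensity, arbitrary units, indexed ``(x, y, z, t)``.
    times
        Seconds from acquisition start, one entry per volume, strictly
        increasing.
    voxel_dims
        Voxel edge lengths in mm, one per spatial axis, all positive.
    n_baseline
        Number of pre-contrast volumes acquired before the bolus.
    """

    data: np.ndarray
    times: np.ndarray
    voxel_dims: tuple[float, float, float]
    n_baseline: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 4:
            raise DimensionalityError(
                f"dynamic series must be 4D, got {self.data.ndim}D"
            )
        if self.times.ndim != 1 or len(self.times) != self.data.shape[3]:
            raise ValidationError("times must be 1D and match the t axis")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("times must be strictly increasing")
        if not (1 <= self.n_baseline < len(self.times)):
            raise ValidationError(
                f"n_baseline must be in [1, {len(self.times) - 1}], "
                f"got {self.n_baseline}"
            )
        self.voxel_dims = tuple(float(v) for v in self.voxel_dims)
        if len(self.voxel_dims) != 3 or any(v <= 0 for v in self.voxel_dims):
            raise ValidationError("voxel_dims must be 3 positive lengths (mm)")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass
class RoiMask:
    """Integer label volume plus a role -> label mapping.

    ``background`` is always label 0; every other declared role maps to a
    distinct positive integer on the same grid as the paired dynamic series.
    """

    labels: np.ndarray
    label_map: dict[str, int]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise DimensionalityError("mask labels must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.allclose(self.labels, np.round(self.labels)):
                raise ValidationError("mask labels must be integers")
            self.labels = np.round(self.labels).astype(np.int32)
        self.label_map = dict(self.label_map)
        if self.label_map.get("background", 0) != 0:
            raise ValidationError("background role must map to label 0")
        self.label_map.setdefault("background", 0)
        non_bg = {r: v for r, v in self.label_map.items() if r != "background"}
        values = list(non_bg.values())
        if any(v <= 0 for v in values):
            raise ValidationError("non-background roles must map to positive labels")
        if len(set(values)) != len(values):
            raise ValidationError("roles must map to distinct labels")

    def voxels(self, role: str) -> np.ndarray:
        """Boolean mask of voxels carrying ``role``."""
        if role not in self.label_map:
            raise ValidationError(f"role {role!r} not declared in mask")
        return self.labels == self.label_map[role]

    def require_nonempty(self, role: str) -> np.ndarray:
        sel = self.voxels(role)
        if not sel.any():
            raise ValidationError(f"role {role!r} has no voxels")
        return sel

    def check_grid(self, series: DynamicSeries) -> None:
        if self.labels.shape != series.spatial_shape:
            raise ValidationError(
                f"mask grid {self.labels.shape} does not match series grid "
                f"{series.spatial_shape}"
            )


@dataclass
class Aif:
    """Arterial input function: a baseline-normalised concentration proxy.

    After baseline normalisation the mean over the pre-contrast window is
    ~0 by construction; the curve is in arbitrary signal units under the
    linear signal-concentration assumption.
    """

    times: np.ndarray
    conc: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.times.shape != self.conc.shape or self.times.ndim != 1:
            raise ValidationError("AIF times and conc must be equal-length 1D")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("AIF times must be strictly increasing")


@dataclass
class TwoCfmParams:
    """Parameters of the two-compartment filtration model.

    Attributes
    ----------
    F_P : plasma flow, ml/min per 100 ml tissue.
    V_P : plasma volume, ml per 100 ml tissue.
    F_T : tubular flow (filtration), ml/min per 100 ml tissue.
    T_T : tubular mean transit time, seconds.
    delay : bolus arrival delay, seconds.
    """

    F_P: float
    V_P: float
    F_T: float
    T_T: float
    delay: float = 0.0

    def __post_init__(self) -> None:
        for name in ("F_P", "V_P", "F_T", "T_T", "delay"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    @property
    def T_P(self) -> float:
        """Plasma mean transit time V_P / (F_P + F_T), seconds."""
        denom = flow_to_per_second(self.F_P + self.F_T)
        if denom == 0:
            return np.inf
        return (self.V_P / 100.0) / denom

    def as_array(self) -> np.ndarray:
        return np.array([self.F_P, self.V_P, self.F_T, self.T_T, self.delay])


PARAM_NAMES = ("F_P", "V_P", "F_T", "T_T", "delay")


@dataclass
class ParamMaps:
    """Voxel-wise 2CFM parameter maps plus goodness of fit.

    Each map is a 3D array on the mask grid; voxels where no fit was
    attempted or the fit failed carry :data:`NOT_FITTED` and are excluded
    from ``fitted_mask``.  ``chi2`` is the residual sum of squares in
    (signal units)^2.
    """

    maps: dict[str, np.ndarray]
    chi2: np.ndarray
    fitted_mask: np.ndarray

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.maps.values()}
        shapes.add(self.chi2.shape)
        shapes.add(self.fitted_mask.shape)
        if len(shapes) != 1:
            raise ValidationError("all parameter maps must share one grid")
        missing = set(PARAM_NAMES) - set(self.maps)
        if missing:
            raise ValidationError(f"parameter maps missing {sorted(missing)}")
        fitted_chi2 = self.chi2[self.fitted_mask]
        if fitted_chi2.size and np.nanmin(fitted_chi2) < 0:
            raise ValidationError("chi2 must be non-negative on fitted voxels")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[name]


@dataclass
class FluorescenceTrace:
    """Transcutaneous fluorescence recording at nominally 1 Hz.

    ``background_window`` is the pre-injection interval (seconds) whose mean
    signal estimates the skin autofluorescence; by protocol it is the first
    minute of the recording.
    """

    times: np.ndarray
    signal: np.ndarray
    background_window: tuple[float, float] = (0.0, 60.0)

    #: allowed deviation from uniform 1 s sampling, seconds
    SAMPLING_TOL = 1e-6

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.shape != self.signal.shape or self.times.ndim != 1:
            raise ValidationError("trace times and signal must be equal-length 1D")
        if len(self.times) < 2:
            raise ValidationError("trace must contain at least 2 samples")
        dt = np.diff(self.times)
        if not np.all(dt > 0):
            raise ValidationError("trace times must be strictly increasing")
        if np.max(np.abs(dt - 1.0)) > self.SAMPLING_TOL:
            raise ValidationError("trace must be uniformly sampled at 1 s")
        t0, t1 = self.background_window
        if not (self.times[0] <= t0 < t1):
            raise ValidationError("background window must be a valid interval")

    def background_selector(self) -> np.ndarray:
        t0, t1 = self.background_window
        return (self.times >= t0) & (self.times < t1)


@dataclass
class ClearanceFit:
    """Result of the one-compartment (monoexponential) clearance fit.

    ``t_half`` is the elimination half-life in **minutes**; ``background``
    and ``amplitude`` are in the trace's arbitrary units; ``fit_window``
    records the seconds interval actually fitted.
    """

    background: float
    amplitude: float
    t_half: float
    fit_window: tuple[float, float]
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        if self.t_half <= 0:
            raise ValidationError("t_half must be positive")
        if self.background < 0:
            raise ValidationError("background must be >= 0")
        if self.fit_window[0] >= self.fit_window[1]:
            raise ValidationError("fit_window must be a nonempty interval")


@dataclass
class GfrResult:
    """Absolute GFR for one animal under one method.

    For the MRI method ``per_kidney`` maps each cortex role to
    ``(mean tubular flow ml/100 ml/min, cortex volume ml, gfr ml/min)``
    and ``gfr_total`` is the sum over kidneys.  For the optical method the
    clearance half-life (minutes) and body weight (g) are recorded.
    """

    animal_id: str
    method: str
    gfr_total: float
    per_kidney: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    t_half: float | None = None
    body_weight: float | None = None

    def __post_init__(self) -> None:
        if self.method not in ("optical", "mri"):
            raise ValidationError("method must be 'optical' or 'mri'")
        if self.gfr_total < 0:
            raise ValidationError("gfr_total must be >= 0")
        if self.method == "mri" and self.per_kidney:
            total = sum(v[2] for v in self.per_kidney.values())
            if not np.isclose(total, self.gfr_total, rtol=1e-9, atol=1e-12):
                raise ValidationError("gfr_total must equal the per-kidney sum")


@dataclass
class ComparisonStats:
    """Bland-Altman agreement summary plus the paired test.

    Differences are method A - method B in ml/min; limits of agreement are
    ``bias +/- 2 * sd_diff`` with the sample (n-1) standard deviation.
    """

    n: int
    bias: float
    sd_diff: float
    loa: tuple[float, float]
    n_outside: int
    t_stat: float
    df: int
    p_value: float
    pct_reduction: float | None = None
    degenerate: bool = False
    means: np.ndarray | None = None
    diffs: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.n_outside <= self.n):
            raise ValidationError("n_outside must lie in [0, n]")
        if self.sd_diff > 0 and not self.loa[0] < self.loa[1]:
            raise ValidationError("limits of agreement must be ordered")


# --------------------------------------------------------------------------
# NIfTI I/O
# --------------------------------------------------------------------------

def _affine_from_dims(voxel_dims) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_dims
    return aff


def read_dynamic_series(path, n_baseline: int, dt: float) -> DynamicSeries:
    """Read a 4D NIfTI as a :class:`DynamicSeries`.

    The time axis is reconstructed as ``[0, dt, 2 dt, ...]`` (the scanner's
    nominal temporal resolution); voxel dimensions come from the header.
    """
    if dt <= 0:
        raise ValidationError("dt must be positive")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise DimensionalityError(f"expected a 4D series, got {data.ndim}D")
    voxel_dims = tuple(float(z) for z in img.header.get_zooms()[:3])
    times = dt * np.arange(data.shape[3])
    return DynamicSeries(data, times, voxel_dims, n_baseline)


def write_dynamic_series(series: DynamicSeries, path) -> None:
    img = nib.Nifti1Image(series.data.astype(np.float32),
                          _affine_from_dims(series.voxel_dims))
    img.header.set_zooms(series.voxel_dims + (float(np.diff(series.times).mean()) if series.n_volumes > 1 else 1.0,))
    nib.save(img, str(path))


def read_roi_mask(path, label_map: Mapping[str, int]) -> RoiMask:
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj)
    if labels.ndim != 3:
        raise DimensionalityError(f"expected a 3D mask, got {labels.ndim}D")
    return RoiMask(labels.astype(np.int32), dict(label_map))


def write_roi_mask(mask: RoiMask, voxel_dims, path) -> None:
    img = nib.Nifti1Image(mask.labels.astype(np.int16),
                          _affine_from_dims(voxel_dims))
    nib.save(img, str(path))


def write_param_maps(maps: ParamMaps, voxel_dims, path) -> None:
    """Write parameter maps as one 4D NIfTI (F_P, V_P, F_T, T_T, delay, chi2, fitted)."""
    stack = np.stack(
        [maps[name] for name in PARAM_NAMES] + [maps.chi2, maps.fitted_mask.astype(float)],
        axis=-1,
    )
    img = nib.Nifti1Image(stack.astype(np.float32), _affine_from_dims(voxel_dims))
    nib.save(img, str(path))


def read_param_maps(path) -> ParamMaps:
    img = nib.load(str(path))
    stack = np.asarray(img.dataobj, dtype=float)
    if stack.ndim != 4 or stack.shape[3] != len(PARAM_NAMES) + 2:
        raise DimensionalityError("not a parameter-map stack")
    maps = {name: stack[..., i] for i, name in enumerate(PARAM_NAMES)}
    return ParamMaps(maps, chi2=stack[..., -2], fitted_mask=stack[..., -1] > 0.5)


# --------------------------------------------------------------------------
# CSV I/O
# --------------------------------------------------------------------------

def read_fluorescence_trace(path, background_window=(0.0, 60.0)) -> FluorescenceTrace:
    """Read a 1 Hz fluorescence trace from CSV (columns ``time_s``, ``signal``)."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    tcol = cols.get("time_s", cols.get("time"))
    scol = cols.get("signal")
    if tcol is None or scol is None:
        raise ValidationError("trace CSV must have time and signal columns")
    return FluorescenceTrace(df[tcol].to_numpy(float), df[scol].to_numpy(float),
                             tuple(background_window))


def write_fluorescence_trace(trace: FluorescenceTrace, path) -> None:
    pd.DataFrame({"time_s": trace.times, "signal": trace.signal}).to_csv(
        path, index=False)


def load_reference_gfr_table() -> pd.DataFrame:
    """Load the bundled per-animal GFR table from the dual-modality rat study.

    Twelve rats (six healthy Sprague Dawley, six after unilateral
    nephrectomy), each measured simultaneously by transcutaneous
    FITC-sinistrin clearance and by DCE-MRI.  Columns: ``animal_id``,
    ``group`` (``SD``/``UNX``), ``gfr_optical`` and ``gfr_mri`` in ml/min.
    """
    with resources.files("renogfr.data").joinpath(
            "dual_modality_gfr_rats.csv").open() as fh:
        return pd.read_csv(fh)


def load_reference_group_means() -> pd.DataFrame:
    """Load the group-level GFR means/SDs as reported by the source study.

    The reported healthy-group optical mean (4.34 ml/min) is not exactly
    the mean of that group's rounded per-animal entries (4.15); the
    reported value is retained here verbatim because the study's
    percentage-reduction figures are computed from it.  Columns:
    ``group``, ``method`` (``optical``/``mri``), ``mean``, ``sd`` (ml/min).
    """
    with resources.files("renogfr.data").joinpath(
            "reported_group_means.csv").open() as fh:
        return pd.read_csv(fh)
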