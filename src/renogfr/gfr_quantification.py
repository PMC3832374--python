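"""Absolute GFR per animal, for both modalities.

MRI arm: the mean tubular flow over each kidney's cortex ROI (ml/100 ml/min)
times that cortex volume (ml) gives the single-kidney GFR once the /100 is
made explicit::

    GFR_kidney [ml/min] = mean F_T [ml/100 ml/min] * V_cortex [ml] / 100

and whole-animal GFR is the sum over kidneys.  The /100 is stated rather
than inherited silently: "tubular flow x cortex volume" is only
dimensionally consistent when the flow is per 100 ml of tissue.

Optical arm: the elimination half-life of FITC-sinistrin converts to GFR
through an empirical single-compartment conversion constant calibrated per
100 g body weight::

    GFR [ml/min] = (factor [ml/100 g b.w.] / t_half [min]) * BW [g] / 100

The conversion factor is a mandatory, logged configuration value (default
31.26 ml/100 g b.w. from the rat calibration literature), never hard-coded
into results.
"""

from __future__ import annotations

import numpy as np

from .io_types import (
    ClearanceFit,
    GfrResult,
    ParamMaps,
    RoiMask,
    ValidationError,
)

__all__ = ["DEFAULT_CONVERSION_FACTOR", "cortex_volume", "mri_gfr",
           "optical_gfr"]

#: ml per 100 g body weight; rat FITC-sinistrin calibration constant
DEFAULT_CONVERSION_FACTOR = 31.26


def cortex_volume(mask: RoiMask, voxel_dims) -> dict[str, float]:
    """Cortex volume in ml for every ``cortex_*`` role of the mask.

    Volume = voxel count x voxel volume; voxel_dims are mm, and
    1 ml = 1000 mm^3.
    """
    voxel_ml = float(np.prod(np.asarray(voxel_dims, dtype=float))) / 1000.0
    roles = [r for r in mask.label_map if r.startswith("cortex")]
    if not roles:
        raise ValidationError("mask declares no cortex roles")
    out = {}
    for role in roles:
        sel = mask.require_nonempty(role)
        out[role] = float(sel.sum()) * voxel_ml
    return out


def mri_gfr(maps: ParamMaps, mask: RoiMask, voxel_dims,
            animal_id: str = "") -> GfrResult:
    """Whole-animal MRI GFR: per-kidney mean tubular flow x cortex volume / 100.

    Only voxels where the fit converged contribute to the cortex mean.
    """
    if maps.chi2.shape != mask.labels.shape:
        raise ValidationError("maps and mask must share one grid")
    volumes = cortex_volume(mask, voxel_dims)
    per_kidney: dict[str, tuple[float, float, float]] = {}
    for role, vol in sorted(volumes.items()):
        sel = mask.voxels(role) & maps.fitted_mask
        if not sel.any():
            raise ValidationError(f"no fitted voxels in {role!r}")
        mean_ft = float(maps["F_T"][sel].mean())
        per_kidney[role] = (mean_ft, vol, mean_ft * vol / 100.0)
    total = float(sum(v[2] for v in per_kidney.values()))
    return GfrResult(animal_id=animal_id, method="mri", gfr_total=total,
                     per_kidney=per_kidney)


def optical_gfr(fit: ClearanceFit, body_weight: float,
                factor: float, animal_id: str = "") -> GfrResult:
    """Transcutaneous GFR from the clearance half-life.

    Parameters
    ----------
    fit
        The monoexponential clearance fit (``t_half`` in minutes).
    body_weight
        Grams.
    factor
        Conversion constant in ml per 100 g body weight
        (:data:`DEFAULT_CONVERSION_FACTOR` for rats).  Mandatory: there is
        no implicit default in result-producing code paths.
    """
    if body_weight <= 0:
        raise ValidationError("body_weight must be positive")
    if factor <= 0:
        raise ValidationError("conversion factor must be positive")
    gfr = (factor / fit.t_half) * (body_weight / 100.0)
    return GfrResult(animal_id=animal_id, method="optical", gfr_total=gfr,
                     t_half=fit.t_half, body_weight=body_weight)
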