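"""Digital phantoms and fluorescence traces for testing the analysis chain.

Real inputs to this pipeline are a 4D DCE-MRI renography acquisition (with
hand-drawn aorta and cortex masks) and a 1 Hz transcutaneous FITC-sinistrin
fluorescence recording.  Neither can be regenerated at will, so this module
builds synthetic stand-ins with the statistical structure the analysis
assumes:

* an arterial bolus (gamma-variate first pass plus an exponential
  recirculation tail) sampled on the dynamic grid;
* a blocky abdomen geometry — an aorta cylinder, two kidney cortex slabs
  with medulla cores — whose tissue voxels follow the two-compartment
  filtration model exactly for known ground-truth parameters;
* a configurable signal-concentration response: strictly linear (the
  analysis assumption) or a saturating spoiled-gradient-echo response whose
  low-concentration regime is linear and which compresses at high
  concentration, mimicking the behaviour of gadolinium phantom
  measurements;
* fluorescence traces with a pre-injection background minute, a
  distribution-phase rise and a monoexponential elimination over a constant
  skin background.

All randomness flows from the integer ``seed`` carried by the spec objects;
the same seed reproduces the same arrays bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_types import (
    Aif,
    DynamicSeries,
    FluorescenceTrace,
    ParamMaps,
    RoiMask,
    TwoCfmParams,
    ValidationError,
    PARAM_NAMES,
    NOT_FITTED,
)
from .pk_models import twocfm_concentration

__all__ = [
    "AifParams",
    "PhantomSpec",
    "TraceSpec",
    "make_aif",
    "make_phantom",
    "make_trace",
    "spgr_signal",
    "default_phantom_spec",
]


@dataclass
class AifParams:
    """Parameters of the synthetic arterial input function.

    The first pass is a gamma-variate bolus
    ``A * ((t-t0)/t_peak)^alpha * exp(alpha * (1 - (t-t0)/t_peak))``
    (peak value ``A`` at ``t0 + t_peak``); recirculation is modelled as
    ``A * tail_fraction * (1 - exp(-(t-t0)/tail_rise)) * exp(-(t-t0)/tail_decay)``,
    a slowly decaying plateau.  Times in seconds, amplitude in the
    baseline-normalised signal units of the dynamic series.
    """

    amplitude: float = 60.0
    arrival_time: float = 13.5
    time_to_peak: float = 4.5
    dispersion: float = 3.0          # gamma-variate shape alpha
    tail_fraction: float = 0.12
    tail_rise: float = 8.0           # s
    tail_decay: float = 220.0        # s

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be positive")
        if self.time_to_peak <= 0 or self.tail_rise <= 0 or self.tail_decay <= 0:
            raise ValidationError("AIF time constants must be positive")

    def area(self) -> float:
        """Closed-form time integral of the noise-free AIF (0 to infinity)."""
        from scipy.special import gamma as gamma_fn
        a = self.dispersion
        bolus = (self.amplitude * np.exp(a) * a ** -(a + 1.0)
                 * self.time_to_peak * gamma_fn(a + 1.0))
        b, c = self.tail_rise, self.tail_decay
        tail = self.amplitude * self.tail_fraction * (c - b * c / (b + c))
        return bolus + tail


def make_aif(times: np.ndarray, params: AifParams | None = None) -> Aif:
    """Evaluate the synthetic AIF on ``times``; exactly zero before arrival."""
    params = params or AifParams()
    times = np.asarray(times, dtype=float)
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        raise ValidationError("times must be strictly increasing")
    tau = times - params.arrival_time
    conc = np.zeros_like(times)
    pos = tau > 0
    a = params.dispersion
    x = tau[pos] / params.time_to_peak
    conc[pos] = params.amplitude * x ** a * np.exp(a * (1.0 - x))
    conc[pos] += (params.amplitude * params.tail_fraction
                  * (1.0 - np.exp(-tau[pos] / params.tail_rise))
                  * np.exp(-tau[pos] / params.tail_decay))
    return Aif(times, conc)


def spgr_signal(conc: np.ndarray, s0: float, knee: float,
                tr_r1_base: float = 0.02, flip_deg: float = 20.0) -> np.ndarray:
    """Spoiled-gradient-echo steady-state signal for a relaxivity-linear R1.

    ``S = M sin(a) (1 - E1) / (1 - cos(a) E1)`` with ``E1 = exp(-TR * R1)``
    and ``R1 = R1_0 (1 + conc / knee_scale)``.  The proportionality ``M`` and
    the concentration scaling are chosen so that the response has unit slope
    at zero concentration and departs from linearity by about 5% at
    ``conc = knee`` — reproducing the empirically observed behaviour of
    signal vs gadolinium concentration: linear at low dose, compressive
    beyond a knee.  ``s0`` is added as the pre-contrast baseline.
    """
    conc = np.asarray(conc, dtype=float)
    a = np.deg2rad(flip_deg)
    # concentration scale chosen so saturation reaches 5% exactly at the knee
    # (solved for the default TR*R1_0 and flip angle; knee-independent)
    c_scale = knee / 0.2161951842687859
    r1 = tr_r1_base * (1.0 + conc / c_scale)
    e1 = np.exp(-r1)
    s = np.sin(a) * (1.0 - e1) / (1.0 - np.cos(a) * e1)
    s_base = np.sin(a) * (1.0 - np.exp(-tr_r1_base)) / (
        1.0 - np.cos(a) * np.exp(-tr_r1_base))
    # normalise to unit slope at conc = 0 (numerical derivative at baseline)
    eps = 1e-6 * c_scale
    s_eps = np.sin(a) * (1.0 - np.exp(-tr_r1_base * (1 + eps / c_scale))) / (
        1.0 - np.cos(a) * np.exp(-tr_r1_base * (1 + eps / c_scale)))
    d0 = (s_eps - s_base) / eps
    return s0 + (s - s_base) / d0


@dataclass
class PhantomSpec:
    """Specification of the digital renography phantom.

    ``truth`` maps tissue roles to their ground-truth 2CFM parameters;
    aorta voxels carry the AIF directly.  ``signal_model`` selects the
    concentration-to-signal response: ``"linear"`` (slope 1 over baseline)
    or ``"saturating"`` (spoiled-gradient-echo compression above
    ``saturation_knee``).  Defaults give a 48x32x12 voxel grid at
    0.6x0.6x1.2 mm and 470 frames at 0.9 s — the acquisition scale of a
    small-animal renal TWIST protocol, shrunk spatially to keep tests fast.
    """

    shape: tuple[int, int, int] = (48, 32, 12)
    voxel_dims: tuple[float, float, float] = (0.6, 0.6, 1.2)
    n_volumes: int = 470
    dt: float = 0.9
    n_baseline: int = 15
    baseline_signal: float = 100.0
    aif_params: AifParams = field(default_factory=AifParams)
    truth: dict[str, TwoCfmParams] = field(default_factory=lambda: {
        "cortex_left": TwoCfmParams(F_P=180.0, V_P=22.0, F_T=61.0, T_T=120.0),
        "cortex_right": TwoCfmParams(F_P=180.0, V_P=22.0, F_T=68.0, T_T=120.0),
        "medulla": TwoCfmParams(F_P=60.0, V_P=12.0, F_T=25.0, T_T=200.0),
    })
    noise_sigma: float = 0.0
    signal_model: str = "linear"
    saturation_knee: float = 80.0
    seed: int = 0

    #: smallest grid on which the blocky geometry stays disjoint
    MIN_SHAPE = (16, 12, 6)

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if self.signal_model not in ("linear", "saturating"):
            raise ValidationError("signal_model must be 'linear' or 'saturating'")
        if self.n_baseline < 1 or self.n_baseline >= self.n_volumes:
            raise ValidationError("n_baseline must be in [1, n_volumes)")
        if any(s < m for s, m in zip(self.shape, self.MIN_SHAPE)):
            raise ValidationError(
                f"phantom grid must be at least {self.MIN_SHAPE}, "
                f"got {self.shape}")

    @property
    def times(self) -> np.ndarray:
        return self.dt * np.arange(self.n_volumes)


def _phantom_geometry(shape: tuple[int, int, int]) -> dict[str, np.ndarray]:
    """Blocky abdomen: central aorta cylinder, two cortex slabs, medulla cores.

    Regions are axis-aligned boxes/cylinders scaled to the grid so that any
    grid from ~16 voxels across upwards produces disjoint, nonempty roles.
    """
    nx, ny, nz = shape
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                          indexing="ij")
    geom: dict[str, np.ndarray] = {}
    # aorta: cylinder along z in the middle of the grid
    r = max(1.5, nx / 24.0)
    geom["aorta"] = ((x - nx / 2.0) ** 2 + (y - ny / 2.0) ** 2 <= r ** 2)
    # kidneys: boxes left/right of the aorta, cortex = box minus medulla core
    kw, kh = max(3, nx // 6), max(3, ny // 3)
    z0, z1 = max(0, nz // 4), min(nz, 3 * nz // 4) + 1
    for side, x0 in (("left", nx // 8), ("right", nx - nx // 8 - kw)):
        box = ((x >= x0) & (x < x0 + kw)
               & (y >= ny // 3) & (y < ny // 3 + kh)
               & (z >= z0) & (z < z1))
        core = ((x >= x0 + 1) & (x < x0 + kw - 1)
                & (y >= ny // 3 + 1) & (y < ny // 3 + kh - 1)
                & (z > z0) & (z < z1 - 1))
        geom[f"cortex_{side}"] = box & ~core
        geom.setdefault("medulla", np.zeros(shape, bool))
        geom["medulla"] |= core
    return geom


def make_phantom(spec: PhantomSpec) -> tuple[DynamicSeries, RoiMask, ParamMaps]:
    """Build the phantom series, its label mask, and the ground-truth maps.

    Each tissue voxel's noise-free time course is the 2CFM forward curve for
    its role's truth parameters mapped through the signal model and offset
    by the constant pre-contrast baseline; aorta voxels carry the AIF.
    Gaussian noise of ``spec.noise_sigma`` is added with ``spec.seed``.
    """
    times = spec.times
    aif = make_aif(times, spec.aif_params)
    geom = _phantom_geometry(spec.shape)
    occupied = np.zeros(spec.shape, dtype=int)
    for sel in geom.values():
        occupied += sel.astype(int)
    if occupied.max() > 1:
        raise ValidationError("phantom roles overlap")

    roles = ["aorta", "cortex_left", "cortex_right", "medulla"]
    label_map = {"background": 0}
    label_map.update({r: i + 1 for i, r in enumerate(roles)})
    labels = np.zeros(spec.shape, dtype=np.int32)
    for r in roles:
        labels[geom[r]] = label_map[r]

    curves = {"aorta": aif.conc}
    for role, p in spec.truth.items():
        curves[role] = twocfm_concentration(p, aif, times)

    def to_signal(conc: np.ndarray) -> np.ndarray:
        if spec.signal_model == "linear":
            return spec.baseline_signal + conc
        return spgr_signal(conc, spec.baseline_signal, spec.saturation_knee)

    data = np.full(spec.shape + (spec.n_volumes,), spec.baseline_signal)
    for role in roles:
        if role in curves:
            data[geom[role], :] = to_signal(curves[role])

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sigma, size=data.shape)

    series = DynamicSeries(data, times, spec.voxel_dims, spec.n_baseline)
    mask = RoiMask(labels, label_map)

    maps = {name: np.full(spec.shape, NOT_FITTED) for name in PARAM_NAMES}
    chi2 = np.full(spec.shape, NOT_FITTED)
    fitted = np.zeros(spec.shape, dtype=bool)
    for role, p in spec.truth.items():
        sel = geom[role]
        for name in PARAM_NAMES:
            maps[name][sel] = getattr(p, name)
        chi2[sel] = 0.0
        fitted[sel] = True
    truth_maps = ParamMaps(maps, chi2=chi2, fitted_mask=fitted)
    return series, mask, truth_maps


def default_phantom_spec(**overrides) -> PhantomSpec:
    """The reference phantom configuration, with keyword overrides."""
    return PhantomSpec(**overrides)


@dataclass
class TraceSpec:
    """Specification of a synthetic transcutaneous fluorescence trace.

    The model is a constant skin background for the first
    ``injection_time`` seconds, then
    ``background + amplitude * (1 - exp(-t_e/distribution_phase)) *
    2^(-t_e/(60 t_half))`` with ``t_e`` the time since injection — a
    distribution-phase rise to a peak followed by monoexponential
    elimination.  ``t_half`` in minutes; everything else in seconds or
    arbitrary units.
    """

    background: float = 120.0
    amplitude: float = 900.0
    t_half: float = 25.0             # minutes
    distribution_phase: float = 180.0  # s
    noise_sigma: float = 0.0
    duration: float = 5400.0         # 90 min at 1 Hz
    injection_time: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_half <= 0:
            raise ValidationError("t_half must be positive")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if self.duration < 60.0 * 2.0 * self.t_half:
            import warnings
            warnings.warn("trace shorter than 2 half-lives; tail fit may be "
                          "poorly conditioned", stacklevel=2)


def make_trace(spec: TraceSpec) -> FluorescenceTrace:
    """Generate a 1 Hz fluorescence trace from ``spec`` (seeded noise)."""
    times = np.arange(0.0, spec.duration + 0.5, 1.0)
    te = times - spec.injection_time
    signal = np.full_like(times, spec.background)
    post = te > 0
    signal[post] += (spec.amplitude
                     * (1.0 - np.exp(-te[post] / spec.distribution_phase))
                     * np.exp2(-te[post] / (60.0 * spec.t_half)))
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        signal = signal + rng.normal(0.0, spec.noise_sigma, size=signal.shape)
    return FluorescenceTrace(times, signal,
                             background_window=(0.0, spec.injection_time))
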