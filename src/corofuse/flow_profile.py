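"""Biphasic coronary inlet velocity model and its patient-specific calibration.

Resting coronary flow is diastolic-dominant: the model superposes two
Gaussian components, a diastolic peak of amplitude ``Vd_max`` at phase
fraction 0.7 and a smaller systolic peak ``Vs_max`` at 0.3,

    V(t) = Vd_max exp(-(t/T - 0.7)² / 2σ_d²) + Vs_max exp(-(t/T - 0.3)² / 2σ_s²)

with widths σ_d = 0.15 and σ_s = 0.1 controlling phase durations.
Patient-specific calibration rescales phase samples by normalized contrast
enhancement ratios R(t_i) and a global factor α:  Vp(t_i) = α R(t_i) V(t_i).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FlowProfileParams",
    "PersonalizedProfile",
    "velocity",
    "diastolic_component",
    "systolic_component",
    "dsvr",
    "contrast_ratio",
    "personalize",
]


@dataclass
class FlowProfileParams:
    """Parameters of the biphasic coronary velocity model (dimensionless amplitudes)."""

    Vd_max: float = 1.0
    Vs_max: float = 0.4
    t_d_peak: float = 0.7  # diastolic peak, fraction of cardiac period
    t_s_peak: float = 0.3  # systolic peak, fraction of cardiac period
    sigma_d: float = 0.15
    sigma_s: float = 0.1
    T: float = 1.0  # cardiac period, s (60/HR)

    def __post_init__(self) -> None:
        if not (self.Vd_max > self.Vs_max):
            raise ValueError("diastolic dominance requires Vd_max > Vs_max")
        if self.sigma_d <= 0 or self.sigma_s <= 0:
            raise ValueError("Gaussian widths must be positive")
        if self.T <= 0:
            raise ValueError("cardiac period must be positive")

    @classmethod
    def from_heart_rate(cls, hr_bpm: float, **kw) -> "FlowProfileParams":
        return cls(T=60.0 / hr_bpm, **kw)


def diastolic_component(t, params: FlowProfileParams):
    """Diastolic Gaussian Vd(t); equals ``Vd_max`` exactly at t = t_d_peak·T."""
    x = np.mod(np.asarray(t, dtype=float), params.T) / params.T
    out = params.Vd_max * np.exp(-((x - params.t_d_peak) ** 2) / (2.0 * params.sigma_d**2))
    return float(out) if out.ndim == 0 else out


def systolic_component(t, params: FlowProfileParams):
    """Systolic Gaussian Vs(t); equals ``Vs_max`` exactly at t = t_s_peak·T."""
    x = np.mod(np.asarray(t, dtype=float), params.T) / params.T
    out = params.Vs_max * np.exp(-((x - params.t_s_peak) ** 2) / (2.0 * params.sigma_s**2))
    return float(out) if out.ndim == 0 else out


def velocity(t, params: FlowProfileParams):
    """Total biphasic velocity V(t) = Vd(t) + Vs(t); t is taken modulo T.

    The Gaussians are evaluated on the single cycle without periodic images;
    the neglected tails at the period edges are below exp(-8).
    """
    return diastolic_component(t, params) + systolic_component(t, params)


def dsvr(
    params: FlowProfileParams,
    systole_window: tuple[float, float] = (0.0, 0.4),
    n_samples: int = 2001,
) -> float:
    """Diastolic-to-systolic velocity ratio.

    Ratio of the peak velocity over the diastolic window to the peak over the
    systolic window (windows as fractions of the period; systole defaults to
    [0, 0.4], diastole to the remainder). > 1 for the default
    diastolic-dominant parameters.
    """
    frac = np.linspace(0.0, 1.0, n_samples)
    v = velocity(frac * params.T, params)
    lo, hi = systole_window
    sys_mask = (frac >= lo) & (frac <= hi)
    dia_mask = ~sys_mask
    return float(v[dia_mask].max() / v[sys_mask].max())


def contrast_ratio(hu_series, hu_base: float, hu_peak: float):
    """Normalized contrast-enhancement ratio R_i = (HU_i − HU_base)/(HU_peak − HU_base).

    ``hu_base`` is the pre-contrast baseline attenuation, ``hu_peak`` the
    maximum enhancement. Values are passed through unclamped; ratios above 1
    indicate local HU overshoot and are left to the caller to interpret.
    """
    if hu_peak <= hu_base:
        raise ValueError("HU_peak must exceed HU_base")
    r = (np.asarray(hu_series, dtype=float) - hu_base) / (hu_peak - hu_base)
    return float(r) if r.ndim == 0 else r


@dataclass
class PersonalizedProfile:
    """Phase-sampled personalized inlet velocity Vp_i = α·R_i·V(t_i)."""

    t: np.ndarray  # phase times, s
    R: np.ndarray  # contrast ratios, dimensionless
    alpha: float
    Vp: np.ndarray = field(init=False)
    baseline: np.ndarray = field(init=False)

    params: FlowProfileParams = field(default_factory=FlowProfileParams)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if self.alpha <= 0:
            raise ValueError("calibration factor alpha must be positive")
        if np.any(self.R < 0):
            raise ValueError("contrast ratios must be non-negative")
        if self.t.shape != self.R.shape:
            raise ValueError("t and R must have matching shapes")
        self.baseline = np.atleast_1d(velocity(self.t, self.params))
        self.Vp = self.alpha * self.R * self.baseline


def personalize(
    params: FlowProfileParams, t, R, alpha: float = 1.0
) -> PersonalizedProfile:
    """Calibrate the baseline profile with contrast ratios and factor α."""
    return PersonalizedProfile(t=np.asarray(t), R=np.asarray(R), alpha=alpha, params=params)


def calibration_factor(
    q_coronary_ml_s: float,
    a_inlet_mm2: float,
    t,
    R,
    params: FlowProfileParams,
) -> float:
    """Default α: match mean personalized inlet flow to the coronary allocation.

    α = Q_coronary / (A_inlet · mean(R_i·V(t_i))) with Q in mm³/s (= µL/s) and
    A in mm², so that mean(Vp·A_inlet) equals the allocated coronary flow.
    """
    t = np.asarray(t, dtype=float)
    R = np.asarray(R, dtype=float)
    mean_rv = float(np.mean(R * np.atleast_1d(velocity(t, params))))
    if mean_rv <= 0 or a_inlet_mm2 <= 0:
        raise ValueError("need positive inlet area and non-degenerate R·V samples")
    return q_coronary_ml_s * 1e3 / (a_inlet_mm2 * mean_rv)
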