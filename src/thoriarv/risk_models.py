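"""Parametric injury-risk functions for the THOR anthropomorphic test device.

Each model maps a measured injury metric (a force, moment, deflection or
dimensionless criterion value) to a probability of injury at or above a
given AIS (abbreviated injury scale) severity level, and exposes the
closed-form inverse: the metric value at a specified acceptable probability,
i.e. the injury assessment reference value (IARV).

Five functional families cover every metric:

* two-parameter Weibull cumulative risk (head: HIC-15; brain: BrIC),
* ordered probit with per-AIS cut points (neck tension, chest deflection,
  ankle inversion/eversion),
* logistic dose-response (acetabular force, ankle dorsiflexion, forearm
  moments, distal forearm speed, NHTSA chest curves),
* a covariate-adjusted logistic for neck compression (age, loading rate,
  gender), and
* a log-linear dynamic-response-index (DRI) chain for thoracic spine load.

All probabilities are plain fractions in (0, 1) unless a function says
otherwise (the DRI chain works in percent, matching its published form).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

from scipy.stats import norm

__all__ = [
    "MissingParameterError",
    "ClampedInversionWarning",
    "WeibullRiskModel",
    "OrderedProbitRiskModel",
    "LogisticRiskModel",
    "NeckCompressionModel",
    "DRISpinalRiskModel",
    "HipFractureModel",
    "FRIModel",
    "ShoulderAgeModel",
    "NCAPChestModel",
    "FMVSS_CHEST_MODELS",
    "fmvss_chest_risk",
    "HIC_RISK_MODEL",
    "BRIC_RISK_MODEL",
    "BRIC_CRITICAL_RATE_RAD_S",
    "NECK_TENSION_MODEL",
    "CHEST_DEFLECTION_MODEL",
    "ANKLE_INVERSION_EVERSION_MODEL",
    "ANKLE_DORSIFLEXION_MODEL",
    "THOR_LATERAL_FORCE_MODEL",
    "EUROSID_PELVIS_MODEL",
    "BASS_FOREARM_MODEL",
    "DUMA_FOREARM_MODEL",
    "ADFS_PMHS_MODEL",
    "ADFS_THOR_MODEL",
    "NECK_COMPRESSION_MODEL",
    "DRI_SPINAL_MODEL",
    "SHOULDER_AGE_MODEL",
    "HIP_FRACTURE_MODEL",
    "NCAP_CHEST_MODEL",
]


class MissingParameterError(ValueError):
    """A model parameter required for this evaluation was never published
    and has not been supplied by the caller."""


class ClampedInversionWarning(UserWarning):
    """An IARV inversion produced a negative metric value and was clamped
    to zero (the risk curve does not pass through the origin)."""


def _check_probability(p: float) -> None:
    if not 0.0 < p < 1.0:
        raise ValueError(f"probability must lie strictly in (0, 1), got {p!r}")


# --------------------------------------------------------------------------
# Weibull family (HIC-15, BrIC)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class WeibullRiskModel:
    """Cumulative Weibull risk: p(AIS>=n | x) = 1 - exp(-(x / scale_n)^shape).

    Parameters
    ----------
    shape
        Dimensionless Weibull exponent, shared across AIS levels
        (4.34 for HIC-15, 2.84 for BrIC).
    scales
        Per-AIS-level scale parameter in metric units. Levels with no
        published scale are simply absent; requesting them raises
        :class:`MissingParameterError`.
    """

    shape: float
    scales: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.shape <= 0:
            raise ValueError("Weibull shape must be positive")
        for level, scale in self.scales.items():
            if scale <= 0:
                raise ValueError(f"Weibull scale for AIS {level} must be positive")

    def _scale(self, level: int) -> float:
        try:
            return self.scales[level]
        except KeyError:
            raise MissingParameterError(
                f"no Weibull scale parameter is available for AIS >= {level}; "
                "supply it explicitly (it was never published for this metric)"
            ) from None

    def risk(self, x: float, level: int = 1) -> float:
        """Probability of an AIS >= ``level`` injury at metric value ``x``."""
        if x < 0:
            raise ValueError("metric value must be non-negative")
        scale = self._scale(level)
        return 1.0 - math.exp(-((x / scale) ** self.shape))

    def iarv(self, p: float, level: int = 1) -> float:
        """Metric value whose risk of AIS >= ``level`` injury equals ``p``."""
        _check_probability(p)
        scale = self._scale(level)
        return scale * (-math.log1p(-p)) ** (1.0 / self.shape)


# --------------------------------------------------------------------------
# Ordered probit family (neck tension, chest deflection, ankle inv/ev)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OrderedProbitRiskModel:
    """Ordered probit: p(AIS>=n | x) = 1 - Phi(c_n - beta * x).

    ``cut_points`` maps AIS level -> cut point c_n (metric-scaled); they must
    be strictly increasing with level so that severities are ordered.
    ``slope`` (beta) has inverse metric units.
    """

    cut_points: Mapping[int, float]
    slope: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("probit slope must be positive")
        levels = sorted(self.cut_points)
        cuts = [self.cut_points[n] for n in levels]
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError("cut points must increase strictly with AIS level")

    def _cut(self, level: int) -> float:
        try:
            return self.cut_points[level]
        except KeyError:
            raise MissingParameterError(
                f"no cut point is defined for AIS >= {level}"
            ) from None

    def risk(self, x: float, level: int = 1) -> float:
        return float(1.0 - norm.cdf(self._cut(level) - x * self.slope))

    def iarv(self, p: float, level: int = 1) -> float:
        _check_probability(p)
        return float((self._cut(level) - norm.ppf(1.0 - p)) / self.slope)


# --------------------------------------------------------------------------
# Logistic family
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LogisticRiskModel:
    """Logistic dose-response: p(x) = 1 / (1 + exp(intercept - slope * x)).

    Published curves come in two equivalent notations; the location/scale
    form p = 1 / (1 + exp(-(x - c) / b)) maps onto this one with
    intercept = c / b and slope = 1 / b (see :meth:`from_location_scale`).

    ``clamp_negative_iarv`` controls the behaviour of :meth:`iarv` when the
    closed-form inversion is negative (curves that do not pass through the
    origin): the result is clamped to 0 with a
    :class:`ClampedInversionWarning`, never silently.
    """

    intercept: float
    slope: float
    clamp_negative_iarv: bool = True

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("logistic slope must be positive (risk increases with the metric)")

    @classmethod
    def from_location_scale(cls, location: float, scale: float, **kw) -> "LogisticRiskModel":
        """Build from the p = 1/(1 + exp(-(x - c)/b)) parameterisation."""
        if scale <= 0:
            raise ValueError("logistic scale must be positive")
        return cls(intercept=location / scale, slope=1.0 / scale, **kw)

    def risk(self, x: float) -> float:
        # numerically safe scalar expit
        z = self.intercept - self.slope * x
        if z > 0:
            ez = math.exp(-z)
            return ez / (1.0 + ez)
        return 1.0 / (1.0 + math.exp(z))

    def iarv(self, p: float) -> float:
        _check_probability(p)
        x = (self.intercept - math.log(1.0 / p - 1.0)) / self.slope
        if x < 0 and self.clamp_negative_iarv:
            warnings.warn(
                f"logistic inversion at p={p} gives a negative metric value "
                f"({x:.4g}); clamped to 0 because the fitted curve does not "
                "pass through the origin",
                ClampedInversionWarning,
                stacklevel=2,
            )
            return 0.0
        return x


# --------------------------------------------------------------------------
# Neck axial compression (covariate tolerance model)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NeckCompressionModel:
    """Cervical-spine axial compression tolerance with age / loading-rate /
    gender covariates.

    The 50%-risk tolerance force is linear in the covariates:

        Fz50 = b0 + b1*A + b2*LR + b3*G + b4*A*LR   [N]

    with A the age in years, LR the loading rate in m/s and G a gender
    indicator (0 female, 1 male). Risk at an applied force follows a
    logistic with steepness ``beta5``; that steepness was never published,
    so risk and IARV evaluation require it explicitly, while the tolerance
    itself does not.
    """

    beta0: float = 934.2
    beta1: float = 8.9
    beta2: float = 11.0
    beta3: float = 665.0
    beta4: float = -0.134
    beta5: float | None = None

    def tolerance(self, age: float, loading_rate: float, gender: int) -> float:
        """50%-injury-risk compressive force in newtons."""
        if gender not in (0, 1):
            raise ValueError("gender indicator must be 0 (female) or 1 (male)")
        if not 0 < age < 120:
            raise ValueError(f"age {age} outside a plausible human range")
        return (
            self.beta0
            + self.beta1 * age
            + self.beta2 * loading_rate
            + self.beta3 * gender
            + self.beta4 * age * loading_rate
        )

    def _require_beta5(self) -> float:
        if self.beta5 is None:
            raise MissingParameterError(
                "the logistic steepness beta5 of the neck-compression risk "
                "function was never published; supply beta5 to evaluate risk "
                "or invert an IARV"
            )
        return self.beta5

    def risk(self, force: float, age: float, loading_rate: float, gender: int) -> float:
        beta5 = self._require_beta5()
        tol = self.tolerance(age, loading_rate, gender)
        return 1.0 / (1.0 + math.exp(beta5 * (tol - force)))

    def iarv(self, p: float, age: float, loading_rate: float, gender: int) -> float:
        _check_probability(p)
        beta5 = self._require_beta5()
        tol = self.tolerance(age, loading_rate, gender)
        # at p = 0.5 the log term vanishes and the IARV equals the tolerance
        return tol - math.log(1.0 / p - 1.0) / beta5


# --------------------------------------------------------------------------
# DRI spinal chain (thoracic spine axial compression)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DRISpinalRiskModel:
    """Log-linear map between the dynamic response index and spinal injury
    risk **in percent**: p% = 10^((DRI - intercept) / slope).

    ``intercept`` is the DRI at 1% risk (the 10^0 point); the percent
    convention is the only one under which the published thoracic force
    chain reproduces (5.80 kN at 5%).
    """

    slope: float = 3.73
    intercept: float = 15.8

    def risk_percent(self, dri: float) -> float:
        return 10.0 ** ((dri - self.intercept) / self.slope)

    def dri_at_risk(self, percent: float) -> float:
        if percent <= 0:
            raise ValueError("risk percent must be positive")
        return self.slope * math.log10(percent) + self.intercept


# --------------------------------------------------------------------------
# Hip / femoral head models
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HipFractureModel:
    """Lognormal hip-fracture risk under transmitted force, with stature and
    posture covariates:

        Risk = Phi( (ln F - ln[ e^(c0 + c1*s) * (1 - (f - a)/100) ]) / sigma )

    F in kN, stature s in cm, hip flexion f in degrees (neutral 30) and
    abduction a in degrees (neutral 15). The posture factor is 1 in the
    neutral posture and shrinks as flexion exceeds abduction relative to
    neutral: 1 - ((f - 30) - (a - 15)) / 100. It multiplies the stature
    term inside the logarithm; the grouping is isolated in
    :meth:`median_force` so an alternative reading is a one-line change.
    """

    c0: float = -0.2141
    c1: float = 0.0114
    sigma: float = 0.1991
    flexion_neutral: float = 30.0
    abduction_neutral: float = 15.0

    def median_force(self, stature_cm: float, flexion_deg: float = 30.0,
                     abduction_deg: float = 15.0) -> float:
        """Force (kN) at 50% fracture risk for the given stature/posture."""
        posture = 1.0 - ((flexion_deg - self.flexion_neutral)
                         - (abduction_deg - self.abduction_neutral)) / 100.0
        return math.exp(self.c0 + self.c1 * stature_cm) * posture

    def risk(self, force_kn: float, stature_cm: float, flexion_deg: float = 30.0,
             abduction_deg: float = 15.0) -> float:
        if force_kn <= 0:
            raise ValueError("force must be positive")
        med = self.median_force(stature_cm, flexion_deg, abduction_deg)
        return float(norm.cdf((math.log(force_kn) - math.log(med)) / self.sigma))

    def iarv(self, p: float, stature_cm: float, flexion_deg: float = 30.0,
             abduction_deg: float = 15.0) -> float:
        _check_probability(p)
        med = self.median_force(stature_cm, flexion_deg, abduction_deg)
        return float(med * math.exp(self.sigma * norm.ppf(p)))


@dataclass(frozen=True)
class FRIModel:
    """Fracture-risk-index logistic: p = 1 / (1 + exp(-(F/F_fracture - mu) * phi)).

    The FRI is the ratio of applied to fracture force; ``mu`` is the FRI at
    50% risk and ``phi`` the slope factor.
    """

    fracture_force: float
    mu: float
    phi: float

    def __post_init__(self) -> None:
        if self.fracture_force <= 0:
            raise ValueError("fracture force must be positive")

    def fri(self, applied_force: float) -> float:
        return applied_force / self.fracture_force

    def risk(self, applied_force: float) -> float:
        return 1.0 / (1.0 + math.exp(-(self.fri(applied_force) - self.mu) * self.phi))

    def iarv(self, p: float) -> float:
        _check_probability(p)
        fri = self.mu - math.log(1.0 / p - 1.0) / self.phi
        return fri * self.fracture_force


# --------------------------------------------------------------------------
# Shoulder (age-dependent Weibull on the THOR scale)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ShoulderAgeModel:
    """Lateral shoulder contact force risk, age-dependent, on the THOR scale.

    The underlying WorldSID risk curve is a Weibull whose scale decays
    exponentially with age; the THOR transfer gain (THOR reads ~2x the
    WorldSID contact force in matched tests) folds in multiplicatively:

        F_THOR(p, age) = gain * exp(b0 - b1*age) * (-ln(1 - p))^(1/k)
    """

    intercept: float = 8.14
    age_slope: float = 0.0055
    shape: float = 7.41
    thor_gain: float = 2.016

    def _scale(self, age: float) -> float:
        if age <= 0:
            raise ValueError("age must be positive")
        return self.thor_gain * math.exp(self.intercept - self.age_slope * age)

    def risk(self, force_thor: float, age: float) -> float:
        if force_thor < 0:
            raise ValueError("force must be non-negative")
        return 1.0 - math.exp(-((force_thor / self._scale(age)) ** self.shape))

    def iarv(self, p: float, age: float) -> float:
        _check_probability(p)
        return self._scale(age) * (-math.log1p(-p)) ** (1.0 / self.shape)


# --------------------------------------------------------------------------
# NHTSA chest models (Hybrid-III sternal compression)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NCAPChestModel:
    """NHTSA NCAP age-adjusted AIS>=3 chest risk:

        p = 1 / (1 + exp(a0 - a1*Age - a2 * Dmax^a3)),  Dmax in mm.
    """

    a0: float = 12.597
    a1: float = 0.05861
    a2: float = 1.568
    a3: float = 0.4612

    def risk(self, deflection_mm: float, age: float) -> float:
        if deflection_mm < 0:
            raise ValueError("deflection must be non-negative")
        z = self.a0 - self.a1 * age - self.a2 * deflection_mm ** self.a3
        return 1.0 / (1.0 + math.exp(z))


#: FMVSS-208 logistic chest-risk curves by AIS level (intercept, slope on mm).
FMVSS_CHEST_MODELS: Mapping[int, LogisticRiskModel] = {
    2: LogisticRiskModel(1.8706, 0.04439),
    3: LogisticRiskModel(3.7124, 0.0475),
    4: LogisticRiskModel(5.0952, 0.0475),
    5: LogisticRiskModel(8.8274, 0.0459),
}


def fmvss_chest_risk(deflection_mm: float, level: int) -> float:
    """Risk of an AIS >= ``level`` chest injury at ``deflection_mm`` of
    sternal compression (FMVSS-208 family, levels 2-5)."""
    if deflection_mm < 0:
        raise ValueError("deflection must be non-negative")
    try:
        model = FMVSS_CHEST_MODELS[level]
    except KeyError:
        raise MissingParameterError(f"no FMVSS chest curve for AIS >= {level}") from None
    return model.risk(deflection_mm)


# --------------------------------------------------------------------------
# Published default model instances
# --------------------------------------------------------------------------

#: HIC-15 mild-traumatic-brain-injury risk (AIS>=1), Weibull alpha=4.34, beta=671.
HIC_RISK_MODEL = WeibullRiskModel(shape=4.34, scales={1: 671.0})

#: BrIC risk family: shape 2.84 is published, the per-AIS scale parameters
#: lambda_n are not; the model ships unconfigured and raises
#: MissingParameterError until scales are supplied.
BRIC_RISK_MODEL = WeibullRiskModel(shape=2.84, scales={})

#: BrIC critical angular rates (rad/s) about X, Y, Z.
BRIC_CRITICAL_RATE_RAD_S = (66.3, 53.8, 41.5)

#: Neck axial tension ordered probit (force in N).
NECK_TENSION_MODEL = OrderedProbitRiskModel(
    cut_points={1: 6.30, 2: 8.56, 3: 9.28, 4: 10.19}, slope=0.0053
)

#: Sternal compression ordered probit (deflection in mm).
CHEST_DEFLECTION_MODEL = OrderedProbitRiskModel(
    cut_points={1: 4.17, 2: 5.61, 3: 6.29, 4: 7.32}, slope=0.103
)

#: Ankle inversion/eversion moment probit (Nm), single AIS>=2 curve.
ANKLE_INVERSION_EVERSION_MODEL = OrderedProbitRiskModel(
    cut_points={2: 4.0}, slope=0.10
)

#: Ankle dorsiflexion moment logistic (Nm), AIS>=2.
ANKLE_DORSIFLEXION_MODEL = LogisticRiskModel.from_location_scale(60.23, 9.217)

#: THOR lateral (pelvis/acetabular) contact force logistic (N), AIS>=2.
THOR_LATERAL_FORCE_MODEL = LogisticRiskModel(6.403, 0.0011)

#: EuroSID-2re pelvic force logistic (N), AIS>=2.
EUROSID_PELVIS_MODEL = LogisticRiskModel(6.403, 0.00163)

#: SAE 5th-percentile-female instrumented-arm forearm moment logistic (Nm).
BASS_FOREARM_MODEL = LogisticRiskModel.from_location_scale(66.2, 15.0)

#: 5th-percentile-female PMHS forearm moment logistic (Nm).
DUMA_FOREARM_MODEL = LogisticRiskModel.from_location_scale(58.0, 6.62)

#: Average distal forearm speed logistic on the PMHS scale (m/s).
ADFS_PMHS_MODEL = LogisticRiskModel(6.749, 0.645)

#: Average distal forearm speed logistic mass-scaled to the THOR arm (m/s).
ADFS_THOR_MODEL = LogisticRiskModel(9.845, 0.645)

#: Neck compression tolerance model; beta5 unpublished, risk not evaluable.
NECK_COMPRESSION_MODEL = NeckCompressionModel()

#: DRI <-> spinal injury risk (percent) chain.
DRI_SPINAL_MODEL = DRISpinalRiskModel()

#: Age-dependent lateral shoulder force model on the THOR scale.
SHOULDER_AGE_MODEL = ShoulderAgeModel()

#: NHTSA frontal-impact hip fracture model (force in kN).
HIP_FRACTURE_MODEL = HipFractureModel()

#: NHTSA NCAP age-adjusted chest risk.
NCAP_CHEST_MODEL = NCAPChestModel()
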