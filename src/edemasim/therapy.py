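"""Anti-angiogenic (bevacizumab-like) treatment as a parameter modification.

The drug binds free angiogenic factor (VEGF), which the model represents as
vascular normalization: vessels become more efficient nutrient deliverers
and higher factor levels are required for the same angiogenic "action".
Concretely, over the treatment course the normoxic->hypoxic conversion rate
``beta`` is divided by 10, the hypoxic->normoxic rate ``gamma`` is
multiplied by 10, and the half-saturation constants for vascular
proliferation (``K_m``) and vessel permeability (``K_half``) are both
doubled.  Parameters switch instantaneously at the course boundaries; no
pharmacokinetic onset/washout is modeled.

The course starts when the virtual T1Gd circle-equivalent radius first
reaches the trigger radius (default 1 cm, a typical size at which the
therapy is considered clinically) and lasts a fixed duration (default
100 days, a representative course length).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

from .parameters import ModelParameters, ParameterError


@dataclass(frozen=True)
class TreatmentProtocol:
    """Trigger radius, course duration, and the three modification factors."""

    trigger_radius_cm: float = 1.0
    duration_days: float = 100.0
    f_beta: float = 10.0    # beta -> beta / f_beta
    f_gamma: float = 10.0   # gamma -> gamma * f_gamma
    f_angio: float = 2.0    # K_m, K_half -> x f_angio

    def __post_init__(self) -> None:
        if self.duration_days <= 0:
            raise ParameterError("treatment duration must be positive")
        for name in ("f_beta", "f_gamma", "f_angio"):
            if getattr(self, name) < 1.0:
                raise ParameterError(f"{name} must be >= 1")
        if self.trigger_radius_cm <= 0:
            raise ParameterError("trigger radius must be positive")

    @property
    def trigger_radius_mm(self) -> float:
        return 10.0 * self.trigger_radius_cm


def modified_parameters(params: ModelParameters,
                        protocol: TreatmentProtocol) -> ModelParameters:
    """The on-treatment parameter set.

    Pure: returns a copy touching exactly beta, gamma, K_m, and K_half.
    """
    return params.replace(
        beta=params.beta / protocol.f_beta,
        gamma=params.gamma * protocol.f_gamma,
        K_m=params.K_m * protocol.f_angio,
        K_half=params.K_half * protocol.f_angio,
    )


def treatment_active(day: float, trigger_day: float | None,
                     protocol: TreatmentProtocol) -> bool:
    """Whether treatment is on at ``day``.

    The course covers the half-open interval
    ``[trigger_day, trigger_day + duration)`` — exactly ``duration`` treated
    days; always False when the trigger has not fired.
    """
    if day < 0:
        raise ValueError(f"day must be nonnegative, got {day}")
    if trigger_day is None:
        return False
    return trigger_day <= day < trigger_day + protocol.duration_days
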