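"""Model parameter registry with units, provenance, and unit conversion.

The simulator couples five cellular/molecular species (normoxic cells ``c``,
hypoxic cells ``h``, necrotic cells ``n``, vascular endothelial cells ``v``,
angiogenic factors ``a``) with tumor-associated vasogenic edema fluid ``l``.
Rates are quoted in the units customary for glioma kinetic modelling
(per year, mm^2/year), except for the edema block whose literature values are
quoted per day / per second.  All dynamics are evaluated in a single internal
unit system (per day, mm) produced by :meth:`ModelParameters.to_internal`.

Cell densities are handled internally as fractions of the carrying capacity
``K``, so ``K`` cancels out of the cellular dynamics; the angiogenic-factor
production/consumption constants are therefore expressed per unit cell
*fraction* rather than per cell.  The capillary fluid level ``l_v`` is
normalized to 1, making the edema field a fluid fraction.
"""

from __future__ import annotations

import csv
import dataclasses
import io
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

DAYS_PER_YEAR = 365.0
SECONDS_PER_DAY = 86400.0


@dataclass(frozen=True)
class ParamInfo:
    """Registry entry: default value, units, and where the number comes from."""

    default: float
    units: str
    provenance: str


#: Registry of every model constant.  Rates per year unless stated otherwise.
#: The edema block (D_l, K_max, K_half, delta_l, l_v) uses its native units.
PARAMETER_REGISTRY: dict[str, ParamInfo] = {
    "rho": ParamInfo(
        75.0, "1/year",
        "Net proliferation rate of normoxic cells; patient-specific kinetic "
        "parameter, aggressive-case value used in the virtual experiments."),
    "D_w": ParamInfo(
        53.0, "mm^2/year",
        "Net invasion rate in white matter; aggressive-case value."),
    "D_g": ParamInfo(
        0.53, "mm^2/year",
        "Net invasion rate in gray matter; aggressive-case value (D_w/100)."),
    "gamma": ParamInfo(
        365.0, "1/year",
        "Maximum hypoxic->normoxic conversion rate (1/day); phenotype "
        "recovery is fast once oxygen delivery is restored."),
    "beta": ParamInfo(
        18.25, "1/year",
        "Maximum normoxic->hypoxic conversion rate (0.05/day); order-of-"
        "magnitude estimate for hypoxic phenotype switching."),
    "alpha_h": ParamInfo(
        7.3, "1/year",
        "Hypoxic->necrotic conversion rate when vascular efficiency is low "
        "(0.02/day); hypoxic cells survive on the order of weeks."),
    "alpha_n": ParamInfo(
        3.65, "1/year",
        "Contact-necrosis rate; cells in contact with necrosis die at this "
        "rate (0.01/day)."),
    "D_v": ParamInfo(
        3.15, "mm^2/year",
        "Vascular endothelial cell dispersal, ~1e-9 cm^2/s, endothelial "
        "migration scale."),
    "mu": ParamInfo(
        36.5, "1/year",
        "Maximum vasculature proliferation rate (0.1/day); endothelial "
        "doubling on a 1-2 week scale under full angiogenic stimulation."),
    "K_m": ParamInfo(
        5.75e-6, "mmol/cc tissue",
        "Angiogenic-factor concentration at half-maximal vascular "
        "proliferation; an order of magnitude above the permeability "
        "half-saturation — building vessels takes far more sustained "
        "stimulus than leaking ones."),
    "q": ParamInfo(
        1.0e-5, "mmol/cc per vascular fraction",
        "Angiogenic factor consumed per unit of newly proliferated "
        "vasculature (vasculature measured as fraction of K)."),
    "omega": ParamInfo(
        36.5, "1/year per vascular fraction",
        "Factor consumption for vasculature maintenance."),
    "lambda_": ParamInfo(
        36.5, "1/year",
        "Natural decay of angiogenic factors (0.1/day effective tissue "
        "half-life ~ 1 week)."),
    "delta_c": ParamInfo(
        8.0e-6, "mmol/cc tissue/year per cell fraction",
        "Angiogenic-factor production by normoxic cells; calibrated (with "
        "delta_h) so that untreated edema tracks the bulk-tumor margin."),
    "delta_h": ParamInfo(
        1.5e-3, "mmol/cc tissue/year per cell fraction",
        "Angiogenic-factor production by hypoxic cells; ~40x the normoxic "
        "rate (delta_h > delta_c), hypoxic cells dominate VEGF output."),
    "D_a": ParamInfo(
        630.0, "mm^2/year",
        "Angiogenic-factor dispersal, ~2e-7 cm^2/s, VEGF-scale diffusivity "
        "in tissue."),
    "K": ParamInfo(
        1.0e5, "cells/mm^3",
        "Cell carrying capacity, 1e8 cells/cc of brain tissue."),
    "D_l": ParamInfo(
        0.77e-3, "mm^2/s",
        "Edema fluid diffusion; average ADC of normal brain tissue."),
    "K_max": ParamInfo(
        36.0, "1/day",
        "Maximal K_trans (vessel permeability) in response to angiogenic "
        "factors; matches values observed in grade IV gliomas on DCE-MRI."),
    "K_half": ParamInfo(
        5.75e-7, "mmol/cc tissue",
        "Angiogenic-factor concentration at half-maximal K_trans."),
    "delta_l": ParamInfo(
        0.3 * 36.0, "1/day",
        "Edema fluid reabsorption (drainage) rate, 0.3 x K_max."),
    "l_v": ParamInfo(
        1.0, "fluid fraction",
        "Capillary fluid level, normalized to 1 so edema is a fraction."),
}


class ParameterError(ValueError):
    """Invalid or inconsistent model parameters."""


@dataclass(frozen=True)
class ModelParameters:
    """All rate constants of the growth/edema model, in registry units.

    Instances are immutable; use :func:`dataclasses.replace` (or
    :meth:`replace`) to derive modified sets, e.g. for therapy.
    """

    rho: float = PARAMETER_REGISTRY["rho"].default
    D_w: float = PARAMETER_REGISTRY["D_w"].default
    D_g: float = PARAMETER_REGISTRY["D_g"].default
    gamma: float = PARAMETER_REGISTRY["gamma"].default
    beta: float = PARAMETER_REGISTRY["beta"].default
    alpha_h: float = PARAMETER_REGISTRY["alpha_h"].default
    alpha_n: float = PARAMETER_REGISTRY["alpha_n"].default
    D_v: float = PARAMETER_REGISTRY["D_v"].default
    mu: float = PARAMETER_REGISTRY["mu"].default
    K_m: float = PARAMETER_REGISTRY["K_m"].default
    q: float = PARAMETER_REGISTRY["q"].default
    omega: float = PARAMETER_REGISTRY["omega"].default
    lambda_: float = PARAMETER_REGISTRY["lambda_"].default
    delta_c: float = PARAMETER_REGISTRY["delta_c"].default
    delta_h: float = PARAMETER_REGISTRY["delta_h"].default
    D_a: float = PARAMETER_REGISTRY["D_a"].default
    K: float = PARAMETER_REGISTRY["K"].default
    D_l: float = PARAMETER_REGISTRY["D_l"].default
    K_max: float = PARAMETER_REGISTRY["K_max"].default
    K_half: float = PARAMETER_REGISTRY["K_half"].default
    delta_l: float = PARAMETER_REGISTRY["delta_l"].default
    l_v: float = PARAMETER_REGISTRY["l_v"].default
    #: Drainage model: "constant" uses delta_l as-is; "permeability" uses the
    #: spatially varying alternative delta_l(a) = 0.3 * K_trans(a).
    drainage_model: str = "constant"

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "drainage_model":
                continue
            value = getattr(self, f.name)
            if value < 0:
                raise ParameterError(f"{f.name} must be nonnegative, got {value}")
        if self.delta_h <= self.delta_c:
            raise ParameterError(
                f"delta_h ({self.delta_h}) must exceed delta_c ({self.delta_c})")
        if self.drainage_model not in ("constant", "permeability"):
            raise ParameterError(
                f"unknown drainage_model {self.drainage_model!r}")

    def replace(self, **changes) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def to_internal(self) -> "InternalParameters":
        """Convert every constant to the internal per-day / mm unit system."""
        y = DAYS_PER_YEAR
        return InternalParameters(
            rho=self.rho / y,
            D_w=self.D_w / y,
            D_g=self.D_g / y,
            gamma=self.gamma / y,
            beta=self.beta / y,
            alpha_h=self.alpha_h / y,
            alpha_n=self.alpha_n / y,
            D_v=self.D_v / y,
            mu=self.mu / y,
            K_m=self.K_m,
            q=self.q,
            omega=self.omega / y,
            lambda_=self.lambda_ / y,
            delta_c=self.delta_c / y,
            delta_h=self.delta_h / y,
            D_a=self.D_a / y,
            K=self.K,
            D_l=self.D_l * SECONDS_PER_DAY,
            K_max=self.K_max,
            K_half=self.K_half,
            delta_l=self.delta_l,
            l_v=self.l_v,
            drainage_model=self.drainage_model,
        )

    @classmethod
    def from_internal(cls, p: "InternalParameters") -> "ModelParameters":
        """Inverse of :meth:`to_internal`; the round trip is the identity."""
        y = DAYS_PER_YEAR
        return cls(
            rho=p.rho * y, D_w=p.D_w * y, D_g=p.D_g * y, gamma=p.gamma * y,
            beta=p.beta * y, alpha_h=p.alpha_h * y, alpha_n=p.alpha_n * y,
            D_v=p.D_v * y, mu=p.mu * y, K_m=p.K_m, q=p.q,
            omega=p.omega * y, lambda_=p.lambda_ * y,
            delta_c=p.delta_c * y, delta_h=p.delta_h * y, D_a=p.D_a * y,
            K=p.K, D_l=p.D_l / SECONDS_PER_DAY, K_max=p.K_max,
            K_half=p.K_half, delta_l=p.delta_l, l_v=p.l_v,
            drainage_model=p.drainage_model,
        )

    # ------------------------------------------------------------------ IO

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParameters":
        """Load a parameter set from YAML; unlisted fields keep defaults."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParameters":
        """Accepts plain ``name: value`` entries or the annotated
        ``name: {value: ..., units: ..., provenance: ...}`` form."""
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
        flat = {k: (v["value"] if isinstance(v, dict) else v)
                for k, v in data.items()}
        return cls(**flat)

    def to_yaml(self, path: str | Path | None = None) -> str:
        """Serialize as YAML; each entry carries value, units, provenance."""
        doc = {}
        for f in fields(self):
            if f.name == "drainage_model":
                doc[f.name] = {"value": self.drainage_model}
                continue
            info = PARAMETER_REGISTRY[f.name]
            doc[f.name] = {
                "value": float(getattr(self, f.name)),
                "units": info.units,
                "provenance": info.provenance,
            }
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    def export_internal_csv(self, path: str | Path | None = None) -> str:
        """Emit the fully resolved per-day parameter table as CSV."""
        internal = self.to_internal()
        buf = io.StringIO()
        writer = csv.writer(buf)
        writer.writerow(["parameter", "value_registry_units", "registry_units",
                         "value_per_day", "provenance"])
        for f in fields(self):
            if f.name == "drainage_model":
                continue
            info = PARAMETER_REGISTRY[f.name]
            writer.writerow([
                f.name,
                repr(float(getattr(self, f.name))),
                info.units,
                repr(float(getattr(internal, f.name))),
                info.provenance,
            ])
        text = buf.getvalue()
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass(frozen=True)
class InternalParameters:
    """Mirror of :class:`ModelParameters` with every rate per day, lengths mm.

    This is what the kinetics and solver consume; never construct it by hand
    from registry-unit values.
    """

    rho: float
    D_w: float
    D_g: float
    gamma: float
    beta: float
    alpha_h: float
    alpha_n: float
    D_v: float
    mu: float
    K_m: float
    q: float
    omega: float
    lambda_: float
    delta_c: float
    delta_h: float
    D_a: float
    K: float
    D_l: float
    K_max: float
    K_half: float
    delta_l: float
    l_v: float
    drainage_model: str = "constant"
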