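"""Kinetic parameters and reaction fluxes of the reduced metabolic model.

Three reactions drive steady-state ATP production in the model:

* the adenine nucleotide translocase (ANT), an electrogenic 1:1
  ADP(in)/ATP(out) exchanger on the inner membrane, driven by the fixed
  membrane potential ψ_m;
* the F1F0 ATP synthase (AS), phosphorylating matrix ADP, with a steep
  (8th-power) dependence on ψ_m and a calcium activation factor;
* a "surrogate kinase" mass-action reaction cycling ATP ↔ ADP outside the
  matrix, standing in for adenylate/creatine kinase activity.

All fluxes are evaluated in the package unit system (μm, ms, mM, mV);
membrane fluxes are densities in molecules·ms⁻¹·μm⁻².
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from importlib import resources
from typing import Any

import numpy as np
import yaml

from .units import thermal_voltage_mv

__all__ = [
    "KineticParams",
    "SoluteState",
    "ant_flux",
    "as_flux",
    "surrogate_kinase_rate",
    "load_params",
    "save_params",
    "default_params",
    "curve_params",
]


@dataclass
class KineticParams:
    """Rate constants, binding constants and physical parameters.

    Velocities are flux densities per μm² of membrane; binding constants in
    mM; potentials in mV; diffusivities in μm²/ms.  The ionic-fraction
    fields scale total ADP/ATP to the charged species (ADP³⁻, ATP⁴⁻) that
    the translocase actually binds.  Parameters marked "calibrated" in the
    bundled file are not printed in the source model and are fixed by the
    calibration protocol (see :func:`cristaflux.solver.calibrate`).
    """

    V_ANT: float = 2000.0  # max translocase velocity, molecules/ms/μm²
    V_AS: float = 1000.0  # max synthase velocity, molecules/ms/μm²
    K_ADP: float = 1.0  # synthase ADP binding constant, mM
    K_ATP: float = 4.5  # synthase ATP binding constant, mM
    K_Pi: float = 1.0  # synthase phosphate binding constant, mM
    K_Ca_ATP: float = 1.65e-4  # synthase Ca activation constant, mM
    K_V_ATP: float = 131.4  # half-maximal potential for the synthase, mV
    psi_m: float = 172.0  # inner-membrane potential, mV
    f_P: float = 0.5  # effective-potential fraction for the translocase
    T: float = 310.0  # temperature, K
    f_ADP3_m: float = 1.0  # ionic fraction of matrix ADP that is ADP³⁻
    f_ADP3_e: float = 1.0  # ionic fraction of external ADP that is ADP³⁻
    f_ATP4_m: float = 1.0  # ionic fraction of matrix ATP that is ATP⁴⁻
    f_ATP4_e: float = 1.0  # ionic fraction of external ATP that is ATP⁴⁻
    Pi_m: float = 3.0  # matrix phosphate, mM (held constant)
    Pi_e: float = 1.0  # external phosphate, mM (held constant)
    Ca_m: float = 2.0e-4  # matrix free calcium, mM (held constant)
    k_f: float = 0.009  # kinase forward rate, ms⁻¹
    k_r: float = 1.0  # kinase reverse rate, mM⁻¹·ms⁻¹
    kinase_scale: float = 1.0  # effective kinase activity density (calibrated)
    D_ADP: float = 0.15  # ADP diffusivity, μm²/ms
    D_ATP: float = 0.15  # ATP diffusivity, μm²/ms
    as_flat_denominator: bool = False  # alternative flat-sum synthase grouping
    provenance: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        positive = [
            "V_ANT", "V_AS", "K_ADP", "K_ATP", "K_Pi", "K_Ca_ATP", "K_V_ATP",
            "T", "Pi_m", "Pi_e", "D_ADP", "D_ATP",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0.0 <= self.f_P <= 1.0:
            raise ValueError(f"f_P must be in [0, 1], got {self.f_P}")
        for name in ("f_ADP3_m", "f_ADP3_e", "f_ATP4_m", "f_ATP4_e"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.Ca_m < 0:
            raise ValueError(f"Ca_m must be >= 0, got {self.Ca_m}")
        if self.psi_m < 0:
            raise ValueError(f"psi_m must be >= 0, got {self.psi_m}")
        if self.k_f < 0 or self.k_r < 0 or self.kinase_scale < 0:
            raise ValueError("kinase rate constants must be >= 0")

    @property
    def rt_over_f(self) -> float:
        """RT/F in mV."""
        return thermal_voltage_mv(self.T)

    def replace(self, **changes: Any) -> "KineticParams":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("provenance", None)
        return d


@dataclass
class SoluteState:
    """Total adenine nucleotide concentrations (mM), matrix and external."""

    ADP_m: float
    ATP_m: float
    ADP_e: float
    ATP_e: float

    def __post_init__(self) -> None:
        for name in ("ADP_m", "ATP_m", "ADP_e", "ATP_e"):
            v = getattr(self, name)
            if np.any(np.asarray(v) < 0):
                raise ValueError(f"{name} must be >= 0")


def _check_species(value, name: str) -> None:
    if np.any(np.asarray(value) <= 0):
        raise ValueError(f"{name} appears in a denominator and must be > 0")


def ant_flux(state: SoluteState, p: KineticParams):
    """Adenine nucleotide translocase flux density.

    Positive flux imports external ADP into the matrix and exports matrix
    ATP (1:1 exchange).  The thermodynamic driving term vanishes when
    [ATP⁴⁻]_e·[ADP³⁻]_m / ([ADP³⁻]_e·[ATP⁴⁻]_m) = exp(Fψ/RT); the flux is
    suppressed both by external ATP competing for the outward-facing
    carrier (screened by the fraction f_P of the potential) and by matrix
    ADP competing for the inward-facing carrier.

    External concentrations may be numpy arrays; matrix values are scalars.
    Returns molecules·ms⁻¹·μm⁻².
    """
    adp3_e = p.f_ADP3_e * np.asarray(state.ADP_e, dtype=float)
    atp4_e = p.f_ATP4_e * np.asarray(state.ATP_e, dtype=float)
    adp3_m = p.f_ADP3_m * state.ADP_m
    atp4_m = p.f_ATP4_m * state.ATP_m
    _check_species(adp3_e, "ADP3-_e")
    _check_species(atp4_m, "ATP4-_m")
    u = p.psi_m / p.rt_over_f
    numerator = 1.0 - (atp4_e * adp3_m) / (adp3_e * atp4_m) * np.exp(-u)
    denom = (1.0 + (atp4_e / adp3_e) * np.exp(-p.f_P * u)) * (1.0 + adp3_m / atp4_m)
    return p.V_ANT * numerator / denom


def as_flux(state: SoluteState, p: KineticParams):
    """ATP synthase flux density (matrix ADP + Pi → matrix ATP).

    Michaelis-type kinetics in matrix ADP, Pi and ATP, gated by an
    8th-power Hill factor in the membrane potential and a saturating
    calcium activation factor 1−exp(−Ca/K_Ca).  Returns
    molecules·ms⁻¹·μm⁻².  With ``p.as_flat_denominator`` the binding terms
    are summed instead of the factored (1+ADP/K)(1+Pi/K)+ATP/K form.
    """
    adp_m = np.asarray(state.ADP_m, dtype=float)
    atp_m = np.asarray(state.ATP_m, dtype=float)
    if np.any(adp_m < 0) or np.any(atp_m < 0):
        raise ValueError("concentrations must be >= 0")
    a = adp_m / p.K_ADP
    pi = p.Pi_m / p.K_Pi
    t = atp_m / p.K_ATP
    numerator = a * pi - t
    if p.as_flat_denominator:
        denom = 1.0 + a + pi + t
    else:
        denom = (1.0 + a) * (1.0 + pi) + t
    psi8 = p.psi_m**8
    v_gate = psi8 / (p.K_V_ATP**8 + psi8)
    ca_gate = 1.0 - np.exp(-p.Ca_m / p.K_Ca_ATP)
    return p.V_AS * numerator / denom * v_gate * ca_gate


def surrogate_kinase_rate(ATP_e, ADP_e, Pi_e, p: KineticParams):
    """Mass-action ATP ↔ ADP cycling rate outside the matrix, mM/ms.

    Positive rate converts external ATP to ADP (k_f·ATP − k_r·ADP·Pi).
    """
    ATP_e = np.asarray(ATP_e, dtype=float)
    ADP_e = np.asarray(ADP_e, dtype=float)
    if np.any(ATP_e < 0) or np.any(ADP_e < 0):
        raise ValueError("concentrations must be >= 0")
    return p.k_f * ATP_e - p.k_r * ADP_e * Pi_e


# ---------------------------------------------------------------------------
# Parameter serialization

def save_params(p: KineticParams, path) -> None:
    """Write a parameter set to YAML, with units and provenance annotations."""
    doc = {
        "units": {
            "velocities": "molecules/ms/um^2",
            "binding_constants": "mM",
            "potentials": "mV",
            "diffusivities": "um^2/ms",
            "rates": "1/ms or 1/(mM ms)",
        },
        "parameters": p.to_dict(),
        "provenance": p.provenance,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_params(path_or_stream) -> KineticParams:
    """Load a parameter set from a YAML file path or open stream."""
    if hasattr(path_or_stream, "read"):
        doc = yaml.safe_load(path_or_stream)
    else:
        with open(path_or_stream) as fh:
            doc = yaml.safe_load(fh)
    fields = dict(doc.get("parameters", {}))
    provenance = doc.get("provenance", {}) or {}
    return KineticParams(**fields, provenance=provenance)


def default_params() -> KineticParams:
    """The bundled calibrated parameter set.

    Printed constants (ψ_m, f_P, kinase rates, boundary concentrations)
    carry provenance "printed"; the remaining constants carry "calibrated"
    and were fixed by the documented calibration protocol.
    """
    ref = resources.files("cristaflux.data").joinpath("params_default.yaml")
    with ref.open("r") as fh:
        return load_params(fh)


def curve_params() -> KineticParams:
    """The bundled parameter set for the 3-D lamellar flux-curve family.

    Identical printed constants, but calibrated to the crista-topology
    contrast (detached-crista plateau, CJ-width ordering) rather than the
    2-D gradient battery; the surrogate kinase runs at full strength.
    """
    ref = resources.files("cristaflux.data").joinpath("params_curves3d.yaml")
    with ref.open("r") as fh:
        return load_params(fh)
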