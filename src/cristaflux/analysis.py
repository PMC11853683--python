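"""Topology analysis: ADP gradients, the Rule of 2, penalties, and scoring.

Steady-state intracristal ADP falls along a crista with distance from the
CJ opening(s).  For cristae open at both ends the profile is captured by
the quadratic gradient law

    ADP(x) = ADP₀ − a·x·(L − x),      a = k·ADP₀ / L,

where k (μm⁻¹) measures gradient steepness.  A one-CJ crista of length L
reproduces the first half of the profile of a two-CJ crista of length 2L
(the *Rule of 2*), so two-CJ flux–length curves can be synthesized from
one-CJ curves evaluated at L/2.  The fractional loss of synthase flux
relative to a crista-free model is the *diffusion penalty*; membrane-area
bookkeeping decomposes model fluxes into IBM and crista contributions and
recombines per-crista contributions into a whole-mitochondrion score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from . import geometry as geo
from .solver import (BoundaryConditions, SteadyStateResult, solve_steady_state)

__all__ = [
    "ADPProfile", "QuadraticFit", "FluxCurve",
    "midline_profile", "mirror_profile", "depletion", "fit_quadratic",
    "rule_of_two_check", "diffusion_penalty", "decompose_flux",
    "ibm_correction", "speed_zone", "build_flux_curves", "census_score",
    "CURVE_CLASSES",
]

CURVE_CLASSES = ("no_cj", "one_narrow", "one_wide", "two_narrow", "two_wide")


@dataclass
class ADPProfile:
    """Midline intracristal [ADP] versus distance from the CJ opening."""

    x: np.ndarray  # μm, strictly increasing
    adp: np.ndarray  # mM
    ADP0: float  # boundary-adjacent concentration, mM
    L_CRIS: float  # μm
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.adp = np.asarray(self.adp, dtype=float)
        if self.x.size != self.adp.size or self.x.size == 0:
            raise ValueError("x and adp must be nonempty and of equal length")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly increasing")
        if np.any(self.adp < 0):
            raise ValueError("adp must be >= 0")


@dataclass
class QuadraticFit:
    """Parameters of the quadratic gradient law."""

    a: float  # mM·μm⁻²
    k: float  # μm⁻¹
    R2: float
    ADP0: float = np.nan


def midline_profile(result: SteadyStateResult, crista_id: int = 1) -> ADPProfile:
    """Extract the midline ADP profile of one crista from a solved model."""
    ml = result.model.midlines[crista_id]
    adp = result.ADP_e.reshape(-1)[ml.cells]
    return ADPProfile(
        x=ml.x.copy(), adp=adp, ADP0=float(adp[0]), L_CRIS=ml.length,
        meta={"label": ml.label, "ADP_cyt": result.bc.ADP_cyt if result.bc else None},
    )


def mirror_profile(profile: ADPProfile) -> ADPProfile:
    """Mirror a one-CJ profile into its Rule-of-2 equivalent (length 2L)."""
    L = profile.L_CRIS
    x2 = np.concatenate([profile.x, 2 * L - profile.x[::-1]])
    # drop a duplicated midpoint if the last sample sits exactly at L
    keep = np.concatenate([[True], np.diff(x2) > 0])
    adp2 = np.concatenate([profile.adp, profile.adp[::-1]])
    return ADPProfile(x=x2[keep], adp=adp2[keep], ADP0=profile.ADP0,
                      L_CRIS=2 * L, meta=dict(profile.meta, mirrored=True))


def depletion(profile: ADPProfile) -> float:
    """Area-based ADP depletion: 1 − (∫ adp dx) / (ADP₀ · span).

    Trapezoid quadrature over the sampled midline span; 0 for a flat
    profile at ADP₀, → 1 as the interior is fully depleted.
    """
    if profile.ADP0 <= 0:
        raise ValueError("ADP0 must be > 0 for a depletion measure")
    span = profile.x[-1] - profile.x[0]
    if span <= 0:
        raise ValueError("profile must span a positive distance")
    area = float(np.trapezoid(profile.adp, profile.x))
    return 1.0 - area / (profile.ADP0 * span)


def fit_quadratic(profile: ADPProfile) -> QuadraticFit:
    """Least-squares fit of ADP(x) = ADP₀ − a·x(L−x) with ADP₀ fixed.

    Intended for both-ends profiles (or one-CJ profiles mirrored via the
    Rule of 2).  Returns the curvature a, steepness k = a·L/ADP₀ and R²
    of the fit.
    """
    if profile.x.size < 4:
        raise ValueError("need at least 4 points to fit the gradient law")
    L = profile.L_CRIS
    w = profile.x * (L - profile.x)
    y = profile.ADP0 - profile.adp
    denom = float(np.dot(w, w))
    a = float(np.dot(w, y)) / denom if denom > 0 else 0.0
    resid = profile.adp - (profile.ADP0 - a * w)
    ss_res = float(np.dot(resid, resid))
    ss_tot = float(np.sum((profile.adp - profile.adp.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return QuadraticFit(a=a, k=a * L / profile.ADP0, R2=max(min(r2, 1.0), 0.0),
                        ADP0=profile.ADP0)


def rule_of_two_check(profile_1cj: ADPProfile, profile_2cj: ADPProfile) -> float:
    """Max relative deviation between a 1-CJ profile (length L) and the
    first half of a 2-CJ profile (length 2L), on a common grid."""
    L = profile_1cj.L_CRIS
    if abs(profile_2cj.L_CRIS - 2 * L) > 0.05 * max(2 * L, 1e-9):
        raise ValueError(
            f"profiles are not Rule-of-2 partners: lengths {L} vs "
            f"{profile_2cj.L_CRIS} (expected {2 * L})")
    c1, c2 = profile_1cj.meta.get("ADP_cyt"), profile_2cj.meta.get("ADP_cyt")
    if c1 is not None and c2 is not None and abs(c1 - c2) > 1e-12:
        raise ValueError("profiles were computed at different cytosolic ADP")
    lo = max(profile_1cj.x[0], profile_2cj.x[0])
    hi = min(profile_1cj.x[-1], L)
    xs = np.linspace(lo, hi, 200)
    a1 = np.interp(xs, profile_1cj.x, profile_1cj.adp)
    a2 = np.interp(xs, profile_2cj.x, profile_2cj.adp)
    return float(np.max(np.abs(a1 - a2)) / profile_1cj.ADP0)


def diffusion_penalty(J_model: float, J_max: float) -> float:
    """Fractional flux loss (J_max − J_model)/J_max due to restricted diffusion."""
    if J_max <= 0:
        raise ValueError("J_max must be > 0")
    return (J_max - J_model) / J_max


def decompose_flux(J_model: float, ledger: tuple[float, float, float],
                   J_max: float) -> float:
    """Crista-only flux from the area-weighted decomposition.

    With ledger = (S_IBM, S_CRIS, S_IM) and the IBM operating at J_max,
    J_CRIS = (S_IM/S_CRIS)·J_model − (S_IBM/S_CRIS)·J_max, the inverse of
    J_model = (S_IBM/S_IM)·J_max + (S_CRIS/S_IM)·J_CRIS.
    """
    s_ibm, s_cris, s_im = ledger
    if s_cris <= 0:
        raise ValueError("S_CRIS = 0: use the crista-free baseline directly")
    return (s_im / s_cris) * J_model - (s_ibm / s_cris) * J_max


def ibm_correction(j_over_jmax_cris: float, s_cris_frac: float) -> float:
    """Add the IBM contribution to a crista-only relative flux.

    The IBM fraction (1 − s_cris_frac) of the membrane is unaffected by
    intracristal diffusion and operates at J_max:
    J/J_max = s_cris_frac·(J/J_max)_cris + (1 − s_cris_frac).
    """
    if not (0 <= j_over_jmax_cris <= 1 and 0 <= s_cris_frac <= 1):
        raise ValueError("inputs must be fractions in [0, 1]")
    return s_cris_frac * j_over_jmax_cris + (1.0 - s_cris_frac)


def speed_zone(j_rel: float) -> str:
    """Classify a relative flux: fast ≥ 0.9, moderate [0.75, 0.9), slow < 0.75."""
    if not 0 <= j_rel <= 1:
        raise ValueError("j_rel must be in [0, 1]")
    if j_rel >= 0.9:
        return "fast"
    if j_rel >= 0.75:
        return "moderate"
    return "slow"


# ---------------------------------------------------------------------------
# Flux–length curves and census scoring


@dataclass
class FluxCurve:
    """Sampled J/J_MAX versus crista length with a monotone interpolant."""

    topology: str
    lengths: np.ndarray
    values: np.ndarray
    rule_of_two_of: str | None = None

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        order = np.argsort(self.lengths)
        self.lengths, self.values = self.lengths[order], self.values[order]
        self._interp = PchipInterpolator(self.lengths, self.values)

    def __call__(self, L):
        """Interpolated J/J_MAX at length L; flat-clamped outside the range.

        For Rule-of-2 synthesized classes the underlying one-CJ curve is
        evaluated at L/2.
        """
        L = np.asarray(L, dtype=float)
        if self.rule_of_two_of:
            L = L / 2.0
        L = np.clip(L, self.lengths[0], self.lengths[-1])
        return self._interp(L)


def _rule_of_two_curve(base: FluxCurve, name: str) -> FluxCurve:
    c = FluxCurve(topology=name, lengths=base.lengths.copy(),
                  values=base.values.copy())
    c.rule_of_two_of = base.topology
    return c


def build_flux_curves(
    p,
    lengths=(0.075, 0.15, 0.225, 0.45, 0.9),
    bc: BoundaryConditions | None = None,
    h: float = 0.01,
    n_cristae: int = 4,
    classes=CURVE_CLASSES,
    tol: float = 1e-9,
) -> dict[str, FluxCurve]:
    """Run the 3-D lamellar simulations and assemble flux–length curves.

    Solves the detached / one-narrow-CJ / one-wide-CJ topologies at each
    length, extracts the crista-only relative flux via the area-weighted
    decomposition against a crista-free 3-D baseline, and synthesizes the
    two-CJ classes with the Rule of 2 (value at L equals the one-CJ value
    at L/2).
    """
    bc = bc or BoundaryConditions(ADP_cyt=0.037)
    base = solve_steady_state(geo.build_no_crista_3d(h=h, n_cristae=n_cristae),
                              p, bc, tol=tol)
    j_max = base.j_AS
    mode_of = {"no_cj": "none", "one_narrow": "narrow", "one_wide": "wide"}
    curves: dict[str, FluxCurve] = {}
    for cls in ("no_cj", "one_narrow", "one_wide"):
        if cls not in classes and f"two_{cls.split('_')[1]}" not in classes:
            continue
        vals = []
        for L in lengths:
            m = geo.build_lamellar_3d(L, mode_of[cls], h=h, n_cristae=n_cristae)
            res = solve_steady_state(m, p, bc, tol=tol)
            ledger = (res.meta["S_IBM"], res.meta["S_CRIS"], res.meta["S_IM"])
            j_cris = decompose_flux(res.j_AS, ledger, j_max)
            vals.append(j_cris / j_max)
        curves[cls] = FluxCurve(topology=cls, lengths=np.array(lengths),
                                values=np.array(vals))
    if "two_narrow" in classes and "one_narrow" in curves:
        curves["two_narrow"] = _rule_of_two_curve(curves["one_narrow"], "two_narrow")
    if "two_wide" in classes and "one_wide" in curves:
        curves["two_wide"] = _rule_of_two_curve(curves["one_wide"], "two_wide")
    return {c: curves[c] for c in classes if c in curves}


_ENDS_TO_CLASS = {"none": "no_cj", "one": "one_narrow", "both": "two_narrow"}


def census_score(census: pd.DataFrame, curves: dict[str, FluxCurve],
                 class_override: str | None = None) -> float:
    """Whole-mitochondrion J/J_MAX as the length-weighted sum over cristae.

    Each crista contributes its curve value (class chosen from its CJ-end
    connectivity, or ``class_override`` / a ``class`` column) weighted by
    its relative membrane length, f_i = L_i / ΣL.  Lengths outside a
    curve's sampled range are flat-clamped.
    """
    if census is None or len(census) == 0:
        raise ValueError("census is empty")
    weights = census["length_um"].to_numpy(dtype=float)
    if np.any(weights <= 0):
        raise ValueError("census lengths must be > 0")
    f = weights / weights.sum()
    total = 0.0
    for frac, (_, row) in zip(f, census.iterrows()):
        if class_override is not None:
            cls = class_override
        elif "class" in census.columns and isinstance(row.get("class"), str) \
                and row["class"]:
            cls = row["class"]
        else:
            cls = _ENDS_TO_CLASS[str(row["cj_ends"])]
        if cls not in curves:
            raise KeyError(f"no flux curve for topology class {cls!r}")
        total += frac * float(curves[cls](float(row["length_um"])))
    return total
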