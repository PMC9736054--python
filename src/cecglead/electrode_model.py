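"""Capacitive electrode coupling and motion-artifact sensitivity.

A non-contact electrode couples to the body through the capacitance of
the insulating gap.  The electrode plate is equipotential, and with the
coupling admittance far below the body's, its potential is the
coupling-capacitance-weighted average of the body surface potential
under it:

    Ve = ∬ V·Ce dS / ∬ Ce dS,     Ce = ε0·εr / d

with d the local electrode–skin distance.  The frequency ω enters the
gap admittance jωCe but cancels in the ratio, so Ve is frequency-free.

Motion-artifact sensitivity follows the two limiting displacement
regimes: movement *normal* to the body perturbs Ce at fixed V, while
*tangential* slide samples V along the surface at fixed Ce, making the
sensitivity proportional to the tangential electric field.  Both are
computed as explicit finite differences of the Ve formula.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward_solver import SurfaceFieldMap
from .thorax_model import BoundarySurface, GeometryError, SurfacePatch, ThoraxMesh

__all__ = [
    "EPSILON_0",
    "CapacitiveElectrode",
    "ElectrodeCoupling",
    "plate_capacitance",
    "electrode_coupling",
    "electrode_potential",
    "displacement_sensitivity",
    "artifact_susceptibility",
]

EPSILON_0 = 8.8541878128e-12  # F/m


@dataclass(frozen=True)
class CapacitiveElectrode:
    """Circular capacitive electrode.

    Defaults follow the backrest setup modelled here: 2 cm diameter
    plate, 1 mm gap (a thin cotton layer, electrically air-dominated so
    εr = 1).  ``omega`` is the nominal angular signal frequency; it is
    carried for completeness but cancels from the potential formula.
    """

    center: tuple[float, float, float]
    radius: float = 0.01
    gap: float = 1.0e-3
    eps_r: float = 1.0
    omega: float = 2.0 * np.pi * 10.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("electrode radius must be > 0")
        if self.gap <= 0:
            raise ValueError("electrode gap must be > 0")
        if self.eps_r < 1:
            raise ValueError("relative permittivity must be >= 1")

    @property
    def area(self) -> float:
        return float(np.pi * self.radius**2)


def plate_capacitance(area: float, gap: float, eps_r: float = 1.0) -> float:
    """Parallel-plate capacitance C = ε0·εr·S/d."""
    if area <= 0 or gap <= 0:
        raise ValueError("area and gap must be > 0")
    if eps_r < 1:
        raise ValueError("relative permittivity must be >= 1")
    return EPSILON_0 * eps_r * area / gap


@dataclass
class ElectrodeCoupling:
    """Discrete coupling of one electrode to a surface patch.

    ``ce`` holds the per-vertex specific capacitance ε0εr/d (F/m²) and
    ``gap_profile`` the per-vertex plate–surface distance.  On a curved
    surface the rigid plate sits parallel to the local tangent plane at
    the nominal gap above the closest surface point, so the profile
    (and hence Ce) varies across the patch; on a flat patch it is
    uniform.
    """

    electrode: CapacitiveElectrode
    patch: SurfacePatch
    ce: np.ndarray
    gap_profile: np.ndarray
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(self.ce <= 0):
            raise GeometryError("non-positive specific capacitance")

    @property
    def total_capacitance(self) -> float:
        return float((self.ce * self.patch.weights).sum())

    def scaled_ce(self, factor: float) -> "ElectrodeCoupling":
        return ElectrodeCoupling(self.electrode, self.patch, factor * self.ce,
                                 self.gap_profile, list(self.warnings))


def _surface_of(obj) -> BoundarySurface:
    if isinstance(obj, ThoraxMesh):
        return obj.boundary
    if isinstance(obj, BoundarySurface):
        return obj
    raise TypeError("expected a ThoraxMesh or BoundarySurface")


def electrode_coupling(surface, electrode: CapacitiveElectrode,
                       gap_excursion: float = 0.0) -> ElectrodeCoupling:
    """Couple an electrode to the surface region under it.

    The patch is the set of boundary triangles whose centroid lies
    within the electrode radius of its centre (Euclidean distance — in
    the gap ≪ radius regime geodesic corrections are negligible).
    ``gap_excursion`` adds a rigid normal displacement of the plate, the
    mechanism used for gap-modulation motion artifacts.

    The model is stated for plates larger than their distance to the
    body; a violation is recorded as a warning, not an error.
    """
    surface = _surface_of(surface)
    center = np.asarray(electrode.center, float)
    dmin = np.linalg.norm(surface.vertices - center, axis=1).min()
    if dmin > 2.0 * electrode.radius:
        raise GeometryError(
            f"electrode centre is {dmin:.3g} m from the surface "
            f"(> 2 radii); no coupling")
    try:
        patch = surface.patch_within(center, electrode.radius)
    except GeometryError as exc:
        raise GeometryError(
            f"electrode at {center} couples to no surface triangle "
            f"(radius {electrode.radius} m vs local mesh size)") from exc
    # rigid plate parallel to the mean patch normal, at the nominal gap
    # above the closest surface point under it
    n = (surface.vertex_normals[patch.vertex_idx]
         * patch.weights[:, None]).sum(0)
    n /= np.linalg.norm(n)
    height = (patch.vertices - center) @ n
    gap = electrode.gap + gap_excursion
    if gap <= 0:
        raise GeometryError("plate displaced through the body surface")
    d = gap + (height.max() - height)
    warnings = []
    if gap >= 2.0 * electrode.radius:
        warnings.append(
            f"gap {gap:.3g} m >= electrode diameter "
            f"{2 * electrode.radius:.3g} m: outside the stated validity regime")
    ce = EPSILON_0 * electrode.eps_r / d
    return ElectrodeCoupling(electrode, patch, ce, d, warnings)


def electrode_potential(fieldmap: SurfaceFieldMap,
                        coupling: ElectrodeCoupling) -> float:
    """Electrode potential Ve: the Ce-weighted mean of V under the plate."""
    if coupling.patch.surface is not fieldmap.surface:
        raise ValueError("coupling patch and field map use different surfaces")
    w = coupling.ce * coupling.patch.weights
    denom = w.sum()
    if denom <= 0:
        raise GeometryError("zero total capacitance")
    return float((fieldmap.V[coupling.patch.vertex_idx] * w).sum() / denom)


def displacement_sensitivity(fieldmap: SurfaceFieldMap,
                             coupling: ElectrodeCoupling,
                             mode: str,
                             direction: np.ndarray | None = None,
                             step: float = 1.0e-4) -> float:
    """Finite-difference sensitivity ΔVe/Δs (V/m) to electrode motion.

    ``mode="normal"``: the plate retreats by ``step`` at fixed surface
    potential; only the gap profile (hence Ce) changes.  With a uniform
    gap the Ce rescaling cancels from the Ve ratio and the sensitivity
    is exactly zero.

    ``mode="tangential"``: the patch centre slides by ``step`` along
    ``direction`` projected onto the local tangent plane, at fixed gap;
    to first order this samples the tangential electric field under the
    electrode.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    ve0 = electrode_potential(fieldmap, coupling)
    el = coupling.electrode
    if mode == "normal":
        d = coupling.gap_profile + step
        ce = EPSILON_0 * el.eps_r / d
        shifted = ElectrodeCoupling(el, coupling.patch, ce, d)
        return (electrode_potential(fieldmap, shifted) - ve0) / step
    if mode == "tangential":
        if direction is None:
            raise ValueError("tangential mode needs a direction")
        direction = np.asarray(direction, float)
        surface = coupling.patch.surface
        n = (surface.vertex_normals[coupling.patch.vertex_idx]
             * coupling.patch.weights[:, None]).sum(0)
        n /= np.linalg.norm(n)
        t = direction - (direction @ n) * n
        tn = np.linalg.norm(t)
        if tn == 0:
            raise ValueError("direction is normal to the surface")
        t /= tn
        new_center = np.asarray(el.center, float) + step * t
        try:
            shifted = electrode_coupling(
                surface,
                CapacitiveElectrode(tuple(new_center), el.radius, el.gap,
                                    el.eps_r, el.omega))
        except GeometryError as exc:
            raise GeometryError(
                f"shifted electrode leaves the surface region: {exc}") from exc
        return (electrode_potential(fieldmap, shifted) - ve0) / step
    raise ValueError(f"unknown displacement mode {mode!r}")


def artifact_susceptibility(fieldmap: SurfaceFieldMap,
                            coupling: ElectrodeCoupling) -> float:
    """Motion-artifact susceptibility score (V/m).

    The magnitude of the coupling-weighted mean tangential field under
    the electrode: regions of high tangential field produce large Ve
    changes under slide motion, regions of low field are quiet.
    Invariant under uniform rescaling of Ce.
    """
    w = coupling.ce * coupling.patch.weights
    et = fieldmap.tangential[coupling.patch.vertex_idx]
    mean_vec = (et * w[:, None]).sum(0) / w.sum()
    return float(np.linalg.norm(mean_vec))
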