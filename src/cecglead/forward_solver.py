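"""Quasi-static forward ECG solver on labelled tetrahedral meshes.

The cardiac generator is an equivalent current dipole; the body is a
piecewise-homogeneous volume conductor.  The electric potential φ obeys
the Poisson problem ∇·σ∇φ = I_SV with I_SV = −∇·J_h and a homogeneous
Neumann condition ∂φ/∂n = 0 on the body surface (no current leaves the
body).  Discretization is standard P1 (linear) finite elements with
per-element constant conductivity; the pure-Neumann null space is fixed
by the zero-boundary-mean gauge, enforced with a single Lagrange
multiplier so lead voltages are gauge-free.

The dipole is realized as point monopole pairs ±I = ±|p|/δ separated by
δ and distributed to the vertices of their containing tetrahedra by
barycentric weights.  By default the dipole is split into three
axis-aligned monopole pairs (one per Cartesian moment component), which
makes the discrete load exactly linear in the moment vector — the
property the lead-field basis relies on.  A single pair aligned with
the moment direction is available via ``mode="aligned"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .thorax_model import BoundarySurface, GeometryError, ThoraxMesh

__all__ = [
    "DipoleSource",
    "PotentialSolution",
    "SurfaceFieldMap",
    "LeadFieldBasis",
    "SolverError",
    "angles_to_moment",
    "dipole_load",
    "solve_forward",
    "surface_field_map",
    "lead_field_basis",
]

DEFAULT_DELTA = 0.002  # m — monopole separation realizing the dipole


class SolverError(RuntimeError):
    """Linear solve failed to reach the requested residual."""


def angles_to_moment(magnitude: float, azimuth: float,
                     elevation: float) -> np.ndarray:
    """Dipole moment vector from magnitude and (azimuth, elevation).

    Azimuth is measured from the +x axis in the x–y plane; elevation is
    the polar angle from the +z axis.  With the body frame used here
    (x left→right shoulder, y back→front, z up), the reference heart
    axis has azimuth 5π/6 and elevation 3π/4.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    se, ce = np.sin(elevation), np.cos(elevation)
    return magnitude * np.array([se * np.cos(azimuth), se * np.sin(azimuth), ce])


@dataclass(frozen=True)
class DipoleSource:
    """Equivalent cardiac dipole: position (m) and moment vector (A·m)."""

    position: np.ndarray
    moment: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, float))
        object.__setattr__(self, "moment", np.asarray(self.moment, float))
        if self.position.shape != (3,) or self.moment.shape != (3,):
            raise ValueError("position and moment must be 3-vectors")

    @classmethod
    def from_angles(cls, position, magnitude: float, azimuth: float,
                    elevation: float) -> "DipoleSource":
        return cls(np.asarray(position, float),
                   angles_to_moment(magnitude, azimuth, elevation))

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.moment))


# --------------------------------------------------------------------------
# FEM machinery (assembled once per mesh, cached)
# --------------------------------------------------------------------------

class _FemOperator:
    """Stiffness matrix, element gradients and gauged factorization."""

    def __init__(self, mesh: ThoraxMesh):
        self.mesh = mesh
        v = mesh.vertices
        t = mesh.tets
        e = v[t[:, 1:]] - v[t[:, [0]]]          # (T,3,3) edge matrix rows
        minv = np.linalg.inv(e)                  # columns give ∇λ_{1..3}
        g123 = np.transpose(minv, (0, 2, 1))     # (T,3,3): rows ∇λ_1..3
        g0 = -g123.sum(axis=1, keepdims=True)
        self.grads = np.concatenate([g0, g123], axis=1)  # (T,4,3)
        vol = mesh.tet_volumes()
        sig = mesh.tet_conductivity()
        ke = np.einsum("tid,tjd->tij", self.grads, self.grads)
        ke *= (sig * vol)[:, None, None]
        rows = np.repeat(t, 4, axis=1).ravel()
        cols = np.tile(t, (1, 4)).ravel()
        n = len(v)
        self.stiffness = sp.coo_matrix(
            (ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
        # gauge vector: boundary vertex area weights, normalized to sum 1
        a = np.zeros(n)
        b = mesh.boundary
        a[b.mesh_vertex_ids] = b.vertex_areas
        self.gauge = a / a.sum()
        bordered = sp.bmat(
            [[self.stiffness, self.gauge[:, None]],
             [self.gauge[None, :], None]], format="csc")
        self._lu = spla.splu(bordered)

    def solve(self, load: np.ndarray, rtol: float = 1e-8) -> np.ndarray:
        rhs = np.concatenate([load, [0.0]])
        x = self._lu.solve(rhs)
        phi = x[:-1]
        scale = np.linalg.norm(load)
        if scale > 0:
            res = self.stiffness @ phi + self.gauge * x[-1] - load
            rel = np.linalg.norm(res) / scale
            if rel > rtol:
                raise SolverError(f"linear solve residual {rel:.2e} > {rtol:g}")
        return phi


def _fem(mesh: ThoraxMesh) -> _FemOperator:
    op = getattr(mesh, "_fem_operator", None)
    if op is None:
        op = _FemOperator(mesh)
        mesh._fem_operator = op
    return op


# --------------------------------------------------------------------------
# dipole load
# --------------------------------------------------------------------------

def _add_monopole(mesh: ThoraxMesh, load: np.ndarray, pos: np.ndarray,
                  current: float, which: str) -> None:
    try:
        tid, lam = mesh.locate(pos)
    except GeometryError as exc:
        raise GeometryError(f"{which} monopole at {pos} outside mesh") from exc
    load[mesh.tets[tid]] += current * lam


def dipole_load(mesh: ThoraxMesh, source: DipoleSource,
                delta: float = DEFAULT_DELTA, mode: str = "split") -> np.ndarray:
    """Per-vertex current load (A) realizing the dipole.

    ``mode="split"`` (default) uses one ±|p_k|/δ monopole pair per
    Cartesian moment component, exactly linear in the moment.
    ``mode="aligned"`` uses a single pair along the moment direction.
    Either way the load sums to zero (source/sink cancellation), the
    compatibility condition of the pure-Neumann problem, and reproduces
    the requested first moment exactly.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    load = np.zeros(len(mesh.vertices))
    m = source.moment
    p = np.linalg.norm(m)
    if p == 0:
        return load
    if mode == "aligned":
        u = m / p
        cur = p / delta
        _add_monopole(mesh, load, source.position + 0.5 * delta * u, cur, "positive")
        _add_monopole(mesh, load, source.position - 0.5 * delta * u, -cur, "negative")
    elif mode == "split":
        for k in range(3):
            if m[k] == 0.0:
                continue
            off = np.zeros(3)
            off[k] = 0.5 * delta
            cur = m[k] / delta
            _add_monopole(mesh, load, source.position + off, cur, f"+{'xyz'[k]}")
            _add_monopole(mesh, load, source.position - off, -cur, f"-{'xyz'[k]}")
    else:
        raise ValueError(f"unknown dipole mode {mode!r}")
    total = np.abs(load.sum())
    if total > 1e-12 * (p / delta):
        raise SolverError(f"incompatible load: net current {total:.3e} A")
    return load


# --------------------------------------------------------------------------
# solutions and surface fields
# --------------------------------------------------------------------------

@dataclass
class PotentialSolution:
    """FEM potential (V) at every mesh vertex under the declared gauge."""

    phi: np.ndarray
    mesh: ThoraxMesh
    source: DipoleSource | None
    gauge: str = "zero-boundary-mean"

    @property
    def boundary_phi(self) -> np.ndarray:
        return self.phi[self.mesh.boundary.mesh_vertex_ids]

    def boundary_mean(self) -> float:
        b = self.mesh.boundary
        w = b.vertex_areas
        return float((self.boundary_phi * w).sum() / w.sum())


@dataclass
class SurfaceFieldMap:
    """Potential and electric field sampled at boundary vertices.

    ``E`` is the full field −∇φ averaged onto vertices; ``tangential``
    is E minus its component along the outward vertex normal — the part
    that drives slide-type motion artifacts.
    """

    surface: BoundarySurface
    V: np.ndarray
    E: np.ndarray
    tangential: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, float)
        self.E = np.asarray(self.E, float)
        n = self.surface.vertex_normals
        self.tangential = self.E - (np.einsum("ij,ij->i", self.E, n)[:, None] * n)

    def scaled(self, factor: float) -> "SurfaceFieldMap":
        return SurfaceFieldMap(self.surface, factor * self.V, factor * self.E)


def solve_forward(mesh: ThoraxMesh, source: DipoleSource,
                  delta: float = DEFAULT_DELTA,
                  mode: str = "split") -> PotentialSolution:
    """Solve the Neumann forward problem for one dipole source."""
    load = dipole_load(mesh, source, delta=delta, mode=mode)
    phi = _fem(mesh).solve(load)
    return PotentialSolution(phi, mesh, source)


def surface_field_map(solution: PotentialSolution) -> SurfaceFieldMap:
    """Sample φ and E = −∇φ on the boundary.

    The P1 gradient is constant per tet; each boundary triangle
    contributes its owning tet's field to its three vertices with
    one-third of the triangle area as weight.
    """
    mesh = solution.mesh
    fem = _fem(mesh)
    b = mesh.boundary
    etet = -np.einsum("tid,ti->td", fem.grads[mesh.boundary_owner],
                      solution.phi[mesh.tets[mesh.boundary_owner]])
    ev = np.zeros((b.n_vertices, 3))
    wsum = np.zeros(b.n_vertices)
    w = b.triangle_areas / 3.0
    for k in range(3):
        np.add.at(ev, b.triangles[:, k], w[:, None] * etet)
        np.add.at(wsum, b.triangles[:, k], w)
    ev /= wsum[:, None]
    return SurfaceFieldMap(b, solution.boundary_phi, ev)


# --------------------------------------------------------------------------
# lead-field basis
# --------------------------------------------------------------------------

class LeadFieldBasis:
    """Unit-moment solutions at a fixed source position.

    By linearity of the forward problem (and of the split dipole load),
    the solution for any moment m is m·(basis solutions); time-varying
    dipoles therefore need no re-solve.
    """

    def __init__(self, mesh: ThoraxMesh, position: np.ndarray,
                 delta: float = DEFAULT_DELTA):
        self.mesh = mesh
        self.position = np.asarray(position, float)
        self.delta = delta
        fem = _fem(mesh)
        sols = []
        for k in range(3):
            m = np.zeros(3)
            m[k] = 1.0
            src = DipoleSource(self.position, m)
            sols.append(PotentialSolution(
                fem.solve(dipole_load(mesh, src, delta=delta, mode="split")),
                mesh, src))
        self.solutions = sols
        self.field_maps = [surface_field_map(s) for s in sols]
        # (3, n_boundary) unit-moment boundary potentials
        self.boundary_basis = np.stack([s.boundary_phi for s in sols])

    def potential(self, moment: np.ndarray) -> np.ndarray:
        """Full-volume potential for an arbitrary moment vector."""
        moment = np.asarray(moment, float)
        return sum(moment[k] * self.solutions[k].phi for k in range(3))

    def solution(self, moment: np.ndarray) -> PotentialSolution:
        src = DipoleSource(self.position, np.asarray(moment, float))
        return PotentialSolution(self.potential(moment), self.mesh, src)

    def field_map(self, moment: np.ndarray) -> SurfaceFieldMap:
        moment = np.asarray(moment, float)
        V = moment @ self.boundary_basis
        E = np.tensordot(moment, np.stack([f.E for f in self.field_maps]), axes=1)
        return SurfaceFieldMap(self.mesh.boundary, V, E)

    def boundary_potential_series(self, moments: np.ndarray,
                                  vertex_idx: np.ndarray | None = None) -> np.ndarray:
        """Boundary potentials for a (n, 3) moment time series.

        Returns an (n, n_vertices) array; ``vertex_idx`` restricts to a
        subset of boundary vertices (e.g. an electrode patch).
        """
        basis = self.boundary_basis
        if vertex_idx is not None:
            basis = basis[:, vertex_idx]
        return np.asarray(moments, float) @ basis


def lead_field_basis(mesh: ThoraxMesh, position,
                     delta: float = DEFAULT_DELTA) -> LeadFieldBasis:
    return LeadFieldBasis(mesh, position, delta=delta)
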