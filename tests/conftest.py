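"""Shared fixtures: oracle sphere meshes and a desk-scale thorax study.

Heavy objects (meshes, factorized forward operators) are session-scoped
so the whole suite builds each of them once.
"""

import numpy as np
import pytest

from cecglead import (CapacitiveElectrode, CardiacCycleModel, DipoleSource,
                      MotionEventModel, add_motion_artifact, add_noise,
                      build_homogeneous_sphere, build_synthetic_thorax,
                      calibrated_noise_sigma, downsample_averaging,
                      electrode_coupling, extract_back_patch,
                      lead_field_basis, optimize_lead, simulate_lead_signal,
                      solve_forward, surface_field_map)

SPHERE_R = 0.1       # m
SPHERE_SIGMA = 0.2   # S/m
DIPOLE_P = 2.0e-5    # A·m


@pytest.fixture(scope="session")
def sphere_mesh():
    """~60k-tet homogeneous ball, the analytic dipole-in-sphere oracle."""
    return build_homogeneous_sphere(SPHERE_R, SPHERE_SIGMA, resolution=0.008)


@pytest.fixture(scope="session")
def sphere_mesh_coarse():
    """~25k-tet ball: one refinement step below the oracle mesh."""
    return build_homogeneous_sphere(SPHERE_R, SPHERE_SIGMA, resolution=0.011)


@pytest.fixture(scope="session")
def z_dipole():
    return DipoleSource((0.0, 0.0, 0.0), (0.0, 0.0, DIPOLE_P))


@pytest.fixture(scope="session")
def sphere_solution(sphere_mesh, z_dipole):
    return solve_forward(sphere_mesh, z_dipole)


@pytest.fixture(scope="session")
def sphere_fieldmap(sphere_solution):
    return surface_field_map(sphere_solution)


def sphere_analytic_boundary(mesh, p=DIPOLE_P, sigma=SPHERE_SIGMA, R=SPHERE_R):
    """Closed form φ(R,θ) = 3p·cosθ/(4πσR²) for a centred z-dipole,
    area-weight de-meaned to match the solver gauge."""
    b = mesh.boundary
    ct = b.vertices[:, 2] / np.linalg.norm(b.vertices, axis=1)
    ana = 3.0 * p * ct / (4.0 * np.pi * sigma * R**2)
    w = b.vertex_areas
    return ana - (ana * w).sum() / w.sum()


@pytest.fixture(scope="session")
def thorax_study():
    """Desk-scale thorax study: mesh, basis, R-instant field, optimal lead."""
    mesh = build_synthetic_thorax(resolution=0.02, surface_resolution=0.011)
    source = DipoleSource.from_angles((0.1, 0.03, 0.0), DIPOLE_P,
                                      5 * np.pi / 6, 3 * np.pi / 4)
    basis = lead_field_basis(mesh, source.position)
    fieldmap = basis.field_map(source.moment)
    patch = extract_back_patch(mesh, 0.35, z_band=(-0.16, 0.16))
    scores = optimize_lead(mesh, source, patch, spacing=0.02,
                           fieldmap=fieldmap)
    best = scores[0]
    model = CardiacCycleModel.default()
    return {
        "mesh": mesh, "source": source, "basis": basis,
        "fieldmap": fieldmap, "patch": patch, "scores": scores,
        "best": best, "model": model,
        "coupling_a": electrode_coupling(mesh, best.config.electrode_a),
        "coupling_b": electrode_coupling(mesh, best.config.electrode_b),
    }


def synthesize_study_trace(study, seed, duration=900.0, target_snr_db=21.0,
                           motion_rate=2.0, coupling_a=None, coupling_b=None,
                           sigma=None):
    """One acquisition-chain trace under the study conditions.

    2.3 kHz native rate, gap-modulation motion events on both
    electrodes, averaging downsample to 72 Hz, then white noise
    calibrated to the target SNR (or a fixed ``sigma``).
    """
    ca = coupling_a if coupling_a is not None else study["coupling_a"]
    cb = coupling_b if coupling_b is not None else study["coupling_b"]
    tr = simulate_lead_signal(study["basis"], ca, cb, study["model"],
                              duration, 2300.0)
    for coup, sign, off in ((ca, 1.0, 0), (cb, -1.0, 7919)):
        ev = MotionEventModel(rate_per_min=motion_rate, excursion=5.0e-4,
                              seed=seed + off)
        tr = add_motion_artifact(tr, study["basis"], study["model"], coup,
                                 ev, sign=sign)
    tr = downsample_averaging(tr, 72.0)
    if sigma is None:
        sigma = calibrated_noise_sigma(tr, target_snr_db)
    return add_noise(tr, sigma, seed=seed), sigma
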