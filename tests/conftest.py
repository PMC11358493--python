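"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from alphadose3d import AC225_CHAIN, bin_kernel_to_voxels, generate_csda_kernel


@pytest.fixture(scope="session")
def chain():
    return AC225_CHAIN


@pytest.fixture(scope="session")
def radial_kernel():
    return generate_csda_kernel(AC225_CHAIN, radial_step=1.0)


@pytest.fixture(scope="session")
def voxel_kernel(radial_kernel):
    return bin_kernel_to_voxels(radial_kernel, (39.0, 39.0, 10.0))


@pytest.fixture(scope="session")
def iso_kernel(radial_kernel):
    """Isotropic 20-um kernel for small 3D convolution tests."""
    return bin_kernel_to_voxels(radial_kernel, (20.0, 20.0, 20.0))


def bateman_ratio_ode(r0: float, t: float, lam_a: float, lam_b: float) -> float:
    """Daughter/parent activity ratio by numerical ODE integration.

    Independent of the closed forms under test: integrates the
    two-nuclide Bateman system dNa/dt = -la Na, dNb/dt = la Na - lb Nb
    with initial numbers chosen to realize the requested activity ratio.
    """
    na0 = 1.0
    nb0 = r0 * lam_a * na0 / lam_b  # Ab(0)/Aa(0) = r0
    sol = solve_ivp(
        lambda _, y: [-lam_a * y[0], lam_a * y[0] - lam_b * y[1]],
        (0.0, t),
        [na0, nb0],
        rtol=1e-11,
        atol=1e-16,
        dense_output=True,
    )
    na, nb = sol.y[:, -1]
    return (lam_b * nb) / (lam_a * na)


def gamma_exhaustive(ref, ev, dose_tol, dist_tol_um, pixel_um, normalization="local"):
    """Brute-force gamma map: exhaustive search over every eval pixel."""
    ny, nx = ref.shape
    d_norm_global = ref.max()
    gamma = np.zeros_like(ref, dtype=float)
    ii, jj = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    for i in range(ny):
        for j in range(nx):
            d_norm = ref[i, j] if normalization == "local" else d_norm_global
            dist = np.hypot(ii - i, jj - j) * pixel_um
            with np.errstate(divide="ignore", invalid="ignore"):
                dd = (ev - ref[i, j]) / (dose_tol * d_norm)
            g2 = dd**2 + (dist / dist_tol_um) ** 2
            gamma[i, j] = np.sqrt(np.nanmin(g2))
    return gamma
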