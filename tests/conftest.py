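"""Shared fixtures: phantoms, tips and simulated topographs.

Everything is generated programmatically; module-scoped fixtures keep
the simulation work shared across tests.
"""

import numpy as np
import pytest

from afmfibril.helical import extend_helical
from afmfibril.phantoms import CrossSectionSpec, make_phantom, simulate_noisy_afm
from afmfibril.tipsim import TipModel


@pytest.fixture(scope="session")
def tip5() -> TipModel:
    return TipModel(radius_nm=5.0, half_angle_deg=18.0)


@pytest.fixture(scope="session")
def ellipse_phantom():
    """C2 elliptical phantom (a=4, b=2 nm), left-handed, cod 50 nm."""
    spec = CrossSectionSpec(kind="ellipse", a=4.0, b=2.0)
    return make_phantom(
        spec, twist_deg=-360 / (2 * 50.0) * 0.47, rise_nm=0.47,
        length_nm=40.0, voxel_nm=0.5, label="c2_ellipse", with_volume=True,
    )


@pytest.fixture(scope="session")
def c1_phantom():
    """Asymmetric C1 phantom with the screw axis off the centre of mass."""
    spec = CrossSectionSpec(kind="fourier", r0=3.0,
                            harmonics={1: (0.35, 0.3), 2: (0.12, 1.0)})
    return make_phantom(
        spec, twist_deg=-360 / 55.0 * 0.47, rise_nm=0.47,
        length_nm=40.0, voxel_nm=0.5, label="c1_fourier", with_volume=True,
    )


@pytest.fixture(scope="session")
def ellipse_topograph(ellipse_phantom, tip5):
    """Noise-free simulated topograph of the extended C2 phantom."""
    ext = extend_helical(
        ellipse_phantom.surface, ellipse_phantom.surface.helical,
        2.6 * ellipse_phantom.truth.cod_nm,
    )
    return simulate_noisy_afm(ext, tip5, pixel_nm=1.0)


@pytest.fixture(scope="session")
def c1_topograph(c1_phantom, tip5):
    ext = extend_helical(
        c1_phantom.surface, c1_phantom.surface.helical,
        2.6 * c1_phantom.truth.cod_nm,
    )
    return simulate_noisy_afm(ext, tip5, pixel_nm=1.0)


def cylinder_surface(radius_nm: float, length_nm: float, step_nm: float = 0.25,
                     axis: str = "z") -> np.ndarray:
    """Dense point cloud of a cylinder along the chosen axis (resting frame
    for 'y': lowest point at z=0)."""
    t = np.linspace(0, 2 * np.pi, max(int(2 * np.pi * radius_nm / step_nm), 36),
                    endpoint=False)
    zs = np.arange(0.0, length_nm + step_nm / 2, step_nm)
    ring_x = radius_nm * np.cos(t)
    ring_y = radius_nm * np.sin(t)
    pts = []
    for z in zs:
        if axis == "z":
            pts.append(np.column_stack([ring_x, ring_y, np.full_like(t, z)]))
        elif axis == "y":
            pts.append(
                np.column_stack([ring_x, np.full_like(t, z), radius_nm + ring_y])
            )
        elif axis == "x":
            pts.append(np.column_stack([np.full_like(t, z), ring_x, ring_y]))
    return np.vstack(pts)
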