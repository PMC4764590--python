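import numpy as np
import pytest

import untwist as ut


@pytest.fixture(scope="session")
def bent_twisted_phantom():
    """Rendered phantom with a 180° bend and 90° twist (SNR 10)."""
    return ut.make_phantom(n_pairs=10, length=60, bend_angle=np.pi,
                           twist_total=np.pi / 2, r_head=7, r_tail=5,
                           voxel_size=1.0, noise_snr=10, seed=1)


@pytest.fixture(scope="session")
def straight_phantom():
    """Rendered straight, untwisted phantom (noiseless)."""
    return ut.make_phantom(n_pairs=10, length=60, bend_angle=0.0,
                           twist_total=0.0, r_head=7, r_tail=7,
                           voxel_size=1.0, noise_snr=np.inf, seed=2)


@pytest.fixture(scope="session")
def geometry_phantom():
    """Geometry-only phantom (no volume): 180° bend, 360° twist, 120 µm."""
    return ut.make_phantom(n_pairs=10, length=120, bend_angle=np.pi,
                           twist_total=2 * np.pi, render=False, seed=3)


@pytest.fixture(scope="session")
def straight_lattice():
    """Straight 11-pair lattice spanning 100 µm with constant width 10 µm."""
    z = np.linspace(0.0, 100.0, 11)
    left = np.stack([np.full(11, -5.0), np.zeros(11), z], axis=1)
    right = np.stack([np.full(11, 5.0), np.zeros(11), z], axis=1)
    return ut.Lattice(left, right)


@pytest.fixture(scope="session")
def semicircle_lattice():
    """Lattice whose midline is a semicircle of radius 50 µm (length πR)."""
    R = 50.0
    th = np.linspace(0, np.pi, 11)
    mid = np.stack([R * np.sin(th), np.zeros_like(th), R * (1 - np.cos(th))], axis=1)
    off = np.array([0.0, 5.0, 0.0])    # width along y, out of the bend plane
    return ut.Lattice(mid - off, mid + off), R
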