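"""Shared fixtures: canonical outlines and independent oracles."""

import numpy as np
import pytest

from morphodisp import Outline


def circle_points(n: int = 512, radius: float = 1.0) -> np.ndarray:
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return radius * np.column_stack([np.cos(t), np.sin(t)])


def random_smooth_outline(rng: np.random.Generator, n: int = 300) -> Outline:
    """Random star-shaped outline (radial Fourier series, always simple)."""
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    r = np.ones_like(t)
    for k in range(1, 6):
        r += rng.uniform(-0.08, 0.08) * np.cos(k * t)
        r += rng.uniform(-0.08, 0.08) * np.sin(k * t)
    return Outline(f"rand{rng.integers(1 << 30)}", np.column_stack([r * np.cos(t), r * np.sin(t)]))


def efd_integral_oracle(outline: Outline, n_harmonics: int, samples: int = 10_000) -> np.ndarray:
    """Independent oracle: trapezoid integration of the Fourier integrals.

    a_n = (2/T) int x(t) cos(2 pi n t / T) dt over the arc-length
    parameterized piecewise-linear contour; likewise b, c, d.
    """
    pts = outline.points
    closed = np.vstack([pts, pts[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    T = t[-1]
    s = np.linspace(0.0, T, samples + 1)
    x = np.interp(s, t, closed[:, 0])
    y = np.interp(s, t, closed[:, 1])
    out = []
    for n in range(1, n_harmonics + 1):
        c = np.cos(2.0 * np.pi * n * s / T)
        sn = np.sin(2.0 * np.pi * n * s / T)
        out.append(
            [
                2.0 / T * np.trapezoid(x * c, s),
                2.0 / T * np.trapezoid(x * sn, s),
                2.0 / T * np.trapezoid(y * c, s),
                2.0 / T * np.trapezoid(y * sn, s),
            ]
        )
    return np.array(out)


def similarity_transform(
    pts: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Random rotation + scale + translation + starting-point roll."""
    th = rng.uniform(0.0, 2.0 * np.pi)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    q = pts @ R.T * rng.uniform(0.3, 4.0) + rng.normal(0.0, 10.0, size=2)
    return np.roll(q, rng.integers(len(pts)), axis=0)


@pytest.fixture
def unit_square() -> Outline:
    return Outline("square", np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]))


@pytest.fixture
def circle() -> Outline:
    return Outline("circle", circle_points())


@pytest.fixture
def ellipse() -> Outline:
    t = np.linspace(0.0, 2.0 * np.pi, 2000, endpoint=False)
    return Outline("ellipse", np.column_stack([2.0 * np.cos(t), np.sin(t)]))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230913)
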