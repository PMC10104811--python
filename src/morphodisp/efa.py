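"""Elliptic Fourier analysis of closed outlines.

A closed outline traversed at uniform speed decomposes into a series of
harmonically related ellipses.  For a polygon with segment steps
``(dx_p, dy_p)``, lengths ``dt_p``, cumulative arc length ``t_p`` and
perimeter ``T``, harmonic ``n`` contributes four coefficients

    a_n = T / (2 n^2 pi^2) * sum_p (dx_p/dt_p) [cos(2 pi n t_p / T) - cos(2 pi n t_{p-1} / T)]

with ``b_n`` using sines and ``c_n, d_n`` the same expressions on ``dy``.
Two constants ``(A0, C0)`` locate the outline centroid.  This is the
classic chain-code harmonics formulation used throughout outline-based
morphometrics.

Normalisation on the first harmonic removes digitisation starting point,
rotation and size, leaving descriptors (NEFDs) that depend on shape alone;
these are the features the downstream morphospace PCA consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .outline_io import Outline, ValidationError

__all__ = [
    "EFDSet",
    "NEFDSet",
    "compute_efd",
    "normalize_efd",
    "reconstruct",
    "coefficient_matrix",
    "feature_columns",
]

DEFAULT_HARMONICS = 20


@dataclass
class EFDSet:
    """Raw elliptic Fourier descriptors of one specimen.

    ``coeffs`` has shape (N, 4) with columns (a_n, b_n, c_n, d_n); ``dc``
    is (A0, C0).  Translating the input outline changes only ``dc``.
    """

    specimen_id: str
    coeffs: np.ndarray
    dc: np.ndarray
    perimeter: float
    group: str = ""
    time_slice: str = "other"

    @property
    def n_harmonics(self) -> int:
        return len(self.coeffs)

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.dc = np.asarray(self.dc, dtype=float)
        if self.coeffs.ndim != 2 or self.coeffs.shape[1] != 4:
            raise ValueError("coeffs must have shape (N, 4)")
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError(f"{self.specimen_id}: non-finite coefficients")
        if self.perimeter <= 0:
            raise ValueError(f"{self.specimen_id}: non-positive perimeter")


@dataclass
class NEFDSet(EFDSet):
    """Normalised descriptors plus the normalisation record.

    After normalisation a_1 = 1 and b_1 = c_1 = 0; |d_1| <= 1 is the
    aspect ratio of the first-harmonic ellipse.  ``scale`` is the
    semi-major axis E* divided out, ``psi`` the removed rotation, ``theta``
    the removed starting-point phase (radians), ``reflected`` whether the
    optional reflection alignment fired.
    """

    scale: float = 1.0
    psi: float = 0.0
    theta: float = 0.0
    reflected: bool = False


def compute_efd(outline: Outline, n_harmonics: int = DEFAULT_HARMONICS) -> EFDSet:
    """Compute elliptic Fourier descriptors of a closed outline.

    Exact for the polygonal contour (the integrals are evaluated in closed
    form segment by segment), deterministic for fixed input.
    """
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    pts = outline.points
    d = np.roll(pts, -1, axis=0) - pts
    dt = np.hypot(d[:, 0], d[:, 1])
    if np.any(dt == 0):
        raise ValidationError(f"{outline.specimen_id}: zero-length segment")
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    if T <= 0:
        raise ValidationError(f"{outline.specimen_id}: zero perimeter")

    n = np.arange(1, n_harmonics + 1)[:, None]  # (N, 1)
    phi = (2.0 * np.pi / T) * t[None, :]  # (1, K+1)
    cosnphi = np.cos(n * phi)
    sinnphi = np.sin(n * phi)
    dcos = cosnphi[:, 1:] - cosnphi[:, :-1]  # (N, K)
    dsin = sinnphi[:, 1:] - sinnphi[:, :-1]
    const = T / (2.0 * (n.ravel() ** 2) * np.pi**2)
    vx = d[:, 0] / dt
    vy = d[:, 1] / dt
    a = const * (dcos @ vx)
    b = const * (dsin @ vx)
    c = const * (dcos @ vy)
    dd = const * (dsin @ vy)

    # DC component: arc-length centroid of the contour
    xi = np.concatenate([[0.0], np.cumsum(d[:-1, 0])]) - vx * t[:-1]
    delta = np.concatenate([[0.0], np.cumsum(d[:-1, 1])]) - vy * t[:-1]
    dt2 = t[1:] ** 2 - t[:-1] ** 2
    a0 = pts[0, 0] + (np.sum(vx / 2.0 * dt2) + np.sum(xi * dt)) / T
    c0 = pts[0, 1] + (np.sum(vy / 2.0 * dt2) + np.sum(delta * dt)) / T

    return EFDSet(
        specimen_id=outline.specimen_id,
        coeffs=np.column_stack([a, b, c, dd]),
        dc=np.array([a0, c0]),
        perimeter=T,
        group=outline.group,
        time_slice=outline.time_slice,
    )


def _rotation(angle: float) -> np.ndarray:
    ca, sa = np.cos(angle), np.sin(angle)
    return np.array([[ca, -sa], [sa, ca]])


def normalize_efd(efd: EFDSet, allow_reflection: bool = False) -> NEFDSet:
    """Normalise descriptors on the first-harmonic ellipse.

    The starting-point phase theta = 1/2 atan2(2(a1 b1 + c1 d1),
    a1^2 + c1^2 - b1^2 - d1^2) aligns the parameter origin with the
    first ellipse's major axis; harmonic n is rotated in parameter by
    n*theta.  The spatial rotation psi = atan2(c1*, a1*) is then removed
    from every harmonic and all coefficients divided by the semi-major
    axis length E*.

    theta has two pi-separated solutions (the two ends of the major
    axis); they yield normalised coefficients differing only in the sign
    of the even harmonics.  The residual ambiguity is broken
    shape-intrinsically — the leading even-harmonic coefficient (first
    entry of a2, b2, c2, d2, a4, ... exceeding 1e-7 in magnitude) is made
    positive — so the result is deterministic and invariant to the input's
    orientation, size, position and starting point.

    With ``allow_reflection``, a negative normalised d_1 is flipped by
    negating b_n and d_n throughout (mirror alignment, as offered by the
    classic outline-analysis GUIs); default off, assuming specimens are
    digitised in consistent aspect.
    """
    A = efd.coeffs
    a1, b1, c1, d1 = A[0]
    e_major = a1 * a1 + c1 * c1
    e_minor = b1 * b1 + d1 * d1
    if e_major + e_minor <= 0:
        raise ValidationError(f"{efd.specimen_id}: degenerate first harmonic")
    theta = 0.5 * np.arctan2(2.0 * (a1 * b1 + c1 * d1), e_major - e_minor)

    n = np.arange(1, efd.n_harmonics + 1)
    As = A.reshape(-1, 2, 2)  # harmonic n as [[a, b], [c, d]]

    def apply(theta_val: float) -> np.ndarray:
        cn, sn = np.cos(n * theta_val), np.sin(n * theta_val)
        rot = np.empty((len(n), 2, 2))
        rot[:, 0, 0] = cn
        rot[:, 0, 1] = -sn
        rot[:, 1, 0] = sn
        rot[:, 1, 1] = cn
        return As @ rot

    B = apply(theta)
    a1s, c1s = B[0, 0, 0], B[0, 1, 0]
    psi = np.arctan2(c1s, a1s)
    scale = np.hypot(a1s, c1s)
    if scale <= 0:
        raise ValidationError(f"{efd.specimen_id}: degenerate first harmonic")
    C = (_rotation(-psi) @ B) / scale
    coeffs = C.reshape(-1, 4)

    # resolve the theta vs theta + pi ambiguity: it flips the sign of the
    # even harmonics only, so fix the leading even-harmonic entry positive
    if efd.n_harmonics >= 2:
        even = coeffs[1::2].ravel()
        lead = even[np.abs(even) > 1e-7]
        if len(lead) and lead[0] < 0:
            coeffs = coeffs.copy()
            coeffs[1::2] *= -1.0
            theta += np.pi
            psi += np.pi

    reflected = False
    if allow_reflection and coeffs[0, 3] < 0:
        coeffs = coeffs * np.array([1.0, -1.0, 1.0, -1.0])
        reflected = True

    return NEFDSet(
        specimen_id=efd.specimen_id,
        coeffs=coeffs,
        dc=efd.dc.copy(),
        perimeter=efd.perimeter,
        group=efd.group,
        time_slice=efd.time_slice,
        scale=float(scale),
        psi=float(psi),
        theta=float(theta),
        reflected=reflected,
    )


def reconstruct(
    efd: EFDSet,
    n_points: int = 200,
    harmonics_used: int | None = None,
    include_dc: bool = True,
) -> Outline:
    """Inverse transform: sample the truncated harmonic series.

    x(t) = A0 + sum_n a_n cos(2 pi n t / T) + b_n sin(2 pi n t / T),
    y(t) analogously with c_n, d_n, at ``n_points`` equally spaced t.
    """
    N = efd.n_harmonics
    if harmonics_used is None:
        harmonics_used = N
    if not 1 <= harmonics_used <= N:
        raise ValueError(f"harmonics_used must be in [1, {N}]")
    n = np.arange(1, harmonics_used + 1)[:, None]
    t = np.linspace(0.0, 1.0, n_points, endpoint=False)[None, :]
    cosnt = np.cos(2.0 * np.pi * n * t)
    sinnt = np.sin(2.0 * np.pi * n * t)
    a, b, c, d = (efd.coeffs[:harmonics_used, i][:, None] for i in range(4))
    x = np.sum(a * cosnt + b * sinnt, axis=0)
    y = np.sum(c * cosnt + d * sinnt, axis=0)
    if include_dc:
        x = x + efd.dc[0]
        y = y + efd.dc[1]
    return Outline(
        specimen_id=efd.specimen_id,
        points=np.column_stack([x, y]),
        group=efd.group,
        time_slice=efd.time_slice,
        provenance=f"reconstructed:{harmonics_used}h",
    )


def feature_columns(n_harmonics: int) -> list[str]:
    """Column names of the PCA feature matrix: d1 then a2..dN."""
    cols = ["d1"]
    for h in range(2, n_harmonics + 1):
        cols += [f"a{h}", f"b{h}", f"c{h}", f"d{h}"]
    return cols


def coefficient_matrix(nefds: list[NEFDSet]) -> pd.DataFrame:
    """Assemble the per-specimen feature matrix for the morphospace PCA.

    One row per specimen; the constants a_1 = 1, b_1 = c_1 = 0 are
    dropped, d_1 (first-ellipse aspect ratio) is kept, giving 4N - 3
    feature columns preceded by specimen_id, group, time_slice metadata.
    """
    if not nefds:
        raise ValueError("empty NEFD list")
    N = nefds[0].n_harmonics
    if any(e.n_harmonics != N for e in nefds):
        counts = sorted({e.n_harmonics for e in nefds})
        raise ValueError(f"mixed harmonic counts: {counts}")
    rows = np.vstack([e.coeffs.ravel()[3:] for e in nefds])
    meta = pd.DataFrame(
        {
            "specimen_id": [e.specimen_id for e in nefds],
            "group": [e.group for e in nefds],
            "time_slice": [e.time_slice for e in nefds],
        }
    )
    feats = pd.DataFrame(rows, columns=feature_columns(N))
    return pd.concat([meta, feats], axis=1)
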