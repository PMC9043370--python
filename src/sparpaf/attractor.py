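"""Symmetric Projection Attractor Reconstruction (SPAR).

A roughly periodic signal x(t) is delay-embedded as triples
(x(t), x(t - tau), x(t - 2 tau)) with tau equal to one third of the mean
cardiac cycle length, then projected onto the plane orthogonal to the
(1,1,1) diagonal:

    v = (x + y - 2 z) / sqrt(6),    w = (x - y) / sqrt(2)

for the triple (x, y, z).  The projection removes any constant (vertical)
offset of the signal exactly, and with tau = period/3 a strictly periodic
signal produces a point set invariant under rotation by 2 pi / 3, which is
the characteristic 3-fold symmetry of the attractor.  Negating the signal
rotates the attractor by pi, which is the signature used to diagnose a
sign-flip acquisition artefact from the angular density of the attractor
core.

The attractor is summarized by a normalized 2-D density image and by polar
density profiles: a radial density over r = sqrt(v^2 + w^2) and two angular
densities, one for the high-density central core (r <= r_c) and one for the
low-density arms (r > r_c), where the core radius r_c is the radius
enclosing a configured fraction of the points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import EmbeddingError, ParameterError
from .preprocess import SubStrip

__all__ = [
    "AttractorPoints",
    "AttractorImage",
    "DensityProfile",
    "embed",
    "embed_samples",
    "density_image",
    "compute_core_radius",
    "density_profiles",
    "profile_band_summary",
    "detect_sign_flip",
    "rotation_angle_between",
]

DEFAULT_N_BINS = 101
DEFAULT_N_ANGLE_BINS = 120
DEFAULT_N_R_BINS = 100


@dataclass
class AttractorPoints:
    """The (v, w)-plane point set of the SPAR projection."""

    tau: float  # delay in seconds (mean RR / 3)
    v: np.ndarray
    w: np.ndarray

    @property
    def r(self) -> np.ndarray:
        return np.hypot(self.v, self.w)

    @property
    def theta(self) -> np.ndarray:
        """Angles in [0, 2 pi)."""
        return np.mod(np.arctan2(self.w, self.v), 2 * np.pi)

    def rotated(self, angle: float) -> "AttractorPoints":
        c, s = np.cos(angle), np.sin(angle)
        return AttractorPoints(self.tau, c * self.v - s * self.w, s * self.v + c * self.w)


@dataclass
class AttractorImage:
    """Normalized 2-D density of the attractor on a symmetric square grid."""

    grid: np.ndarray  # (n_bins, n_bins), sums to 1
    extent: float  # symmetric bounds [-extent, extent] on both axes
    n_bins: int


@dataclass
class DensityProfile:
    """Polar densities of the attractor point set.

    ``r_density`` integrates to 1 over the radial grid; the two angular
    densities integrate to the core and arm point-mass fractions, which sum
    to 1. All angular densities are 2 pi - periodic by construction.
    """

    r_grid: np.ndarray  # bin centres
    r_density: np.ndarray
    theta_grid: np.ndarray  # bin centres in [0, 2 pi)
    theta_core_density: np.ndarray
    theta_arm_density: np.ndarray
    core_radius: float


def embed_samples(samples: np.ndarray, fs: float, tau: float) -> AttractorPoints:
    """Delay-embed a raw sample sequence with delay ``tau`` (seconds)."""
    x = np.asarray(samples, dtype=np.float64)
    lag = int(round(tau * fs))
    if lag < 1:
        raise EmbeddingError(f"delay {tau:.6g} s rounds to 0 samples at {fs} Hz")
    if 2 * lag >= len(x):
        raise EmbeddingError(f"2 x delay ({2 * lag} samples) exceeds segment length {len(x)}")
    a = x[2 * lag :]  # x(t)
    b = x[lag:-lag]  # x(t - tau)
    c = x[: -2 * lag]  # x(t - 2 tau)
    # Formulated via differences so a constant offset cancels to rounding.
    v = ((a - c) + (b - c)) / np.sqrt(6.0)
    w = (a - b) / np.sqrt(2.0)
    return AttractorPoints(tau=lag / fs, v=v, w=w)


def embed(substrip: SubStrip) -> AttractorPoints:
    """SPAR embedding of a preprocessed sub-strip at tau = mean R-R / 3."""
    return embed_samples(substrip.samples, substrip.fs, substrip.mean_rr / 3.0)


def density_image(points: AttractorPoints, n_bins: int = DEFAULT_N_BINS) -> AttractorImage:
    """2-D histogram of the point set over a symmetric extent, sum 1."""
    if n_bins < 8:
        raise ParameterError(f"n_bins must be >= 8, got {n_bins}")
    if points.v.size == 0:
        raise ParameterError("cannot build a density image from an empty point set")
    extent = float(max(np.max(np.abs(points.v)), np.max(np.abs(points.w)))) * 1.05
    if extent == 0:
        extent = 1.0  # degenerate all-origin point set still gets a valid grid
    edges = np.linspace(-extent, extent, n_bins + 1)
    grid, _, _ = np.histogram2d(points.v, points.w, bins=[edges, edges])
    grid /= grid.sum()
    return AttractorImage(grid=grid, extent=extent, n_bins=n_bins)


def compute_core_radius(points: AttractorPoints, fraction: float = 0.5) -> float:
    """Radius enclosing ``fraction`` of the points (a quantile of r)."""
    if not 0 < fraction <= 1:
        raise ParameterError(f"fraction must lie in (0, 1], got {fraction}")
    r = points.r
    if r.size < 10:
        raise ParameterError("need at least 10 points to define a core radius")
    return float(np.quantile(r, fraction))


def density_profiles(
    points: AttractorPoints,
    core_radius: float,
    n_angle_bins: int = DEFAULT_N_ANGLE_BINS,
    n_r_bins: int = DEFAULT_N_R_BINS,
    r_max: float | None = None,
) -> DensityProfile:
    """Radial density plus core/arm angular densities.

    The radial histogram covers [0, r_max]; the theta histogram of points
    with r <= core_radius (the core) and r > core_radius (the arms) are each
    normalized as densities whose integrals equal the respective point-mass
    fractions, so the two integrate to 1 jointly.  An empty partition gives
    an all-zero profile rather than an error.
    """
    r = points.r
    theta = points.theta
    n = r.size
    if n == 0:
        raise ParameterError("empty point set")
    if r_max is None:
        r_max = float(np.max(r)) or 1.0

    r_edges = np.linspace(0.0, r_max, n_r_bins + 1)
    r_counts, _ = np.histogram(r, bins=r_edges)
    dr = r_edges[1] - r_edges[0]
    r_density = r_counts / (n * dr)

    t_edges = np.linspace(0.0, 2 * np.pi, n_angle_bins + 1)
    dt = t_edges[1] - t_edges[0]
    core = r <= core_radius
    core_counts, _ = np.histogram(theta[core], bins=t_edges)
    arm_counts, _ = np.histogram(theta[~core], bins=t_edges)
    theta_core = core_counts / (n * dt)
    theta_arm = arm_counts / (n * dt)

    return DensityProfile(
        r_grid=0.5 * (r_edges[:-1] + r_edges[1:]),
        r_density=r_density,
        theta_grid=0.5 * (t_edges[:-1] + t_edges[1:]),
        theta_core_density=theta_core,
        theta_arm_density=theta_arm,
        core_radius=float(core_radius),
    )


def profile_band_summary(profiles: list[np.ndarray]) -> dict[str, np.ndarray]:
    """Pointwise mean, mean+SD and 5th-95th percentile envelopes.

    ``profiles`` is a list of equally-gridded density arrays (e.g. the
    theta-core densities of one class); the summary is what the shaded-band
    profile figures display per class.
    """
    if not profiles:
        raise ParameterError("need at least one profile")
    arr = np.asarray(profiles, dtype=np.float64)
    if arr.ndim != 2:
        raise ParameterError("profiles must share a common grid")
    return {
        "mean": arr.mean(axis=0),
        "mean_plus_sd": arr.mean(axis=0) + arr.std(axis=0),
        "p5": np.percentile(arr, 5, axis=0),
        "p95": np.percentile(arr, 95, axis=0),
    }


def detect_sign_flip(
    theta_core: np.ndarray, reference: np.ndarray
) -> tuple[bool, float]:
    """Diagnose a sign-flip acquisition artefact from the theta-core density.

    The phase is the argmax of the circular cross-correlation of the density
    against the reference; a negated signal rotates the attractor by pi, so
    a phase closer to pi than to 0 flags the record as flipped (the remedy
    being signal negation before re-embedding).  Returns
    ``(is_flipped, phase)`` with phase in [0, 2 pi).
    """
    d = np.asarray(theta_core, dtype=np.float64)
    ref = np.asarray(reference, dtype=np.float64)
    if d.shape != ref.shape:
        raise ParameterError("density and reference must share the angular grid")
    if not d.any() or not ref.any():
        raise ParameterError("all-zero theta-core density; sign convention undetermined")
    nb = d.size
    # circular cross-correlation c[k] = sum_i d[(i+k) mod nb] * ref[i]
    corr = np.array([np.dot(np.roll(d, -k), ref) for k in range(nb)])
    phase = 2 * np.pi * int(np.argmax(corr)) / nb
    dist0 = min(phase, 2 * np.pi - phase)
    dist_pi = abs(phase - np.pi)
    return bool(dist_pi < dist0), float(phase)


def rotation_angle_between(p1: AttractorPoints, p2: AttractorPoints) -> float:
    """Least-squares rotation about the origin mapping ``p1`` onto ``p2``.

    Assumes pointwise correspondence (same source indices), as when the two
    sets come from transformed versions of one signal. Returns radians in
    [0, 2 pi).
    """
    if p1.v.shape != p2.v.shape:
        raise ParameterError("point sets must correspond pointwise")
    dot = float(np.dot(p1.v, p2.v) + np.dot(p1.w, p2.w))
    cross = float(np.dot(p1.v, p2.w) - np.dot(p1.w, p2.v))
    return float(np.mod(np.arctan2(cross, dot), 2 * np.pi))
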