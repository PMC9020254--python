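"""Random-sampling primitives for photon transport.

Free-path lengths, scattering-angle cosines for the Henyey-Greenstein and
Rayleigh phase functions, rotation of direction cosines by a sampled
deflection, and cosine-weighted (Lambertian) launch directions.

All samplers are pure functions of uniform variates, so they can be driven by
any RNG stream and checked against closed-form moments.  Directions are plain
numpy arrays of three direction cosines; vectorised inputs of shape ``(n, 3)``
are accepted everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhaseFunction",
    "phase_moments",
    "sample_free_path",
    "sample_hg_cosine",
    "sample_rayleigh_cosine",
    "scatter_direction",
    "sample_lambertian_direction",
    "normalize_direction",
    "TINY_UNIFORM",
]

#: Smallest positive uniform; a raw u = 0 from an RNG is remapped onto it
#: before -log(u) so a free path can never be infinite.
TINY_UNIFORM = 2.0 ** -53

# |mu_z| above this uses the degenerate (axis-aligned) rotation formulas.
_AXIAL_GUARD = 1.0 - 1e-12

# Directions further than this from unit norm are rejected as invalid.
_UNIT_TOL = 1e-6


@dataclass(frozen=True)
class PhaseFunction:
    """A rotationally symmetric single-scattering phase function p(cos th).

    Two models are supported:

    ``"hg"``
        Henyey-Greenstein with asymmetry ``g`` (|g| < 1); ``g = 0`` reduces to
        isotropic scattering.  Moments: <cos th> = g, <cos^2 th> = (1+2g^2)/3.
    ``"rayleigh"``
        p(mu) = (3/8)(1 + mu^2) on [-1, 1]; <cos th> = 0, <cos^2 th> = 2/5.

    Note that HG(g=0) and Rayleigh share a zero first moment but differ in the
    second (1/3 vs 0.4), which is exactly what the higher-order coordinate
    moments of the infinite-medium benchmarks resolve.
    """

    kind: str
    g: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("hg", "rayleigh"):
            raise ValueError(f"unknown phase function kind: {self.kind!r}")
        if self.kind == "rayleigh" and self.g != 0.0:
            raise ValueError("the Rayleigh phase function has no g parameter")
        if not -1.0 < self.g < 1.0:
            raise ValueError(f"HG asymmetry must satisfy |g| < 1, got {self.g}")

    @classmethod
    def hg(cls, g: float) -> "PhaseFunction":
        return cls("hg", float(g))

    @classmethod
    def rayleigh(cls) -> "PhaseFunction":
        return cls("rayleigh")

    @classmethod
    def isotropic(cls) -> "PhaseFunction":
        return cls("hg", 0.0)

    def moments(self) -> tuple[float, float]:
        """Exact (g, g2) = (<cos th>, <cos^2 th>) of the phase function."""
        if self.kind == "rayleigh":
            return 0.0, 0.4
        return self.g, (1.0 + 2.0 * self.g * self.g) / 3.0

    @property
    def label(self) -> str:
        if self.kind == "rayleigh":
            return "rayleigh"
        return f"hg(g={self.g:g})"

    def sample_cosine(self, u):
        """Draw scattering cosines from uniforms ``u``."""
        if self.kind == "rayleigh":
            return sample_rayleigh_cosine(u)
        return sample_hg_cosine(self.g, u)


def phase_moments(spec: PhaseFunction) -> tuple[float, float]:
    """Exact first and second moments of cos(theta) for ``spec``."""
    return spec.moments()


def sample_free_path(mus: float, u):
    """Invert the exponential free-path law: length = -ln(u) / mus.

    Parameters
    ----------
    mus : scattering coefficient in mm^-1, > 0.
    u : uniform variates strictly inside (0, 1).

    The mean of the sampled lengths converges to 1/mus and the second moment
    to 2/mus^2, the first-order coordinate benchmarks of the pencil beam.
    """
    if not mus > 0.0:
        raise ValueError(f"scattering coefficient must be positive, got {mus}")
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0.0) or np.any(u >= 1.0):
        raise ValueError("uniform variates must lie strictly inside (0, 1)")
    out = -np.log(u) / mus
    return float(out) if out.ndim == 0 else out


def sample_hg_cosine(g: float, u):
    """Inverse-CDF sample of the Henyey-Greenstein scattering cosine.

    ``g = 0`` returns the isotropic cosine 2u - 1; otherwise the standard
    closed-form inversion.  Over many draws <cos th> -> g and
    <cos^2 th> -> (1 + 2 g^2)/3.
    """
    if not -1.0 < g < 1.0:
        raise ValueError(f"HG asymmetry must satisfy |g| < 1, got {g}")
    u = np.asarray(u, dtype=float)
    if np.any(u < 0.0) or np.any(u > 1.0):
        raise ValueError("uniform variates must lie in [0, 1]")
    if g == 0.0:
        out = 2.0 * u - 1.0
    else:
        t = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        out = (1.0 + g * g - t * t) / (2.0 * g)
        out = np.clip(out, -1.0, 1.0)
    return float(out) if out.ndim == 0 else out


def sample_rayleigh_cosine(u):
    """Inverse-CDF sample of the Rayleigh scattering cosine.

    The target density is p(mu) = (3/8)(1 + mu^2) on [-1, 1] with CDF
    F(mu) = (3 mu + mu^3 + 4)/8.  Setting F(mu) = u gives the depressed cubic
    mu^3 + 3 mu + (4 - 8u) = 0 whose Cardano discriminant (2-4u)^2 + 1 is
    bounded below by 1, so the single-real-root closed form is always valid::

        w  = 4u - 2
        mu = cbrt(w + sqrt(w^2 + 1)) + cbrt(w - sqrt(w^2 + 1))
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0.0) or np.any(u > 1.0):
        raise ValueError("uniform variates must lie in [0, 1]")
    w = 4.0 * u - 2.0
    s = np.sqrt(w * w + 1.0)
    out = np.cbrt(w + s) + np.cbrt(w - s)
    out = np.clip(out, -1.0, 1.0)
    return float(out) if out.ndim == 0 else out


def normalize_direction(direction):
    """Renormalize direction cosines to unit norm."""
    d = np.asarray(direction, dtype=float)
    norm = np.sqrt(np.sum(d * d, axis=-1, keepdims=True))
    if np.any(norm == 0.0):
        raise ValueError("zero direction vector")
    return d / norm


def scatter_direction(direction, cos_theta, phi):
    """Rotate unit direction(s) by a polar deflection and azimuth.

    The returned direction makes angle arccos(``cos_theta``) with the input
    and azimuth ``phi`` about it, using the standard local-frame rotation of
    multi-layer photon-transport codes.  Near-axial input (|mu_z| within
    1e-12 of 1) switches to the degenerate formulas to avoid cancellation.
    """
    d = np.asarray(direction, dtype=float)
    ct = np.asarray(cos_theta, dtype=float)
    ph = np.asarray(phi, dtype=float)
    if d.shape[-1] != 3:
        raise ValueError("direction must have 3 components on the last axis")
    norm = np.sqrt(np.sum(d * d, axis=-1))
    if np.any(np.abs(norm - 1.0) > _UNIT_TOL):
        raise ValueError("input direction is not unit-norm")
    if np.any(np.abs(ct) > 1.0 + 1e-12):
        raise ValueError("|cos_theta| must not exceed 1")
    ct = np.clip(ct, -1.0, 1.0)

    d = d / norm[..., None]
    ux, uy, uz = d[..., 0], d[..., 1], d[..., 2]
    st = np.sqrt(np.clip(1.0 - ct * ct, 0.0, 1.0))
    cp, sp = np.cos(ph), np.sin(ph)

    axial = np.abs(uz) > _AXIAL_GUARD
    sign = np.where(uz >= 0.0, 1.0, -1.0)
    # general branch; denom guarded so the masked lanes stay finite
    den = np.sqrt(np.maximum(1.0 - uz * uz, 1e-24))
    gx = st * (ux * uz * cp - uy * sp) / den + ux * ct
    gy = st * (uy * uz * cp + ux * sp) / den + uy * ct
    gz = -st * cp * den + uz * ct
    ax = st * cp
    ay = sign * st * sp
    az = sign * ct
    out = np.stack(
        [np.where(axial, ax, gx), np.where(axial, ay, gy), np.where(axial, az, gz)],
        axis=-1,
    )
    return normalize_direction(out)


def sample_lambertian_direction(u1, u2, inward_normal):
    """Cosine-weighted direction into the medium.

    The polar angle w.r.t. the inward normal has density 2 cos(th) sin(th)
    (i.e. cos(th) = sqrt(u1)), the azimuth is 2 pi u2.  This realizes a
    Lambertian (uniform-radiance) source by area-law weighting; the mean of
    cos(th) over many draws is 2/3 and cos^2(th) is uniform on (0, 1).
    """
    u1 = np.asarray(u1, dtype=float)
    u2 = np.asarray(u2, dtype=float)
    ct = np.sqrt(np.clip(u1, 0.0, 1.0))
    normal = normalize_direction(inward_normal)
    if normal.ndim == 1 and u1.ndim > 0:
        normal = np.broadcast_to(normal, u1.shape + (3,))
    return scatter_direction(normal, ct, 2.0 * np.pi * u2)
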