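"""Closed-form radiative-transfer reference values.

Two families of exact benchmarks for a non-absorbing medium:

1. *Infinite medium*: the statistical moments of the coordinates of the k-th
   scattering event of a pencil beam, as functions of the scattering
   coefficient mus and the phase-function moments g = <cos th> and
   g2 = <cos^2 th>.  Full second-moment sets are available for orders 1-4;
   <z_k>, <d_k^2> and the path-length moments <l_k^m> for any order; and the
   complete second-moment set for any order under isotropic scattering.

2. *Bounded media under Lambertian illumination*: the invariant solutions
   for radiance, fluence rate and mean partial path lengths, which depend
   only on the refractive-index ratio nj/ne and (for path lengths) on the
   sub-volume geometry — never on the scattering properties.  For a
   non-scattering layered slab with nj > ne, trapped trajectories reduce the
   angular support to |cos th| >= cos(theta_max) and scale fluence and path
   lengths by (1 - cos theta_max).

All functions are pure and exact; they are the reference side of the
one-sample t-tests in :mod:`photonbench.verify`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sampling import PhaseFunction
from .slab_sim import LayeredSlab

__all__ = [
    "UNIT_FLUX_RADIANCE",
    "MomentBenchmark",
    "InvariantSolution",
    "infinite_moments",
    "mean_z_any_order",
    "mean_d2_any_order",
    "pathlength_moment",
    "isotropic_second_moments",
    "invariant_radiance",
    "invariant_fluence",
    "invariant_layer_pathlength",
    "slab_layer_pathlength",
    "theta_max",
    "nonscattering_solutions",
    "benchmark_table",
]

#: Source radiance I0 equivalent to unit incoming flux per unit area
#: (the normalization used by the slab simulator): I0 = 1/pi W m^-2 sr^-1.
UNIT_FLUX_RADIANCE = 1.0 / math.pi


@dataclass(frozen=True)
class MomentBenchmark:
    """Exact moments of the k-th scattering event coordinates (mm, mm^2)."""

    k: int
    x: float
    y: float
    z: float
    x2: float
    y2: float
    z2: float
    rho2: float
    d2: float
    l: float
    l2: float

    def as_dict(self) -> dict[str, float]:
        return {
            "x": self.x, "y": self.y, "z": self.z,
            "x2": self.x2, "y2": self.y2, "z2": self.z2,
            "rho2": self.rho2, "d2": self.d2, "l": self.l, "l2": self.l2,
        }


def infinite_moments(k: int, g: float, g2: float, mus: float) -> MomentBenchmark:
    """Exact coordinate moments of the k-th scattering order, k in 1..4.

    Valid for any rotationally symmetric phase function with first and
    second cosine moments (g, g2).  The second transverse moments <x_k^2>
    are polynomials in g and g2; <rho^2> = 2 <x^2> and <d^2> = <rho^2> +
    <z^2> hold exactly by construction.  Orders above 4 are served by
    :func:`mean_z_any_order`, :func:`mean_d2_any_order`,
    :func:`pathlength_moment` and :func:`isotropic_second_moments`.
    """
    if not 1 <= k <= 4:
        raise ValueError(
            "full moment sets exist for orders 1-4 only; use the any-order "
            "functions for higher k"
        )
    if not mus > 0.0:
        raise ValueError("mus must be positive")
    m2 = mus * mus
    if k == 1:
        x2 = 0.0
        z2 = 2.0 / m2
        z = 1.0 / mus
    elif k == 2:
        x2 = (1.0 - g2) / m2
        z2 = 2.0 * (1.0 + g + g2) / m2
        z = (1.0 + g) / mus
    elif k == 3:
        x2 = (1.5 + g - g * g2 - 1.5 * g2 * g2) / m2
        z2 = (3.0 + 2.0 * g + 2.0 * g * g + 2.0 * g * g2 + 3.0 * g2 * g2) / m2
        z = (1.0 + g + g * g) / mus
    else:
        x2 = (
            2.25 + 1.5 * g - 1.5 * g * g2 * g2 + g * g - g * g * g2
            - 0.75 * g2 + 0.75 * g2 * g2 - 2.25 * g2 ** 3
        ) / m2
        z2 = (
            3.5 + 3.0 * g * (1.0 + g2 * g2) + 2.0 * g * g * (1.0 + g2)
            + 2.0 * g ** 3 + 1.5 * g2 - 1.5 * g2 * g2 + 4.5 * g2 ** 3
        ) / m2
        z = (1.0 + g + g * g + g ** 3) / mus
    rho2 = 2.0 * x2
    return MomentBenchmark(
        k=k, x=0.0, y=0.0, z=z, x2=x2, y2=x2, z2=z2, rho2=rho2,
        d2=rho2 + z2, l=pathlength_moment(k, 1, mus), l2=pathlength_moment(k, 2, mus),
    )


def mean_z_any_order(k: int, g: float, mus: float) -> float:
    """<z_k> = (1 - g^k) / (mus (1 - g)) for any order k >= 1.

    The g = 0 branch returns 1/mus for every k; the k -> infinity limit is
    the transport mean free path 1/(mus (1 - g)).
    """
    if k < 1:
        raise ValueError("order must be >= 1")
    if g == 1.0:
        raise ValueError("g = 1 (pure forward scattering) is degenerate")
    if g == 0.0:
        return 1.0 / mus
    return (1.0 - g ** k) / (mus * (1.0 - g))


def mean_d2_any_order(k: int, g: float, mus: float) -> float:
    """<d_k^2> = 2 (k - (k+1) g + g^(k+1)) / (mus (1-g))^2 for any k >= 1."""
    if k < 1:
        raise ValueError("order must be >= 1")
    if g == 0.0:
        return 2.0 * k / (mus * mus)
    return 2.0 * (k - (k + 1) * g + g ** (k + 1)) / (mus * (1.0 - g)) ** 2


def pathlength_moment(k: int, m: int, mus: float) -> float:
    """<l_k^m> = k (k+1) ... (k+m-1) / mus^m (rising factorial).

    Path-length statistics are independent of the phase function.
    """
    if k < 1 or m < 1:
        raise ValueError("order and moment must be >= 1")
    val = 1.0
    for i in range(m):
        val *= k + i
    return val / mus ** m


def isotropic_second_moments(k: int, mus: float) -> tuple[float, float, float, float]:
    """(<x^2>, <z^2>, <rho^2>, <d^2>) at order k for isotropic scattering.

    <x_k^2> = (2/3)(k-1)/mus^2, <z_k^2> = (2/3)(k+2)/mus^2, so that
    <z_k^2> - <x_k^2> = 2/mus^2 (the first-order longitudinal variance) for
    every k, and <d_k^2> = 2k/mus^2.
    """
    if k < 1:
        raise ValueError("order must be >= 1")
    m2 = mus * mus
    x2 = 2.0 / 3.0 * (k - 1) / m2
    z2 = 2.0 / 3.0 * (k + 2) / m2
    return x2, z2, 2.0 * x2, 2.0 * x2 + z2


# -- invariant solutions under Lambertian illumination ------------------


@dataclass(frozen=True)
class InvariantSolution:
    """Exact radiance/fluence/path-length values in one sub-volume.

    ``cos_theta_max`` is 1 - (support cutoff): the radiance occupies
    |cos th| >= cos_theta_max; ``cos_theta_max = 0`` means full-sphere
    support (the generic scattering case).
    """

    radiance: float
    fluence: float
    layer_pathlength: float
    cos_theta_max: float = 0.0

    @property
    def support_fraction(self) -> float:
        return 1.0 - self.cos_theta_max


def invariant_radiance(nj: float, ne: float, i0: float = UNIT_FLUX_RADIANCE) -> float:
    """Radiance (nj/ne)^2 I0, independent of position, direction, scattering."""
    if not (nj > 0.0 and ne > 0.0):
        raise ValueError("refractive indices must be positive")
    return (nj / ne) ** 2 * i0


def invariant_fluence(nj: float, ne: float, i0: float = UNIT_FLUX_RADIANCE) -> float:
    """Fluence rate 4 pi (nj/ne)^2 I0 (the radiance integrated over 4 pi)."""
    return 4.0 * math.pi * invariant_radiance(nj, ne, i0)


def invariant_layer_pathlength(nj: float, ne: float, vj: float, sigma: float) -> float:
    """Mean path length 4 (nj/ne)^2 Vj / Sigma in sub-volume Vj.

    Sigma is the external surface of the whole body.  This is the
    index-weighted mean-chord generalization of the 4V/S invariance.
    """
    if not (vj > 0.0 and sigma > 0.0):
        raise ValueError("volume and surface must be positive")
    if not (nj > 0.0 and ne > 0.0):
        raise ValueError("refractive indices must be positive")
    return 4.0 * (nj / ne) ** 2 * vj / sigma


def slab_layer_pathlength(sj: float, nj: float, ne: float) -> float:
    """Slab specialization 2 sj (nj/ne)^2 (both faces illuminated, Vj/Sigma = sj/2)."""
    if not sj > 0.0:
        raise ValueError("layer thickness must be positive")
    return invariant_layer_pathlength(nj, ne, sj / 2.0, 1.0)


def theta_max(slab: LayeredSlab, j: int) -> float:
    """Maximum polar angle carrying radiation in layer j of a non-scattering slab.

    Directions in a non-scattering plane-parallel stack conserve the Snell
    invariant xi = n sin(theta); entering from outside bounds xi by ne, and
    traversing a layer of index n_i requires xi <= n_i (total internal
    reflection blocks the crossing otherwise).  The largest invariant able to
    reach layer j is therefore min(ne, indices of the layers crossed) along
    the less restrictive of the two entry sides, and
    sin(theta_max) = xi_max / n_j, capped at 1 (full support, pi/2).

    Layers are indexed from 1.
    """
    if not slab.is_nonscattering:
        raise ValueError("theta_max is defined for non-scattering slabs only")
    m = slab.n_layers
    if not 1 <= j <= m:
        raise ValueError(f"layer index must be in 1..{m}")
    ns = slab.indices
    top = min([slab.ne] + list(ns[: j - 1]))
    bottom = min([slab.ne] + list(ns[j:]))
    xi_max = max(top, bottom)
    return math.asin(min(1.0, xi_max / ns[j - 1]))


def nonscattering_solutions(slab: LayeredSlab, j: int,
                            i0: float = UNIT_FLUX_RADIANCE) -> InvariantSolution:
    """Trapped-regime solutions for layer j of a non-scattering slab.

    The radiance keeps the invariant level (nj/ne)^2 I0 but only on the
    angular support |cos th| >= cos(theta_max); the fluence rate and the
    mean layer path length are scaled by (1 - cos theta_max).  With nj <= the
    limiting chain index the support is the full sphere and the generic
    invariant solutions are recovered exactly.
    """
    if not slab.is_nonscattering:
        raise ValueError(
            "trapped-regime solutions require a non-scattering slab; use the "
            "invariant_* functions for scattering media"
        )
    tm = theta_max(slab, j)
    factor = 1.0 - math.cos(tm)
    layer = slab.layers[j - 1]
    return InvariantSolution(
        radiance=invariant_radiance(layer.n, slab.ne, i0),
        fluence=invariant_fluence(layer.n, slab.ne, i0) * factor,
        layer_pathlength=slab_layer_pathlength(layer.thickness, layer.n, slab.ne) * factor,
        cos_theta_max=math.cos(tm),
    )


def benchmark_table(phase: PhaseFunction, mus: float = 1.0, k_max: int = 4) -> pd.DataFrame:
    """Exact moment table for orders 1..k_max (long format, mm / mm^2).

    Orders above 4 carry only the quantities with any-order closed forms
    (plus the full isotropic set when the phase function is isotropic);
    unavailable cells are NaN.
    """
    g, g2 = phase.moments()
    isotropic = phase.moments() == (0.0, 1.0 / 3.0)
    rows = []
    for k in range(1, k_max + 1):
        if k <= 4:
            vals = infinite_moments(k, g, g2, mus).as_dict()
        else:
            vals = {
                "x": 0.0, "y": 0.0,
                "z": mean_z_any_order(k, g, mus),
                "d2": mean_d2_any_order(k, g, mus),
                "l": pathlength_moment(k, 1, mus),
                "l2": pathlength_moment(k, 2, mus),
                "x2": np.nan, "y2": np.nan, "z2": np.nan, "rho2": np.nan,
            }
            if isotropic:
                x2, z2, rho2, _ = isotropic_second_moments(k, mus)
                vals.update(x2=x2, y2=x2, z2=z2, rho2=rho2)
        for q, v in vals.items():
            rows.append((k, q, v))
    return pd.DataFrame(rows, columns=["k", "quantity", "value"])
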