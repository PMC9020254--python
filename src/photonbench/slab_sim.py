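"""Step-2 simulator: photon transport through a non-absorbing layered slab.

The slab is laterally infinite, bounded by planes z = 0 and z = Z, and built
from ordered layers with individual thickness, refractive index, scattering
coefficient and phase function.  Lambertian illumination of both faces is
realized by reciprocity: photon i is injected at a single point of face
(i mod 2) with a cosine-weighted direction drawn in the external medium and
Fresnel-refracted at entry.  Photons specularly reflected at the entry face
contribute zero internal path but still count in N, consistent with the
invariant solutions holding under illumination of the physical boundary.

Track lengths per (layer, polar-angle bin) estimate the radiance; per-layer
per-photon path totals estimate the mean partial path lengths <Lj> and, via
Phi_j = 2 <Lj> / s_j (unit incident flux on both faces), the fluence rate.

Residual optical depth is carried across interfaces (exponential
memorylessness), non-scattering layers propagate straight rays, and every
interface crossing applies unpolarized Fresnel reflection/refraction with
the Snell invariant n sin(theta) conserved.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd

from . import _kernels
from .sampling import PhaseFunction, normalize_direction

__all__ = [
    "Layer",
    "LayeredSlab",
    "AngularGrid",
    "SlabTallies",
    "InjectedDefect",
    "fresnel_reflectance",
    "refract",
    "run_step2",
    "estimate_pathlengths",
    "estimate_fluence",
    "estimate_radiance",
    "four_layer_slab",
    "hundred_layer_slab",
]


class InjectedDefect(IntEnum):
    """Deliberate physics defects for verification sensitivity fixtures.

    A verification method is only trustworthy if it *fails* on a broken
    simulator; these switches break the boundary physics in controlled ways
    so the test battery's detection power can be demonstrated.
    """

    NONE = _kernels.DEFECT_NONE
    SWAP_FRESNEL_INDICES = _kernels.DEFECT_SWAP_FRESNEL
    MISSING_TIR = _kernels.DEFECT_MISSING_TIR


@dataclass(frozen=True)
class Layer:
    """One slab layer: thickness (mm), refractive index, mus (mm^-1), phase."""

    thickness: float
    n: float
    mus: float = 0.0
    phase: PhaseFunction = PhaseFunction.isotropic()

    def __post_init__(self) -> None:
        if not self.thickness > 0.0:
            raise ValueError("layer thickness must be positive")
        if not self.n > 0.0:
            raise ValueError("refractive index must be positive")
        if self.mus < 0.0:
            raise ValueError("scattering coefficient must be non-negative")


@dataclass(frozen=True)
class LayeredSlab:
    """Ordered layers between z = 0 and z = Z plus the external index ne."""

    layers: tuple[Layer, ...]
    ne: float = 1.0

    def __post_init__(self) -> None:
        if len(self.layers) == 0:
            raise ValueError("a slab needs at least one layer")
        if not self.ne > 0.0:
            raise ValueError("external refractive index must be positive")
        object.__setattr__(self, "layers", tuple(self.layers))

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def edges(self) -> np.ndarray:
        """Cumulative layer boundaries 0 = z0 < z1 < ... < zM = Z."""
        return np.concatenate([[0.0], np.cumsum([la.thickness for la in self.layers])])

    @property
    def total_thickness(self) -> float:
        return float(sum(la.thickness for la in self.layers))

    @property
    def indices(self) -> np.ndarray:
        return np.array([la.n for la in self.layers])

    @property
    def mus_values(self) -> np.ndarray:
        return np.array([la.mus for la in self.layers])

    @property
    def is_scattering(self) -> bool:
        """True if every layer scatters (mus > 0 everywhere)."""
        return bool(np.all(self.mus_values > 0.0))

    @property
    def is_nonscattering(self) -> bool:
        return bool(np.all(self.mus_values == 0.0))

    def with_mus(self, mus: float) -> "LayeredSlab":
        """Copy of the slab with every layer's mus replaced."""
        return LayeredSlab(
            tuple(Layer(la.thickness, la.n, mus, la.phase) for la in self.layers),
            self.ne,
        )

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "slab": {
                "ne": self.ne,
                "layer": [
                    {
                        "s": la.thickness,
                        "n": la.n,
                        "mus": la.mus,
                        "phase": la.phase.kind,
                        "g": la.phase.g,
                    }
                    for la in self.layers
                ],
            }
        }

    @classmethod
    def from_dict(cls, data: dict) -> "LayeredSlab":
        try:
            slab = data["slab"]
            layers = tuple(
                Layer(
                    float(entry["s"]),
                    float(entry["n"]),
                    float(entry.get("mus", 0.0)),
                    PhaseFunction(entry.get("phase", "hg"), float(entry.get("g", 0.0))),
                )
                for entry in slab["layer"]
            )
            return cls(layers, float(slab.get("ne", 1.0)))
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"malformed slab configuration: {exc}") from exc

    @classmethod
    def from_toml(cls, path) -> "LayeredSlab":
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))


def four_layer_slab(profile: str = "up", mus: float = 1.0,
                    phase: PhaseFunction = PhaseFunction.isotropic()) -> LayeredSlab:
    """Four 2.5 mm layers with a monotone refractive-index profile.

    ``"up"``: n = 1.2, 1.4, 1.6, 1.8 with external index 1;
    ``"dw"``: the mirrored decreasing profile with external index 2.
    """
    if profile == "up":
        ns, ne = (1.2, 1.4, 1.6, 1.8), 1.0
    elif profile == "dw":
        ns, ne = (1.8, 1.6, 1.4, 1.2), 2.0
    else:
        raise ValueError("profile must be 'up' or 'dw'")
    return LayeredSlab(tuple(Layer(2.5, n, mus, phase) for n in ns), ne)


def hundred_layer_slab(profile: str = "up", mus: float = 1.0,
                       phase: PhaseFunction = PhaseFunction.isotropic()) -> LayeredSlab:
    """One hundred 0.1 mm layers with a linear index ramp between 1 and 2.

    ``"up"``: n_j = 1 + j/100 (1.01 .. 2.00), external index 1;
    ``"dw"``: the reversed ramp (2.00 .. 1.01), external index 2.
    """
    ramp = [1.0 + j / 100.0 for j in range(1, 101)]
    if profile == "up":
        ns, ne = ramp, 1.0
    elif profile == "dw":
        ns, ne = ramp[::-1], 2.0
    else:
        raise ValueError("profile must be 'up' or 'dw'")
    return LayeredSlab(tuple(Layer(0.1, n, mus, phase) for n in ns), ne)


@dataclass(frozen=True)
class AngularGrid:
    """Uniform-in-theta polar grid on [0, pi] for radiance binning."""

    n_bins: int = 180

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")

    @property
    def theta_edges(self) -> np.ndarray:
        return np.linspace(0.0, np.pi, self.n_bins + 1)

    @property
    def theta_centers_deg(self) -> np.ndarray:
        edges = self.theta_edges
        return np.degrees(0.5 * (edges[:-1] + edges[1:]))

    @property
    def cos_edges(self) -> np.ndarray:
        return np.cos(self.theta_edges)

    @property
    def solid_angles(self) -> np.ndarray:
        """Exact solid angle per bin; sums to 4 pi."""
        c = self.cos_edges
        return 2.0 * np.pi * (c[:-1] - c[1:])


@dataclass
class SlabTallies:
    """Raw tallies of a slab run.

    ``track[b, j, t]`` is the track-length sum of batch b in layer j and
    polar bin t; ``path_sum``/``path_sumsq`` are per-layer per-photon path
    accumulators, ``total_*`` the whole-slab equivalents.  The batch split of
    the track tallies provides radiance standard errors; path-length errors
    come from the per-photon sums of squares.
    """

    n_photons: int
    grid: AngularGrid
    track: np.ndarray = field(repr=False)
    path_sum: np.ndarray = field(repr=False)
    path_sumsq: np.ndarray = field(repr=False)
    total_sum: float
    total_sumsq: float
    n_reflected: int
    n_transmitted: int
    n_aborted: int
    n_entry_rejected: int

    @property
    def n_batches(self) -> int:
        return self.track.shape[0]

    @property
    def n_layers(self) -> int:
        return self.track.shape[1]

    def batch_counts(self) -> np.ndarray:
        """Photon count per batch under the i*n_batches//N partition."""
        nb, n = self.n_batches, self.n_photons
        starts = np.array([-(-b * n // nb) for b in range(nb + 1)])
        return np.diff(starts)


def fresnel_reflectance(ni: float, nt: float, cos_i):
    """Unpolarized Fresnel reflectance (mean of s- and p-polarized).

    Returns exactly 1 in the total-internal-reflection regime
    (ni sin(theta_i) > nt).
    """
    if not (ni > 0.0 and nt > 0.0):
        raise ValueError("refractive indices must be positive")
    ci = np.asarray(cos_i, dtype=float)
    if np.any(ci <= 0.0) or np.any(ci > 1.0):
        raise ValueError("incidence cosine must lie in (0, 1]")
    st2 = (ni / nt) ** 2 * (1.0 - ci * ci)
    tir = st2 >= 1.0
    ct = np.sqrt(np.where(tir, 0.0, 1.0 - st2))
    with np.errstate(divide="ignore", invalid="ignore"):
        rs = (ni * ci - nt * ct) / (ni * ci + nt * ct)
        rp = (nt * ci - ni * ct) / (nt * ci + ni * ct)
    out = np.where(tir, 1.0, 0.5 * (rs * rs + rp * rp))
    if ni == nt:
        out = np.zeros_like(ci)
    return float(out) if out.ndim == 0 else out


def refract(direction, ni: float, nt: float, normal):
    """Snell refraction of unit direction(s) across a plane interface.

    The tangential component is scaled by ni/nt (conserving n sin(theta));
    the normal component keeps its sign.  Raises in the TIR regime: the
    caller must branch on ``fresnel_reflectance(...) == 1`` first.
    """
    d = normalize_direction(direction)
    nrm = normalize_direction(normal)
    if nrm.ndim == 1 and d.ndim > 1:
        nrm = np.broadcast_to(nrm, d.shape)
    cos_n = np.sum(d * nrm, axis=-1)
    if np.any(cos_n == 0.0):
        raise ValueError("direction does not cross the interface")
    tang = d - cos_n[..., None] * nrm
    st2 = (ni / nt) ** 2 * np.sum(tang * tang, axis=-1)
    if np.any(st2 >= 1.0):
        raise ValueError("total internal reflection: refract() is undefined")
    new_cos = np.sqrt(1.0 - st2) * np.sign(cos_n)
    out = (ni / nt) * tang + new_cos[..., None] * nrm
    return normalize_direction(out)


def run_step2(slab: LayeredSlab, n_photons: int, grid: AngularGrid | None = None,
              seed: int = 0, *, n_batches: int = 50, event_cap: int = 10_000_000,
              defect: InjectedDefect = InjectedDefect.NONE) -> SlabTallies:
    """Trace ``n_photons`` trajectories through ``slab`` and tally.

    Photons alternate entry faces; the run is sequential and reproducible
    from ``seed``.  Photons exceeding ``event_cap`` interface/scattering
    events are aborted and reported via ``n_aborted`` (a nonzero count fails
    verification by default).
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    if seed < 0:
        raise ValueError("seed must be non-negative")
    if grid is None:
        grid = AngularGrid()
    n_batches = min(n_batches, n_photons)
    if n_batches < 1:
        raise ValueError("n_batches must be >= 1")
    pkind = np.array(
        [0 if la.phase.kind == "hg" else 1 for la in slab.layers], dtype=np.int64
    )
    pg = np.array([la.phase.g for la in slab.layers])
    (track, lsum, lsumsq, tot_sum, tot_sumsq, n_refl, n_trans, n_aborted,
     n_entry_rej) = _kernels.slab_kernel(
        seed, n_photons, slab.edges, slab.indices, slab.mus_values, pkind, pg,
        slab.ne, grid.n_bins, n_batches, event_cap, int(defect),
    )
    return SlabTallies(
        n_photons=n_photons,
        grid=grid,
        track=track,
        path_sum=lsum,
        path_sumsq=lsumsq,
        total_sum=float(tot_sum),
        total_sumsq=float(tot_sumsq),
        n_reflected=int(n_refl),
        n_transmitted=int(n_trans),
        n_aborted=int(n_aborted),
        n_entry_rejected=int(n_entry_rej),
    )


def _mean_se(total: np.ndarray, total_sq: np.ndarray, n: int):
    mean = total / n
    var = (total_sq / n - mean * mean) * (n / (n - 1.0))
    return mean, np.sqrt(np.maximum(var, 0.0) / n)


def estimate_pathlengths(tallies: SlabTallies) -> pd.DataFrame:
    """Per-layer mean partial path lengths <Lj> and the total <L>, with SEs.

    Photons that never reach a layer (including entry-rejected ones)
    contribute zero path there, as the Lambertian benchmarks require.
    Returns rows for layers 1..M plus a final row labelled ``"total"``.
    """
    n = tallies.n_photons
    if n < 2:
        raise ValueError("at least two photons are needed for standard errors")
    mean, se = _mean_se(tallies.path_sum, tallies.path_sumsq, n)
    tmean, tse = _mean_se(np.array(tallies.total_sum), np.array(tallies.total_sumsq), n)
    rows = [(j + 1, mean[j], se[j]) for j in range(tallies.n_layers)]
    rows.append(("total", float(tmean), float(tse)))
    return pd.DataFrame(rows, columns=["layer", "mean_mm", "se_mm"])


def estimate_fluence(tallies: SlabTallies, slab: LayeredSlab) -> pd.DataFrame:
    """Per-layer fluence-rate estimates Phi_j = 2 <Lj> / s_j, with SEs.

    With unit incident flux on each face, the power entering per unit slab
    area is 2, and Phi_j V_j = (power per area) <Lj> A gives the factor
    2/s_j.  Units are W m^-2 under the I0 = 1/pi normalization.
    """
    n = tallies.n_photons
    if n < 2:
        raise ValueError("at least two photons are needed for standard errors")
    thickness = np.array([la.thickness for la in slab.layers])
    mean, se = _mean_se(tallies.path_sum, tallies.path_sumsq, n)
    est = 2.0 * mean / thickness
    est_se = 2.0 * se / thickness
    return pd.DataFrame(
        {
            "layer": np.arange(1, tallies.n_layers + 1),
            "estimate": est,
            "se": est_se,
        }
    )


def estimate_radiance(tallies: SlabTallies, slab: LayeredSlab,
                      grid: AngularGrid | None = None) -> pd.DataFrame:
    """Layer-averaged radiance per polar bin, W m^-2 sr^-1.

    The track-length estimator is I_j(bin) = (2/s_j) * track / (N dOmega);
    standard errors come from the spread of the per-batch estimates.  In a
    scattering slab the profile is flat at (nj/ne)^2 / pi; in the
    non-scattering trapped regime it is a step vanishing beyond the maximum
    entrance angle.
    """
    if grid is None:
        grid = tallies.grid
    n = tallies.n_photons
    nb = tallies.n_batches
    thickness = np.array([la.thickness for la in slab.layers])
    domega = grid.solid_angles
    total = tallies.track.sum(axis=0)  # (M, B)
    est = 2.0 * total / (thickness[:, None] * n * domega[None, :])
    counts = tallies.batch_counts().astype(float)
    per_batch = (
        2.0
        * tallies.track
        / (thickness[None, :, None] * counts[:, None, None] * domega[None, None, :])
    )
    if nb > 1:
        se = per_batch.std(axis=0, ddof=1) / math.sqrt(nb)
    else:
        se = np.full_like(est, np.nan)
    m, b = est.shape
    return pd.DataFrame(
        {
            "layer": np.repeat(np.arange(1, m + 1), b),
            "theta_deg": np.tile(grid.theta_centers_deg, m),
            "estimate": est.ravel(),
            "se": se.ravel(),
        }
    )
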