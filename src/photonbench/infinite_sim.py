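"""Step-1 simulator: moments of scattering-event coordinates in an infinite medium.

A pencil beam enters a non-absorbing infinite medium at the origin along +z.
Each trajectory is followed for exactly ``k_max`` scattering events; at every
order k the event coordinates (x, y, z), their squares, the squared distances
rho^2 = x^2+y^2 and d^2 = x^2+y^2+z^2, and the cumulative path length l (and
l^2) are accumulated as running sums and sums of squares.  Means and standard
errors per order are then compared against the closed forms in
:mod:`photonbench.benchmarks`.

Tallies are O(k_max) in memory: per-photon data is reduced immediately.
Photons are processed in fixed blocks of ``RNG_BLOCK`` trajectories, each
block driven by its own counter-based Philox generator keyed on
``(seed, block_index)``; tallies are therefore bitwise independent of how a
run is split across block-aligned sub-ranges (see :func:`run_step1`'s
``start``/``stop`` and :meth:`MomentTally.merge`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sampling import TINY_UNIFORM, PhaseFunction, scatter_direction

__all__ = [
    "QUANTITIES",
    "RNG_BLOCK",
    "InfiniteRunConfig",
    "MomentTally",
    "run_step1",
    "moment_estimates",
]

#: Tallied quantities, in fixed column order.
QUANTITIES = ("x", "y", "z", "x2", "y2", "z2", "rho2", "d2", "l", "l2")

#: Photons per RNG block (one Philox stream per block).
RNG_BLOCK = 1 << 16


@dataclass(frozen=True)
class InfiniteRunConfig:
    """Configuration of an infinite-medium run.

    mus : scattering coefficient in mm^-1 (> 0)
    phase : single-scattering phase function
    n_photons : number of trajectories (>= 1)
    k_max : highest tracked scattering order (>= 1)
    seed : base RNG seed (non-negative)
    """

    mus: float
    phase: PhaseFunction
    n_photons: int
    k_max: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.mus > 0.0:
            raise ValueError("mus must be positive")
        if self.n_photons < 1:
            raise ValueError("n_photons must be >= 1")
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


@dataclass
class MomentTally:
    """Running sums and sums of squares per scattering order and quantity.

    ``sums[q, k-1]`` and ``sumsq[q, k-1]`` hold S and SS for quantity
    ``QUANTITIES[q]`` at order k; every order receives exactly ``n_photons``
    contributions (nothing terminates early in a non-absorbing infinite
    medium).
    """

    n_photons: int
    k_max: int
    sums: np.ndarray = field(repr=False)
    sumsq: np.ndarray = field(repr=False)

    @classmethod
    def empty(cls, k_max: int) -> "MomentTally":
        nq = len(QUANTITIES)
        return cls(0, k_max, np.zeros((nq, k_max)), np.zeros((nq, k_max)))

    def merge(self, other: "MomentTally") -> "MomentTally":
        """Combine two tallies from disjoint photon ranges (in place)."""
        if other.k_max != self.k_max:
            raise ValueError("cannot merge tallies with different k_max")
        self.n_photons += other.n_photons
        self.sums += other.sums
        self.sumsq += other.sumsq
        return self

    # -- reductions -----------------------------------------------------

    def means(self) -> np.ndarray:
        """Sample means, shape (n_quantities, k_max)."""
        return self.sums / self.n_photons

    def ses(self) -> np.ndarray:
        """Standard errors of the means, shape (n_quantities, k_max)."""
        n = self.n_photons
        if n < 2:
            raise ValueError("at least two photons are needed for a standard error")
        m = self.means()
        var = (self.sumsq / n - m * m) * (n / (n - 1.0))
        return np.sqrt(np.maximum(var, 0.0) / n)

    def mean(self, quantity: str, k: int) -> float:
        return float(self.sums[QUANTITIES.index(quantity), k - 1] / self.n_photons)

    def se(self, quantity: str, k: int) -> float:
        return float(self.ses()[QUANTITIES.index(quantity), k - 1])


def _simulate_block(rng, nb: int, mus: float, phase: PhaseFunction, k_max: int,
                    sums: np.ndarray, sumsq: np.ndarray) -> None:
    x = np.zeros(nb)
    y = np.zeros(nb)
    z = np.zeros(nb)
    path = np.zeros(nb)
    direction = np.zeros((nb, 3))
    direction[:, 2] = 1.0
    for k in range(k_max):
        u = rng.random(nb)
        np.maximum(u, TINY_UNIFORM, out=u)
        step = -np.log(u) / mus
        x += direction[:, 0] * step
        y += direction[:, 1] * step
        z += direction[:, 2] * step
        path += step
        x2 = x * x
        y2 = y * y
        z2 = z * z
        rho2 = x2 + y2
        d2 = rho2 + z2
        l2 = path * path
        for qi, arr in enumerate((x, y, z, x2, y2, z2, rho2, d2, path, l2)):
            sums[qi, k] += arr.sum()
            sumsq[qi, k] += (arr * arr).sum()
        if k + 1 < k_max:
            ct = phase.sample_cosine(rng.random(nb))
            phi = 2.0 * np.pi * rng.random(nb)
            direction = scatter_direction(direction, ct, phi)


def run_step1(config: InfiniteRunConfig, *, start: int = 0, stop: int | None = None) -> MomentTally:
    """Propagate trajectories and tally per-order coordinate moments.

    ``start``/``stop`` select a photon sub-range; ``start`` must be a multiple
    of :data:`RNG_BLOCK` so that the per-block RNG streams line up, which makes
    a full run bitwise identical to the merge of its block-aligned pieces.
    """
    n = config.n_photons
    if stop is None:
        stop = n
    if not 0 <= start < stop <= n:
        raise ValueError("invalid photon range")
    if start % RNG_BLOCK != 0:
        raise ValueError(f"start must be a multiple of {RNG_BLOCK}")
    tally = MomentTally.empty(config.k_max)
    first = start // RNG_BLOCK
    last = (stop + RNG_BLOCK - 1) // RNG_BLOCK
    for b in range(first, last):
        lo = b * RNG_BLOCK
        hi = min(lo + RNG_BLOCK, stop)
        rng = np.random.Generator(np.random.Philox(np.random.SeedSequence([config.seed, b])))
        _simulate_block(rng, hi - lo, config.mus, config.phase, config.k_max,
                        tally.sums, tally.sumsq)
        tally.n_photons += hi - lo
    return tally


# Quantities whose tally is structurally zero for a pencil beam along z:
# their sample mean is identically 0 and a relative error is undefined.
_STRUCTURAL_ZERO = {("x", None), ("y", None), ("x2", 1), ("y2", 1), ("rho2", 1)}


def _rel_se_defined(quantity: str, k: int) -> bool:
    if quantity in ("x", "y"):
        return False
    if k == 1 and quantity in ("x2", "y2", "rho2"):
        return False
    return True


def moment_estimates(tally: MomentTally) -> pd.DataFrame:
    """Tabulate (order, quantity, mean, se, rel_se, n) from a tally.

    ``rel_se`` = se/|mean| is reported as NaN for the quantities whose exact
    value is zero (the transverse first moments everywhere, and the
    transverse second moments at the first order), where a relative
    uncertainty is undefined.
    """
    if tally.n_photons < 2:
        raise ValueError("at least two photons are needed for moment estimates")
    m = tally.means()
    s = tally.ses()
    rows = []
    for k in range(1, tally.k_max + 1):
        for qi, q in enumerate(QUANTITIES):
            mean = m[qi, k - 1]
            se = s[qi, k - 1]
            rel = se / abs(mean) if (_rel_se_defined(q, k) and mean != 0.0) else np.nan
            rows.append((k, q, mean, se, rel, tally.n_photons))
    return pd.DataFrame(rows, columns=["k", "quantity", "mean", "se", "rel_se", "n"])
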