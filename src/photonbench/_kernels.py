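"""Numba kernels for the layered-slab transport loop.

The slab simulator is an event loop per photon (free flights, interface
Fresnel decisions, scattering) that does not vectorise cleanly, so the hot
loop is compiled with numba.  Scalar helpers here mirror the vectorised
samplers in :mod:`photonbench.sampling`; the unit tests assert the two
implementations agree.

Defect codes (used by the verification sensitivity fixtures):
  0  correct physics
  1  reflectance computed with ni and nt swapped (wrong side of the critical
     angle) while refraction stays correct
  2  total-internal-reflection branch missing: a photon that should be
     trapped crosses the interface with its direction unchanged
"""

from __future__ import annotations

import numpy as np
from numba import njit

DEFECT_NONE = 0
DEFECT_SWAP_FRESNEL = 1
DEFECT_MISSING_TIR = 2

_TINY = 2.0 ** -53


@njit(cache=False)
def _fresnel_r(ni, nt, ci):
    """Unpolarized Fresnel reflectance for incidence cosine ci in (0, 1]."""
    if ni == nt:
        return 0.0
    st2 = (ni / nt) * (ni / nt) * (1.0 - ci * ci)
    if st2 >= 1.0:
        return 1.0
    ct = np.sqrt(1.0 - st2)
    rs = (ni * ci - nt * ct) / (ni * ci + nt * ct)
    rp = (nt * ci - ni * ct) / (nt * ci + ni * ct)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=False)
def _hg_cos(g, u):
    if g == 0.0:
        return 2.0 * u - 1.0
    t = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    mu = (1.0 + g * g - t * t) / (2.0 * g)
    if mu > 1.0:
        mu = 1.0
    elif mu < -1.0:
        mu = -1.0
    return mu


@njit(cache=False)
def _cbrt(x):
    if x >= 0.0:
        return x ** (1.0 / 3.0)
    return -((-x) ** (1.0 / 3.0))


@njit(cache=False)
def _rayleigh_cos(u):
    # Cardano root of mu^3 + 3 mu + (4 - 8u) = 0; discriminant >= 1 always.
    w = 4.0 * u - 2.0
    s = np.sqrt(w * w + 1.0)
    mu = _cbrt(w + s) + _cbrt(w - s)
    if mu > 1.0:
        mu = 1.0
    elif mu < -1.0:
        mu = -1.0
    return mu


@njit(cache=False)
def _rotate(ux, uy, uz, ct, phi):
    st = np.sqrt(max(0.0, 1.0 - ct * ct))
    cp = np.cos(phi)
    sp = np.sin(phi)
    if abs(uz) > 1.0 - 1e-12:
        sign = 1.0 if uz >= 0.0 else -1.0
        nx = st * cp
        ny = sign * st * sp
        nz = sign * ct
    else:
        den = np.sqrt(1.0 - uz * uz)
        nx = st * (ux * uz * cp - uy * sp) / den + ux * ct
        ny = st * (uy * uz * cp + ux * sp) / den + uy * ct
        nz = -st * cp * den + uz * ct
    norm = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=False)
def slab_kernel(seed, n_photons, edges, n_lay, mus_lay, pkind, pg, ne,
                n_bins, n_batches, event_cap, defect):
    """Trace photons through a laterally infinite layered slab.

    Photon i is injected at a point of face (i mod 2) with a cosine-weighted
    external direction (Lambertian illumination by reciprocity, alternating
    sides), Fresnel-refracted at entry, and followed until it exits either
    face.  Track lengths accumulate into per-(batch, layer, angle-bin) sums
    and per-layer per-photon totals.

    Returns (track, lsum, lsumsq, tot_sum, tot_sumsq,
             n_reflected, n_transmitted, n_aborted, n_entry_rejected).
    """
    m = n_lay.shape[0]
    z_total = edges[m]
    track = np.zeros((n_batches, m, n_bins))
    lsum = np.zeros(m)
    lsumsq = np.zeros(m)
    lpath = np.zeros(m)
    tot_sum = 0.0
    tot_sumsq = 0.0
    n_refl = 0
    n_trans = 0
    n_aborted = 0
    n_entry_rejected = 0
    bins_per_rad = n_bins / np.pi
    np.random.seed(seed)

    for i in range(n_photons):
        batch = i * n_batches // n_photons
        parity = i & 1
        entry_face = parity  # 0: z=0 face, 1: z=Z face

        # cosine-weighted polar angle in the external medium
        ce = np.sqrt(np.random.random())
        if ce < 1e-12:
            ce = 1e-12
        j = 0 if parity == 0 else m - 1
        nj = n_lay[j]
        if defect == DEFECT_SWAP_FRESNEL:
            r_entry = _fresnel_r(nj, ne, ce)
        else:
            r_entry = _fresnel_r(ne, nj, ce)
        if np.random.random() < r_entry:
            # specular entry rejection: zero internal path, exits entry side
            n_entry_rejected += 1
            n_refl += 1
            tot_sumsq += 0.0
            continue
        sin_e = np.sqrt(1.0 - ce * ce)
        sin_in = sin_e * ne / nj
        s2 = sin_in * sin_in
        if s2 >= 1.0:  # only reachable in defect modes
            s2 = 1.0 - 1e-12
            sin_in = np.sqrt(s2)
        cz = np.sqrt(1.0 - s2)
        phi = 2.0 * np.pi * np.random.random()
        ux = sin_in * np.cos(phi)
        uy = sin_in * np.sin(phi)
        uz = cz if parity == 0 else -cz
        zpos = 0.0 if parity == 0 else z_total

        tau = -1.0  # residual optical depth; < 0 means "not drawn"
        jmin = j
        jmax = j
        events = 0
        exit_face = -1  # -1 while in flight; 0/1 exit faces; -2 aborted

        while True:
            events += 1
            if events > event_cap:
                exit_face = -2
                n_aborted += 1
                break
            mus_j = mus_lay[j]
            if uz > 0.0:
                db = (edges[j + 1] - zpos) / uz
            elif uz < 0.0:
                db = (edges[j] - zpos) / uz
            else:
                db = 1e300
            scatter_here = False
            if mus_j > 0.0:
                if tau < 0.0:
                    uu = np.random.random()
                    if uu < _TINY:
                        uu = _TINY
                    tau = -np.log(uu)
                lfree = tau / mus_j
                if lfree < db:
                    scatter_here = True
                    seg = lfree
                else:
                    seg = db
            else:
                if db >= 1e299:
                    # grazing direction in a void layer: cannot progress
                    exit_face = -2
                    n_aborted += 1
                    break
                seg = db

            if seg > 0.0:
                c = uz
                if c > 1.0:
                    c = 1.0
                elif c < -1.0:
                    c = -1.0
                bidx = int(np.arccos(c) * bins_per_rad)
                if bidx >= n_bins:
                    bidx = n_bins - 1
                track[batch, j, bidx] += seg
                lpath[j] += seg

            if scatter_here:
                zpos += uz * seg
                tau = -1.0
                u = np.random.random()
                if pkind[j] == 0:
                    ct = _hg_cos(pg[j], u)
                else:
                    ct = _rayleigh_cos(u)
                phi = 2.0 * np.pi * np.random.random()
                ux, uy, uz = _rotate(ux, uy, uz, ct, phi)
                continue

            # interface interaction
            zpos = edges[j + 1] if uz > 0.0 else edges[j]
            if mus_j > 0.0:
                tau -= db * mus_j
                if tau < 0.0:
                    tau = 0.0
            if uz > 0.0:
                external = j == m - 1
                nt = ne if external else n_lay[j + 1]
            else:
                external = j == 0
                nt = ne if external else n_lay[j - 1]
            ni = n_lay[j]
            ci = abs(uz)
            st2 = (ni / nt) * (ni / nt) * (1.0 - ci * ci)

            if defect == DEFECT_MISSING_TIR and st2 >= 1.0:
                # buggy code: trapped photon crosses with direction unchanged
                if external:
                    exit_face = 1 if uz > 0.0 else 0
                    break
                j += 1 if uz > 0.0 else -1
                if j < jmin:
                    jmin = j
                if j > jmax:
                    jmax = j
                continue

            if defect == DEFECT_SWAP_FRESNEL:
                refl = _fresnel_r(nt, ni, ci)
            else:
                refl = _fresnel_r(ni, nt, ci)
            if np.random.random() < refl:
                uz = -uz
            else:
                if st2 >= 1.0:  # only reachable in defect modes
                    st2 = 1.0 - 1e-12
                scale = ni / nt
                ux *= scale
                uy *= scale
                nuz = np.sqrt(max(0.0, 1.0 - st2))
                uz = nuz if uz > 0.0 else -nuz
                if external:
                    exit_face = 1 if uz > 0.0 else 0
                    break
                j += 1 if uz > 0.0 else -1
                if j < jmin:
                    jmin = j
                if j > jmax:
                    jmax = j

        # reduce per-photon path tallies
        tot = 0.0
        for jj in range(jmin, jmax + 1):
            v = lpath[jj]
            lsum[jj] += v
            lsumsq[jj] += v * v
            tot += v
            lpath[jj] = 0.0
        tot_sum += tot
        tot_sumsq += tot * tot
        if exit_face == entry_face:
            n_refl += 1
        elif exit_face >= 0:
            n_trans += 1

    return (track, lsum, lsumsq, tot_sum, tot_sumsq,
            n_refl, n_trans, n_aborted, n_entry_rejected)
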