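"""Numba kernels for voxel photon-packet transport.

Weighted-packet Monte Carlo in the MCML lineage, adapted to a voxel grid:

* 3D DDA traversal with per-voxel path segments;
* scattering optical depth sampled once (-ln xi) and consumed across voxel
  boundaries (carry-over), so heterogeneous media are handled without bias;
* absorption applied continuously along each segment, w <- w*exp(-mu_a*l),
  with the track-length fluence estimator integral(w ds) tallied per voxel —
  valid even where mu_a = 0 (the cavity);
* unpolarized Fresnel reflection / Snell refraction at voxel faces where the
  refractive index changes; the outer grid boundary is absorbing (escape);
* Russian roulette below a weight threshold, with its weight creation /
  destruction folded into the absorbed tally so that
  absorbed + escaped = launched holds to floating-point precision;
* a counter-based per-photon RNG stream (SplitMix64 keyed by (seed, photon
  index)) so results are independent of execution order.

All positions inside the kernel are grid-corner-relative, cm.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

SRC_POINT = 0
SRC_FIBER = 1

_WMIN = 1e-4         # roulette trigger weight
_PSURV = 0.1         # roulette survival probability
_DIR_EPS = 1e-12
_MAX_STEPS = 50_000_000  # per-photon safeguard; never reached in practice

_SM_GAMMA = np.uint64(0x9E3779B97F4A7C15)
_SM_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_SM_MIX2 = np.uint64(0x94D049BB133111EB)
_KEY_MIX = np.uint64(0xD1B54A32D192ED03)
_INV_2_53 = 1.0 / 9007199254740992.0  # 2^-53


@njit(cache=True, inline="always")
def _sm_next(state):
    """SplitMix64 step: returns (new_state, uniform float64 in [0, 1))."""
    state = state + _SM_GAMMA
    z = state
    z = (z ^ (z >> np.uint64(30))) * _SM_MIX1
    z = (z ^ (z >> np.uint64(27))) * _SM_MIX2
    z = z ^ (z >> np.uint64(31))
    return state, float(z >> np.uint64(11)) * _INV_2_53


@njit(cache=True, inline="always")
def _photon_state(seed, ip):
    """Independent per-photon stream keyed by (seed, photon index)."""
    s = (np.uint64(seed) * _SM_GAMMA) ^ ((np.uint64(ip) + np.uint64(1)) * _KEY_MIX)
    # burn two outputs to decorrelate nearby keys
    s, _ = _sm_next(s)
    s, _ = _sm_next(s)
    return s


@njit(cache=True, inline="always")
def _fresnel(ni, nt, ci):
    """Unpolarized Fresnel reflectance; 1 beyond the critical angle."""
    if ni == nt:
        return 0.0
    if ci > 1.0:
        ci = 1.0
    si = math.sqrt(max(0.0, 1.0 - ci * ci))
    st = ni * si / nt
    if st >= 1.0:
        return 1.0
    ct = math.sqrt(1.0 - st * st)
    rs = (ni * ci - nt * ct) / (ni * ci + nt * ct)
    rp = (nt * ci - ni * ct) / (nt * ci + ni * ct)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, inline="always")
def _sample_hg(g, u):
    """Henyey–Greenstein cos(theta) via the closed-form inverse CDF."""
    if abs(g) < 1e-6:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    return ct


@njit(cache=True, inline="always")
def _spin(ux, uy, uz, ct, phi):
    """Rotate a unit direction by polar angle acos(ct), azimuth phi (MCML)."""
    st = math.sqrt(max(0.0, 1.0 - ct * ct))
    cp = math.cos(phi)
    sp = math.sin(phi)
    if abs(uz) > 0.99999:
        nx = st * cp
        ny = st * sp
        nz = ct if uz >= 0.0 else -ct
    else:
        den = math.sqrt(1.0 - uz * uz)
        nx = st * (ux * uz * cp - uy * sp) / den + ux * ct
        ny = st * (uy * uz * cp + ux * sp) / den + uy * ct
        nz = -st * cp * den + uz * ct
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True)
def run_transport(
    labels,          # (nx, ny, nz) int8
    mua, mus, gfac, nidx,  # per-label arrays, length 3
    hx, hy, hz,      # spacing, cm
    src_kind,        # SRC_POINT or SRC_FIBER
    sx, sy, sz,      # source position, corner-relative cm
    ax, ay, az,      # fiber axis (unit)
    e1x, e1y, e1z,   # fiber frame vector 1 (unit, perp to axis)
    e2x, e2y, e2z,   # fiber frame vector 2
    core_r,          # fiber core radius, cm
    cos_max,         # cos of acceptance half-angle in the launch medium
    n_photons,
    seed,
    fluence,         # (nx, ny, nz) float64 output, raw sum(w*dl)
):
    """Propagate photon packets; returns (absorbed_weight, escaped_weight)."""
    nx_, ny_, nz_ = labels.shape
    absorbed = 0.0
    escaped = 0.0

    for ip in range(n_photons):
        st8 = _photon_state(seed, ip)

        # --- launch ---
        if src_kind == SRC_POINT:
            st8, u = _sm_next(st8)
            ct = 2.0 * u - 1.0
            st8, u = _sm_next(st8)
            phi = 2.0 * math.pi * u
            s_ = math.sqrt(max(0.0, 1.0 - ct * ct))
            dx = s_ * math.cos(phi)
            dy = s_ * math.sin(phi)
            dz = ct
            px, py, pz = sx, sy, sz
        else:
            st8, u = _sm_next(st8)
            rr = core_r * math.sqrt(u)
            st8, u = _sm_next(st8)
            psi = 2.0 * math.pi * u
            ox = rr * (math.cos(psi) * e1x + math.sin(psi) * e2x)
            oy = rr * (math.cos(psi) * e1y + math.sin(psi) * e2y)
            oz = rr * (math.cos(psi) * e1z + math.sin(psi) * e2z)
            px, py, pz = sx + ox, sy + oy, sz + oz
            st8, u = _sm_next(st8)
            ct = 1.0 - u * (1.0 - cos_max)  # uniform in solid angle inside cone
            st8, u = _sm_next(st8)
            phi = 2.0 * math.pi * u
            s_ = math.sqrt(max(0.0, 1.0 - ct * ct))
            dx = s_ * (math.cos(phi) * e1x + math.sin(phi) * e2x) + ct * ax
            dy = s_ * (math.cos(phi) * e1y + math.sin(phi) * e2y) + ct * ay
            dz = s_ * (math.cos(phi) * e1z + math.sin(phi) * e2z) + ct * az

        ix = int(px / hx)
        iy = int(py / hy)
        iz = int(pz / hz)
        if ix < 0 or ix >= nx_ or iy < 0 or iy >= ny_ or iz < 0 or iz >= nz_:
            escaped += 1.0
            continue

        w = 1.0
        st8, u = _sm_next(st8)
        tau = -math.log(1.0 - u)  # dimensionless scattering depth

        alive = True
        nstep = 0
        while alive:
            nstep += 1
            if nstep > _MAX_STEPS:
                escaped += w
                break
            lab = labels[ix, iy, iz]
            ma = mua[lab]
            ms = mus[lab]
            nn = nidx[lab]

            # distance to the next voxel face along each axis
            if dx > _DIR_EPS:
                tbx = ((ix + 1) * hx - px) / dx
            elif dx < -_DIR_EPS:
                tbx = (ix * hx - px) / dx
            else:
                tbx = 1e30
            if dy > _DIR_EPS:
                tby = ((iy + 1) * hy - py) / dy
            elif dy < -_DIR_EPS:
                tby = (iy * hy - py) / dy
            else:
                tby = 1e30
            if dz > _DIR_EPS:
                tbz = ((iz + 1) * hz - pz) / dz
            elif dz < -_DIR_EPS:
                tbz = (iz * hz - pz) / dz
            else:
                tbz = 1e30

            axis = 0
            tb = tbx
            if tby < tb:
                tb = tby
                axis = 1
            if tbz < tb:
                tb = tbz
                axis = 2
            if tb < 0.0:
                tb = 0.0

            if ms > 0.0:
                tsc = tau / ms
            else:
                tsc = 1e30
            scatter = tsc <= tb
            s_seg = tsc if scatter else tb

            # --- tally (track length) and continuous absorption ---
            if ma > 0.0:
                att = math.exp(-ma * s_seg)
                fluence[ix, iy, iz] += w * (1.0 - att) / ma
                absorbed += w * (1.0 - att)
                w *= att
            else:
                fluence[ix, iy, iz] += w * s_seg

            px += s_seg * dx
            py += s_seg * dy
            pz += s_seg * dz
            tau -= s_seg * ms

            if scatter:
                st8, u = _sm_next(st8)
                ct = _sample_hg(gfac[lab], u)
                st8, u = _sm_next(st8)
                phi = 2.0 * math.pi * u
                dx, dy, dz = _spin(dx, dy, dz, ct, phi)
                st8, u = _sm_next(st8)
                tau = -math.log(1.0 - u)
            else:
                # --- voxel face crossing ---
                jx, jy, jz = ix, iy, iz
                if axis == 0:
                    if dx > 0.0:
                        jx += 1
                        px = jx * hx
                    else:
                        px = ix * hx
                        jx -= 1
                elif axis == 1:
                    if dy > 0.0:
                        jy += 1
                        py = jy * hy
                    else:
                        py = iy * hy
                        jy -= 1
                else:
                    if dz > 0.0:
                        jz += 1
                        pz = jz * hz
                    else:
                        pz = iz * hz
                        jz -= 1

                if jx < 0 or jx >= nx_ or jy < 0 or jy >= ny_ or jz < 0 or jz >= nz_:
                    escaped += w
                    alive = False
                else:
                    n2 = nidx[labels[jx, jy, jz]]
                    if n2 != nn:
                        if axis == 0:
                            ci = abs(dx)
                        elif axis == 1:
                            ci = abs(dy)
                        else:
                            ci = abs(dz)
                        refl = _fresnel(nn, n2, ci)
                        st8, u = _sm_next(st8)
                        if u < refl:
                            # total / partial internal reflection: stay put
                            if axis == 0:
                                dx = -dx
                            elif axis == 1:
                                dy = -dy
                            else:
                                dz = -dz
                        else:
                            ratio = nn / n2
                            ct2 = math.sqrt(max(0.0, 1.0 - ratio * ratio * (1.0 - ci * ci)))
                            if axis == 0:
                                sgn = 1.0 if dx > 0.0 else -1.0
                                dy *= ratio
                                dz *= ratio
                                dx = sgn * ct2
                            elif axis == 1:
                                sgn = 1.0 if dy > 0.0 else -1.0
                                dx *= ratio
                                dz *= ratio
                                dy = sgn * ct2
                            else:
                                sgn = 1.0 if dz > 0.0 else -1.0
                                dx *= ratio
                                dy *= ratio
                                dz = sgn * ct2
                            ix, iy, iz = jx, jy, jz
                    else:
                        ix, iy, iz = jx, jy, jz

            # --- Russian roulette (weight-conserving bookkeeping) ---
            if alive and w < _WMIN:
                st8, u = _sm_next(st8)
                if u < _PSURV:
                    wnew = w / _PSURV
                    absorbed -= wnew - w
                    w = wnew
                else:
                    absorbed += w
                    alive = False

    return absorbed, escaped
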