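"""Compiled single-CPU photon-transport kernel.

Everything here operates on plain arrays in voxel coordinates (world cm /
dx) and is jitted with numba; :mod:`voxlight.transport` provides the typed
user-facing surface and a pure-Python reference stepper that mirrors this
kernel draw-for-draw.

Random numbers come from a per-photon xorshift64* stream seeded with a
splitmix64 hash of (run seed, photon index), so runs are bitwise
reproducible and photon i's trajectory does not depend on how many photons
run before it.

Boundary modes: 0 = matched (no Fresnel), 1 = facet normal, 2 = stored
surface normal of the pre-crossing voxel, 3 = masked trilinear interpolation
of same-medium surface normals at the crossing point.  Zero-vector normals
fall back surface -> facet and interpolated -> stored -> facet.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

#: voxel-units offset applied after a face event to step off the face
NUDGE = 1e-7
#: hard cap on events per photon (guards against pathological loops)
MAX_EVENTS = 20_000_000

# stats slots
S_LAUNCHED, S_DEPOSITED, S_ESCAPED, S_KILLED, S_BOOSTED, S_LOST = range(6)

# escape-row columns
E_FACE, E_X, E_Y, E_Z, E_UX, E_UY, E_UZ, E_W, E_NREFL, E_NTRANS = range(10)

_U64 = np.uint64
_GOLDEN = _U64(0x9E3779B97F4A7C15)
_MIX1 = _U64(0xBF58476D1CE4E5B9)
_MIX2 = _U64(0x94D049BB133111EB)
_XSMULT = _U64(2685821657736338717)
_INV53 = 1.0 / 9007199254740992.0  # 2^-53


@njit(cache=True)
def _seed_state(seed, index):
    """splitmix64 hash of (seed, photon index) -> nonzero uint64 state."""
    z = (_U64(seed) + _U64(1)) * _GOLDEN + (_U64(index) + _U64(1)) * _GOLDEN
    z = (z ^ (z >> _U64(30))) * _MIX1
    z = (z ^ (z >> _U64(27))) * _MIX2
    z = z ^ (z >> _U64(31))
    if z == _U64(0):
        z = _GOLDEN
    return z


@njit(cache=True)
def _rand(state):
    """xorshift64* uniform double in [0, 1)."""
    s = state[0]
    s ^= s >> _U64(12)
    s ^= (s << _U64(25)) & _U64(0xFFFFFFFFFFFFFFFF)
    s ^= s >> _U64(27)
    state[0] = s
    return float((s * _XSMULT) >> _U64(11)) * _INV53


@njit(cache=True)
def _fresnel(ci, n1, n2):
    if n1 == n2:
        return 0.0
    sin_t2 = (n1 / n2) * (n1 / n2) * (1.0 - ci * ci)
    if sin_t2 >= 1.0:
        return 1.0
    ct = math.sqrt(1.0 - sin_t2)
    rs = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
    rp = (n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def _hg_cos(g, u):
    """Henyey-Greenstein cos(theta) from a uniform deviate."""
    if abs(g) < 1e-12:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    return ct


@njit(cache=True)
def _spin_dir(ux, uy, uz, ct, phi):
    """Rotate a unit direction by scattering angle acos(ct) and azimuth phi."""
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
        nz = -den * st * cp + uz * ct
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True)
def _interp_normal(gx, gy, gz, labels, nv, px, py, pz, ci, cj, ck):
    """Masked trilinear blend of same-medium vertex normals at (px,py,pz)."""
    nx_, ny_, nz_ = labels.shape
    n_cur = nv[labels[ci, cj, ck]]
    rx = math.floor(px + 0.5)
    ry = math.floor(py + 0.5)
    rz = math.floor(pz + 0.5)
    xd = px - rx + 0.5
    yd = py - ry + 0.5
    zd = pz - rz + 0.5
    lx = int(rx) - 1
    ly = int(ry) - 1
    lz = int(rz) - 1
    ax = 0.0
    ay = 0.0
    az = 0.0
    for a in range(2):
        i = lx + a
        if i < 0 or i >= nx_:
            continue
        wx = xd if a == 1 else 1.0 - xd
        for b in range(2):
            j = ly + b
            if j < 0 or j >= ny_:
                continue
            wy = yd if b == 1 else 1.0 - yd
            for c in range(2):
                k = lz + c
                if k < 0 or k >= nz_:
                    continue
                if nv[labels[i, j, k]] != n_cur:
                    continue
                w = wx * wy * (zd if c == 1 else 1.0 - zd)
                ax += w * gx[i, j, k]
                ay += w * gy[i, j, k]
                az += w * gz[i, j, k]
    norm = math.sqrt(ax * ax + ay * ay + az * az)
    if norm < 1e-9:
        return 0.0, 0.0, 0.0
    return ax / norm, ay / norm, az / norm


@njit(cache=True)
def _boundary_normal(mode, axis, sgn, gx, gy, gz, labels, nv,
                     px, py, pz, ci, cj, ck):
    """Boundary normal for a face crossing, before orientation.

    Falls back to the axis-aligned facet normal whenever the requested
    estimate is the zero vector.
    """
    if mode >= 3:
        nx, ny, nz = _interp_normal(gx, gy, gz, labels, nv, px, py, pz, ci, cj, ck)
        if nx != 0.0 or ny != 0.0 or nz != 0.0:
            return nx, ny, nz
    if mode >= 2:
        nx = float(gx[ci, cj, ck])
        ny = float(gy[ci, cj, ck])
        nz = float(gz[ci, cj, ck])
        if nx != 0.0 or ny != 0.0 or nz != 0.0:
            return nx, ny, nz
    # facet normal opposing the direction of travel along the crossed axis
    nx = 0.0
    ny = 0.0
    nz = 0.0
    if axis == 0:
        nx = -float(sgn)
    elif axis == 1:
        ny = -float(sgn)
    else:
        nz = -float(sgn)
    return nx, ny, nz


@njit(cache=True)
def _trace(labels, nv, muav, musv, gv, gx, gy, gz, dx, mode,
           rth, rsurv, state, x, y, z, ux, uy, uz,
           fluence, esc, row, stats):
    nx_, ny_, nz_ = labels.shape
    w = 1.0
    sleft = 0.0
    nrefl = 0
    ntrans = 0
    for _ in range(MAX_EVENTS):
        ix = int(math.floor(x))
        iy = int(math.floor(y))
        iz = int(math.floor(z))
        if ix < 0 or ix >= nx_ or iy < 0 or iy >= ny_ or iz < 0 or iz >= nz_:
            # can only happen for a source disk poking out of the grid
            stats[S_LOST] += w
            return
        lab = labels[ix, iy, iz]
        mua = muav[lab]
        mus = musv[lab]
        mut = mua + mus
        # distance (voxel units) to the voxel faces along the direction
        if ux > 1e-12:
            tx = (ix + 1 - x) / ux
        elif ux < -1e-12:
            tx = (ix - x) / ux
        else:
            tx = 1e30
        if uy > 1e-12:
            ty = (iy + 1 - y) / uy
        elif uy < -1e-12:
            ty = (iy - y) / uy
        else:
            ty = 1e30
        if uz > 1e-12:
            tz = (iz + 1 - z) / uz
        elif uz < -1e-12:
            tz = (iz - z) / uz
        else:
            tz = 1e30
        if tx <= ty and tx <= tz:
            tface = tx
            axis = 0
            sgn = 1 if ux > 0 else -1
        elif ty <= tz:
            tface = ty
            axis = 1
            sgn = 1 if uy > 0 else -1
        else:
            tface = tz
            axis = 2
            sgn = 1 if uz > 0 else -1
        if mut > 0.0:
            if sleft <= 0.0:
                sleft = -math.log(1.0 - _rand(state))
            tint = sleft / (mut * dx)
            if tint <= tface:
                # interaction inside this voxel: drop then spin
                x += tint * ux
                y += tint * uy
                z += tint * uz
                sleft = 0.0
                dw = w * mua / mut
                fluence[ix, iy, iz] += dw
                stats[S_DEPOSITED] += dw
                w -= dw
                ct = _hg_cos(gv[lab], _rand(state))
                phi = 2.0 * math.pi * _rand(state)
                ux, uy, uz = _spin_dir(ux, uy, uz, ct, phi)
                if w < rth:
                    if _rand(state) <= 1.0 / rsurv:
                        stats[S_BOOSTED] += w * (rsurv - 1.0)
                        w *= rsurv
                    else:
                        stats[S_KILLED] += w
                        return
                continue
            sleft -= tface * mut * dx
        # advance to the face and snap the crossed coordinate exactly onto it
        x += tface * ux
        y += tface * uy
        z += tface * uz
        if axis == 0:
            x = float(ix + 1) if sgn > 0 else float(ix)
        elif axis == 1:
            y = float(iy + 1) if sgn > 0 else float(iy)
        else:
            z = float(iz + 1) if sgn > 0 else float(iz)
        jx, jy, jz = ix, iy, iz
        if axis == 0:
            jx += sgn
        elif axis == 1:
            jy += sgn
        else:
            jz += sgn
        if jx < 0 or jx >= nx_ or jy < 0 or jy >= ny_ or jz < 0 or jz >= nz_:
            # grid exit: record the escape
            esc[row, E_FACE] = float(2 * axis + (1 if sgn > 0 else 0))
            esc[row, E_X] = x * dx
            esc[row, E_Y] = y * dx
            esc[row, E_Z] = z * dx
            esc[row, E_UX] = ux
            esc[row, E_UY] = uy
            esc[row, E_UZ] = uz
            esc[row, E_W] = w
            esc[row, E_NREFL] = float(nrefl)
            esc[row, E_NTRANS] = float(ntrans)
            stats[S_ESCAPED] += w
            return
        n1 = nv[lab]
        n2 = nv[labels[jx, jy, jz]]
        if mode == 0 or n1 == n2:
            x += NUDGE * ux
            y += NUDGE * uy
            z += NUDGE * uz
            continue
        bnx, bny, bnz = _boundary_normal(mode, axis, sgn, gx, gy, gz,
                                         labels, nv, x, y, z, ix, iy, iz)
        # orient against the incident direction
        dot = bnx * ux + bny * uy + bnz * uz
        if dot > 0.0:
            bnx = -bnx
            bny = -bny
            bnz = -bnz
            dot = -dot
        ci = -dot
        if ci > 1.0:
            ci = 1.0
        if _rand(state) <= _fresnel(ci, n1, n2):
            ux = ux - 2.0 * dot * bnx
            uy = uy - 2.0 * dot * bny
            uz = uz - 2.0 * dot * bnz
            norm = math.sqrt(ux * ux + uy * uy + uz * uz)
            ux /= norm
            uy /= norm
            uz /= norm
            nrefl += 1
        else:
            eta = n1 / n2
            sin_t2 = eta * eta * (1.0 - ci * ci)
            ct = math.sqrt(max(0.0, 1.0 - sin_t2))
            ux = eta * ux + (eta * ci - ct) * bnx
            uy = eta * uy + (eta * ci - ct) * bny
            uz = eta * uz + (eta * ci - ct) * bnz
            norm = math.sqrt(ux * ux + uy * uy + uz * uz)
            ux /= norm
            uy /= norm
            uz /= norm
            ntrans += 1
        x += NUDGE * ux
        y += NUDGE * uy
        z += NUDGE * uz
    stats[S_LOST] += w


@njit(cache=True)
def _launch_one(state, ox, oy, oz, sdx, sdy, sdz, radius_vox):
    """Sample one photon start on a collimated disk (voxel coordinates)."""
    x, y, z = ox, oy, oz
    if radius_vox > 0.0:
        # orthonormal frame perpendicular to the beam axis
        if abs(sdx) < 0.9:
            vx, vy, vz = 1.0, 0.0, 0.0
        else:
            vx, vy, vz = 0.0, 1.0, 0.0
        e1x = sdy * vz - sdz * vy
        e1y = sdz * vx - sdx * vz
        e1z = sdx * vy - sdy * vx
        norm = math.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
        e1x /= norm
        e1y /= norm
        e1z /= norm
        e2x = sdy * e1z - sdz * e1y
        e2y = sdz * e1x - sdx * e1z
        e2z = sdx * e1y - sdy * e1x
        r = radius_vox * math.sqrt(_rand(state))
        th = 2.0 * math.pi * _rand(state)
        ca = r * math.cos(th)
        sa = r * math.sin(th)
        x += ca * e1x + sa * e2x
        y += ca * e1y + sa * e2y
        z += ca * e1z + sa * e2z
    # step off any face/edge the start point may sit on
    x += 1e-6 * sdx
    y += 1e-6 * sdy
    z += 1e-6 * sdz
    return x, y, z


@njit(cache=True)
def run_kernel(labels, nv, muav, musv, gv, gx, gy, gz, dx, mode,
               n_photons, seed, ox, oy, oz, sdx, sdy, sdz, radius_vox,
               rth, rsurv, fluence, esc, launches, stats):
    state = np.empty(1, dtype=np.uint64)
    for i in range(n_photons):
        state[0] = _seed_state(seed, i)
        x, y, z = _launch_one(state, ox, oy, oz, sdx, sdy, sdz, radius_vox)
        launches[i, 0] = x * dx
        launches[i, 1] = y * dx
        launches[i, 2] = z * dx
        launches[i, 3] = sdx
        launches[i, 4] = sdy
        launches[i, 5] = sdz
        stats[S_LAUNCHED] += 1.0
        _trace(labels, nv, muav, musv, gv, gx, gy, gz, dx, mode,
               rth, rsurv, state, x, y, z, sdx, sdy, sdz,
               fluence, esc, i, stats)


@njit(cache=True)
def rng_stream(seed, index, n):
    """The exact uniform stream photon ``index`` consumes (for the reference
    stepper and for tests)."""
    state = np.empty(1, dtype=np.uint64)
    state[0] = _seed_state(seed, index)
    out = np.empty(n)
    for i in range(n):
        out[i] = _rand(state)
    return out


@njit(cache=True)
def hg_cos_samples(g, u):
    """Vectorized Henyey-Greenstein cos(theta) transform of uniforms."""
    out = np.empty(u.size)
    for i in range(u.size):
        out[i] = _hg_cos(g, u[i])
    return out
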