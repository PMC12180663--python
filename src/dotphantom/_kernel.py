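"""Numba kernel for voxel Monte Carlo photon transport in a slab.

Implementation notes (the contracts live in :mod:`dotphantom.mc`):

* Weighted packets with implicit capture: the packet weight is
  ``mult * exp(-att)`` where ``att`` accumulates mua * pathlength and
  ``mult`` collects Russian-roulette boosts.  The exponential is evaluated
  lazily (on exit and at roulette checkpoints only), so the inner loop is
  free of transcendentals apart from the step-length log.
* Two-zone geometry: outside the bounding box of the non-host voxels the
  medium is the homogeneous host and only slab faces / box entry need ray
  tests; inside the box a per-voxel traversal runs.  In both zones a cheap
  lower bound on the distance to the nearest material change (slab-face
  gaps outside, a precomputed safe-distance map inside) lets most flights
  scatter without any boundary computation.
* Refractive-index changes are handled at axis-aligned faces with
  unpolarized Fresnel reflect-or-transmit sampling and Snell refraction;
  total internal reflection falls out of the same expressions.
* The RNG is a counter-based xorshift64* stream seeded per photon index via
  splitmix64, so results are bit-reproducible for a fixed (seed, n_photons)
  regardless of batching.  Isotropic deflections use Marsaglia's
  uniform-sphere method; anisotropic ones Henyey-Greenstein with a
  rejection-sampled azimuth (no trigonometric calls either way).

Tally layout (float64[9]): 0 detected weight, 1 weighted detected pathlength
sum, 2 absorbed, 3 back-reflected, 4 side-escaped, 5 roulette-killed,
6 roulette-gain, 7 detected packet count, 8 unused.
"""

import math

import numpy as np
from numba import njit, uint64

MASK64 = uint64(0xFFFFFFFFFFFFFFFF)
_EPS_NUDGE = 1e-7  # mm; push across a face after a boundary event
_BIG = 1e30


@njit(cache=True, fastmath=True, inline="always")
def _splitmix64(z):
    z = (z + uint64(0x9E3779B97F4A7C15)) & MASK64
    z = ((z ^ (z >> uint64(30))) * uint64(0xBF58476D1CE4E5B9)) & MASK64
    z = ((z ^ (z >> uint64(27))) * uint64(0x94D049BB133111EB)) & MASK64
    return (z ^ (z >> uint64(31))) & MASK64


@njit(cache=True, fastmath=True, inline="always")
def _rng_next(state):
    s = state
    s ^= (s >> uint64(12))
    s &= MASK64
    s ^= (s << uint64(25)) & MASK64
    s ^= (s >> uint64(27))
    s &= MASK64
    val = (s * uint64(0x2545F4914F6CDD1D)) & MASK64
    # 53-bit mantissa, strictly inside (0, 1)
    u = (float(val >> uint64(11)) + 0.5) * (1.0 / 9007199254740992.0)
    return u, s


@njit(cache=True, fastmath=True, inline="always")
def _photon_state(seed_base, i):
    st = _splitmix64(seed_base ^ (uint64(i) * uint64(0x9E3779B97F4A7C15)))
    if st == uint64(0):
        st = uint64(0x1234567887654321)
    return st


@njit(cache=True, fastmath=True, inline="always")
def _hg_cos(g, u):
    """Henyey-Greenstein polar-angle cosine from a uniform deviate."""
    if g < 1e-6:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    c = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return c


@njit(cache=True, fastmath=True, inline="always")
def _fresnel_r(n1, n2, ci):
    """Unpolarized Fresnel reflectance; returns (R, cos of refracted angle)."""
    if n1 == n2:
        return 0.0, ci
    sin_t2 = (n1 / n2) * (n1 / n2) * (1.0 - ci * ci)
    if sin_t2 >= 1.0:
        return 1.0, 0.0
    ct = math.sqrt(1.0 - sin_t2)
    rs = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
    rp = (n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)
    return 0.5 * (rs * rs + rp * rp), ct


@njit(cache=True, fastmath=True, inline="always")
def _spin(ux, uy, uz, cost, cosp, sinp):
    sint = math.sqrt(max(0.0, 1.0 - cost * cost))
    if abs(uz) > 0.99999:
        nx = sint * cosp
        ny = sint * sinp
        nz = cost if uz >= 0.0 else -cost
    else:
        tmp = math.sqrt(1.0 - uz * uz)
        nx = sint * (ux * uz * cosp - uy * sinp) / tmp + ux * cost
        ny = sint * (uy * uz * cosp + ux * sinp) / tmp + uy * cost
        nz = -sint * cosp * tmp + uz * cost
    # renormalize to curb drift
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True, fastmath=True, inline="always")
def _scatter_dir(st, g, ux, uy, uz):
    """Draw a post-scattering direction; returns (state, ux, uy, uz)."""
    if g < 1e-6:
        # isotropic: uniform direction on the sphere (Marsaglia)
        while True:
            u, st = _rng_next(st)
            pa = 2.0 * u - 1.0
            u, st = _rng_next(st)
            pb = 2.0 * u - 1.0
            r2 = pa * pa + pb * pb
            if 0.0 < r2 <= 1.0:
                break
        tmp = 2.0 * math.sqrt(1.0 - r2)
        return st, pa * tmp, pb * tmp, 1.0 - 2.0 * r2
    u, st = _rng_next(st)
    cost = _hg_cos(g, u)
    while True:
        u, st = _rng_next(st)
        pa = 2.0 * u - 1.0
        u, st = _rng_next(st)
        pb = 2.0 * u - 1.0
        r2 = pa * pa + pb * pb
        if 0.0 < r2 <= 1.0:
            break
    inv = 1.0 / r2
    cosp = (pa * pa - pb * pb) * inv
    sinp = 2.0 * pa * pb * inv
    nx, ny, nz = _spin(ux, uy, uz, cost, cosp, sinp)
    return st, nx, ny, nz


@njit(cache=True, fastmath=True)
def run_photons(
    labels,            # uint8 (nx, ny, nz)
    dsafe,             # float64 (nx, ny, nz): lower bound on distance to a
                       # material change, 0 where unknown (forces traversal)
    mua_tab, mus_tab, n_tab, g_tab,   # float64[nlabels]
    h,                 # voxel size, mm
    ox, oy,            # physical origin of x/y axes (z origin = 0)
    lx, ly, d,         # physical slab extents, mm
    ext_n,
    bxlo, bxhi, bylo, byhi, bzlo, bzhi, have_box,
    x0, y0,            # pencil-beam entry point
    n_photons, seed,
    img,               # float64 (npix, npix), row = y, col = x
    img_inv,           # float64 (npix, npix): weights scored with 1/cos_in
    npix, pitch, det_cos_min,
    roulette_threshold, roulette_factor,
):
    tallies = np.zeros(9, dtype=np.float64)
    seed_base = _splitmix64(uint64(seed))
    half_field = 0.5 * npix * pitch
    log_thresh = math.log(roulette_threshold) if roulette_threshold > 0 else -_BIG
    nx_v, ny_v, nz_v = labels.shape

    for i in range(n_photons):
        st = _photon_state(seed_base, i)
        x = x0
        y = y0
        z = _EPS_NUDGE
        ux = 0.0
        uy = 0.0
        uz = 1.0
        att = 0.0
        path = 0.0
        mult = 1.0
        w_ref = 1.0
        # roulette triggers when weight < threshold: att > log(mult) - log(thr)
        att_kill = -log_thresh
        u, st = _rng_next(st)
        s = -math.log(u)
        alive = True

        while alive:
            in_box = have_box and (bxlo <= x < bxhi and bylo <= y < byhi
                                   and bzlo <= z < bzhi)
            ix = 0
            iy = 0
            iz = 0
            if in_box:
                ix = int((x - ox) / h)
                iy = int((y - oy) / h)
                iz = int(z / h)
                if ix < 0:
                    ix = 0
                elif ix >= nx_v:
                    ix = nx_v - 1
                if iy < 0:
                    iy = 0
                elif iy >= ny_v:
                    iy = ny_v - 1
                if iz < 0:
                    iz = 0
                elif iz >= nz_v:
                    iz = nz_v - 1
                lab = int(labels[ix, iy, iz])
            else:
                lab = 0
            mua = mua_tab[lab]
            mus = mus_tab[lab]
            t_s = _BIG if mus <= 0.0 else s / mus

            # --- free-flight fast path --------------------------------------
            # Lower bound on the distance to anything that could matter: slab
            # faces always; outside the box additionally the Chebyshev gap to
            # the box, inside it the precomputed safe distance.
            if t_s < _BIG:
                db = z if z < d - z else d - z
                t = x - ox
                if t < db:
                    db = t
                t = ox + lx - x
                if t < db:
                    db = t
                t = y - oy
                if t < db:
                    db = t
                t = oy + ly - y
                if t < db:
                    db = t
                if in_box:
                    t = dsafe[ix, iy, iz]
                    if t < db:
                        db = t
                elif have_box:
                    gb = bxlo - x
                    t = x - bxhi
                    if t > gb:
                        gb = t
                    t = bylo - y
                    if t > gb:
                        gb = t
                    t = y - byhi
                    if t > gb:
                        gb = t
                    t = bzlo - z
                    if t > gb:
                        gb = t
                    t = z - bzhi
                    if t > gb:
                        gb = t
                    if gb < db:
                        db = gb
                if t_s < db:
                    x += ux * t_s
                    y += uy * t_s
                    z += uz * t_s
                    att += mua * t_s
                    path += t_s
                    st, ux, uy, uz = _scatter_dir(st, g_tab[lab], ux, uy, uz)
                    u, st = _rng_next(st)
                    s = -math.log(u)
                    if att > att_kill:
                        w = mult * math.exp(-att)
                        tallies[2] += w_ref - w
                        u, st = _rng_next(st)
                        if u * roulette_factor < 1.0:
                            mult *= roulette_factor
                            tallies[6] += (roulette_factor - 1.0) * w
                            w_ref = mult * math.exp(-att)
                            att_kill = math.log(mult) - log_thresh
                        else:
                            tallies[5] += w
                            alive = False
                    continue

            # --- nearest boundary along the direction of flight -------------
            t_b = _BIG
            axis = -1
            if in_box:
                if ux > 0.0:
                    t = ((ix + 1) * h + ox - x) / ux
                    if t < t_b:
                        t_b = t
                        axis = 0
                elif ux < 0.0:
                    t = (ix * h + ox - x) / ux
                    if t < t_b:
                        t_b = t
                        axis = 0
                if uy > 0.0:
                    t = ((iy + 1) * h + oy - y) / uy
                    if t < t_b:
                        t_b = t
                        axis = 1
                elif uy < 0.0:
                    t = (iy * h + oy - y) / uy
                    if t < t_b:
                        t_b = t
                        axis = 1
                if uz > 0.0:
                    t = ((iz + 1) * h - z) / uz
                    if t < t_b:
                        t_b = t
                        axis = 2
                elif uz < 0.0:
                    t = (iz * h - z) / uz
                    if t < t_b:
                        t_b = t
                        axis = 2
            else:
                if ux > 0.0:
                    t = (ox + lx - x) / ux
                    if t < t_b:
                        t_b = t
                        axis = 0
                elif ux < 0.0:
                    t = (ox - x) / ux
                    if t < t_b:
                        t_b = t
                        axis = 0
                if uy > 0.0:
                    t = (oy + ly - y) / uy
                    if t < t_b:
                        t_b = t
                        axis = 1
                elif uy < 0.0:
                    t = (oy - y) / uy
                    if t < t_b:
                        t_b = t
                        axis = 1
                if uz > 0.0:
                    t = (d - z) / uz
                    if t < t_b:
                        t_b = t
                        axis = 2
                elif uz < 0.0:
                    t = -z / uz
                    if t < t_b:
                        t_b = t
                        axis = 2
                if have_box:
                    # ray/AABB entry distance to the heterogeneous region
                    tmin = 0.0
                    tmax = t_b
                    hit = True
                    for a in range(3):
                        if a == 0:
                            p = x
                            uu = ux
                            lo = bxlo
                            hi = bxhi
                        elif a == 1:
                            p = y
                            uu = uy
                            lo = bylo
                            hi = byhi
                        else:
                            p = z
                            uu = uz
                            lo = bzlo
                            hi = bzhi
                        if uu == 0.0:
                            if p < lo or p >= hi:
                                hit = False
                                break
                        else:
                            t1 = (lo - p) / uu
                            t2 = (hi - p) / uu
                            if t1 > t2:
                                t1, t2 = t2, t1
                            if t1 > tmin:
                                tmin = t1
                            if t2 < tmax:
                                tmax = t2
                            if tmin > tmax:
                                hit = False
                                break
                    if hit and tmin > 0.0 and tmin < t_b:
                        t_b = tmin
                        axis = 3  # box entry: no optical interface by itself

            if t_s < t_b:
                # --- scattering event ---
                x += ux * t_s
                y += uy * t_s
                z += uz * t_s
                att += mua * t_s
                path += t_s
                st, ux, uy, uz = _scatter_dir(st, g_tab[lab], ux, uy, uz)
                u, st = _rng_next(st)
                s = -math.log(u)
                if att > att_kill:
                    w = mult * math.exp(-att)
                    tallies[2] += w_ref - w
                    u, st = _rng_next(st)
                    if u * roulette_factor < 1.0:
                        mult *= roulette_factor
                        tallies[6] += (roulette_factor - 1.0) * w
                        w_ref = mult * math.exp(-att)
                        att_kill = math.log(mult) - log_thresh
                    else:
                        tallies[5] += w
                        alive = False
            else:
                # --- boundary event ---
                x += ux * t_b
                y += uy * t_b
                z += uz * t_b
                att += mua * t_b
                path += t_b
                s -= mus * t_b
                if s < 0.0:
                    s = 0.0
                if axis == 3:
                    # entered the heterogeneous bounding box; same host medium
                    x += ux * _EPS_NUDGE
                    y += uy * _EPS_NUDGE
                    z += uz * _EPS_NUDGE
                    continue
                # probe the medium on the far side of the face
                qx = x + ux * _EPS_NUDGE
                qy = y + uy * _EPS_NUDGE
                qz = z + uz * _EPS_NUDGE
                exterior = (qz <= 0.0 or qz >= d or qx <= ox or qx >= ox + lx
                            or qy <= oy or qy >= oy + ly)
                if exterior:
                    n2 = ext_n
                else:
                    if have_box and (bxlo <= qx < bxhi and bylo <= qy < byhi
                                     and bzlo <= qz < bzhi):
                        jx = int((qx - ox) / h)
                        jy = int((qy - oy) / h)
                        jz = int(qz / h)
                        if jx < 0:
                            jx = 0
                        elif jx >= nx_v:
                            jx = nx_v - 1
                        if jy < 0:
                            jy = 0
                        elif jy >= ny_v:
                            jy = ny_v - 1
                        if jz < 0:
                            jz = 0
                        elif jz >= nz_v:
                            jz = nz_v - 1
                        n2 = n_tab[labels[jx, jy, jz]]
                    else:
                        n2 = n_tab[0]
                n1 = n_tab[lab]
                if axis == 0:
                    ci = abs(ux)
                elif axis == 1:
                    ci = abs(uy)
                else:
                    ci = abs(uz)
                refl, ct = _fresnel_r(n1, n2, ci)
                reflect = False
                if refl >= 1.0:
                    reflect = True
                elif refl > 0.0:
                    u, st = _rng_next(st)
                    if u < refl:
                        reflect = True
                if reflect:
                    if axis == 0:
                        ux = -ux
                    elif axis == 1:
                        uy = -uy
                    else:
                        uz = -uz
                else:
                    if n1 != n2:
                        # Snell refraction at an axis-aligned face
                        ratio = n1 / n2
                        ux *= ratio
                        uy *= ratio
                        uz *= ratio
                        if axis == 0:
                            ux = math.copysign(ct, ux)
                        elif axis == 1:
                            uy = math.copysign(ct, uy)
                        else:
                            uz = math.copysign(ct, uz)
                        norm = math.sqrt(ux * ux + uy * uy + uz * uz)
                        ux /= norm
                        uy /= norm
                        uz /= norm
                    if exterior:
                        w = mult * math.exp(-att)
                        tallies[2] += w_ref - w
                        if axis == 2 and uz > 0.0:
                            tallies[0] += w
                            tallies[1] += w * path
                            tallies[7] += 1.0
                            if uz >= det_cos_min:
                                col = int((x + half_field) / pitch)
                                row = int((y + half_field) / pitch)
                                if 0 <= col < npix and 0 <= row < npix:
                                    img[row, col] += w
                                    # second angular moment for radiance
                                    # reconstruction (ci = internal cosine)
                                    img_inv[row, col] += w / ci
                        elif axis == 2:
                            tallies[3] += w
                        else:
                            tallies[4] += w
                        alive = False
                        continue
                x += ux * _EPS_NUDGE
                y += uy * _EPS_NUDGE
                z += uz * _EPS_NUDGE
    return tallies
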