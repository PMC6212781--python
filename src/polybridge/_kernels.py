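"""Numba kernels for the Brownian-dynamics engine.

Everything here works on flat arrays in nm / kT / Brownian-time units.
Particles are ordered beads first (``0..nb-1``, bonded in a chain), then
factors.  Specific attraction acts only between a binding-competent factor
and a bead carrying the factor's color (color-set membership is encoded as
a bitmask intersection).

The pair potential:

* excluded volume for ``r < contact``:  U = E0 (1 - r/contact)^2 with the
  force capped at ``f_cap`` (soft core; overlapping particles never produce
  non-finite forces),
* specific/nonspecific binding for ``contact <= r < contact + w``:
  U = -eps cos^2( (pi/2) (r - contact)/w ), a smooth well of depth ``eps``
  whose force vanishes at both ends of the range,
* harmonic bonds between consecutive beads, optional harmonic-cosine
  bending, optional harmonic spherical confinement.

The neighbor list is a Verlet list with a counting-sort cell list behind
it; pairs are stored with their interaction cutoff, contact distance and
attraction bookkeeping resolved at build time, so the per-step force loop
only loads precomputed pair data (competence is the one thing checked per
step, because factors switch on the fly).
"""

import numpy as np
from numba import njit

# status codes returned by _run_chunk
OK = 0
STABILITY_ABORT = 1
PAIR_OVERFLOW = 2

# state-vector slots (int64 array shared between python and the kernel)
S_NPAIRS = 0
S_SWITCH_PTR = 1
S_FRAME_PTR = 2
S_NEEDS_REBUILD = 3
S_STEPS_DONE = 4
S_BAD_PARTICLE = 5
S_NNEAR = 6
S_NEEDS_NEAR = 7

#: inner skin of the two-level Verlet list (nm); the force loop touches only
#: pairs within (cutoff + inner skin), refreshed by a cheap scan of the full
#: list, which itself is rebuilt through the cell grid at the outer skin.
SKIN_INNER_NM = 30.0


@njit(cache=True, fastmath=True)
def _build_pairs(
    pos, radius, nb, bead_mask, factor_bit, eps_spec, eps_ns, attr_w, skin,
    skin_inner, pair_i, pair_j, pair_contact, pair_cut2, pair_eps, pair_fa,
    pair_near2,
):
    """Typed Verlet list: pairs within (interaction cutoff + skin).

    ``pair_near2`` stores (cutoff + skin_inner)^2 per pair so the near-list
    refresh needs no square roots.  Returns the number of pairs, or -1 if
    the buffers are too small.
    """
    P = pos.shape[0]
    cap = pair_i.shape[0]
    rmax = radius.max()
    gather = 2.0 * rmax + attr_w + skin  # largest possible selection radius
    g2 = gather * gather
    # beads share one radius, so bead-bead pairs take a branch-free path
    contact_bb = 2.0 * radius[0]
    cut2_bb = contact_bb * contact_bb
    near_bb = contact_bb + skin_inner
    near2_bb = near_bb * near_bb
    sel_bb = contact_bb + skin
    sel2_bb = sel_bb * sel_bb

    minx = pos[0, 0]
    maxx = pos[0, 0]
    miny = pos[0, 1]
    maxy = pos[0, 1]
    minz = pos[0, 2]
    maxz = pos[0, 2]
    for i in range(P):
        if pos[i, 0] < minx:
            minx = pos[i, 0]
        if pos[i, 0] > maxx:
            maxx = pos[i, 0]
        if pos[i, 1] < miny:
            miny = pos[i, 1]
        if pos[i, 1] > maxy:
            maxy = pos[i, 1]
        if pos[i, 2] < minz:
            minz = pos[i, 2]
        if pos[i, 2] > maxz:
            maxz = pos[i, 2]

    ncx = int((maxx - minx) / gather) + 1
    ncy = int((maxy - miny) / gather) + 1
    ncz = int((maxz - minz) / gather) + 1
    ncells = ncx * ncy * ncz

    n = 0
    if P < 128 or ncells > 1_000_000:
        for i in range(P - 1):
            for j in range(i + 1, P):
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                d2 = dx * dx + dy * dy + dz * dz
                if d2 < g2:
                    contact = radius[i] + radius[j]
                    cut = contact
                    eps = 0.0
                    fa = -1
                    if (i < nb) != (j < nb):
                        if i < nb:
                            fb = i
                            ff = j - nb
                        else:
                            fb = j
                            ff = i - nb
                        if bead_mask[fb] & factor_bit[ff]:
                            e = eps_spec[ff]
                        else:
                            e = eps_ns[ff]
                        if e > 0.0:
                            eps = e
                            fa = ff
                            cut = contact + attr_w
                    sel = cut + skin
                    if d2 < sel * sel:
                        if n >= cap:
                            return -1
                        pair_i[n] = i
                        pair_j[n] = j
                        pair_contact[n] = contact
                        pair_cut2[n] = cut * cut
                        pair_eps[n] = eps
                        pair_fa[n] = fa
                        pair_near2[n] = (cut + skin_inner) ** 2
                        n += 1
        return n

    # counting-sort cell list: particles grouped contiguously by cell
    cell = np.empty(P, np.int32)
    count = np.zeros(ncells + 1, np.int32)
    for i in range(P):
        cx = int((pos[i, 0] - minx) / gather)
        cy = int((pos[i, 1] - miny) / gather)
        cz = int((pos[i, 2] - minz) / gather)
        if cx >= ncx:
            cx = ncx - 1
        if cy >= ncy:
            cy = ncy - 1
        if cz >= ncz:
            cz = ncz - 1
        c = (cz * ncy + cy) * ncx + cx
        cell[i] = c
        count[c + 1] += 1
    for c in range(ncells):
        count[c + 1] += count[c]
    order = np.empty(P, np.int32)
    fill = count[:ncells].copy()
    for i in range(P):
        c = cell[i]
        order[fill[c]] = i
        fill[c] += 1
    # cache-friendly scan: contiguous sorted copies of the coordinates
    sx = np.empty(P)
    sy = np.empty(P)
    sz = np.empty(P)
    for k in range(P):
        i = order[k]
        sx[k] = pos[i, 0]
        sy[k] = pos[i, 1]
        sz[k] = pos[i, 2]

    # half stencil: same cell (j after i in sort order) + 13 neighbor cells
    for cz in range(ncz):
        for cy in range(ncy):
            for cx in range(ncx):
                c = (cz * ncy + cy) * ncx + cx
                a0 = count[c]
                a1 = count[c + 1]
                if a0 == a1:
                    continue
                for s in range(14):
                    # stencil offsets covering each unordered cell pair once
                    if s == 0:
                        ox, oy, oz = 0, 0, 0
                    elif s == 1:
                        ox, oy, oz = 1, 0, 0
                    elif s == 2:
                        ox, oy, oz = -1, 1, 0
                    elif s == 3:
                        ox, oy, oz = 0, 1, 0
                    elif s == 4:
                        ox, oy, oz = 1, 1, 0
                    elif s == 5:
                        ox, oy, oz = -1, -1, 1
                    elif s == 6:
                        ox, oy, oz = 0, -1, 1
                    elif s == 7:
                        ox, oy, oz = 1, -1, 1
                    elif s == 8:
                        ox, oy, oz = -1, 0, 1
                    elif s == 9:
                        ox, oy, oz = 0, 0, 1
                    elif s == 10:
                        ox, oy, oz = 1, 0, 1
                    elif s == 11:
                        ox, oy, oz = -1, 1, 1
                    elif s == 12:
                        ox, oy, oz = 0, 1, 1
                    else:
                        ox, oy, oz = 1, 1, 1
                    cx2 = cx + ox
                    cy2 = cy + oy
                    cz2 = cz + oz
                    if cx2 < 0 or cx2 >= ncx or cy2 < 0 or cy2 >= ncy or cz2 >= ncz:
                        continue
                    c2 = (cz2 * ncy + cy2) * ncx + cx2
                    b0 = count[c2]
                    b1 = count[c2 + 1]
                    for ai in range(a0, a1):
                        xi = sx[ai]
                        yi = sy[ai]
                        zi = sz[ai]
                        j0 = ai + 1 if s == 0 else b0
                        i = order[ai]
                        for bj in range(j0, b1):
                            dx = xi - sx[bj]
                            dy = yi - sy[bj]
                            dz = zi - sz[bj]
                            d2 = dx * dx + dy * dy + dz * dz
                            if d2 >= g2:
                                continue
                            j = order[bj]
                            if i < nb and j < nb:
                                if d2 < sel2_bb:
                                    if n >= cap:
                                        return -1
                                    if i < j:
                                        pair_i[n] = i
                                        pair_j[n] = j
                                    else:
                                        pair_i[n] = j
                                        pair_j[n] = i
                                    pair_contact[n] = contact_bb
                                    pair_cut2[n] = cut2_bb
                                    pair_eps[n] = 0.0
                                    pair_fa[n] = -1
                                    pair_near2[n] = near2_bb
                                    n += 1
                                continue
                            contact = radius[i] + radius[j]
                            cut = contact
                            eps = 0.0
                            fa = -1
                            if (i < nb) != (j < nb):
                                if i < nb:
                                    fb = i
                                    ff = j - nb
                                else:
                                    fb = j
                                    ff = i - nb
                                if bead_mask[fb] & factor_bit[ff]:
                                    e = eps_spec[ff]
                                else:
                                    e = eps_ns[ff]
                                if e > 0.0:
                                    eps = e
                                    fa = ff
                                    cut = contact + attr_w
                            sel = cut + skin
                            if d2 < sel * sel:
                                if n >= cap:
                                    return -1
                                if i < j:
                                    pair_i[n] = i
                                    pair_j[n] = j
                                else:
                                    pair_i[n] = j
                                    pair_j[n] = i
                                pair_contact[n] = contact
                                pair_cut2[n] = cut * cut
                                pair_eps[n] = eps
                                pair_fa[n] = fa
                                pair_near2[n] = (cut + skin_inner) ** 2
                                n += 1
    return n


@njit(cache=True, fastmath=True)
def _pair_and_bonded_forces(
    pos, radius, competent, near_i, near_j, near_contact, near_cut2, near_eps,
    near_fa, nnear, nb, k_bond, r0_bond, e0_rep, f_cap, attr_w,
    kappa, r_conf, k_conf, f,
):
    """Forces from the compacted near pair list plus bonds, bending, confinement."""
    P = pos.shape[0]
    for i in range(P):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0

    pi = np.pi
    for p in range(nnear):
        i = near_i[p]
        j = near_j[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= near_cut2[p]:
            continue
        contact = near_contact[p]
        if r2 < 1e-12:
            f[i, 0] += f_cap
            f[j, 0] -= f_cap
            continue
        r = np.sqrt(r2)
        fmag = 0.0  # positive = repulsive along (i - j)
        if r < contact:
            fr = 2.0 * e0_rep * (contact - r) / (contact * contact)
            if fr > f_cap:
                fr = f_cap
            fmag = fr
        else:
            fa = near_fa[p]
            if fa >= 0 and competent[fa] == 1:
                fmag = -near_eps[p] * pi / (2.0 * attr_w) * np.sin(
                    pi * (r - contact) / attr_w
                )
            else:
                continue
        s = fmag / r
        fx = s * dx
        fy = s * dy
        fz = s * dz
        f[i, 0] += fx
        f[i, 1] += fy
        f[i, 2] += fz
        f[j, 0] -= fx
        f[j, 1] -= fy
        f[j, 2] -= fz

    # harmonic bonds along the chain
    for b in range(nb - 1):
        dx = pos[b, 0] - pos[b + 1, 0]
        dy = pos[b, 1] - pos[b + 1, 1]
        dz = pos[b, 2] - pos[b + 1, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            continue
        s = -k_bond * (r - r0_bond) / r
        fx = s * dx
        fy = s * dy
        fz = s * dz
        f[b, 0] += fx
        f[b, 1] += fy
        f[b, 2] += fz
        f[b + 1, 0] -= fx
        f[b + 1, 1] -= fy
        f[b + 1, 2] -= fz

    # harmonic-cosine bending stiffness: U = kappa (1 - cos theta)
    if kappa > 0.0:
        for m in range(1, nb - 1):
            b1x = pos[m, 0] - pos[m - 1, 0]
            b1y = pos[m, 1] - pos[m - 1, 1]
            b1z = pos[m, 2] - pos[m - 1, 2]
            b2x = pos[m + 1, 0] - pos[m, 0]
            b2y = pos[m + 1, 1] - pos[m, 1]
            b2z = pos[m + 1, 2] - pos[m, 2]
            n1 = np.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
            n2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
            if n1 < 1e-12 or n2 < 1e-12:
                continue
            ux = b1x / n1
            uy = b1y / n1
            uz = b1z / n1
            vx = b2x / n2
            vy = b2y / n2
            vz = b2z / n2
            ct = ux * vx + uy * vy + uz * vz
            fax = -kappa * (vx - ct * ux) / n1
            fay = -kappa * (vy - ct * uy) / n1
            faz = -kappa * (vz - ct * uz) / n1
            fcx = kappa * (ux - ct * vx) / n2
            fcy = kappa * (uy - ct * vy) / n2
            fcz = kappa * (uz - ct * vz) / n2
            f[m - 1, 0] += fax
            f[m - 1, 1] += fay
            f[m - 1, 2] += faz
            f[m + 1, 0] += fcx
            f[m + 1, 1] += fcy
            f[m + 1, 2] += fcz
            f[m, 0] -= fax + fcx
            f[m, 1] -= fay + fcy
            f[m, 2] -= faz + fcz

    # spherical confinement about the origin
    if r_conf > 0.0:
        for i in range(P):
            rr = np.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2)
            lim = r_conf - radius[i]
            if rr > lim and rr > 1e-12:
                s = -k_conf * (rr - lim) / rr
                f[i, 0] += s * pos[i, 0]
                f[i, 1] += s * pos[i, 1]
                f[i, 2] += s * pos[i, 2]


@njit(cache=True, fastmath=True)
def _run_chunk(
    pos,
    build_pos,
    near_pos,
    radius,
    mobility_dt,
    noise_scale,
    nb,
    bead_mask,
    factor_bit,
    eps_spec,
    eps_ns,
    competent,
    k_bond,
    r0_bond,
    e0_rep,
    f_cap,
    attr_w,
    kappa,
    r_conf,
    k_conf,
    skin,
    skin_inner,
    drift_max,
    noise,
    step0,
    sw_steps,
    sw_fac,
    frame_steps,
    frames_pos,
    frames_comp,
    pair_i,
    pair_j,
    pair_contact,
    pair_cut2,
    pair_eps,
    pair_fa,
    pair_near2,
    near_i,
    near_j,
    near_contact,
    near_cut2,
    near_eps,
    near_fa,
    state,
    f,
):
    """Advance ``noise.shape[0]`` BD steps; returns a status code.

    ``noise`` holds uniform variates in [0, 1); the kernel centers them and
    ``noise_scale`` includes the sqrt(12) variance correction, so each
    coordinate receives zero-mean noise of variance 2 D dt (moment-matched
    to the Langevin noise; the displacement over any few steps is Gaussian
    to excellent approximation).

    ``state`` carries the neighbor-list, switching-event and frame pointers
    across chunk boundaries (see the S_* constants).  On PAIR_OVERFLOW the
    caller grows the pair buffers and re-enters with the remaining noise.
    """
    P = pos.shape[0]
    nsteps = noise.shape[0]
    skin_half2 = (skin / 2.0) * (skin / 2.0)
    skin_inner_half2 = (skin_inner / 2.0) * (skin_inner / 2.0)
    drift_max2 = drift_max * drift_max

    for s in range(nsteps):
        if state[S_NEEDS_REBUILD] == 1:
            n = _build_pairs(
                pos, radius, nb, bead_mask, factor_bit, eps_spec, eps_ns,
                attr_w, skin, skin_inner, pair_i, pair_j, pair_contact,
                pair_cut2, pair_eps, pair_fa, pair_near2,
            )
            if n < 0:
                state[S_STEPS_DONE] = s
                return PAIR_OVERFLOW
            state[S_NPAIRS] = n
            for i in range(P):
                build_pos[i, 0] = pos[i, 0]
                build_pos[i, 1] = pos[i, 1]
                build_pos[i, 2] = pos[i, 2]
            state[S_NEEDS_REBUILD] = 0
            state[S_NEEDS_NEAR] = 1

        if state[S_NEEDS_NEAR] == 1:
            nn = 0
            for p in range(state[S_NPAIRS]):
                i = pair_i[p]
                j = pair_j[p]
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                if dx * dx + dy * dy + dz * dz < pair_near2[p]:
                    near_i[nn] = i
                    near_j[nn] = j
                    near_contact[nn] = pair_contact[p]
                    near_cut2[nn] = pair_cut2[p]
                    near_eps[nn] = pair_eps[p]
                    near_fa[nn] = pair_fa[p]
                    nn += 1
            state[S_NNEAR] = nn
            for i in range(P):
                near_pos[i, 0] = pos[i, 0]
                near_pos[i, 1] = pos[i, 1]
                near_pos[i, 2] = pos[i, 2]
            state[S_NEEDS_NEAR] = 0

        _pair_and_bonded_forces(
            pos, radius, competent, near_i, near_j, near_contact, near_cut2,
            near_eps, near_fa, state[S_NNEAR], nb, k_bond, r0_bond,
            e0_rep, f_cap, attr_w, kappa, r_conf, k_conf, f,
        )

        maxd2 = 0.0
        bad = -1
        maxmove2 = 0.0
        maxnear2 = 0.0
        for i in range(P):
            gx = mobility_dt[i] * f[i, 0]
            gy = mobility_dt[i] * f[i, 1]
            gz = mobility_dt[i] * f[i, 2]
            d2 = gx * gx + gy * gy + gz * gz
            if d2 > maxd2:
                maxd2 = d2
                bad = i
            ns = noise_scale[i]
            pos[i, 0] += gx + ns * (noise[s, i, 0] - 0.5)
            pos[i, 1] += gy + ns * (noise[s, i, 1] - 0.5)
            pos[i, 2] += gz + ns * (noise[s, i, 2] - 0.5)
            mx = pos[i, 0] - build_pos[i, 0]
            my = pos[i, 1] - build_pos[i, 1]
            mz = pos[i, 2] - build_pos[i, 2]
            m2 = mx * mx + my * my + mz * mz
            if m2 > maxmove2:
                maxmove2 = m2
            qx = pos[i, 0] - near_pos[i, 0]
            qy = pos[i, 1] - near_pos[i, 1]
            qz = pos[i, 2] - near_pos[i, 2]
            q2 = qx * qx + qy * qy + qz * qz
            if q2 > maxnear2:
                maxnear2 = q2

        if maxd2 > drift_max2 or not np.isfinite(maxd2):
            state[S_STEPS_DONE] = s + 1
            state[S_BAD_PARTICLE] = bad
            return STABILITY_ABORT

        gstep = step0 + s + 1

        while state[S_SWITCH_PTR] < sw_steps.shape[0] and sw_steps[state[S_SWITCH_PTR]] == gstep:
            fa = sw_fac[state[S_SWITCH_PTR]]
            competent[fa] = 1 - competent[fa]
            state[S_SWITCH_PTR] += 1

        while (
            state[S_FRAME_PTR] < frame_steps.shape[0]
            and frame_steps[state[S_FRAME_PTR]] == gstep
        ):
            k = state[S_FRAME_PTR]
            for i in range(P):
                frames_pos[k, i, 0] = pos[i, 0]
                frames_pos[k, i, 1] = pos[i, 1]
                frames_pos[k, i, 2] = pos[i, 2]
            for i in range(P - nb):
                frames_comp[k, i] = competent[i]
            state[S_FRAME_PTR] += 1

        if maxmove2 > skin_half2:
            state[S_NEEDS_REBUILD] = 1
        elif maxnear2 > skin_inner_half2:
            state[S_NEEDS_NEAR] = 1

    state[S_STEPS_DONE] = nsteps
    return OK
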