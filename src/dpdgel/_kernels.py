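"""Numba kernels for the DPD engine.

One compiled ``dpd_step`` advances the system by a single modified
velocity-Verlet step (velocity-prediction factor 0.5) and evaluates all
forces: soft conservative/dissipative/random pairs through a cell list,
harmonic bonds, cosine bending angles, one-sided harmonic walls, tether
springs and the periodic-Poiseuille body force.  The pairwise random force
is generated from a counter-based hash keyed by (seed, step, pair) so the
same draw is used for ij and ji (exact Newton's third law) and trajectories
are bitwise reproducible for a given seed.

Parameter/flag vector layout (see P_* / F_* constants below).
"""

import numpy as np
from numba import njit

# ---- parameter vector indices ------------------------------------------------
P_RC = 0
P_A = 1
P_GAMMA = 2
P_SIGMA = 3
P_KBT = 4
P_DT = 5
P_KBOND = 6
P_REQ = 7
P_KBEND = 8
P_KW_BOT_SOL = 9
P_KW_BOT_GEL = 10
P_KW_TOP_SOL = 11
P_KW_MOVE_GEL = 12
P_FN = 13
P_WALL_MOB = 14
P_V_SLIDE = 15
P_K_TETHER = 16
P_BODY_FX = 17
P_COUETTE_V = 18
P_STANDOFF = 19
NPARAMS = 20

# ---- flag vector indices -----------------------------------------------------
F_PBCZ = 0
F_BOTTOM_WALL = 1
F_TOP_SOL_WALL = 2
F_MOVING_WALL = 3
F_TETHERS = 4
F_POISEUILLE = 5
F_COUETTE_TOP = 6
F_INIT_ONLY = 7
NFLAGS = 8

# ---- output vector indices ---------------------------------------------------
O_FF = 0          # horizontal (x) tether force on gel this step
O_FWALL = 1       # vertical gel reaction force on the moving wall
O_BOUNCE_PX = 2   # x-momentum transferred to the bottom wall by bounce-back
O_EBOND = 3
O_EANGLE = 4
O_TETH_FZ = 5
NOUT = 6

_MASK = np.uint64(0xFFFFFFFFFFFFFFFF)
_SQRT12 = np.sqrt(12.0)

# half stencil for the cell list: the self cell plus 13 forward neighbours
_STENCIL_X = np.array([0, 1, -1, 0, 1, -1, 0, 1, -1, 0, 1, -1, 0, 1], np.int64)
_STENCIL_Y = np.array([0, 0, 1, 1, 1, -1, -1, -1, 0, 0, 0, 1, 1, 1], np.int64)
_STENCIL_Z = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1, 1, 1, 1], np.int64)


@njit(cache=True, inline="always")
def _mix64(x):
    # splitmix64 finalizer
    x = (x + np.uint64(0x9E3779B97F4A7C15)) & _MASK
    z = x
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & _MASK
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & _MASK
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _pair_noise(seed, step, i, j):
    """Zero-mean unit-variance uniform draw, symmetric in (i, j)."""
    if i > j:
        i, j = j, i
    h = _mix64(np.uint64(seed) ^ _mix64(np.uint64(step)))
    h = _mix64(h ^ ((np.uint64(i) << np.uint64(32)) | np.uint64(j)))
    u = (h >> np.uint64(11)) * (1.0 / 9007199254740992.0)  # [0, 1)
    return _SQRT12 * (u - 0.5)


@njit(cache=True, fastmath=True)
def _pair_forces_cells(pos, vel, frc, Lx, Ly, Lz, pbcz,
                       a, gamma, sigma_dt, rc, seed, step):
    """Accumulate DPD pair forces using a freshly built cell list.

    ``sigma_dt`` = sigma / sqrt(dt).  Falls back to an O(N^2) scan when the
    box is too small for a 3-cell-wide list in a periodic direction.
    """
    n = pos.shape[0]
    rc2 = rc * rc
    inv_rc = 1.0 / rc

    ncx = int(Lx * inv_rc)
    ncy = int(Ly * inv_rc)
    # pad open-z cell range by 1 cutoff on each side for wall penetration
    z0 = -rc
    zspan = Lz + 2.0 * rc
    if pbcz:
        z0 = 0.0
        zspan = Lz
    ncz = int(zspan * inv_rc)
    if ncz < 1:
        ncz = 1

    if ncx < 3 or ncy < 3 or (pbcz and ncz < 3):
        # brute-force path for tiny boxes
        for i in range(n - 1):
            for j in range(i + 1, n):
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                dx -= Lx * np.rint(dx / Lx)
                dy -= Ly * np.rint(dy / Ly)
                if pbcz:
                    dz -= Lz * np.rint(dz / Lz)
                r2 = dx * dx + dy * dy + dz * dz
                if r2 < rc2 and r2 > 1e-24:
                    r = np.sqrt(r2)
                    w = 1.0 - r * inv_rc
                    dvx = vel[i, 0] - vel[j, 0]
                    dvy = vel[i, 1] - vel[j, 1]
                    dvz = vel[i, 2] - vel[j, 2]
                    evdot = (dx * dvx + dy * dvy + dz * dvz) / r
                    zeta = _pair_noise(seed, step, i, j)
                    s = (a * w - gamma * w * w * evdot + sigma_dt * w * zeta) / r
                    frc[i, 0] += s * dx
                    frc[i, 1] += s * dy
                    frc[i, 2] += s * dz
                    frc[j, 0] -= s * dx
                    frc[j, 1] -= s * dy
                    frc[j, 2] -= s * dz
        return

    cx = Lx / ncx
    cy = Ly / ncy
    cz = zspan / ncz
    ncells = ncx * ncy * ncz
    head = np.full(ncells, -1, np.int64)
    nxt = np.empty(n, np.int64)
    for i in range(n):
        ix = int(pos[i, 0] / cx)
        iy = int(pos[i, 1] / cy)
        iz = int((pos[i, 2] - z0) / cz)
        if ix < 0:
            ix = 0
        elif ix >= ncx:
            ix = ncx - 1
        if iy < 0:
            iy = 0
        elif iy >= ncy:
            iy = ncy - 1
        if iz < 0:
            iz = 0
        elif iz >= ncz:
            iz = ncz - 1
        c = (iz * ncy + iy) * ncx + ix
        nxt[i] = head[c]
        head[c] = i

    hx = 0.5 * Lx
    hy = 0.5 * Ly
    hz = 0.5 * Lz
    for i in range(n):
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        vxi = vel[i, 0]
        vyi = vel[i, 1]
        vzi = vel[i, 2]
        fxi = 0.0
        fyi = 0.0
        fzi = 0.0
        ix = int(xi / cx)
        iy = int(yi / cy)
        iz = int((zi - z0) / cz)
        if ix < 0:
            ix = 0
        elif ix >= ncx:
            ix = ncx - 1
        if iy < 0:
            iy = 0
        elif iy >= ncy:
            iy = ncy - 1
        if iz < 0:
            iz = 0
        elif iz >= ncz:
            iz = ncz - 1
        # half stencil: self cell (j > i only) + 13 forward neighbour cells
        for sc in range(14):
            dxc = _STENCIL_X[sc]
            dyc = _STENCIL_Y[sc]
            dzc = _STENCIL_Z[sc]
            self_cell = sc == 0
            jz = iz + dzc
            if pbcz:
                if jz < 0:
                    jz += ncz
                elif jz >= ncz:
                    jz -= ncz
            elif jz < 0 or jz >= ncz:
                continue
            jy = iy + dyc
            if jy < 0:
                jy += ncy
            elif jy >= ncy:
                jy -= ncy
            jx = ix + dxc
            if jx < 0:
                jx += ncx
            elif jx >= ncx:
                jx -= ncx
            j = head[(jz * ncy + jy) * ncx + jx]
            while j != -1:
                if (not self_cell) or j > i:
                    if j != i:
                        dx = xi - pos[j, 0]
                        dy = yi - pos[j, 1]
                        dz = zi - pos[j, 2]
                        if dx > hx:
                            dx -= Lx
                        elif dx < -hx:
                            dx += Lx
                        if dy > hy:
                            dy -= Ly
                        elif dy < -hy:
                            dy += Ly
                        if pbcz:
                            if dz > hz:
                                dz -= Lz
                            elif dz < -hz:
                                dz += Lz
                        r2 = dx * dx + dy * dy + dz * dz
                        if r2 < rc2 and r2 > 1e-24:
                            inv_r = 1.0 / np.sqrt(r2)
                            w = 1.0 - r2 * inv_r * inv_rc
                            dvx = vxi - vel[j, 0]
                            dvy = vyi - vel[j, 1]
                            dvz = vzi - vel[j, 2]
                            evdot = (dx * dvx + dy * dvy + dz * dvz) * inv_r
                            zeta = _pair_noise(seed, step, i, j)
                            s = (a * w - gamma * w * w * evdot
                                 + sigma_dt * w * zeta) * inv_r
                            sx = s * dx
                            sy = s * dy
                            sz = s * dz
                            fxi += sx
                            fyi += sy
                            fzi += sz
                            frc[j, 0] -= sx
                            frc[j, 1] -= sy
                            frc[j, 2] -= sz
                j = nxt[j]
        frc[i, 0] += fxi
        frc[i, 1] += fyi
        frc[i, 2] += fzi


@njit(cache=True, fastmath=True)
def _bond_forces(pos, frc, bonds, k, req, Lx, Ly, Lz, pbcz):
    """Harmonic bonds U = k (r - req)^2; returns total bond energy."""
    e = 0.0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= Lx * np.rint(dx / Lx)
        dy -= Ly * np.rint(dy / Ly)
        if pbcz:
            dz -= Lz * np.rint(dz / Lz)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            continue
        dr = r - req
        e += k * dr * dr
        s = -2.0 * k * dr / r
        frc[i, 0] += s * dx
        frc[i, 1] += s * dy
        frc[i, 2] += s * dz
        frc[j, 0] -= s * dx
        frc[j, 1] -= s * dy
        frc[j, 2] -= s * dz
    return e


@njit(cache=True, fastmath=True)
def _angle_forces(pos, frc, angles, k, Lx, Ly, Lz, pbcz):
    """Bending U = k (1 + cos theta) on consecutive triples; returns energy.

    theta is the angle at the central bead; theta = pi (straight chain) is
    the minimum with U = 0.
    """
    e = 0.0
    for t in range(angles.shape[0]):
        i = angles[t, 0]
        j = angles[t, 1]
        m = angles[t, 2]
        ux = pos[i, 0] - pos[j, 0]
        uy = pos[i, 1] - pos[j, 1]
        uz = pos[i, 2] - pos[j, 2]
        wx = pos[m, 0] - pos[j, 0]
        wy = pos[m, 1] - pos[j, 1]
        wz = pos[m, 2] - pos[j, 2]
        ux -= Lx * np.rint(ux / Lx)
        uy -= Ly * np.rint(uy / Ly)
        wx -= Lx * np.rint(wx / Lx)
        wy -= Ly * np.rint(wy / Ly)
        if pbcz:
            uz -= Lz * np.rint(uz / Lz)
            wz -= Lz * np.rint(wz / Lz)
        nu2 = ux * ux + uy * uy + uz * uz
        nw2 = wx * wx + wy * wy + wz * wz
        if nu2 < 1e-16 or nw2 < 1e-16:
            continue  # degenerate arm
        nu = np.sqrt(nu2)
        nw = np.sqrt(nw2)
        c = (ux * wx + uy * wy + uz * wz) / (nu * nw)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        e += k * (1.0 + c)
        # F_i = -k * d(cos)/d r_i, etc.
        fix = -k * (wx / (nu * nw) - c * ux / nu2)
        fiy = -k * (wy / (nu * nw) - c * uy / nu2)
        fiz = -k * (wz / (nu * nw) - c * uz / nu2)
        fmx = -k * (ux / (nu * nw) - c * wx / nw2)
        fmy = -k * (uy / (nu * nw) - c * wy / nw2)
        fmz = -k * (uz / (nu * nw) - c * wz / nw2)
        frc[i, 0] += fix
        frc[i, 1] += fiy
        frc[i, 2] += fiz
        frc[m, 0] += fmx
        frc[m, 1] += fmy
        frc[m, 2] += fmz
        frc[j, 0] -= fix + fmx
        frc[j, 1] -= fiy + fmy
        frc[j, 2] -= fiz + fmz
    return e


@njit(cache=True, fastmath=True)
def dpd_step(pos, vel, frc, species, img,
             bonds, angles, tether_ids, anchors,
             box, wall_h, p, flags, step, seed, out):
    """One modified velocity-Verlet DPD step (in place).

    ``frc`` must hold the forces for the current positions on entry (prime
    with flags[F_INIT_ONLY]=1 once) and holds the new forces on exit.
    ``img`` (N, 2) int64 counts x/y wrap events for unwrapped coordinates.
    ``wall_h`` is a 1-element array with the moving-wall height.  ``out``
    receives per-step diagnostics.
    """
    n = pos.shape[0]
    Lx = box[0]
    Ly = box[1]
    Lz = box[2]
    pbcz = flags[F_PBCZ] == 1
    dt = p[P_DT]
    half = 0.5 * dt
    init_only = flags[F_INIT_ONLY] == 1

    if not init_only:
        # half kick + drift
        for i in range(n):
            vel[i, 0] += half * frc[i, 0]
            vel[i, 1] += half * frc[i, 1]
            vel[i, 2] += half * frc[i, 2]
            pos[i, 0] += dt * vel[i, 0]
            pos[i, 1] += dt * vel[i, 1]
            pos[i, 2] += dt * vel[i, 2]
            if pos[i, 0] < 0.0:
                pos[i, 0] += Lx
                img[i, 0] -= 1
            elif pos[i, 0] >= Lx:
                pos[i, 0] -= Lx
                img[i, 0] += 1
            if pos[i, 1] < 0.0:
                pos[i, 1] += Ly
                img[i, 1] -= 1
            elif pos[i, 1] >= Ly:
                pos[i, 1] -= Ly
                img[i, 1] += 1
            if pbcz:
                if pos[i, 2] < 0.0:
                    pos[i, 2] += Lz
                elif pos[i, 2] >= Lz:
                    pos[i, 2] -= Lz

        # bounce-back no-slip at the bottom wall (solvent only; gel is kept
        # off the wall by its harmonic guard)
        bounce_px = 0.0
        if flags[F_BOTTOM_WALL] == 1:
            for i in range(n):
                if species[i] == 0 and pos[i, 2] < 0.0:
                    pos[i, 2] = -pos[i, 2]
                    bounce_px += 2.0 * vel[i, 0]
                    vel[i, 0] = -vel[i, 0]
                    vel[i, 1] = -vel[i, 1]
                    vel[i, 2] = -vel[i, 2]
        if flags[F_COUETTE_TOP] == 1:
            Vtop = p[P_COUETTE_V]
            for i in range(n):
                if species[i] == 0 and pos[i, 2] > Lz:
                    pos[i, 2] = 2.0 * Lz - pos[i, 2]
                    vel[i, 0] = 2.0 * Vtop - vel[i, 0]
                    vel[i, 1] = -vel[i, 1]
                    vel[i, 2] = -vel[i, 2]
        # O_BOUNCE_PX tallies the bottom wall only, so the Couette shear
        # stress can be read off one plate
        out[O_BOUNCE_PX] = bounce_px

    # ---- forces at new positions (velocities = lambda-predicted) ----
    for i in range(n):
        frc[i, 0] = 0.0
        frc[i, 1] = 0.0
        frc[i, 2] = 0.0

    sigma_dt = p[P_SIGMA] / np.sqrt(dt) if dt > 0 else 0.0
    _pair_forces_cells(pos, vel, frc, Lx, Ly, Lz, pbcz,
                       p[P_A], p[P_GAMMA], sigma_dt, p[P_RC], seed, step)
    out[O_EBOND] = _bond_forces(pos, frc, bonds, p[P_KBOND], p[P_REQ],
                                Lx, Ly, Lz, pbcz)
    out[O_EANGLE] = _angle_forces(pos, frc, angles, p[P_KBEND],
                                  Lx, Ly, Lz, pbcz)

    # one-sided harmonic walls, U = K d^2 inside the repulsion zone.  The
    # zone extends one ``standoff`` above the bottom plane (below the top
    # boundary): a bead hugging a bare wall loses its wall-side neighbours
    # and would otherwise be pushed onto the plane by the unbalanced bulk
    # repulsion; the in-zone spring counters that pile-up and keeps gel a
    # thin solvent layer away from the wall.
    zw = p[P_STANDOFF]
    if flags[F_BOTTOM_WALL] == 1:
        ks = p[P_KW_BOT_SOL]
        kg = p[P_KW_BOT_GEL]
        for i in range(n):
            z = pos[i, 2]
            if z < zw:
                kk = ks if species[i] == 0 else kg
                frc[i, 2] += 2.0 * kk * (zw - z)
    if flags[F_TOP_SOL_WALL] == 1:
        # containment for every species: gel normally never gets here (the
        # moving wall sits below), but an unconfined network would ratchet
        # out through the solvent-depleted zone
        kt = p[P_KW_TOP_SOL]
        ztw = Lz - zw
        for i in range(n):
            if pos[i, 2] > ztw:
                frc[i, 2] += -2.0 * kt * (pos[i, 2] - ztw)

    f_wall = 0.0
    n_contact = 0
    if flags[F_MOVING_WALL] == 1:
        km = p[P_KW_MOVE_GEL]
        h = wall_h[0]
        for i in range(n):
            if species[i] != 0 and pos[i, 2] > h:
                d = pos[i, 2] - h
                frc[i, 2] += -2.0 * km * d
                f_wall += 2.0 * km * d   # gel pushes the wall up
                n_contact += 1
    out[O_FWALL] = f_wall

    ff = 0.0
    teth_fz = 0.0
    if flags[F_TETHERS] == 1:
        kt = p[P_K_TETHER]
        for t in range(tether_ids.shape[0]):
            i = tether_ids[t]
            # unwrapped bead coordinates vs advected anchor
            dx = (pos[i, 0] + img[i, 0] * Lx) - anchors[t, 0]
            dy = (pos[i, 1] + img[i, 1] * Ly) - anchors[t, 1]
            dz = pos[i, 2] - anchors[t, 2]
            fx = -2.0 * kt * dx
            fy = -2.0 * kt * dy
            fz = -2.0 * kt * dz
            frc[i, 0] += fx
            frc[i, 1] += fy
            frc[i, 2] += fz
            ff += fx
            teth_fz += fz
    out[O_FF] = ff
    out[O_TETH_FZ] = teth_fz

    if flags[F_POISEUILLE] == 1:
        fb = p[P_BODY_FX]
        zmid = 0.5 * Lz
        for i in range(n):
            if pos[i, 2] < zmid:
                frc[i, 0] += fb
            else:
                frc[i, 0] -= fb

    if init_only:
        return

    # second half kick
    for i in range(n):
        vel[i, 0] += half * frc[i, 0]
        vel[i, 1] += half * frc[i, 1]
        vel[i, 2] += half * frc[i, 2]

    # overdamped moving-wall height + anchor advection.  The wall feels
    # the one-sided contact reaction plus the z-reaction of its tethers;
    # both are stiff linear springs in h, so the height update is
    # semi-implicit (gain divided by 1 + dt*mob*k_eff) and stays stable
    # for any mobility, approaching quasi-static force balance.
    if flags[F_MOVING_WALL] == 1:
        k_eff = 2.0 * p[P_K_TETHER] * tether_ids.shape[0] \
            + 2.0 * p[P_KW_MOVE_GEL] * n_contact
        gain = dt * p[P_WALL_MOB] / (1.0 + dt * p[P_WALL_MOB] * k_eff)
        dh = gain * (f_wall - teth_fz - p[P_FN])
        wall_h[0] += dh
    else:
        dh = 0.0
    if flags[F_TETHERS] == 1:
        dxa = p[P_V_SLIDE] * dt
        for t in range(anchors.shape[0]):
            anchors[t, 0] += dxa
            anchors[t, 2] += dh


@njit(cache=True)
def brute_force_pairs(pos, Lx, Ly, Lz, pbcz, cutoff):
    """All pairs within ``cutoff`` by O(N^2) scan (test oracle & small boxes)."""
    n = pos.shape[0]
    out = []
    c2 = cutoff * cutoff
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= Lx * np.rint(dx / Lx)
            dy -= Ly * np.rint(dy / Ly)
            if pbcz:
                dz -= Lz * np.rint(dz / Lz)
            if dx * dx + dy * dy + dz * dz <= c2:
                out.append((i, j))
    return out


@njit(cache=True)
def pore_radius_scan(probe, nodes, dvals, Lx, Ly, pbcz, Lz):
    """Largest-inscribed-sphere radius at one probe point.

    ``nodes``/``dvals`` are candidate sphere centres with their clearance
    (distance to the nearest obstacle minus the obstacle radius), sorted by
    decreasing clearance.  The best sphere containing the probe is the
    first candidate whose centre lies within its own clearance of the
    probe; minimum image in x, y (and z when periodic).
    """
    best = 0.0
    for k in range(nodes.shape[0]):
        d = dvals[k]
        if d <= best:
            break
        dx = nodes[k, 0] - probe[0]
        dy = nodes[k, 1] - probe[1]
        dz = nodes[k, 2] - probe[2]
        dx -= Lx * np.rint(dx / Lx)
        dy -= Ly * np.rint(dy / Ly)
        if pbcz:
            dz -= Lz * np.rint(dz / Lz)
        if dx * dx + dy * dy + dz * dz <= d * d:
            best = d
            break
    return best
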