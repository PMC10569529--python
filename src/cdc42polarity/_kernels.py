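"""Numba kernels for the particle engine.

One unified kernel advances the system in either geometry.  Positions are
stored as (N, 3) float64 (z = 0 on the plane).  Bookkeeping structures:

* per-species member lists (``members``/``mpos``/``count``) with O(1)
  swap-removal, used for aggregated first-order sampling and for iterating
  the rarer side of each bimolecular reaction;
* a doubly-linked uniform cell grid (cell size >= rho) updated
  incrementally as particles move;
* a per-particle "stamp" array holding the index of the step in which the
  particle last reacted, enforcing at most one reaction per particle per
  step without any per-step clearing.

Gaussian increments are consumed from a pregenerated float32 buffer
(`zbuf`); the kernel returns early when the buffer runs low and the Python
wrapper refills it.  Slowly diffusing species (membrane proteins,
receptors) are advanced in blocks of M steps with exact Gaussian increments
of variance 2*D*M*dt, with M chosen so the rms move per update stays below
rho/10; fast cytosolic and extracellular species move every step.
First-order channels are sampled in aggregate: the number of firings per
step is Binomial(n, p), and firing particles are drawn uniformly from the
species list.  Uniform/binomial/Poisson draws use numba's internal
generator, seeded once per run.
"""

import math

import numpy as np
from numba import njit

# pheromone handling modes
PH_NONE, PH_BATH, PH_POINT = 0, 1, 2


@njit(cache=True)
def seed_kernel_rng(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _binomial_small(n, p):
    """Exact Binomial(n, p) via geometric skips; O(n*p + 1) for small p."""
    if p <= 0.0 or n <= 0:
        return 0
    if p >= 1.0:
        return n
    log1mp = math.log(1.0 - p)
    m = 0
    i = 0
    while True:
        u = np.random.random()
        i += int(math.log(u) / log1mp) + 1
        if i > n:
            return m
        m += 1


@njit(cache=True, inline="always")
def _cell_index(x, y, z, mode, L, G, cell, ncx, ncy, ncz):
    if mode == 0:
        ix = int(x / cell)
        iy = int(y / cell)
        if ix >= ncx:
            ix = ncx - 1
        if iy >= ncy:
            iy = ncy - 1
        return (ix * ncy + iy) * ncz
    ix = int((x + G) / cell)
    iy = int((y + G) / cell)
    iz = int((z + G) / cell)
    if ix < 0 or iy < 0 or iz < 0 or ix >= ncx or iy >= ncy or iz >= ncz:
        return -1
    return (ix * ncy + iy) * ncz + iz


@njit(cache=True, inline="always")
def _grid_remove(i, head, nxt, prv, cellof):
    c = cellof[i]
    if c < 0:
        return
    p = prv[i]
    n = nxt[i]
    if p >= 0:
        nxt[p] = n
    else:
        head[c] = n
    if n >= 0:
        prv[n] = p
    cellof[i] = -1


@njit(cache=True, inline="always")
def _grid_insert(i, c, head, nxt, prv, cellof):
    cellof[i] = c
    if c < 0:
        return
    h = head[c]
    nxt[i] = h
    prv[i] = -1
    if h >= 0:
        prv[h] = i
    head[c] = i


@njit(cache=True, inline="always")
def _rebin(i, pos, mode, L, G, cell, ncx, ncy, ncz, head, nxt, prv, cellof):
    c = _cell_index(pos[i, 0], pos[i, 1], pos[i, 2], mode, L, G, cell, ncx, ncy, ncz)
    if c != cellof[i]:
        _grid_remove(i, head, nxt, prv, cellof)
        _grid_insert(i, c, head, nxt, prv, cellof)


@njit(cache=True, inline="always")
def _list_add(i, s, members, mpos, count):
    k = count[s]
    members[s, k] = i
    mpos[i] = k
    count[s] = k + 1


@njit(cache=True, inline="always")
def _list_remove(i, s, members, mpos, count):
    k = mpos[i]
    last = count[s] - 1
    j = members[s, last]
    members[s, k] = j
    mpos[j] = k
    count[s] = last


@njit(cache=True, inline="always")
def _change_species(i, new_s, spec, members, mpos, count):
    _list_remove(i, spec[i], members, mpos, count)
    spec[i] = new_s
    _list_add(i, new_s, members, mpos, count)


@njit(cache=True, inline="always")
def _free_slot(i, spec, members, mpos, count, head, nxt, prv, cellof, free_stack, free_top):
    _list_remove(i, spec[i], members, mpos, count)
    _grid_remove(i, head, nxt, prv, cellof)
    spec[i] = -1
    free_stack[free_top[0]] = i
    free_top[0] += 1


@njit(cache=True, inline="always")
def _alloc_slot(s, spec, members, mpos, count, free_stack, free_top):
    if free_top[0] == 0:
        return -1
    free_top[0] -= 1
    i = free_stack[free_top[0]]
    spec[i] = s
    _list_add(i, s, members, mpos, count)
    return i


@njit(cache=True, inline="always")
def _fix_grid(i, gflag, pos, mode, L, G, cell, ncx, ncy, ncz, head, nxt, prv, cellof):
    """Re-establish grid membership of slot i (gflag = in_grid[species])."""
    if gflag == 1:
        c = _cell_index(pos[i, 0], pos[i, 1], pos[i, 2], mode, L, G, cell, ncx, ncy, ncz)
        if c != cellof[i]:
            _grid_remove(i, head, nxt, prv, cellof)
            _grid_insert(i, c, head, nxt, prv, cellof)
    else:
        _grid_remove(i, head, nxt, prv, cellof)


@njit(cache=True, inline="always")
def _project_membrane(i, pos, R):
    r = math.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2)
    if r > 0.0:
        f = R / r
        pos[i, 0] *= f
        pos[i, 1] *= f
        pos[i, 2] *= f


@njit(cache=True, inline="always")
def _wrap2d(i, pos, L):
    # single-branch wrap: per-step displacements are far below L
    x = pos[i, 0]
    if x >= L:
        x -= L
    elif x < 0.0:
        x += L
    y = pos[i, 1]
    if y >= L:
        y -= L
    elif y < 0.0:
        y += L
    pos[i, 0] = x
    pos[i, 1] = y


@njit(cache=True, inline="always")
def _pair_d2(i, j, pos, mode, L):
    if mode == 0:
        dx = abs(pos[i, 0] - pos[j, 0])
        dy = abs(pos[i, 1] - pos[j, 1])
        if dx > 0.5 * L:
            dx = L - dx
        if dy > 0.5 * L:
            dy = L - dy
        return dx * dx + dy * dy
    dx = pos[i, 0] - pos[j, 0]
    dy = pos[i, 1] - pos[j, 1]
    dz = pos[i, 2] - pos[j, 2]
    return dx * dx + dy * dy + dz * dz


@njit(cache=True)
def _place_product(i, j, pos, mode, L, R, compart_new, rho_off):
    """Place slot j near parent slot i at distance rho_off (dissociation)."""
    if mode == 0:
        th = 2.0 * math.pi * np.random.random()
        pos[j, 0] = pos[i, 0] + rho_off * math.cos(th)
        pos[j, 1] = pos[i, 1] + rho_off * math.sin(th)
        pos[j, 2] = 0.0
        _wrap2d(j, pos, L)
        return
    if compart_new == 2:  # extracellular product released radially outward
        r = math.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2)
        f = (R + rho_off) / r if r > 0 else 0.0
        pos[j, 0] = pos[i, 0] * f
        pos[j, 1] = pos[i, 1] * f
        pos[j, 2] = pos[i, 2] * f
        return
    # tangent-plane offset, then restore the compartment's radius
    gx = np.random.normal()
    gy = np.random.normal()
    gz = np.random.normal()
    r = math.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2)
    if r > 0.0:
        nx0 = pos[i, 0] / r
        ny0 = pos[i, 1] / r
        nz0 = pos[i, 2] / r
        dot = gx * nx0 + gy * ny0 + gz * nz0
        gx -= dot * nx0
        gy -= dot * ny0
        gz -= dot * nz0
    g = math.sqrt(gx * gx + gy * gy + gz * gz)
    if g == 0.0:
        g = 1.0
    pos[j, 0] = pos[i, 0] + rho_off * gx / g
    pos[j, 1] = pos[i, 1] + rho_off * gy / g
    pos[j, 2] = pos[i, 2] + rho_off * gz / g
    if compart_new == 1:  # membrane: back onto the sphere
        _project_membrane(j, pos, R)


@njit(cache=True)
def _inject_bath(j, pos, R, Rbath):
    gx = np.random.normal()
    gy = np.random.normal()
    gz = np.random.normal()
    g = math.sqrt(gx * gx + gy * gy + gz * gz)
    if g == 0.0:
        gx, g = 1.0, 1.0
    u = np.random.random()
    r = (R ** 3 + u * (Rbath ** 3 - R ** 3)) ** (1.0 / 3.0)
    pos[j, 0] = r * gx / g
    pos[j, 1] = r * gy / g
    pos[j, 2] = r * gz / g


@njit(cache=True)
def advance(
    # state
    pos, spec, stamp,
    members, mpos, count,
    head, nxt, prv, cellof,
    free_stack, free_top,
    step0, n_steps,
    # geometry / grid
    mode, L, R, G, cell, ncx, ncy, ncz,
    # species properties
    sig1, sigM, Mint, Moff, compart, mobile, in_grid,
    # first-order reactions
    fo_r, fo_p, fo_np, fo_p1, fo_p2,
    # second-order reactions
    so_a, so_b, so_p, so_bind, so_pa, so_pb, so_iter, so_alpha,
    rho, rho_off,
    # position-modulated activation (frozen pheromone field)
    pm_on, pm_r, pm_prod, pm_axis, pm_edges, pm_p, pm_pmax,
    # explicit pheromone
    ph_mode, ph_spec, ph_rate_dt, ph_src, ph_Rabs, ph_emit_c, ph_emit_R, ph_Rbath,
    # normals buffer
    zbuf, zptr,
    scratch, pbuf,
):
    """Advance up to ``n_steps`` steps; returns the number completed."""
    S = count.shape[0]
    rho2 = rho * rho
    done = 0
    for istep in range(n_steps):
        step = step0 + done
        # ---- make sure enough normals remain for the worst case ----------
        nalive = 0
        for s in range(S):
            nalive += count[s]
        if zptr[0] + 3 * nalive + 64 > zbuf.shape[0]:
            break
        z = zptr[0]

        # ---- diffusion ----------------------------------------------------
        for s in range(S):
            n = count[s]
            if n == 0 or mobile[s] == 0:
                continue
            M = Mint[s]
            if M > 1 and (step % M) != Moff[s]:
                continue
            sg = sigM[s] if M > 1 else sig1[s]
            cm = compart[s]
            gflag = in_grid[s]
            if mode == 0:
                for k in range(n):
                    i = members[s, k]
                    pos[i, 0] += sg * zbuf[z]
                    pos[i, 1] += sg * zbuf[z + 1]
                    z += 2
                    _wrap2d(i, pos, L)
                    if gflag == 1:
                        _rebin(i, pos, mode, L, G, cell, ncx, ncy, ncz,
                               head, nxt, prv, cellof)
            elif cm == 1:  # membrane: tangent step, reproject
                for k in range(n):
                    i = members[s, k]
                    gx = sg * zbuf[z]
                    gy = sg * zbuf[z + 1]
                    gz = sg * zbuf[z + 2]
                    z += 3
                    r = math.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2)
                    nx0 = pos[i, 0] / r
                    ny0 = pos[i, 1] / r
                    nz0 = pos[i, 2] / r
                    dot = gx * nx0 + gy * ny0 + gz * nz0
                    pos[i, 0] += gx - dot * nx0
                    pos[i, 1] += gy - dot * ny0
                    pos[i, 2] += gz - dot * nz0
                    _project_membrane(i, pos, R)
                    _rebin(i, pos, mode, L, G, cell, ncx, ncy, ncz,
                           head, nxt, prv, cellof)
            elif cm == 0:  # cytosol: free step, reflect at the membrane
                for k in range(n):
                    i = members[s, k]
                    pos[i, 0] += sg * zbuf[z]
                    pos[i, 1] += sg * zbuf[z + 1]
                    pos[i, 2] += sg * zbuf[z + 2]
                    z += 3
                    r2 = pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2
                    if r2 > R * R:
                        r = math.sqrt(r2)
                        f = (2.0 * R - r) / r
                        pos[i, 0] *= f
                        pos[i, 1] *= f
                        pos[i, 2] *= f
            else:  # extracellular pheromone; reverse order: absorption removes
                for k in range(n - 1, -1, -1):
                    i = members[s, k]
                    if spec[i] != s:
                        continue
                    pos[i, 0] += sg * zbuf[z]
                    pos[i, 1] += sg * zbuf[z + 1]
                    pos[i, 2] += sg * zbuf[z + 2]
                    z += 3
                    r = math.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2)
                    if ph_mode == PH_POINT and r > ph_Rabs:
                        _free_slot(i, spec, members, mpos, count, head, nxt, prv,
                                   cellof, free_stack, free_top)
                        continue
                    if ph_mode == PH_BATH and r > ph_Rbath:
                        f = (2.0 * ph_Rbath - r) / r
                        pos[i, 0] *= f
                        pos[i, 1] *= f
                        pos[i, 2] *= f
                        r = 2.0 * ph_Rbath - r
                    if r < R:  # reflect at the receiver cell membrane
                        f = (2.0 * R - r) / r if r > 0 else 1.0
                        pos[i, 0] *= f
                        pos[i, 1] *= f
                        pos[i, 2] *= f
                    if ph_emit_R > 0.0:  # reflect at the emitter cell
                        ex = pos[i, 0] - ph_emit_c[0]
                        ey = pos[i, 1] - ph_emit_c[1]
                        ez = pos[i, 2] - ph_emit_c[2]
                        er = math.sqrt(ex * ex + ey * ey + ez * ez)
                        if er < ph_emit_R and er > 0.0:
                            f = (2.0 * ph_emit_R - er) / er
                            pos[i, 0] = ph_emit_c[0] + ex * f
                            pos[i, 1] = ph_emit_c[1] + ey * f
                            pos[i, 2] = ph_emit_c[2] + ez * f
        zptr[0] = z

        # ---- pheromone emission ------------------------------------------
        if ph_mode == PH_POINT and ph_rate_dt > 0.0:
            nem = np.random.poisson(ph_rate_dt)
            for _ in range(nem):
                j = _alloc_slot(ph_spec, spec, members, mpos, count, free_stack, free_top)
                if j < 0:
                    break
                pos[j, 0] = ph_src[0]
                pos[j, 1] = ph_src[1]
                pos[j, 2] = ph_src[2]
                stamp[j] = step

        # ---- first-order reactions (aggregated Binomial sampling) --------
        for q in range(fo_r.shape[0]):
            s = fo_r[q]
            n = count[s]
            if n == 0 or fo_p[q] <= 0.0:
                continue
            m = _binomial_small(n, fo_p[q])
            for _ in range(m):
                nn = count[s]
                if nn == 0:
                    break
                i = members[s, np.random.randint(0, nn)]
                if stamp[i] == step:
                    continue
                stamp[i] = step
                p1 = fo_p1[q]
                _change_species(i, p1, spec, members, mpos, count)
                if mode == 1 and compart[p1] == 1 and compart[s] != 1:
                    _project_membrane(i, pos, R)
                _fix_grid(i, in_grid[p1], pos, mode, L, G, cell, ncx, ncy, ncz,
                          head, nxt, prv, cellof)
                if fo_np[q] == 2:
                    p2 = fo_p2[q]
                    if ph_mode == PH_BATH and p2 == ph_spec:
                        continue  # released pheromone is absorbed into the bath
                    j = _alloc_slot(p2, spec, members, mpos, count, free_stack, free_top)
                    if j < 0:
                        continue
                    stamp[j] = step
                    _place_product(i, j, pos, mode, L, R, compart[p2], rho_off)
                    if in_grid[p2] == 1:
                        c = _cell_index(pos[j, 0], pos[j, 1], pos[j, 2], mode, L, G,
                                        cell, ncx, ncy, ncz)
                        _grid_insert(j, c, head, nxt, prv, cellof)

        # ---- position-modulated activation (frozen gradient) -------------
        if pm_on == 1:
            n = count[pm_r]
            if n > 0 and pm_pmax > 0.0:
                m = _binomial_small(n, pm_pmax)
                for _ in range(m):
                    nn = count[pm_r]
                    if nn == 0:
                        break
                    i = members[pm_r, np.random.randint(0, nn)]
                    if stamp[i] == step:
                        continue
                    r = math.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2)
                    mu = (pos[i, 0] * pm_axis[0] + pos[i, 1] * pm_axis[1]
                          + pos[i, 2] * pm_axis[2]) / r
                    nb = pm_p.shape[0]
                    b = 0
                    while b < nb - 1 and mu < pm_edges[b + 1]:
                        b += 1
                    if np.random.random() * pm_pmax < pm_p[b]:
                        stamp[i] = step
                        _change_species(i, pm_prod, spec, members, mpos, count)
                        _fix_grid(i, in_grid[pm_prod], pos, mode, L, G, cell,
                                  ncx, ncy, ncz, head, nxt, prv, cellof)

        # ---- second-order reactions (scan from the chosen side) ----------
        for q in range(so_a.shape[0]):
            sa = so_a[q]
            sb = so_b[q]
            na = count[sa]
            nb = count[sb]
            if na == 0 or nb == 0 or so_p[q] <= 0.0:
                continue
            it = so_iter[q]
            if it == 0:
                from_a = True
            elif it == 1:
                from_a = False
            else:
                from_a = na <= nb
            s_it = sa if from_a else sb
            s_other = sb if from_a else sa
            alpha = so_alpha[q]
            log1mp = math.log(1.0 - so_p[q])
            nit = count[s_it]
            for k in range(nit):
                scratch[k] = members[s_it, k]
            for k in range(nit):
                # candidate thinning: test with probability alpha and
                # compensate in the compound firing probability below
                if alpha < 1.0 and np.random.random() >= alpha:
                    continue
                i = scratch[k]
                if spec[i] != s_it or stamp[i] == step:
                    continue
                ci = _cell_index(pos[i, 0], pos[i, 1], pos[i, 2], mode, L, G,
                                 cell, ncx, ncy, ncz)
                if ci < 0:
                    continue
                cz = ci % ncz
                cy = (ci // ncz) % ncy
                cx = ci // (ncz * ncy)
                # gather every partner within rho (capped at the buffer size)
                nfound = 0
                for ddx in range(-1, 2):
                    ix = cx + ddx
                    if mode == 0:
                        if ix < 0:
                            ix += ncx
                        elif ix >= ncx:
                            ix -= ncx
                    elif ix < 0 or ix >= ncx:
                        continue
                    for ddy in range(-1, 2):
                        iy = cy + ddy
                        if mode == 0:
                            if iy < 0:
                                iy += ncy
                            elif iy >= ncy:
                                iy -= ncy
                        elif iy < 0 or iy >= ncy:
                            continue
                        for ddz in range(-1, 2):
                            iz = cz + ddz
                            if mode == 0:
                                if iz != 0:
                                    continue
                                iz = 0
                            elif iz < 0 or iz >= ncz:
                                continue
                            j = head[(ix * ncy + iy) * ncz + iz]
                            while j >= 0:
                                if j != i and spec[j] == s_other and stamp[j] != step:
                                    if _pair_d2(i, j, pos, mode, L) <= rho2:
                                        if nfound < pbuf.shape[0]:
                                            pbuf[nfound] = j
                                            nfound += 1
                                j = nxt[j]
                if nfound == 0:
                    continue
                # candidate fires with the compound probability
                # 1 - (1-p)^k, compensated for thinning; the partner is
                # drawn uniformly among those in range
                compound = -math.expm1(nfound * log1mp)
                if np.random.random() * alpha >= compound:
                    continue
                j = pbuf[np.random.randint(0, nfound)]
                ia = i if from_a else j
                ib = j if from_a else i
                stamp[i] = step
                stamp[j] = step
                if so_bind[q] == 1:
                    _change_species(ia, so_pa[q], spec, members, mpos, count)
                    if mode == 1 and compart[so_pa[q]] == 1:
                        _project_membrane(ia, pos, R)
                    _fix_grid(ia, in_grid[so_pa[q]], pos, mode, L, G, cell,
                              ncx, ncy, ncz, head, nxt, prv, cellof)
                    _free_slot(ib, spec, members, mpos, count, head, nxt, prv,
                               cellof, free_stack, free_top)
                    if ph_mode == PH_BATH and sb == ph_spec:
                        jj = _alloc_slot(ph_spec, spec, members, mpos, count,
                                         free_stack, free_top)
                        if jj >= 0:
                            stamp[jj] = step
                            _inject_bath(jj, pos, R, ph_Rbath)
                else:
                    if so_pb[q] != sb:
                        _change_species(ib, so_pb[q], spec, members, mpos, count)
                        if mode == 1 and compart[so_pb[q]] == 1 and compart[sb] != 1:
                            _project_membrane(ib, pos, R)
                        _fix_grid(ib, in_grid[so_pb[q]], pos, mode, L, G, cell,
                                  ncx, ncy, ncz, head, nxt, prv, cellof)
        done += 1
    return done
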