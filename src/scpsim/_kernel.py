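"""Numba inner loop of the Search-Capture-Pull Langevin integrator.

The kernel advances the mechanical state (two nodes, semiflexible
bead-spring filaments, at most one motor link per filament) by a fixed
number of time steps between myosin events.  Capture and motor walking are
handled at event granularity in Python (:mod:`scpsim.simulation`); the
kernel owns forces, the two-noise Langevin update, polymerization growth,
formin arrest, and particle insertion.

All force terms are duplicated in pure numpy in
:func:`scpsim.simulation.total_forces`; agreement of the two routes is
asserted by the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["seed_kernel_rng", "advance"]

OK = 0
UNSTABLE = 1
FULL = 2
NOISE_EXHAUSTED = 3


@njit(cache=False)
def _wrap_angle(a):
    while a > np.pi:
        a -= 2.0 * np.pi
    while a < -np.pi:
        a += 2.0 * np.pi
    return a


@njit(cache=False)
def _accumulate_forces(
    node_pos,
    pos,
    n_parts,
    rest1,
    theta0,
    link_on,
    link_seg,
    link_frac,
    link_rest,
    link_k,
    k_spring,
    l0,
    kappa,
    k_rot,
    node_diameter,
    f_nodes,
    f_parts,
):
    """Fill f_nodes/f_parts with spring + bending + torque + motor forces."""
    n_fil = pos.shape[0]
    f_nodes[:, :] = 0.0
    for f in range(n_fil):  # zero only the active slice: the padded tail is untouched
        for j in range(n_parts[f]):
            f_parts[f, j, 0] = 0.0
            f_parts[f, j, 1] = 0.0
    half_d = 0.5 * node_diameter
    for f in range(n_fil):
        n = n_parts[f]
        if n < 1:
            continue
        # tether spring: formin node centre to particle 0, rest D/2,
        # stiffness scaled inversely with its rest length
        k0 = k_spring * l0 / half_d
        dx = pos[f, 0, 0] - node_pos[0, 0]
        dy = pos[f, 0, 1] - node_pos[0, 1]
        dist = np.sqrt(dx * dx + dy * dy)
        if dist > 1e-12:
            fmag = k0 * (dist - half_d) / dist
            f_parts[f, 0, 0] -= fmag * dx
            f_parts[f, 0, 1] -= fmag * dy
            f_nodes[0, 0] += fmag * dx
            f_nodes[0, 1] += fmag * dy
        # actin segments: growing segment (0-1) has rest rest1[f] and
        # inversely rescaled stiffness, the rest are (l0, k)
        for j in range(n - 1):
            if j == 0:
                rest = rest1[f]
                kseg = k_spring * l0 / rest
            else:
                rest = l0
                kseg = k_spring
            dx = pos[f, j + 1, 0] - pos[f, j, 0]
            dy = pos[f, j + 1, 1] - pos[f, j, 1]
            dist = np.sqrt(dx * dx + dy * dy)
            if dist > 1e-12:
                fmag = kseg * (dist - rest) / dist
                f_parts[f, j, 0] += fmag * dx
                f_parts[f, j, 1] += fmag * dy
                f_parts[f, j + 1, 0] -= fmag * dx
                f_parts[f, j + 1, 1] -= fmag * dy
        # bending at interior particles, rest angle straight
        for j in range(1, n - 1):
            t1x = pos[f, j, 0] - pos[f, j - 1, 0]
            t1y = pos[f, j, 1] - pos[f, j - 1, 1]
            t2x = pos[f, j + 1, 0] - pos[f, j, 0]
            t2y = pos[f, j + 1, 1] - pos[f, j, 1]
            cross = t1x * t2y - t1y * t2x
            dot = t1x * t2x + t1y * t2y
            phi = np.arctan2(cross, dot)
            c = -kappa * phi
            l1sq = t1x * t1x + t1y * t1y
            l2sq = t2x * t2x + t2y * t2y
            if l1sq < 1e-12 or l2sq < 1e-12:
                continue
            gax = -t1y / l1sq
            gay = t1x / l1sq
            gcx = -t2y / l2sq
            gcy = t2x / l2sq
            f_parts[f, j - 1, 0] += c * gax
            f_parts[f, j - 1, 1] += c * gay
            f_parts[f, j + 1, 0] += c * gcx
            f_parts[f, j + 1, 1] += c * gcy
            f_parts[f, j, 0] -= c * (gax + gcx)
            f_parts[f, j, 1] -= c * (gay + gcy)
        # restoring torque holding the filament at its initial emanation
        # angle: a pure couple on the first actin segment, equal and
        # opposite perpendicular forces on particles 0 and 1
        if n >= 2:
            ux = pos[f, 1, 0] - pos[f, 0, 0]
            uy = pos[f, 1, 1] - pos[f, 0, 1]
            ulen = np.sqrt(ux * ux + uy * uy)
            if ulen > 1e-12:
                delta = _wrap_angle(np.arctan2(uy, ux) - theta0[f])
                mag = (k_rot / l0) * delta
                nx = -uy / ulen
                ny = ux / ulen
                f_parts[f, 0, 0] += mag * nx
                f_parts[f, 0, 1] += mag * ny
                f_parts[f, 1, 0] -= mag * nx
                f_parts[f, 1, 1] -= mag * ny
        # motor spring between the myosin node and its attachment point,
        # lever-rule distributed onto the flanking particles
        if link_on[f]:
            s = link_seg[f]
            fr = link_frac[f]
            ax = (1.0 - fr) * pos[f, s, 0] + fr * pos[f, s + 1, 0]
            ay = (1.0 - fr) * pos[f, s, 1] + fr * pos[f, s + 1, 1]
            dx = node_pos[1, 0] - ax
            dy = node_pos[1, 1] - ay
            dist = np.sqrt(dx * dx + dy * dy)
            if dist > 1e-12:
                fmag = link_k[f] * (dist - link_rest[f]) / dist
                fx = fmag * dx
                fy = fmag * dy
                f_parts[f, s, 0] += (1.0 - fr) * fx
                f_parts[f, s, 1] += (1.0 - fr) * fy
                f_parts[f, s + 1, 0] += fr * fx
                f_parts[f, s + 1, 1] += fr * fy
                f_nodes[1, 0] -= fx
                f_nodes[1, 1] -= fy


@njit(cache=False)
def advance(
    node_pos,
    pos,
    n_parts,
    rest1,
    theta0,
    link_on,
    link_seg,
    link_frac,
    link_rest,
    link_k,
    noise_nodes,
    noise_parts,
    noise_buf,
    n_steps,
    dt,
    kBT,
    k_spring,
    l0,
    kappa,
    k_rot,
    zeta_node,
    zeta_part,
    node_diameter,
    growth_rate,
    f_cut,
    smooth_alpha,
    ema_load,
    ema_motor,
    motor_active,
    inhibition,
    latched,
    arrest_latch,
    counters,
):
    """Advance the state by ``n_steps`` Langevin steps of length ``dt``.

    Mutates all state arrays in place.  ``noise_*`` hold the Gaussian draw
    W(t) from the previous step (the integrator reuses it, giving the
    correlated two-noise update that preserves long-time diffusion);
    ``noise_buf`` supplies the fresh standard-normal draws, consumed
    sequentially (pre-generated in Python, where vectorized generation is
    an order of magnitude faster than per-draw sampling here).
    ``counters`` accumulates (arrested step count, total growth step count).
    Returns OK, UNSTABLE (a particle moved more than l0 in one step), FULL
    (a filament hit the particle-array capacity) or NOISE_EXHAUSTED (the
    caller undersized the noise buffer).
    """
    n_fil = pos.shape[0]
    max_p = pos.shape[1]
    f_nodes = np.zeros((2, 2))
    f_parts = np.zeros((n_fil, max_p, 2))
    amp_node = np.sqrt(kBT * dt / (2.0 * zeta_node))
    amp_part = np.sqrt(kBT * dt / (2.0 * zeta_part))
    max_disp = l0
    nbuf = noise_buf.size
    ib = 0
    for _ in range(n_steps):
        need = 4
        for f in range(n_fil):
            need += 2 * n_parts[f] + 2
        if ib + need > nbuf:
            return NOISE_EXHAUSTED
        _accumulate_forces(
            node_pos, pos, n_parts, rest1, theta0,
            link_on, link_seg, link_frac, link_rest, link_k,
            k_spring, l0, kappa, k_rot, node_diameter,
            f_nodes, f_parts,
        )
        # polymerization with formin arrest: growth of the first actin
        # segment pauses while the smoothed formin load exceeds f_cut.
        # Two load channels are smoothed separately (EMA with weight
        # smooth_alpha = dt/tau; alpha >= 1 degenerates to the literal
        # per-step instantaneous rule): the extensional force on the first
        # segment, and the tensile part of an engaged, actively cycling
        # motor's load (its spring force projected against the walking
        # direction, clamped at zero since a filament transmits tension
        # but not sub-segment compression to the formin).  This channel
        # stands in for the slack-independent entropic transmission of
        # myosin force that rigid 100-nm segments cannot carry; it is off
        # for a non-cycling motor (motor_active false), which generates no
        # sustained directional load.
        for f in range(n_fil):
            n = n_parts[f]
            if n < 2:
                continue
            dx = pos[f, 1, 0] - pos[f, 0, 0]
            dy = pos[f, 1, 1] - pos[f, 0, 1]
            dist = np.sqrt(dx * dx + dy * dy)
            k1 = k_spring * l0 / rest1[f]
            f_formin = k1 * (dist - rest1[f])
            f_motor = 0.0
            if link_on[f] and motor_active:
                s = link_seg[f]
                fr = link_frac[f]
                ax = (1.0 - fr) * pos[f, s, 0] + fr * pos[f, s + 1, 0]
                ay = (1.0 - fr) * pos[f, s, 1] + fr * pos[f, s + 1, 1]
                dxm = node_pos[1, 0] - ax
                dym = node_pos[1, 1] - ay
                dm = np.sqrt(dxm * dxm + dym * dym)
                tx = pos[f, s, 0] - pos[f, s + 1, 0]
                ty = pos[f, s, 1] - pos[f, s + 1, 1]
                tl = np.sqrt(tx * tx + ty * ty)
                if dm > 1e-12 and tl > 1e-12:
                    fmag = link_k[f] * (dm - link_rest[f]) / dm
                    f_motor = -(fmag * dxm * tx + fmag * dym * ty) / tl
                    if f_motor < 0.0:
                        f_motor = 0.0
            if smooth_alpha >= 1.0:
                ema_load[f] = f_formin
                ema_motor[f] = f_motor
            else:
                ema_load[f] += smooth_alpha * (f_formin - ema_load[f])
                ema_motor[f] += smooth_alpha * (f_motor - ema_motor[f])
            if growth_rate <= 0.0:
                continue
            counters[1] += 1
            arrested = False
            if inhibition:
                if latched and arrest_latch[f]:
                    arrested = True
                elif ema_load[f] > f_cut or ema_motor[f] > f_cut:
                    arrested = True
                    if latched:
                        arrest_latch[f] = True
            if arrested:
                counters[0] += 1
            else:
                rest1[f] += growth_rate * dt
                if rest1[f] >= 2.0 * l0:
                    if n >= max_p:
                        return FULL
                    # insert a particle at the midpoint of the grown segment
                    midx = 0.5 * (pos[f, 0, 0] + pos[f, 1, 0])
                    midy = 0.5 * (pos[f, 0, 1] + pos[f, 1, 1])
                    for j in range(n, 1, -1):
                        pos[f, j, 0] = pos[f, j - 1, 0]
                        pos[f, j, 1] = pos[f, j - 1, 1]
                        noise_parts[f, j, 0] = noise_parts[f, j - 1, 0]
                        noise_parts[f, j, 1] = noise_parts[f, j - 1, 1]
                        f_parts[f, j, 0] = f_parts[f, j - 1, 0]
                        f_parts[f, j, 1] = f_parts[f, j - 1, 1]
                    pos[f, 1, 0] = midx
                    pos[f, 1, 1] = midy
                    noise_parts[f, 1, 0] = noise_buf[ib]
                    noise_parts[f, 1, 1] = noise_buf[ib + 1]
                    ib += 2
                    f_parts[f, 1, 0] = 0.5 * (f_parts[f, 0, 0] + f_parts[f, 2, 0])
                    f_parts[f, 1, 1] = 0.5 * (f_parts[f, 0, 1] + f_parts[f, 2, 1])
                    n_parts[f] = n + 1
                    rest1[f] -= l0
                    if link_on[f]:
                        if link_seg[f] >= 1:
                            link_seg[f] += 1
                        else:
                            # attachment sat on the split segment
                            if link_frac[f] <= 0.5:
                                link_frac[f] = 2.0 * link_frac[f]
                            else:
                                link_seg[f] = 1
                                link_frac[f] = 2.0 * link_frac[f] - 1.0
        # Langevin update: R += dt F/zeta + sqrt(kBT dt / 2 zeta)(W_new + W_old)
        for i in range(2):
            for c in range(2):
                w_new = noise_buf[ib]
                ib += 1
                step = dt * f_nodes[i, c] / zeta_node + amp_node * (w_new + noise_nodes[i, c])
                node_pos[i, c] += step
                noise_nodes[i, c] = w_new
        for f in range(n_fil):
            for j in range(n_parts[f]):
                sx = dt * f_parts[f, j, 0] / zeta_part
                sy = dt * f_parts[f, j, 1] / zeta_part
                w_new_x = noise_buf[ib]
                w_new_y = noise_buf[ib + 1]
                ib += 2
                sx += amp_part * (w_new_x + noise_parts[f, j, 0])
                sy += amp_part * (w_new_y + noise_parts[f, j, 1])
                if sx * sx + sy * sy > max_disp * max_disp:
                    return UNSTABLE
                pos[f, j, 0] += sx
                pos[f, j, 1] += sy
                noise_parts[f, j, 0] = w_new_x
                noise_parts[f, j, 1] = w_new_y
    return OK
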