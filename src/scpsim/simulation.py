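"""Overdamped-Langevin Search-Capture-Pull model of node coalescence.

Two nodes — a formin node at the origin and a myosin node a set distance
away — are connected by semiflexible bead-spring actin filaments that the
formin elongates.  Myosin dynamics run on a coarser event clock: every
``t_event`` the myosin node captures a filament whose nearest particle
falls within 110% of the node radius, and every event an existing motor
link walks toward the formin-bound barbed end with a linear force–velocity
law v = v0 (1 − F/F_stall) clamped to [0, 2 v0].  Formin-mediated
polymerization extends the first actin segment and pauses while the
smoothed formin load exceeds a threshold (formin mechano-inhibition); the
load combines the first segment's extension force with the tensile load of
an engaged, actively cycling motor, the model's stand-in for the
slack-independent entropic transmission of myosin force to the formin
(see docs/methods.md).

The particle update rule is the two-noise scheme

    R(t+dt) = R(t) + dt F/zeta + sqrt(kBT dt / (2 zeta)) (W(t+dt) + W(t)),

which reuses the previous step's Gaussian draw and preserves the long-time
diffusion coefficient kBT/zeta.  Simulations are 2D throughout, matching
the quasi-2D geometry of both the TIRF assays and the cell cortex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import _kernel
from .datatypes import KBT_DEFAULT

__all__ = [
    "SimParams",
    "SimState",
    "SimResult",
    "in_vitro_params",
    "in_vivo_params",
    "init_state",
    "total_forces",
    "formin_load",
    "motor_speed",
    "myosin_update",
    "langevin_step",
    "polymerize_step",
    "run",
    "coalescence_speed",
    "scan_motor_speed",
    "speed_for_target_coalescence",
    "rod_drag",
    "tangent_correlation",
    "fit_persistence_length_2d",
    "IntegrationError",
]

PA_S_TO_PN_S_NM2 = 1.0e-6


class IntegrationError(RuntimeError):
    """The integrator became unstable (a particle moved more than l0 in one step)."""


@dataclass(frozen=True)
class SimParams:
    """Full parameter set of the Search-Capture-Pull model.

    Units: nm, s, pN, pN·nm; ``medium_viscosity`` in Pa·s.  ``node_drag``
    overrides the Stokes drag 6 pi eta (D/2) on both nodes when set, which
    models bead–coverslip interactions in vitro and membrane anchoring in
    vivo.
    """

    dt: float  # integration step, s
    t_event: float = 0.05  # myosin event clock, s
    kBT: float = KBT_DEFAULT  # pN·nm
    node_diameter: float = 1000.0  # nm
    node_drag: float | None = None  # pN·s/nm; None -> Stokes from viscosity
    medium_viscosity: float = 0.012  # Pa·s, felt by filament particles
    l0: float = 100.0  # actin segment rest length, nm
    actin_radius: float = 3.5  # nm
    persistence_length: float = 10_000.0  # nm
    k_spring: float = 0.25  # pN/nm, actin and motor springs
    k_rot: float = 400.0  # pN·nm, restoring-torque stiffness
    f_cut_formin: float = 0.1  # pN, formin arrest threshold
    f_smooth_tau: float = 5.0  # s, response time of the arrest load average; 0 = instantaneous
    f_stall_myo: float = 6.0  # pN, motor force-velocity scale
    v_myo0: float = 100.0  # nm/s, unloaded motor speed
    elong_rate: float = 10.0  # subunits/s
    subunit_rise: float = 2.7  # nm per subunit
    capture_factor: float = 1.10  # capture radius / node radius
    initial_separation: float = 5000.0  # nm
    n_filaments: int = 2
    max_time: float = 120.0  # s
    formin_inhibition_enabled: bool = True
    latched_arrest: bool = False
    max_particles: int = 512

    def __post_init__(self) -> None:
        if self.dt >= self.t_event:
            raise ValueError("dt must be smaller than t_event")
        for name in (
            "dt", "t_event", "kBT", "node_diameter", "medium_viscosity", "l0",
            "actin_radius", "persistence_length", "k_spring", "k_rot",
            "f_stall_myo", "subunit_rise", "initial_separation", "max_time",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.capture_factor <= 1.0:
            raise ValueError("capture_factor must exceed 1")
        if (
            self.elong_rate < 0 or self.v_myo0 < 0 or self.f_cut_formin < 0
            or self.f_smooth_tau < 0
        ):
            raise ValueError("rates, speeds and thresholds must be non-negative")
        if self.node_drag is not None and self.node_drag <= 0:
            raise ValueError("node_drag must be positive when set")
        if self.k_spring * self.l0**2 < 100.0 * self.kBT:
            warnings.warn(
                "k_spring·l0² is not large against kBT; thermal stretch may be "
                "comparable to the segment length",
                stacklevel=2,
            )

    # --- derived mechanical quantities -------------------------------------

    @property
    def viscosity_pn(self) -> float:
        """Medium viscosity in pN·s/nm²."""
        return self.medium_viscosity * PA_S_TO_PN_S_NM2

    @property
    def zeta_node(self) -> float:
        """Node drag: explicit override or Stokes 6 pi eta R (pN·s/nm)."""
        if self.node_drag is not None:
            return self.node_drag
        return 6.0 * np.pi * self.viscosity_pn * (self.node_diameter / 2.0)

    @property
    def zeta_particle(self) -> float:
        """Rod drag per actin segment (pN·s/nm)."""
        return rod_drag(self.l0, self.actin_radius, self.viscosity_pn)

    @property
    def kappa(self) -> float:
        """Angular stiffness kappa = kBT Lp / l0 (pN·nm)."""
        return self.kBT * self.persistence_length / self.l0

    @property
    def capture_radius(self) -> float:
        return self.capture_factor * self.node_diameter / 2.0

    @property
    def growth_rate_nm(self) -> float:
        """First-segment rest-length growth speed, nm/s."""
        return self.elong_rate * self.subunit_rise

    @property
    def smooth_alpha(self) -> float:
        """Per-step EMA weight for the arrest load (1 = instantaneous)."""
        if self.f_smooth_tau <= 0.0:
            return 1.0
        return min(1.0, self.dt / self.f_smooth_tau)


def rod_drag(l0: float, a: float, eta_pn: float) -> float:
    """Drag of a rod of length l0 and radius a: 4 pi eta l0 / (ln(l0/2a) + 0.84)."""
    return 4.0 * np.pi * eta_pn * l0 / (np.log(l0 / (2.0 * a)) + 0.84)


def in_vitro_params(**overrides) -> SimParams:
    """Biomimetic-bead conditions: 1-µm beads in methylcellulose buffer.

    Bead drag 2.1e-3 pN·s/nm (effective, coverslip-influenced), filament
    viscosity 0.012 Pa·s, elongation 10 subunits/s, unloaded myosin speed
    100 nm/s, beads started 5 µm apart.
    """
    base = dict(
        dt=5e-6,
        node_diameter=1000.0,
        node_drag=2.1e-3,
        medium_viscosity=0.012,
        elong_rate=10.0,
        v_myo0=100.0,
        initial_separation=5000.0,
        max_time=300.0,
    )
    base.update(overrides)
    return SimParams(**base)


def in_vivo_params(**overrides) -> SimParams:
    """Cytokinesis-node conditions on the cell cortex.

    Node drag 100x the in vitro beads (0.21 pN·s/nm, membrane anchoring),
    cytoplasmic viscosity 0.3 Pa·s, elongation 75 subunits/s (~8x in
    vitro), 50-nm nodes.  Nodes start 500 nm apart — a realistic internode
    distance within the node broad band — and the unloaded motor speed is
    the scanned variable (default 60 nm/s).
    """
    base = dict(
        dt=2e-5,
        node_diameter=50.0,
        node_drag=0.21,
        medium_viscosity=0.3,
        elong_rate=75.0,
        v_myo0=60.0,
        initial_separation=500.0,
        max_time=75.0,
    )
    base.update(overrides)
    return SimParams(**base)


@dataclass
class SimState:
    """Instantaneous mechanical state of the two-node system.

    ``pos[f, :n_particles[f]]`` are the particles of filament f ordered
    from the formin node outward: particle 0 sits at the node surface next
    to the formin-bound barbed end, the last particle is the distal tip.
    ``rest1`` is the growing first-segment rest length in [l0, 2 l0).
    ``noise_*`` store the previous Gaussian draw per coordinate for the
    two-noise integrator.
    """

    time: float
    node_pos: np.ndarray  # (2, 2): row 0 formin node, row 1 myosin node
    pos: np.ndarray  # (n_fil, max_particles, 2)
    n_particles: np.ndarray  # (n_fil,) int
    rest1: np.ndarray  # (n_fil,)
    theta0: np.ndarray  # (n_fil,) initial filament angle, rad
    link_on: np.ndarray  # (n_fil,) bool
    link_seg: np.ndarray  # (n_fil,) int
    link_frac: np.ndarray  # (n_fil,)
    link_rest: np.ndarray  # (n_fil,)
    link_k: np.ndarray  # (n_fil,)
    noise_nodes: np.ndarray  # (2, 2)
    noise_parts: np.ndarray  # (n_fil, max_particles, 2)
    arrest_latch: np.ndarray  # (n_fil,) bool
    ema_load: np.ndarray  # (n_fil,) smoothed first-segment load for the arrest rule, pN
    ema_motor: np.ndarray  # (n_fil,) smoothed engaged-motor load for the arrest rule, pN
    counters: np.ndarray  # (2,) int64: arrested steps, growth-eligible steps

    @property
    def separation(self) -> float:
        return float(np.hypot(*(self.node_pos[1] - self.node_pos[0])))

    def filament_particles(self, f: int) -> np.ndarray:
        return self.pos[f, : self.n_particles[f]]

    def copy(self) -> "SimState":
        return SimState(
            time=self.time,
            node_pos=self.node_pos.copy(),
            pos=self.pos.copy(),
            n_particles=self.n_particles.copy(),
            rest1=self.rest1.copy(),
            theta0=self.theta0.copy(),
            link_on=self.link_on.copy(),
            link_seg=self.link_seg.copy(),
            link_frac=self.link_frac.copy(),
            link_rest=self.link_rest.copy(),
            link_k=self.link_k.copy(),
            noise_nodes=self.noise_nodes.copy(),
            noise_parts=self.noise_parts.copy(),
            arrest_latch=self.arrest_latch.copy(),
            ema_load=self.ema_load.copy(),
            ema_motor=self.ema_motor.copy(),
            counters=self.counters.copy(),
        )


MAX_INIT_ANGLE = np.deg2rad(60.0)


def init_state(
    params: SimParams,
    seed: int,
    *,
    n_init_particles: int = 2,
    thermal_init: bool = False,
) -> SimState:
    """Initial state: formin node at the origin, myosin node on the +x axis.

    Filament 1 leaves the formin node at a uniform random angle within
    ±60° of the node-to-node axis; filament 2 (if present) starts
    diametrically opposite.  Particle 0 sits on the node surface, further
    particles continue outward at spacing l0.  ``thermal_init`` draws the
    joint angles from the equilibrium bending distribution instead of a
    straight line (useful for equilibrium-statistics tests).
    """
    rng = np.random.default_rng(seed)
    n_fil = params.n_filaments
    max_p = params.max_particles
    node_pos = np.array([[0.0, 0.0], [params.initial_separation, 0.0]])
    pos = np.zeros((max(n_fil, 1), max_p, 2))
    n_particles = np.full(max(n_fil, 1), 0, dtype=np.int64)
    theta0 = np.zeros(max(n_fil, 1))
    base_angle = rng.uniform(-MAX_INIT_ANGLE, MAX_INIT_ANGLE)
    angle_sd = np.sqrt(params.kBT / params.kappa)
    for f in range(n_fil):
        theta0[f] = base_angle + f * np.pi
        n_particles[f] = n_init_particles
        segment_angles = np.full(n_init_particles, theta0[f])
        if thermal_init and n_init_particles > 2:
            kicks = rng.normal(0.0, angle_sd, size=n_init_particles - 2)
            segment_angles[2:] += np.cumsum(kicks)
        point = node_pos[0] + (params.node_diameter / 2.0) * np.array(
            [np.cos(theta0[f]), np.sin(theta0[f])]
        )
        pos[f, 0] = point
        for j in range(1, n_init_particles):
            ang = segment_angles[j]
            point = point + params.l0 * np.array([np.cos(ang), np.sin(ang)])
            pos[f, j] = point
    noise_nodes = rng.standard_normal((2, 2))
    noise_parts = np.zeros((max(n_fil, 1), max_p, 2))
    for f in range(n_fil):
        noise_parts[f, : n_particles[f]] = rng.standard_normal((n_particles[f], 2))
    return SimState(
        time=0.0,
        node_pos=node_pos,
        pos=pos,
        n_particles=n_particles,
        rest1=np.full(max(n_fil, 1), float(params.l0)),
        theta0=theta0,
        link_on=np.zeros(max(n_fil, 1), dtype=np.bool_),
        link_seg=np.zeros(max(n_fil, 1), dtype=np.int64),
        link_frac=np.zeros(max(n_fil, 1)),
        link_rest=np.zeros(max(n_fil, 1)),
        link_k=np.zeros(max(n_fil, 1)),
        noise_nodes=noise_nodes,
        noise_parts=noise_parts,
        arrest_latch=np.zeros(max(n_fil, 1), dtype=np.bool_),
        ema_load=np.zeros(max(n_fil, 1)),
        ema_motor=np.zeros(max(n_fil, 1)),
        counters=np.zeros(2, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# forces: numpy reference implementation (the numba kernel mirrors this)


def _wrap(a: float) -> float:
    return (a + np.pi) % (2.0 * np.pi) - np.pi


def total_forces(state: SimState, params: SimParams) -> tuple[np.ndarray, np.ndarray]:
    """Per-particle and per-node force vectors of the full energy + torque.

    Pure-numpy reference used by the finite-difference and kernel-agreement
    tests; returns (f_nodes (2, 2), f_parts like state.pos).
    """
    f_nodes = np.zeros_like(state.node_pos)
    f_parts = np.zeros_like(state.pos)
    k, l0, kappa = params.k_spring, params.l0, params.kappa
    half_d = params.node_diameter / 2.0
    for f in range(params.n_filaments):
        n = int(state.n_particles[f])
        if n < 1:
            continue
        p = state.pos[f, :n]
        # tether spring node -> particle 0
        d = p[0] - state.node_pos[0]
        dist = np.hypot(*d)
        if dist > 1e-12:
            fmag = (k * l0 / half_d) * (dist - half_d)
            f_parts[f, 0] -= fmag * d / dist
            f_nodes[0] += fmag * d / dist
        # segment springs
        for j in range(n - 1):
            rest = state.rest1[f] if j == 0 else l0
            kseg = k * l0 / state.rest1[f] if j == 0 else k
            d = p[j + 1] - p[j]
            dist = np.hypot(*d)
            fvec = kseg * (dist - rest) * d / dist
            f_parts[f, j] += fvec
            f_parts[f, j + 1] -= fvec
        # bending
        for j in range(1, n - 1):
            t1 = p[j] - p[j - 1]
            t2 = p[j + 1] - p[j]
            phi = np.arctan2(t1[0] * t2[1] - t1[1] * t2[0], np.dot(t1, t2))
            c = -kappa * phi
            ga = np.array([-t1[1], t1[0]]) / np.dot(t1, t1)
            gc = np.array([-t2[1], t2[0]]) / np.dot(t2, t2)
            f_parts[f, j - 1] += c * ga
            f_parts[f, j + 1] += c * gc
            f_parts[f, j] -= c * (ga + gc)
        # restoring torque: pure couple on the first actin segment
        if n >= 2:
            u = p[1] - p[0]
            ulen = np.hypot(*u)
            delta = _wrap(np.arctan2(u[1], u[0]) - state.theta0[f])
            mag = (params.k_rot / l0) * delta
            nhat = np.array([-u[1], u[0]]) / ulen
            f_parts[f, 0] += mag * nhat
            f_parts[f, 1] -= mag * nhat
        # motor spring
        if state.link_on[f]:
            s, fr = int(state.link_seg[f]), float(state.link_frac[f])
            attach = (1.0 - fr) * p[s] + fr * p[s + 1]
            d = state.node_pos[1] - attach
            dist = np.hypot(*d)
            fvec = state.link_k[f] * (dist - state.link_rest[f]) * d / dist
            f_parts[f, s] += (1.0 - fr) * fvec
            f_parts[f, s + 1] += fr * fvec
            f_nodes[1] -= fvec
    return f_nodes, f_parts


def spring_bend_energy(state: SimState, params: SimParams) -> float:
    """Total conservative energy (springs + bending + motor spring), pN·nm.

    Excludes the restoring torque, which is defined as a force pair rather
    than an energy gradient.
    """
    k, l0, kappa = params.k_spring, params.l0, params.kappa
    half_d = params.node_diameter / 2.0
    e = 0.0
    for f in range(params.n_filaments):
        n = int(state.n_particles[f])
        if n < 1:
            continue
        p = state.pos[f, :n]
        dist = np.hypot(*(p[0] - state.node_pos[0]))
        e += 0.5 * (k * l0 / half_d) * (dist - half_d) ** 2
        for j in range(n - 1):
            rest = state.rest1[f] if j == 0 else l0
            kseg = k * l0 / state.rest1[f] if j == 0 else k
            dist = np.hypot(*(p[j + 1] - p[j]))
            e += 0.5 * kseg * (dist - rest) ** 2
        for j in range(1, n - 1):
            t1 = p[j] - p[j - 1]
            t2 = p[j + 1] - p[j]
            phi = np.arctan2(t1[0] * t2[1] - t1[1] * t2[0], np.dot(t1, t2))
            e += 0.5 * kappa * phi**2
        if state.link_on[f]:
            s, fr = int(state.link_seg[f]), float(state.link_frac[f])
            attach = (1.0 - fr) * p[s] + fr * p[s + 1]
            dist = np.hypot(*(state.node_pos[1] - attach))
            e += 0.5 * state.link_k[f] * (dist - state.link_rest[f]) ** 2
    return e


def formin_load(state: SimState, params: SimParams, filament: int = 0) -> float:
    """Extensional force on the growing first segment, pN (positive = stretched)."""
    n = int(state.n_particles[filament])
    if n < 2:
        return 0.0
    rest = float(state.rest1[filament])
    k1 = params.k_spring * params.l0 / rest
    dist = float(np.hypot(*(state.pos[filament, 1] - state.pos[filament, 0])))
    return k1 * (dist - rest)


def motor_speed(F: float, params: SimParams) -> float:
    """Linear force–velocity law v = v0 (1 − F/F_stall) clamped to [0, 2 v0]."""
    v = params.v_myo0 * (1.0 - F / params.f_stall_myo)
    return float(np.clip(v, 0.0, 2.0 * params.v_myo0))


def _motor_load(state: SimState, params: SimParams, f: int) -> float:
    """Motor-spring force projected on the walking direction; resisting > 0."""
    s, fr = int(state.link_seg[f]), float(state.link_frac[f])
    p = state.pos[f]
    attach = (1.0 - fr) * p[s] + fr * p[s + 1]
    d = state.node_pos[1] - attach
    dist = np.hypot(*d)
    if dist < 1e-12:
        return 0.0
    f_spring = state.link_k[f] * (dist - state.link_rest[f]) * d / dist
    seg = p[s] - p[s + 1]
    seg_len = np.hypot(*seg)
    if seg_len < 1e-12:
        return 0.0
    walk_dir = seg / seg_len  # toward the formin-bound barbed end
    return float(-np.dot(f_spring, walk_dir))


def motor_force(state: SimState, params: SimParams, f: int) -> float:
    """Signed extension force of the motor spring, pN (positive = stretched)."""
    if not state.link_on[f]:
        return 0.0
    s, fr = int(state.link_seg[f]), float(state.link_frac[f])
    p = state.pos[f]
    attach = (1.0 - fr) * p[s] + fr * p[s + 1]
    dist = np.hypot(*(state.node_pos[1] - attach))
    return float(state.link_k[f] * (dist - state.link_rest[f]))


def myosin_update(state: SimState, params: SimParams) -> None:
    """One myosin event: capture within reach, then walk existing links.

    Capture: a filament without a link attaches at its particle closest to
    the myosin node if that distance is within ``capture_radius``; the
    motor-spring rest length is set to the capture distance so the link is
    born force-free.  Walking: the attachment point advances along the
    contour toward the formin-bound barbed end by motor_speed(load)·t_event,
    carrying across segment boundaries and clamping at particle 0.
    Links never detach.
    """
    for f in range(params.n_filaments):
        n = int(state.n_particles[f])
        if n < 1:
            continue
        if not state.link_on[f]:
            d = state.pos[f, :n] - state.node_pos[1]
            dists = np.hypot(d[:, 0], d[:, 1])
            i = int(np.argmin(dists))
            if dists[i] <= params.capture_radius:
                if i < n - 1:
                    state.link_seg[f] = i
                    state.link_frac[f] = 0.0
                else:
                    state.link_seg[f] = n - 2
                    state.link_frac[f] = 1.0
                state.link_rest[f] = max(float(dists[i]), 1.0)
                state.link_k[f] = params.k_spring
                state.link_on[f] = True
            continue
        # walk toward the barbed end (decreasing arclength)
        load = _motor_load(state, params, f)
        dist_to_walk = motor_speed(load, params) * params.t_event
        s, fr = int(state.link_seg[f]), float(state.link_frac[f])
        p = state.pos[f]
        while dist_to_walk > 0.0:
            seg_len = float(np.hypot(*(p[s + 1] - p[s])))
            avail = fr * seg_len
            if avail > dist_to_walk:
                fr -= dist_to_walk / seg_len
                dist_to_walk = 0.0
            else:
                dist_to_walk -= avail
                fr = 0.0
                if s == 0:
                    break  # clamped at the barbed-end side
                s -= 1
                fr = 1.0
        state.link_seg[f] = s
        state.link_frac[f] = fr


def _noise_buffer(
    rng: np.random.Generator,
    state: SimState,
    params: SimParams,
    n_steps: int,
    growth_rate_nm: float,
) -> np.ndarray:
    """Fresh standard-normal draws for ``n_steps`` kernel steps.

    Sized for the current particle count plus the headroom the kernel's
    per-step reservation requires for particles inserted during the chunk;
    draws are consumed sequentially, so the trajectory is a deterministic
    function of the generator state.
    """
    n_fil = state.pos.shape[0]
    insert_max = int(growth_rate_nm * params.dt * n_steps / params.l0) + 1
    per_step = 4
    for f in range(n_fil):
        per_step += 2 * (int(state.n_particles[f]) + insert_max) + 2
    return rng.standard_normal(n_steps * per_step + 2 * n_fil * insert_max)


_MAX_CHUNK_STEPS = 200_000


def _advance_steps(
    state: SimState,
    params: SimParams,
    n_steps: int,
    rng: np.random.Generator,
    growth_rate_nm: float | None = None,
) -> int:
    if growth_rate_nm is None:
        growth_rate_nm = params.growth_rate_nm
    remaining = n_steps
    status = _kernel.OK
    while remaining > 0:
        chunk = min(remaining, _MAX_CHUNK_STEPS)
        buf = _noise_buffer(rng, state, params, chunk, growth_rate_nm)
        status = _kernel.advance(
            state.node_pos, state.pos, state.n_particles, state.rest1, state.theta0,
            state.link_on, state.link_seg, state.link_frac, state.link_rest, state.link_k,
            state.noise_nodes, state.noise_parts, buf,
            chunk, params.dt, params.kBT, params.k_spring, params.l0,
            params.kappa, params.k_rot, params.zeta_node, params.zeta_particle,
            params.node_diameter, growth_rate_nm, params.f_cut_formin,
            params.smooth_alpha, state.ema_load, state.ema_motor,
            params.v_myo0 > 0.0,
            params.formin_inhibition_enabled, params.latched_arrest,
            state.arrest_latch, state.counters,
        )
        state.time += chunk * params.dt
        remaining -= chunk
        if status == _kernel.NOISE_EXHAUSTED:
            raise RuntimeError("internal error: undersized noise buffer")
        if status != _kernel.OK:
            return status
    return status


def langevin_step(
    state: SimState,
    params: SimParams,
    n_steps: int = 1,
    rng: np.random.Generator | None = None,
) -> None:
    """Advance only the Langevin mechanics by ``n_steps`` of dt (no growth, no events)."""
    if rng is None:
        rng = np.random.default_rng(0)
    status = _advance_steps(state, params, n_steps, rng, growth_rate_nm=0.0)
    if status == _kernel.UNSTABLE:
        raise IntegrationError("particle displacement exceeded l0; reduce dt")


def polymerize_step(
    state: SimState,
    params: SimParams,
    n_steps: int = 1,
    rng: np.random.Generator | None = None,
) -> None:
    """Advance mechanics plus polymerization by ``n_steps`` of dt (no myosin events)."""
    if rng is None:
        rng = np.random.default_rng(0)
    status = _advance_steps(state, params, n_steps, rng)
    if status == _kernel.UNSTABLE:
        raise IntegrationError("particle displacement exceeded l0; reduce dt")


@dataclass
class SimResult:
    """Recorded time series and summary statistics of one run."""

    times: np.ndarray  # s, one sample per myosin event
    node_positions: np.ndarray  # (n_samples, 2, 2) nm: formin node, myosin node
    separation: np.ndarray  # nm
    formin_force: np.ndarray  # (n_samples, n_fil) pN
    motor_force: np.ndarray  # (n_samples, n_fil) pN
    captured: np.ndarray  # (n_samples,) bool: any link present
    tension: np.ndarray  # (n_samples,) node-to-node T of the captured filament (nan before capture)
    capture_time: float | None
    taut_time: float | None  # first post-capture time with T <= 1.15
    coalescence_speed: float | None
    arrested_fraction_of_time: float
    coalesced: bool
    params: SimParams
    seed: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time_s": self.times,
                "formin_x": self.node_positions[:, 0, 0],
                "formin_y": self.node_positions[:, 0, 1],
                "myosin_x": self.node_positions[:, 1, 0],
                "myosin_y": self.node_positions[:, 1, 1],
                "separation_nm": self.separation,
                "captured": self.captured,
                "tension": self.tension,
            }
        )
        for f in range(self.formin_force.shape[1]):
            df[f"F_formin_{f}_pN"] = self.formin_force[:, f]
            df[f"F_motor_{f}_pN"] = self.motor_force[:, f]
        return df


MIN_FIT_WINDOW_S = 5.0

#: Node-to-node tension below which the connecting filament counts as taut.
TAUT_TENSION_MAX = 1.15


def node_to_node_tension(state: SimState, params: SimParams) -> float:
    """Tension T of the captured connection: contour / node separation.

    Contour runs from the formin node through the filament to the motor
    attachment and across the motor spring to the myosin node; nan when no
    filament is captured (min over filaments if several are).
    """
    best = np.nan
    for f in range(params.n_filaments):
        if not state.link_on[f]:
            continue
        s, fr = int(state.link_seg[f]), float(state.link_frac[f])
        p = state.pos[f]
        contour = float(np.hypot(*(p[0] - state.node_pos[0])))
        for j in range(s):
            contour += float(np.hypot(*(p[j + 1] - p[j])))
        attach = (1.0 - fr) * p[s] + fr * p[s + 1]
        contour += fr * float(np.hypot(*(p[s + 1] - p[s])))
        contour += float(np.hypot(*(state.node_pos[1] - attach)))
        t_val = contour / max(state.separation, 1e-9)
        if np.isnan(best) or t_val < best:
            best = t_val
    return best


def coalescence_speed(result: SimResult, phase: str = "taut") -> float | None:
    """Node approach speed, nm/s (positive toward contact).

    Sign-flipped least-squares slope of separation vs time from the start of
    the requested phase to the end of the record.  ``phase="taut"`` (default)
    starts at the first post-capture sample where the node-to-node tension is
    within the taut band (T <= 1.15) — nodes only move together once the
    connection is taut, so this window isolates actual coalescence.
    ``phase="capture"`` starts at the capture event (includes the
    slack-consuming period).  None without the phase or with less than 5 s
    of record in it.
    """
    if phase not in {"taut", "capture"}:
        raise ValueError("phase must be 'taut' or 'capture'")
    start = result.taut_time if phase == "taut" else result.capture_time
    if start is None:
        return None
    mask = result.times >= start
    t = result.times[mask]
    if t.size < 3 or t[-1] - t[0] < MIN_FIT_WINDOW_S:
        return None
    slope, _ = np.polyfit(t, result.separation[mask], 1)
    return float(-slope)


def run(params: SimParams, seed: int, *, disable_capture: bool = False) -> SimResult:
    """Run one Search-Capture-Pull simulation to contact, max_time or capacity.

    ``disable_capture`` removes the myosin node's ability to form links
    (a no-myosin control); the mechanics are otherwise identical.
    """
    state = init_state(params, seed)
    rng = np.random.default_rng((seed * 2654435761 + 97) % 2**31)
    steps_per_event = max(1, int(round(params.t_event / params.dt)))
    times, nodes, seps, ffs, mfs, caps, tens = [], [], [], [], [], [], []
    capture_time = None
    coalesced = False
    n_fil = params.n_filaments

    def record() -> None:
        times.append(state.time)
        nodes.append(state.node_pos.copy())
        seps.append(state.separation)
        ffs.append([formin_load(state, params, f) for f in range(n_fil)])
        mfs.append([motor_force(state, params, f) for f in range(n_fil)])
        caps.append(bool(state.link_on[:n_fil].any()))
        tens.append(node_to_node_tension(state, params))

    record()
    while state.time < params.max_time:
        status = _advance_steps(state, params, steps_per_event, rng)
        if status == _kernel.UNSTABLE:
            raise IntegrationError(
                f"integration unstable at t={state.time:.3f}s (dt={params.dt}); reduce dt"
            )
        if status == _kernel.FULL:
            break
        if not disable_capture:
            myosin_update(state, params)
        if capture_time is None and state.link_on[:n_fil].any():
            capture_time = state.time
        record()
        if state.separation <= params.node_diameter:
            coalesced = True
            break
    counters = state.counters
    arrested_frac = float(counters[0] / counters[1]) if counters[1] > 0 else 0.0
    times_arr = np.asarray(times)
    tens_arr = np.asarray(tens)
    # taut onset: start of the final contiguous taut stretch (T <= 1.15).
    # Tension dips below the cut at capture before slack accumulates, so the
    # first crossing is not the coalescence phase; the last one is.
    taut_time = None
    taut = np.isfinite(tens_arr) & (tens_arr <= TAUT_TENSION_MAX)
    if taut.size and taut[-1]:
        not_taut = np.flatnonzero(~taut)
        first_idx = int(not_taut[-1]) + 1 if not_taut.size else int(np.argmax(taut))
        if np.isfinite(tens_arr[first_idx]):
            taut_time = float(times_arr[first_idx])
    result = SimResult(
        times=times_arr,
        node_positions=np.asarray(nodes),
        separation=np.asarray(seps),
        formin_force=np.asarray(ffs),
        motor_force=np.asarray(mfs),
        captured=np.asarray(caps, dtype=bool),
        tension=np.asarray(tens),
        capture_time=capture_time,
        taut_time=taut_time,
        coalescence_speed=None,
        arrested_fraction_of_time=arrested_frac,
        coalesced=coalesced,
        params=params,
        seed=seed,
    )
    result.coalescence_speed = coalescence_speed(result)
    return result


def _jackknife_sd_of_mean(values: np.ndarray) -> float:
    n = values.size
    if n < 2:
        return float("nan")
    total = values.sum()
    leave_one = (total - values) / (n - 1)
    return float(np.sqrt((n - 1) / n * np.sum((leave_one - leave_one.mean()) ** 2)))


def scan_motor_speed(
    params: SimParams,
    speeds: list[float],
    n_reps: int = 12,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Mean coalescence speed vs unloaded motor speed, jackknife s.d.

    Runs ``n_reps`` seeds per speed; only runs with a capture event and a
    long-enough post-capture record contribute.  Columns: ``v_myo0``,
    ``mean_coalescence``, ``jackknife_sd``, ``n_captured``, ``n_runs``.
    """
    if len(speeds) < 1:
        raise ValueError("need at least one motor speed")
    if n_reps < 2:
        raise ValueError("need at least 2 replicates")
    rows = []
    for si, v0 in enumerate(speeds):
        p = replace(params, v_myo0=float(v0))
        vals = []
        for rep in range(n_reps):
            seed = (base_seed + 7919 * si + rep) % 2**31
            res = run(p, seed)
            if res.coalescence_speed is not None:
                vals.append(res.coalescence_speed)
        vals = np.asarray(vals)
        rows.append(
            {
                "v_myo0": v0,
                "mean_coalescence": float(vals.mean()) if vals.size else float("nan"),
                "jackknife_sd": _jackknife_sd_of_mean(vals) if vals.size >= 2 else float("nan"),
                "n_captured": int(vals.size),
                "n_runs": n_reps,
            }
        )
    return pd.DataFrame(rows)


def speed_for_target_coalescence(scan: pd.DataFrame, target: float) -> float | None:
    """Unloaded motor speed at which the mean coalescence speed crosses ``target``.

    Linear interpolation on the scan table (sorted by v_myo0); None if the
    scan never reaches the target.
    """
    df = scan.dropna(subset=["mean_coalescence"]).sort_values("v_myo0")
    v = df["v_myo0"].to_numpy(dtype=float)
    c = df["mean_coalescence"].to_numpy(dtype=float)
    if v.size == 0 or c.max() < target:
        return None
    if c[0] >= target:
        return float(v[0])
    idx = int(np.argmax(c >= target))
    v0, v1, c0, c1 = v[idx - 1], v[idx], c[idx - 1], c[idx]
    if c1 == c0:
        return float(v1)
    return float(v0 + (target - c0) * (v1 - v0) / (c1 - c0))


# ---------------------------------------------------------------------------
# equilibrium-polymer diagnostics


def tangent_correlation(states: list[SimState], filament: int = 0, skip: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble tangent–tangent correlation <t(s)·t(s+Δs)> vs contour offset.

    Skips the first ``skip`` segments (influenced by the node tether and
    restoring torque).  Returns (offsets in segments, correlation).
    """
    n_min = min(int(s.n_particles[filament]) for s in states)
    tangents = []
    for s in states:
        p = s.pos[filament, :n_min]
        t = np.diff(p, axis=0)
        t /= np.linalg.norm(t, axis=1, keepdims=True)
        tangents.append(t[skip:])
    tangents = np.asarray(tangents)  # (n_states, n_seg, 2)
    n_seg = tangents.shape[1]
    max_off = n_seg - 1
    offsets = np.arange(max_off + 1)
    corr = np.empty(offsets.size)
    for k in offsets:
        dots = np.sum(tangents[:, : n_seg - k] * tangents[:, k:], axis=2)
        corr[k] = dots.mean()
    return offsets, corr


def fit_persistence_length_2d(
    offsets: np.ndarray, corr: np.ndarray, l0: float, max_offset: int | None = None
) -> float:
    """Persistence length from a 2D tangent-correlation decay.

    In two dimensions <t(0)·t(s)> = exp(−s/(2 Lp)); the fitted decay length
    is therefore halved to report the conventional (3D-defined) Lp.
    """
    if max_offset is None:
        max_offset = offsets.max()
    mask = (offsets >= 1) & (offsets <= max_offset) & (corr > 0)
    s = offsets[mask] * l0
    y = np.log(corr[mask])
    slope = float(np.dot(s, y) / np.dot(s, s))  # through-origin: ln C(0) = 0
    decay_length = -1.0 / slope
    return decay_length / 2.0
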