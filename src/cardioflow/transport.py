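"""Lagrangian gas-tracer transport through the airway network.

Massless tracers carry a gas-type label (Type A = resident gas, Type B =
fresh gas entering at the trachea) and live in cylindrical coordinates
(z along the conduit axis, r, theta) inside their containing conduit.  Per
time step the model applies, in order:

1. advection along the axis with a quasi-steady Poiseuille profile,
   u(r, z, t) = 2 * Q(t)/A(z) * (1 - (r/R(z))^2), integrated with RK4 on
   linearly time-interpolated flows (r and theta are untouched by advection;
   in trumpet sections the relative radius r/R is held while R(z) changes);
2. stochastic routing at bifurcations crossed during the step, with
   probability proportional to the candidate airways' outgoing flow and the
   relative radius preserved;
3. trachea boundary bookkeeping: the time-integrated inflow volume,
   expressed in tracer quanta, injects its integer part as Type B tracers
   (the fractional remainder is conserved, and turns negative during
   expiration); tracers advected out of the opening are removed;
4. acinar-compartment exchange: tracers reaching a trumpet's distal end join
   a well-mixed tally; accumulated outflux volume releases tracers whose
   types are drawn in proportion to the tallies;
5. random-walk molecular diffusion (see ``_kernels``), sub-stepped 100x by
   default; a tracer diffusing out of the trachea opening is exchanged
   one-for-one with a fresh Type B tracer from the atmosphere reservoir, so
   a zero-flow lung still washes out by diffusion.

Units: mm, ms, mm^3; flows in mm^3/ms (= ml/s); D in cm^2/s externally,
converted internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._kernels import diffuse_kernel
from .airflow import FlowSeries
from .geometry import CYLINDER, TRUMPET, TransportGeometry

__all__ = ["TransportConfig", "TracerPopulation", "Simulation", "seed_tracers"]

TYPE_A = 0
TYPE_B = 1


@dataclass
class TransportConfig:
    """Simulation parameters.

    ``D_cm2_s`` defaults to 0.23 cm^2/s, the self-diffusivity of nitrogen at
    body temperature.  ``dt_ms=None`` picks a tenth of the shortest conduit
    transit time at peak flow.  ``quantum_ml`` is the gas volume represented
    by one tracer; if None it is set so seeding produces ``n_tracers``.
    """

    D_cm2_s: float = 0.23
    dt_ms: float | None = None
    sub_steps: int = 100
    quantum_ml: float | None = None
    n_tracers: int = 10000
    seed: int = 0
    wall_retry: int = 20
    max_route_iters: int = 8

    def __post_init__(self) -> None:
        if self.D_cm2_s < 0:
            raise ValueError("D must be >= 0")
        if self.dt_ms is not None and self.dt_ms <= 0:
            raise ValueError("dt must be > 0")
        if self.sub_steps < 1:
            raise ValueError("sub_steps must be >= 1")

    @property
    def D_mm2_ms(self) -> float:
        return self.D_cm2_s * 100.0 / 1000.0


@dataclass
class TracerPopulation:
    """Flat arrays of in-airway tracers (compartment tracers live in tallies)."""

    conduit: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int32))
    z: np.ndarray = field(default_factory=lambda: np.zeros(0))
    r: np.ndarray = field(default_factory=lambda: np.zeros(0))
    theta: np.ndarray = field(default_factory=lambda: np.zeros(0))
    gas_type: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int8))

    @property
    def n(self) -> int:
        return len(self.conduit)

    def append(self, conduit, z, r, theta, gas_type) -> None:
        self.conduit = np.concatenate([self.conduit, np.asarray(conduit, np.int32)])
        self.z = np.concatenate([self.z, np.asarray(z, float)])
        self.r = np.concatenate([self.r, np.asarray(r, float)])
        self.theta = np.concatenate([self.theta, np.asarray(theta, float)])
        self.gas_type = np.concatenate([self.gas_type, np.asarray(gas_type, np.int8)])

    def keep(self, mask: np.ndarray) -> None:
        self.conduit = self.conduit[mask]
        self.z = self.z[mask]
        self.r = self.r[mask]
        self.theta = self.theta[mask]
        self.gas_type = self.gas_type[mask]


def seed_tracers(
    geometry: TransportGeometry, quantum_mm3: float, seed: int = 0
) -> tuple[TracerPopulation, np.ndarray]:
    """Seed tracers at uniform density: count = round(volume/quantum) per
    element, positions uniform over each conduit's gas volume (z weighted by
    local area, r sampled proportional to sqrt(uniform) so the cross-section
    is covered uniformly).  All seeded tracers are Type A.

    Returns the in-airway population and the per-compartment Type A tallies.
    """
    if quantum_mm3 <= 0:
        raise ValueError("tracer volume quantum must be > 0")
    rng = np.random.default_rng(seed)
    vols = geometry.conduit_volumes
    smallest = min(
        vols.min() if len(vols) else np.inf,
        geometry.comp_volume.min() if geometry.n_compartments else np.inf,
    )
    if quantum_mm3 > smallest:
        warnings.warn(
            "tracer quantum exceeds the smallest element volume; some elements "
            "will be seeded with zero tracers",
            stacklevel=2,
        )
    pop = TracerPopulation()
    for i in range(geometry.n_conduits):
        n_i = int(round(vols[i] / quantum_mm3))
        if n_i == 0:
            continue
        zz = geometry.sample_axial(i, n_i, rng)
        rr = geometry.radius_at(np.full(n_i, i), zz) * np.sqrt(rng.uniform(0, 1, n_i))
        pop.append(
            np.full(n_i, i, dtype=np.int32),
            zz,
            rr,
            rng.uniform(0, 2 * np.pi, n_i),
            np.zeros(n_i, dtype=np.int8),
        )
    tally_a = np.array(
        [int(round(v / quantum_mm3)) for v in geometry.comp_volume], dtype=np.int64
    )
    return pop, tally_a


class Simulation:
    """Drives tracer transport over a TransportGeometry under a FlowSeries.

    ``flows=None`` means zero flow everywhere (diffusion-only state).  All
    randomness comes from one seeded generator; the diffusion kernel reseeds
    deterministically per step from the same master seed.
    """

    def __init__(
        self,
        geometry: TransportGeometry,
        flows: FlowSeries | None = None,
        config: TransportConfig | None = None,
    ):
        self.geometry = geometry
        self.config = config if config is not None else TransportConfig()
        self.rng = np.random.default_rng(self.config.seed)
        self.flows = flows
        self._build_flow_table()

        if self.config.quantum_ml is not None:
            self.quantum = self.config.quantum_ml * 1000.0
        else:
            self.quantum = geometry.total_volume / self.config.n_tracers
        self.dt = self.config.dt_ms if self.config.dt_ms is not None else self._auto_dt()

        self._trumpet_of_comp = np.full(geometry.n_compartments, -1, dtype=np.int32)
        for ci in range(geometry.n_conduits):
            if geometry.compartment[ci] >= 0:
                self._trumpet_of_comp[geometry.compartment[ci]] = ci

        self.pop = TracerPopulation()
        self.tally_a = np.zeros(geometry.n_compartments, dtype=np.int64)
        self.tally_b = np.zeros(geometry.n_compartments, dtype=np.int64)
        self.comp_acc = np.zeros(geometry.n_compartments)
        self.trachea_acc = 0.0
        self.t = 0.0
        self.step_count = 0

        self.n_seeded = 0
        self.n_injected = 0           # advective Type B at the trachea
        self.n_exchanged = 0          # diffusive one-for-one reservoir exchange
        self.n_expired = np.zeros(2, dtype=np.int64)   # by gas type
        self.events = {
            "routing_holds": 0,
            "empty_compartment_releases": 0,
            "forfeited_substeps": 0,
        }

    # -- flows ---------------------------------------------------------------

    def _build_flow_table(self) -> None:
        geo = self.geometry
        if self.flows is None:
            self._qmat = None
            return
        qmat = np.zeros((geo.n_conduits, len(self.flows.times)))
        for i in range(geo.n_conduits):
            aid = geo.airway_id[i]
            if aid < 0:  # trumpet: carries its terminal airway's flow
                aid = geo.airway_id[geo.parent[i]]
            qmat[i] = self.flows.flows[int(aid)]
        times = self.flows.times
        self._period = self.flows.period_ms
        if self._period is not None:
            self._ft = np.concatenate([times, [times[0] + self._period]])
            self._qt = np.concatenate([qmat, qmat[:, :1]], axis=1)
        else:
            self._ft = times
            self._qt = qmat
        self._qmat = qmat

    def _q_at(self, t: float) -> np.ndarray:
        """Per-conduit flow at time t (linear interpolation, periodic wrap)."""
        if self._qmat is None:
            return np.zeros(self.geometry.n_conduits)
        ft = self._ft
        if self._period is not None:
            t = (t - ft[0]) % self._period + ft[0]
        t = min(max(t, ft[0]), ft[-1])
        j = int(np.searchsorted(ft, t, side="right") - 1)
        j = min(max(j, 0), len(ft) - 2)
        w = (t - ft[j]) / (ft[j + 1] - ft[j])
        return self._qt[:, j] * (1 - w) + self._qt[:, j + 1] * w

    def _auto_dt(self) -> float:
        if self._qmat is None:
            return 1.0
        qmax = np.abs(self._qmat).max(axis=1)
        u = 2.0 * qmax / self.geometry.base_area
        with np.errstate(divide="ignore"):
            transit = np.where(u > 0, self.geometry.length / u, np.inf)
        tmin = transit.min()
        return 1.0 if not np.isfinite(tmin) else max(tmin / 10.0, 1e-3)

    # -- setup ---------------------------------------------------------------

    def seed_tracers(self) -> None:
        self.pop, self.tally_a = seed_tracers(
            self.geometry, self.quantum, int(self.rng.integers(2**31))
        )
        self.tally_b = np.zeros_like(self.tally_a)
        self.n_seeded = self.pop.n + int(self.tally_a.sum())

    # -- per-step physics ----------------------------------------------------

    def _advect(self, dt: float) -> None:
        pop = self.pop
        if self._qmat is None or pop.n == 0:
            return
        geo = self.geometry
        q1 = self._q_at(self.t)
        qm = self._q_at(self.t + dt / 2)
        q3 = self._q_at(self.t + dt)
        c = pop.conduit
        lc = geo.length[c]
        r_wall = geo.radius_at(c, np.clip(pop.z, 0, lc))
        rho = np.minimum(pop.r / r_wall, 1.0)
        fac = 2.0 * (1.0 - rho**2)

        def u(qvec, zz):
            a = geo.area_at(c, np.clip(zz, 0, lc))
            return fac * qvec[c] / a

        k1 = dt * u(q1, pop.z)
        k2 = dt * u(qm, pop.z + k1 / 2)
        k3 = dt * u(qm, pop.z + k2 / 2)
        k4 = dt * u(q3, pop.z + k3)
        pop.z = pop.z + (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
        self._route_crossers(qm, dt, rho)
        # relative radius is preserved while the wall radius changes (trumpets)
        lc = geo.length[pop.conduit]
        pop.z = np.clip(pop.z, 0.0, lc)

    def _route_crossers(self, qmid: np.ndarray, dt: float, rho: np.ndarray) -> None:
        """Resolve tracers whose RK4 step crossed a conduit end.

        Candidate airways are weighted by outgoing flow; the remaining step
        time (overshoot distance over exit speed) is spent in the new airway
        at its own Poiseuille speed.  If no candidate carries flow away from
        the junction the tracer is held at the junction for the rest of the
        step.  Theta is redrawn on routing; r/R is preserved.
        """
        pop = self.pop
        geo = self.geometry
        out = np.flatnonzero((pop.z < 0) | (pop.z > geo.length[pop.conduit]))
        if len(out) == 0:
            return
        expired = []
        absorbed = []
        tiny = 1e-12
        for i in out:
            c = int(pop.conduit[i])
            zz = float(pop.z[i])
            rho_i = float(rho[i])
            fac = 2.0 * (1.0 - rho_i**2)
            routed = False
            for _ in range(self.config.max_route_iters):
                ll = geo.length[c]
                if 0.0 <= zz <= ll:
                    break
                if zz < 0.0:
                    p = int(geo.parent[c])
                    if p < 0:
                        expired.append(i)
                        zz = 0.0
                        break
                    sib = int(geo.child2[p]) if geo.child1[p] == c else int(geo.child1[p])
                    if sib < 0:
                        zz = geo.length[p] + zz
                        c = p
                        continue
                    over = -zz
                    u_old = abs(fac * qmid[c] / geo.base_area[c])
                    tau = min(over / max(u_old, tiny), dt)
                    w_p = max(-qmid[p], 0.0)
                    w_s = max(qmid[sib], 0.0)
                    if w_p + w_s <= 0.0:
                        self.events["routing_holds"] += 1
                        zz = 0.0
                        break
                    routed = True
                    if self.rng.uniform(0, w_p + w_s) < w_p:
                        u_new = abs(
                            fac * qmid[p] / float(geo.area_at(p, geo.length[p])[0])
                        )
                        c = p
                        zz = geo.length[p] - u_new * tau
                    else:
                        u_new = abs(fac * qmid[sib] / float(geo.area_at(sib, 0.0)[0]))
                        c = sib
                        zz = u_new * tau
                else:
                    c1 = int(geo.child1[c])
                    if c1 < 0:
                        if geo.kind[c] == TRUMPET:
                            absorbed.append(i)
                            pop.conduit[i] = c
                            zz = ll
                            break
                        zz = ll  # sealed end
                        break
                    if geo.child2[c] < 0:
                        zz = zz - ll
                        c = c1
                        continue
                    c2 = int(geo.child2[c])
                    over = zz - ll
                    u_old = abs(fac * qmid[c] / float(geo.area_at(c, ll)[0]))
                    tau = min(over / max(u_old, tiny), dt)
                    w1 = max(qmid[c1], 0.0)
                    w2 = max(qmid[c2], 0.0)
                    if w1 + w2 <= 0.0:
                        self.events["routing_holds"] += 1
                        zz = ll
                        break
                    routed = True
                    if self.rng.uniform(0, w1 + w2) < w1:
                        chosen = c1
                    else:
                        chosen = c2
                    u_new = abs(fac * qmid[chosen] / float(geo.area_at(chosen, 0.0)[0]))
                    c = chosen
                    zz = u_new * tau
            ll = geo.length[c]
            pop.conduit[i] = c
            pop.z[i] = min(max(zz, 0.0), ll)
            pop.r[i] = rho_i * float(geo.radius_at(c, pop.z[i])[0])
            if routed:
                pop.theta[i] = self.rng.uniform(0, 2 * np.pi)
        self._finalise_exits(expired, absorbed)

    def _finalise_exits(self, expired: list[int], absorbed: list[int]) -> None:
        pop = self.pop
        geo = self.geometry
        for i in absorbed:
            comp = int(geo.compartment[pop.conduit[i]])
            if pop.gas_type[i] == TYPE_A:
                self.tally_a[comp] += 1
            else:
                self.tally_b[comp] += 1
        for i in expired:
            self.n_expired[pop.gas_type[i]] += 1
        drop = np.zeros(pop.n, dtype=bool)
        drop[expired] = True
        drop[absorbed] = True
        if drop.any():
            pop.keep(~drop)

    def _inject_at_trachea(self, n: int, gas_type: int) -> None:
        root = self.geometry.root_index
        r_root = float(self.geometry.radius_at(root, 0.0)[0])
        self.pop.append(
            np.full(n, root, dtype=np.int32),
            np.zeros(n),
            r_root * np.sqrt(self.rng.uniform(0, 1, n)),
            self.rng.uniform(0, 2 * np.pi, n),
            np.full(n, gas_type, dtype=np.int8),
        )

    def _trachea_update(self, dt: float) -> None:
        # Only inspiratory (positive) inflow accumulates: inspired gas is
        # fresh from the ventilator circuit, while expired gas is carried
        # away and never re-inhaled.  Expiratory outflow removes tracers
        # physically as they cross the opening, so subtracting it from the
        # accumulator as well would double-count and starve injection.
        if self._qmat is not None:
            root = self.geometry.root_index
            q0 = self._q_at(self.t)[root]
            q1 = self._q_at(self.t + dt)[root]
            inflow = dt * (q0 + q1) / 2.0
            if inflow > 0:
                self.trachea_acc += inflow / self.quantum
        n = int(np.floor(self.trachea_acc))
        if n >= 1:
            self._inject_at_trachea(n, TYPE_B)
            self.trachea_acc -= n
            self.n_injected += n

    def _compartment_exchange(self, dt: float) -> None:
        geo = self.geometry
        if geo.n_compartments == 0 or self._qmat is None:
            return
        q0 = self._q_at(self.t)
        q1 = self._q_at(self.t + dt)
        for i in range(geo.n_conduits):
            comp = int(geo.compartment[i])
            if comp < 0:
                continue
            outflux = -dt * (q0[i] + q1[i]) / 2.0  # volume from compartment into airway
            if outflux > 0:
                self.comp_acc[comp] += outflux / self.quantum
            n = int(np.floor(self.comp_acc[comp]))
            if n < 1:
                continue
            total = int(self.tally_a[comp] + self.tally_b[comp])
            n_rel = min(n, total)
            if n_rel < n:
                self.events["empty_compartment_releases"] += 1
            self.comp_acc[comp] -= n
            if n_rel == 0:
                continue
            k_a = int(
                self.rng.hypergeometric(self.tally_a[comp], self.tally_b[comp], n_rel)
            ) if total > 0 else 0
            self.tally_a[comp] -= k_a
            self.tally_b[comp] -= n_rel - k_a
            ll = geo.length[i]
            r_end = float(geo.radius_at(i, ll)[0])
            types = np.concatenate(
                [np.zeros(k_a, dtype=np.int8), np.ones(n_rel - k_a, dtype=np.int8)]
            )
            self.rng.shuffle(types)
            self.pop.append(
                np.full(n_rel, i, dtype=np.int32),
                np.full(n_rel, ll),
                r_end * np.sqrt(self.rng.uniform(0, 1, n_rel)),
                self.rng.uniform(0, 2 * np.pi, n_rel),
                types,
            )

    def _diffuse(self, dt: float) -> None:
        cfg = self.config
        if cfg.D_mm2_ms == 0 or self.pop.n == 0:
            return
        geo = self.geometry
        tau = dt / cfg.sub_steps
        sigma = float(np.sqrt(6.0 * cfg.D_mm2_ms * tau))
        status = np.zeros(self.pop.n, dtype=np.int8)
        kernel_seed = int((cfg.seed * 1000003 + self.step_count * 7919 + 1) % (2**31))
        ell = np.abs(
            sigma
            * np.random.default_rng(kernel_seed + 2**31).standard_normal(
                self.pop.n * cfg.sub_steps
            )
        )
        n_forfeit = diffuse_kernel(
            self.pop.conduit,
            self.pop.z,
            self.pop.r,
            self.pop.theta,
            status,
            geo.kind,
            geo.length,
            geo.base_area,
            geo.parent,
            geo.child1,
            geo.child2,
            geo.prof_z,
            geo.prof_arel,
            ell,
            cfg.sub_steps,
            cfg.wall_retry,
            kernel_seed,
        )
        self.events["forfeited_substeps"] += int(n_forfeit)
        expired = list(np.flatnonzero(status == 1))
        absorbed = list(np.flatnonzero(status == 2))
        n_exchange = len(expired)
        comp_release = [int(geo.compartment[self.pop.conduit[i]]) for i in absorbed]
        self._finalise_exits(expired, absorbed)
        if n_exchange:
            # one-for-one exchange with the fresh-gas reservoir at the opening
            self._inject_at_trachea(n_exchange, TYPE_B)
            self.n_exchanged += n_exchange
        # Diffusive crossings into a compartment carry no net volume, so each
        # one exchanges one-for-one with the well-mixed tally: the newcomer
        # joins the tally and a tracer sampled from the (updated) tally is
        # released at the compartment mouth.  A one-way tally would act as a
        # ratchet that pumps tracers into the acini and breaks the uniform
        # tracer density the volume bookkeeping relies on.
        if comp_release:
            rel_conduit, rel_z, rel_r, rel_type = [], [], [], []
            for comp, n_ev in zip(*np.unique(comp_release, return_counts=True)):
                total = int(self.tally_a[comp] + self.tally_b[comp])
                n_rel = min(int(n_ev), total)
                if n_rel == 0:
                    continue
                trumpet = int(self._trumpet_of_comp[comp])
                k_a = int(
                    self.rng.hypergeometric(
                        self.tally_a[comp], self.tally_b[comp], n_rel
                    )
                )
                self.tally_a[comp] -= k_a
                self.tally_b[comp] -= n_rel - k_a
                ll = geo.length[trumpet]
                r_end = float(geo.radius_at(trumpet, ll)[0])
                types = np.concatenate(
                    [np.zeros(k_a, dtype=np.int8), np.ones(n_rel - k_a, dtype=np.int8)]
                )
                self.rng.shuffle(types)
                rel_conduit.append(np.full(n_rel, trumpet, dtype=np.int32))
                rel_z.append(np.full(n_rel, ll))
                rel_r.append(r_end * np.sqrt(self.rng.uniform(0, 1, n_rel)))
                rel_type.append(types)
            if rel_conduit:
                n_tot = sum(len(a) for a in rel_conduit)
                self.pop.append(
                    np.concatenate(rel_conduit),
                    np.concatenate(rel_z),
                    np.concatenate(rel_r),
                    self.rng.uniform(0, 2 * np.pi, n_tot),
                    np.concatenate(rel_type),
                )

    # -- driving -------------------------------------------------------------

    def step(self) -> None:
        dt = self.dt
        self._advect(dt)
        self._trachea_update(dt)
        self._compartment_exchange(dt)
        self._diffuse(dt)
        self.t += dt
        self.step_count += 1

    def run_until(self, t_end: float) -> None:
        while self.t < t_end - 1e-9:
            self.step()

    # -- bookkeeping ---------------------------------------------------------

    @property
    def lung_counts(self) -> tuple[int, int]:
        """(Type A, Type B) tracers resident in the lung (airways + compartments)."""
        n_a = int(np.sum(self.pop.gas_type == TYPE_A) + self.tally_a.sum())
        n_b = int(np.sum(self.pop.gas_type == TYPE_B) + self.tally_b.sum())
        return n_a, n_b

    @property
    def fraction_a(self) -> float:
        n_a, n_b = self.lung_counts
        return n_a / (n_a + n_b) if (n_a + n_b) > 0 else np.nan

    def accounting_balance(self) -> int:
        """lung + expired - seeded - injected; 0 when tracer accounting is exact."""
        n_a, n_b = self.lung_counts
        return (
            n_a
            + n_b
            + int(self.n_expired.sum())
            - self.n_seeded
            - self.n_injected
            - self.n_exchanged
        )
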