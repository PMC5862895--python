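"""Numba kernels for the random-walk diffusion sub-stepping.

The random walk is the hot loop of the transport model (every tracer takes
``sub_steps`` sub-steps per time step), so it runs as a compiled kernel over
the flat geometry arrays.  Semantics:

- per sub-step of duration tau the tracer moves a distance |N(0, sigma)| with
  sigma^2 = 6*D*tau in a direction uniform on the sphere (so the simulated
  mean-squared displacement per sub-step is 6*D*tau, the 3D Einstein
  relation);
- a move whose endpoint would cross the airway wall is redrawn with a fresh
  random direction (same length), up to ``wall_retry`` times, after which the
  sub-step is forfeited;
- a move crossing an airway end at a bifurcation is routed to one of the
  three junction airways with probability proportional to cross-sectional
  area (the tracer may re-enter its own airway); 1-to-1 junctions
  (cylinder-to-trumpet) pass through;
- crossing the trachea opening marks the tracer expired (status 1); crossing
  a trumpet's distal end marks it absorbed into the acinar compartment
  (status 2); a sealed end (bare cylinder with no children) acts as a wall.

Radial containment is preserved by expressing the endpoint's radius relative
to the local wall radius and mapping that relative radius into the new
conduit when the tracer changes conduit.
"""

import numpy as np
from numba import njit

__all__ = ["diffuse_kernel"]


@njit(cache=True)
def _profile(zz, prof_z, prof_arel):
    m = prof_z.shape[0]
    if m == 0:
        return 1.0
    if zz <= prof_z[0]:
        return prof_arel[0]
    if zz >= prof_z[m - 1]:
        return prof_arel[m - 1]
    for j in range(1, m):
        if zz <= prof_z[j]:
            f = (zz - prof_z[j - 1]) / (prof_z[j] - prof_z[j - 1])
            return prof_arel[j - 1] * (1.0 - f) + f * prof_arel[j]
    return prof_arel[m - 1]


@njit(cache=True)
def _area(c, zz, kind, base_area, prof_z, prof_arel):
    if kind[c] == 1:
        return base_area[c] * _profile(zz, prof_z, prof_arel)
    return base_area[c]


@njit(cache=True)
def _radius(c, zz, kind, base_area, prof_z, prof_arel):
    return np.sqrt(_area(c, zz, kind, base_area, prof_z, prof_arel) / np.pi)


@njit(cache=True)
def diffuse_kernel(
    conduit,
    z,
    r,
    theta,
    status,
    kind,
    length,
    base_area,
    parent,
    child1,
    child2,
    prof_z,
    prof_arel,
    ell_arr,
    n_sub,
    wall_retry,
    seed,
):
    """Advance all active tracers by ``n_sub`` diffusion sub-steps in place.

    ``ell_arr`` holds the pre-drawn |N(0, sigma)| step lengths, one per
    (tracer, sub-step), laid out as ``ell_arr[i * n_sub + s]``; directions are
    drawn inside the kernel (uniform on the sphere) so wall-collision redraws
    can consume as many as they need.  ``status`` entries: 0 active, 1 expired
    through the trachea opening, 2 absorbed into the compartment at the end of
    its (final) conduit.  Returns the number of forfeited sub-steps.
    """
    np.random.seed(seed)
    n_forfeit = 0
    for i in range(conduit.shape[0]):
        if status[i] != 0:
            continue
        c = conduit[i]
        zi = z[i]
        x = r[i] * np.cos(theta[i])
        y = r[i] * np.sin(theta[i])
        dead = False
        for _s in range(n_sub):
            ell = ell_arr[i * n_sub + _s]
            ok = False
            for _attempt in range(wall_retry):
                # uniform direction on the sphere
                cz = 2.0 * np.random.random() - 1.0
                az = 2.0 * np.pi * np.random.random()
                sq = np.sqrt(max(0.0, 1.0 - cz * cz))
                dz = ell * cz
                xn = x + ell * sq * np.cos(az)
                yn = y + ell * sq * np.sin(az)
                zn = zi + dz
                rn = np.sqrt(xn * xn + yn * yn)
                cn = c
                state = 0  # 0 in-domain, 1 expired, 2 absorbed, 3 wall-like
                guard = 0
                while guard < 12:
                    ll = length[cn]
                    if zn < 0.0:
                        p = parent[cn]
                        if p < 0:
                            state = 1
                            break
                        sib = child2[p] if child1[p] == cn else child1[p]
                        if sib < 0:
                            zn = length[p] + zn
                            cn = p
                        else:
                            a_self = _area(cn, 0.0, kind, base_area, prof_z, prof_arel)
                            a_p = _area(p, length[p], kind, base_area, prof_z, prof_arel)
                            a_s = _area(sib, 0.0, kind, base_area, prof_z, prof_arel)
                            u = np.random.random() * (a_self + a_p + a_s)
                            if u < a_self:
                                zn = -zn
                            elif u < a_self + a_p:
                                cn = p
                                zn = length[p] + zn
                            else:
                                cn = sib
                                zn = -zn
                    elif zn > ll:
                        c1 = child1[cn]
                        if c1 < 0:
                            if kind[cn] == 1:
                                state = 2
                                break
                            state = 3  # sealed end: behaves like a wall
                            break
                        elif child2[cn] < 0:
                            zn = zn - ll
                            cn = c1
                        else:
                            c2 = child2[cn]
                            a_self = _area(cn, ll, kind, base_area, prof_z, prof_arel)
                            a_1 = _area(c1, 0.0, kind, base_area, prof_z, prof_arel)
                            a_2 = _area(c2, 0.0, kind, base_area, prof_z, prof_arel)
                            u = np.random.random() * (a_self + a_1 + a_2)
                            over = zn - ll
                            if u < a_self:
                                zn = ll - over
                            elif u < a_self + a_1:
                                cn = c1
                                zn = over
                            else:
                                cn = c2
                                zn = over
                    else:
                        break
                    guard += 1
                if guard >= 12 and state == 0:
                    state = 3
                if state == 1 or state == 2:
                    c = cn
                    zi = min(max(zn, 0.0), length[cn])
                    status[i] = state
                    dead = True
                    ok = True
                    break
                if state == 3:
                    continue
                # radial containment: relative radius in the starting conduit
                z_ref = min(max(zi + dz, 0.0), length[c])
                r_ref = _radius(c, z_ref, kind, base_area, prof_z, prof_arel)
                if rn > r_ref:
                    continue  # wall hit: redraw direction
                zn = min(max(zn, 0.0), length[cn])
                if cn != c:
                    # preserve relative radius across the junction
                    scale = (
                        _radius(cn, zn, kind, base_area, prof_z, prof_arel) / r_ref
                    )
                    xn *= scale
                    yn *= scale
                x = xn
                y = yn
                zi = zn
                c = cn
                ok = True
                break
            if not ok:
                n_forfeit += 1
            if dead:
                break
        conduit[i] = c
        z[i] = zi
        r[i] = np.sqrt(x * x + y * y)
        theta[i] = np.arctan2(y, x)
    return n_forfeit
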