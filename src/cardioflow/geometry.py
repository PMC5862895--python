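"""Transport geometry: cylinders, trumpet peripheral sections, compartments.

For gas transport the airway tree is simplified to straight cylinders (one
radius each).  Each terminal cylinder is extended with a trumpet section — a
quasi-1D duct whose total cross-sectional area A(z) grows toward the
periphery following a per-generation morphometry table — ending in a
well-mixed acinar compartment whose cross-sectional area and volume match
the table's deepest generation.

The geometry is stored as flat arrays (kind, length, parent, children,
radii, ...) so the advection and random-walk kernels can run over it without
object indirection.  All trumpets share one relative area profile; each is
scaled so its entrance area matches its terminal airway's cross-section,
keeping A(z) continuous at the junction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tree import AirwayTree

__all__ = [
    "TransportGeometry",
    "simplify_geometry",
    "attach_trumpet_model",
    "default_trumpet_table",
    "womersley_number",
]

CYLINDER = 0
TRUMPET = 1


def default_trumpet_table(
    first_generation: int = 14,
    last_generation: int = 23,
    entrance_diameter_um: float = 88.0,
    entrance_length_mm: float = 0.30,
    diameter_ratio: float = 0.85,
    length_ratio: float = 0.88,
) -> pd.DataFrame:
    """Representative mouse-like distal morphometry table (synthetic).

    Per generation g the table lists the total cross-sectional area of the
    subtree descending from one entrance airway and the generation's length.
    Airway count doubles per generation while diameters shrink by
    ``diameter_ratio``, so area grows by ``2 * diameter_ratio**2 ~ 1.45`` per
    generation (a monotone trumpet).  The values are a constructed,
    configurable stand-in with mouse-scale magnitudes, not a published
    morphometric dataset.
    """
    gens = np.arange(first_generation, last_generation + 1)
    k = gens - first_generation
    a0 = np.pi * (entrance_diameter_um / 2000.0) ** 2   # mm^2
    return pd.DataFrame(
        {
            "generation": gens,
            "area_mm2": a0 * (2.0 * diameter_ratio**2) ** k,
            "length_mm": entrance_length_mm * length_ratio**k,
        }
    )


@dataclass
class TransportGeometry:
    """Flat-array gas-transport domain.

    Conduits are indexed 0..n-1; ``kind`` distinguishes cylinders from
    trumpet sections.  ``child1``/``child2`` are -1 where absent; a terminal
    cylinder's single child is its trumpet, and a trumpet's distal end opens
    into compartment ``compartment[i]``.  ``base_area`` is the cross-section
    at z = 0; trumpets multiply it by the shared relative profile
    ``prof_arel(prof_z)`` (piecewise linear).
    """

    kind: np.ndarray
    length: np.ndarray
    base_area: np.ndarray
    parent: np.ndarray
    child1: np.ndarray
    child2: np.ndarray
    airway_id: np.ndarray
    generation: np.ndarray
    compartment: np.ndarray
    prof_z: np.ndarray = field(default_factory=lambda: np.zeros(0))
    prof_arel: np.ndarray = field(default_factory=lambda: np.zeros(0))
    comp_volume: np.ndarray = field(default_factory=lambda: np.zeros(0))
    comp_area: np.ndarray = field(default_factory=lambda: np.zeros(0))
    index_of_airway: dict[int, int] = field(default_factory=dict)

    # -- basic queries -------------------------------------------------------

    @property
    def n_conduits(self) -> int:
        return len(self.kind)

    @property
    def n_compartments(self) -> int:
        return len(self.comp_volume)

    @property
    def root_index(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    def area_at(self, conduit, z) -> np.ndarray:
        """Cross-sectional area A(z) in mm^2 (vectorised)."""
        conduit, z = np.broadcast_arrays(
            np.atleast_1d(np.asarray(conduit)),
            np.atleast_1d(np.asarray(z, dtype=float)),
        )
        a = self.base_area[conduit].astype(float).copy()
        tr = self.kind[conduit] == TRUMPET
        if np.any(tr):
            a[tr] = self.base_area[conduit[tr]] * np.interp(
                z[tr], self.prof_z, self.prof_arel
            )
        return a

    def radius_at(self, conduit, z) -> np.ndarray:
        return np.sqrt(self.area_at(conduit, z) / np.pi)

    def conduit_volume(self, i: int, n_quad: int = 200) -> float:
        if self.kind[i] == CYLINDER:
            return float(self.base_area[i] * self.length[i])
        zz = np.linspace(0.0, self.length[i], n_quad)
        aa = self.base_area[i] * np.interp(zz, self.prof_z, self.prof_arel)
        return float(np.trapezoid(aa, zz))

    @property
    def conduit_volumes(self) -> np.ndarray:
        return np.array([self.conduit_volume(i) for i in range(self.n_conduits)])

    @property
    def total_volume(self) -> float:
        """Gas volume of conduits plus compartments, mm^3."""
        return float(self.conduit_volumes.sum() + self.comp_volume.sum())

    def sample_axial(self, i: int, n: int, rng: np.random.Generator) -> np.ndarray:
        """Axial positions distributed proportionally to local area."""
        if self.kind[i] == CYLINDER:
            return rng.uniform(0.0, self.length[i], n)
        zz = np.linspace(0.0, self.length[i], 512)
        aa = self.base_area[i] * np.interp(zz, self.prof_z, self.prof_arel)
        cdf = np.concatenate([[0.0], np.cumsum((aa[1:] + aa[:-1]) / 2 * np.diff(zz))])
        cdf /= cdf[-1]
        return np.interp(rng.uniform(0, 1, n), cdf, zz)


def simplify_geometry(tree: AirwayTree) -> TransportGeometry:
    """Straight-cylinder representation of the tree, connectivity preserved.

    Conduits are ordered by airway id; volumes equal sum(pi r^2 L).
    Zero-length segments are rejected (the tree container already enforces
    positive lengths, this guards trees built by other means).
    """
    ids = sorted(tree.segments)
    index = {aid: k for k, aid in enumerate(ids)}
    n = len(ids)
    geo = TransportGeometry(
        kind=np.zeros(n, dtype=np.int8),
        length=np.zeros(n),
        base_area=np.zeros(n),
        parent=np.full(n, -1, dtype=np.int32),
        child1=np.full(n, -1, dtype=np.int32),
        child2=np.full(n, -1, dtype=np.int32),
        airway_id=np.array(ids, dtype=np.int32),
        generation=np.zeros(n, dtype=np.int32),
        compartment=np.full(n, -1, dtype=np.int32),
        index_of_airway=index,
    )
    for aid in ids:
        s = tree[aid]
        k = index[aid]
        if s.length <= 0:
            raise ValueError(f"airway {aid}: zero-length segment")
        geo.length[k] = s.length
        geo.base_area[k] = s.area
        geo.generation[k] = s.generation
        if s.parent_id is not None:
            geo.parent[k] = index[s.parent_id]
        if s.child_ids:
            c = sorted(s.child_ids)
            geo.child1[k] = index[c[0]]
            geo.child2[k] = index[c[1]]
    return geo


def attach_trumpet_model(
    geometry: TransportGeometry,
    model_table: pd.DataFrame | None = None,
    first_generation: int = 14,
    last_generation: int = 23,
    compartment_volume_scale: float = 1.0,
) -> TransportGeometry:
    """Append a trumpet section and an acinar compartment to every terminal.

    ``model_table`` must list ``generation``, ``area_mm2`` and ``length_mm``
    covering generations ``first_generation..last_generation``.  Each
    terminal's trumpet uses the table's relative area growth, scaled so its
    entrance matches the terminal cylinder's cross-section; its length is the
    summed generation lengths beyond the entrance generation.  The
    compartment takes the deepest generation's (scaled) area and volume,
    optionally multiplied by ``compartment_volume_scale`` — scaled-down
    synthetic trees need a larger compartment share to keep the distal gas
    fraction realistic.
    """
    table = model_table if model_table is not None else default_trumpet_table()
    gens = set(int(g) for g in table["generation"])
    need = set(range(first_generation, last_generation + 1))
    if not need <= gens:
        raise ValueError(
            f"model table must cover generations {first_generation}..{last_generation}"
        )
    table = (
        table[table.generation.isin(need)].sort_values("generation").reset_index(drop=True)
    )
    areas = table.area_mm2.to_numpy(float)
    lengths = table.length_mm.to_numpy(float)
    if np.any(areas <= 0) or np.any(lengths <= 0):
        raise ValueError("model table areas and lengths must be positive")
    if np.any(np.diff(areas) < 0):
        raise ValueError("trumpet area must be non-decreasing toward the periphery")

    # shared relative profile: entrance generation at z=0, then cumulative lengths
    prof_z = np.concatenate([[0.0], np.cumsum(lengths[1:])])
    prof_arel = areas / areas[0]
    trumpet_len = prof_z[-1]

    terminals = [
        i
        for i in range(geometry.n_conduits)
        if geometry.kind[i] == CYLINDER and geometry.child1[i] < 0
    ]
    n0 = geometry.n_conduits
    n_t = len(terminals)

    def ext(arr, fill, dtype=None):
        add = np.full(n_t, fill, dtype=arr.dtype if dtype is None else dtype)
        return np.concatenate([arr, add])

    geo = TransportGeometry(
        kind=ext(geometry.kind, TRUMPET),
        length=ext(geometry.length, trumpet_len),
        base_area=ext(geometry.base_area, 0.0),
        parent=ext(geometry.parent, -1),
        child1=ext(geometry.child1, -1),
        child2=ext(geometry.child2, -1),
        airway_id=ext(geometry.airway_id, -1),
        generation=ext(geometry.generation, 0),
        compartment=ext(geometry.compartment, -1),
        prof_z=prof_z,
        prof_arel=prof_arel,
        comp_volume=np.zeros(n_t),
        comp_area=np.zeros(n_t),
        index_of_airway=dict(geometry.index_of_airway),
    )
    for j, term in enumerate(terminals):
        k = n0 + j
        scale = geometry.base_area[term] / areas[0]
        geo.base_area[k] = geometry.base_area[term]
        geo.parent[k] = term
        geo.child1[k] = -1
        geo.generation[k] = geometry.generation[term] + 1
        geo.compartment[k] = j
        geo.child1[term] = k
        geo.comp_area[j] = areas[-1] * scale
        geo.comp_volume[j] = areas[-1] * lengths[-1] * scale * compartment_volume_scale
    return geo


def womersley_number(
    radius_mm: float, period_ms: float, kinematic_viscosity_mm2_ms: float = 0.015
) -> float:
    """alpha = R * sqrt(omega / nu); < 1 justifies the quasi-steady parabolic
    profile.  Default nu is air at body temperature (~15 mm^2/s)."""
    omega = 2 * np.pi / period_ms
    return float(radius_mm * np.sqrt(omega / kinematic_viscosity_mm2_ms))


def check_womersley(geometry: TransportGeometry, period_ms: float) -> float:
    """Warn if any conduit's Womersley number reaches 1; return the maximum."""
    radii = np.sqrt(geometry.base_area / np.pi)
    alpha = np.array([womersley_number(r, period_ms) for r in radii])
    worst = float(alpha.max())
    if worst >= 1.0:
        warnings.warn(
            f"maximum Womersley number {worst:.2f} >= 1: the parabolic profile "
            "assumption is questionable for this geometry/frequency",
            stacklevel=2,
        )
    return worst
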