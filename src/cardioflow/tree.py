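"""Airway-tree container: a rooted bifurcating network of cylindrical segments.

The tree is the substrate for flow propagation and gas transport.  Each
segment is a straight cylinder specified by its two end-points (mm) and a
single radius (mm); the trachea is generation 0 and every branching event
increments the generation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AirwaySegment", "AirwayTree"]


@dataclass
class AirwaySegment:
    """One straight cylindrical airway.

    Coordinates are in mm; ``proximal_point`` is the end nearer the trachea.
    """

    id: int
    parent_id: int | None
    child_ids: list[int]
    proximal_point: np.ndarray
    distal_point: np.ndarray
    radius: float
    generation: int

    def __post_init__(self) -> None:
        self.proximal_point = np.asarray(self.proximal_point, dtype=float)
        self.distal_point = np.asarray(self.distal_point, dtype=float)
        if self.radius <= 0:
            raise ValueError(f"airway {self.id}: radius must be > 0, got {self.radius}")
        if self.length <= 0:
            raise ValueError(f"airway {self.id}: segment length must be > 0")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.distal_point - self.proximal_point))

    @property
    def direction(self) -> np.ndarray:
        return (self.distal_point - self.proximal_point) / self.length

    @property
    def volume(self) -> float:
        """Cylinder volume in mm^3."""
        return float(np.pi * self.radius**2 * self.length)

    @property
    def area(self) -> float:
        """Cross-sectional area in mm^2."""
        return float(np.pi * self.radius**2)


@dataclass
class AirwayTree:
    """Rooted full-binary airway tree (every node has 0 or 2 children)."""

    segments: dict[int, AirwaySegment] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- structure -----------------------------------------------------------

    @property
    def root(self) -> AirwaySegment:
        roots = [s for s in self.segments.values() if s.parent_id is None]
        return roots[0]

    @property
    def terminal_ids(self) -> list[int]:
        """Ids of airways with a parent allowed but no daughters, sorted by id."""
        return sorted(i for i, s in self.segments.items() if not s.child_ids)

    @property
    def bifurcation_ids(self) -> list[int]:
        """Ids of parent airways at bifurcations (nodes with two children)."""
        return sorted(i for i, s in self.segments.items() if len(s.child_ids) == 2)

    def __len__(self) -> int:
        return len(self.segments)

    def __getitem__(self, airway_id: int) -> AirwaySegment:
        return self.segments[airway_id]

    def postorder(self) -> list[int]:
        """Ids in child-before-parent order (iterative; trees can be deep)."""
        order: list[int] = []
        stack = [self.root.id]
        while stack:
            i = stack.pop()
            order.append(i)
            stack.extend(self.segments[i].child_ids)
        order.reverse()
        return order

    def validate(self) -> None:
        roots = [s for s in self.segments.values() if s.parent_id is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        for s in self.segments.values():
            if len(s.child_ids) not in (0, 2):
                raise ValueError(f"airway {s.id}: children count must be 0 or 2")
            if s.parent_id is not None:
                parent = self.segments[s.parent_id]
                if s.generation != parent.generation + 1:
                    raise ValueError(
                        f"airway {s.id}: generation must be parent generation + 1"
                    )
                if s.id not in parent.child_ids:
                    raise ValueError(f"airway {s.id}: not registered with its parent")

    @property
    def total_volume(self) -> float:
        return sum(s.volume for s in self.segments.values())

    # -- i/o -----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in sorted(self.segments.values(), key=lambda s: s.id):
            rows.append(
                dict(
                    id=s.id,
                    parent_id=-1 if s.parent_id is None else s.parent_id,
                    x1=s.proximal_point[0],
                    y1=s.proximal_point[1],
                    z1=s.proximal_point[2],
                    x2=s.distal_point[0],
                    y2=s.distal_point[1],
                    z2=s.distal_point[2],
                    radius_mm=s.radius,
                    generation=s.generation,
                )
            )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AirwayTree":
        children: dict[int, list[int]] = {int(r.id): [] for r in df.itertuples()}
        for r in df.itertuples():
            if int(r.parent_id) >= 0:
                children[int(r.parent_id)].append(int(r.id))
        segments = {}
        for r in df.itertuples():
            i = int(r.id)
            segments[i] = AirwaySegment(
                id=i,
                parent_id=None if int(r.parent_id) < 0 else int(r.parent_id),
                child_ids=sorted(children[i]),
                proximal_point=np.array([r.x1, r.y1, r.z1]),
                distal_point=np.array([r.x2, r.y2, r.z2]),
                radius=float(r.radius_mm),
                generation=int(r.generation),
            )
        return cls(segments)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "AirwayTree":
        return cls.from_frame(pd.read_csv(path))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_frame().to_dict(orient="records"), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "AirwayTree":
        with open(path) as fh:
            return cls.from_frame(pd.DataFrame(json.load(fh)))
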