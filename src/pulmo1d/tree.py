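"""Rooted binary vascular trees of 1D vessel segments."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

logger = logging.getLogger(__name__)

__all__ = ["VesselSegment", "VascularTree"]

#: default reference wall thickness as a fraction of radius (control animals);
#: PH trees conventionally carry a thickened wall (see docs/methods.md)
DEFAULT_WALL_RATIO = 0.10


@dataclass(frozen=True)
class VesselSegment:
    """A straight vessel: single reference radius, no taper.

    Lengths and radii in cm; ``wall_ratio`` is h0/r0.  ``n_grid`` is the
    number of spatial cells the solver uses (None lets the solver choose
    from its target spacing; when set it must be >= 3).
    """

    id: str
    parent_id: str | None
    length: float
    radius: float
    wall_ratio: float = DEFAULT_WALL_RATIO
    n_grid: int | None = None

    def __post_init__(self) -> None:
        if not self.length > 0:
            raise ValueError(f"segment {self.id}: length must be > 0, got {self.length}")
        if not self.radius > 0:
            raise ValueError(f"segment {self.id}: radius must be > 0, got {self.radius}")
        if not 0 < self.wall_ratio < 1:
            raise ValueError(f"segment {self.id}: wall_ratio must be in (0,1), got {self.wall_ratio}")
        if self.n_grid is not None and self.n_grid < 3:
            raise ValueError(f"segment {self.id}: n_grid must be >= 3, got {self.n_grid}")


@dataclass(frozen=True)
class VascularTree:
    """Rooted, connected, acyclic tree in which every junction bifurcates.

    Junctions with more than two children in input files are binarized with
    epsilon-length connector segments (see ``binarize``).
    """

    segments: tuple[VesselSegment, ...]
    _index: dict = field(default_factory=dict, repr=False, compare=False)
    _children: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        index: dict[str, VesselSegment] = {}
        children: dict[str, list[str]] = {}
        roots = []
        for seg in self.segments:
            if seg.id in index:
                raise ValueError(f"duplicate segment id {seg.id!r}")
            index[seg.id] = seg
        for seg in self.segments:
            if seg.parent_id is None:
                roots.append(seg.id)
            else:
                if seg.parent_id not in index:
                    raise ValueError(f"segment {seg.id!r} references unknown parent {seg.parent_id!r}")
                children.setdefault(seg.parent_id, []).append(seg.id)
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        for pid, kids in children.items():
            if len(kids) != 2:
                raise ValueError(
                    f"junction at segment {pid!r} has {len(kids)} children; "
                    "every junction must bifurcate (use VascularTree.binarize)"
                )
        # connectivity + acyclicity: walk from the root
        seen = set()
        stack = [roots[0]]
        while stack:
            sid = stack.pop()
            if sid in seen:
                raise ValueError(f"cycle detected at segment {sid!r}")
            seen.add(sid)
            stack.extend(children.get(sid, []))
        if len(seen) != len(self.segments):
            raise ValueError("tree is not connected")
        object.__setattr__(self, "_index", index)
        object.__setattr__(self, "_children", children)

    # -- queries ---------------------------------------------------------

    @property
    def root_id(self) -> str:
        return next(s.id for s in self.segments if s.parent_id is None)

    @property
    def terminal_ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.segments if s.id not in self._children)

    def segment(self, sid: str) -> VesselSegment:
        try:
            return self._index[sid]
        except KeyError:
            raise KeyError(f"unknown segment id {sid!r}") from None

    def children(self, sid: str) -> tuple[str, ...]:
        return tuple(self._children.get(sid, ()))

    def generation(self, sid: str) -> int:
        """0 for the root, +1 per junction crossed."""
        g = 0
        seg = self.segment(sid)
        while seg.parent_id is not None:
            seg = self.segment(seg.parent_id)
            g += 1
        return g

    def topological_order(self) -> list[str]:
        """Root-first order; every parent precedes its children."""
        order, stack = [], [self.root_id]
        while stack:
            sid = stack.pop()
            order.append(sid)
            stack.extend(reversed(self.children(sid)))
        return order

    def with_segments(self, new_segments) -> "VascularTree":
        return VascularTree(tuple(new_segments))

    # -- construction helpers -------------------------------------------

    @classmethod
    def binarize(cls, segments, epsilon_ratio: float = 1e-3) -> "VascularTree":
        """Build a tree, inserting epsilon-length connectors at n-furcations.

        A junction with k > 2 children becomes a chain of k-1 bifurcations
        joined by connectors whose length is ``epsilon_ratio`` times the
        parent length and whose radius copies the parent.
        """
        segments = list(segments)
        children: dict[str, list[str]] = {}
        for seg in segments:
            if seg.parent_id is not None:
                children.setdefault(seg.parent_id, []).append(seg.id)
        out = {s.id: s for s in segments}
        for pid, kids in list(children.items()):
            if len(kids) <= 2:
                continue
            logger.info("binarizing %d-furcation at segment %s", len(kids), pid)
            parent = out[pid]
            attach = pid
            remaining = list(kids)
            k = 0
            while len(remaining) > 2:
                conn_id = f"{pid}__conn{k}"
                out[conn_id] = VesselSegment(
                    conn_id, attach, epsilon_ratio * parent.length, parent.radius,
                    parent.wall_ratio,
                )
                first = remaining.pop(0)
                out[first] = replace(out[first], parent_id=attach)
                attach = conn_id
                k += 1
            for kid in remaining:
                out[kid] = replace(out[kid], parent_id=attach)
        return cls(tuple(out.values()))
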