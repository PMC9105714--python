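"""Detection and characterization of MB pi-pi stacks.

An MB molecule's stacking geometry is reduced to three quantities derived
from its posed atoms: the least-squares plane of its ring atoms (centroid +
unit normal), and the long axis running from terminal nitrogen #1 to #2.
Two molecules are considered stacked when their planes are nearly parallel,
vertically separated by roughly one van-der-Waals contact distance, and not
laterally slipped past each other; stacks are the connected components of
the resulting contact graph.  The observed equilibrium inter-plane spacing
for MB stacks is about 3.7 A.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .trajectory import Trajectory

__all__ = [
    "MBPlane",
    "Stack",
    "StackRecord",
    "StackSummary",
    "fit_ring_plane",
    "mb_plane",
    "frame_planes",
    "interplane_distance",
    "classify_orientation",
    "is_stacked",
    "detect_stacks",
    "stack_statistics",
    "PARALLEL",
    "ANTIPARALLEL",
    "INDETERMINATE",
]

PARALLEL = "parallel"
ANTIPARALLEL = "antiparallel"
INDETERMINATE = "indeterminate"

#: default edge thresholds of the stacking graph
D_MAX = 4.5  # max inter-plane distance, Angstrom
ANGLE_MAX = 30.0  # max angle between ring normals, degrees (mod 180)
LATERAL_MAX = 3.0  # max in-plane centroid offset, Angstrom

_ORIENT_TOL = 1e-10


class DegenerateGeometryError(ValueError):
    """Raised when ring atoms do not define a plane."""


def fit_ring_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through >= 3 non-collinear points.

    Returns (centroid, unit normal).  The normal's sign is fixed
    deterministically: its largest-magnitude component is made positive,
    preferring the z component on near-ties.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise DegenerateGeometryError("need >= 3 points of shape (n, 3)")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise DegenerateGeometryError("points are collinear or coincident")
    normal = vt[2]
    for comp in (2, 0, 1):
        if abs(normal[comp]) > 1e-9:
            if normal[comp] < 0:
                normal = -normal
            break
    return centroid, normal


@dataclass(frozen=True)
class MBPlane:
    """Stacking-relevant geometry of one posed MB molecule."""

    mol_id: str
    centroid: np.ndarray
    normal: np.ndarray
    long_axis: np.ndarray  # unit vector terminal-N #1 -> terminal-N #2


def mb_plane(mol_id: str, ring_coords: np.ndarray, n_coords: np.ndarray) -> MBPlane:
    centroid, normal = fit_ring_plane(ring_coords)
    axis = np.asarray(n_coords[1], float) - np.asarray(n_coords[0], float)
    norm = np.linalg.norm(axis)
    if norm <= 0:
        raise DegenerateGeometryError(f"{mol_id}: coincident terminal nitrogens")
    return MBPlane(mol_id, centroid, normal, axis / norm)


def frame_planes(traj: Trajectory, frame: int) -> list[MBPlane]:
    return [
        mb_plane(m, traj.ring_coords(frame, m), traj.terminal_n_coords(frame, m))
        for m in traj.mb_ids
    ]


def interplane_distance(mb_a: MBPlane, mb_b: MBPlane) -> float:
    """Mean of the two unsigned centroid-to-plane distances (symmetric)."""
    d_ab = abs(float(np.dot(mb_b.centroid - mb_a.centroid, mb_a.normal)))
    d_ba = abs(float(np.dot(mb_a.centroid - mb_b.centroid, mb_b.normal)))
    return 0.5 * (d_ab + d_ba)


def classify_orientation(mb_a: MBPlane, mb_b: MBPlane) -> str:
    """Relative long-axis orientation of two MB molecules.

    Sign of the dot product of the long-axis unit vectors; an exactly
    perpendicular pair is flagged indeterminate.
    """
    dot = float(np.dot(mb_a.long_axis, mb_b.long_axis))
    if abs(dot) <= _ORIENT_TOL:
        return INDETERMINATE
    return PARALLEL if dot > 0 else ANTIPARALLEL


def _normal_angle_deg(mb_a: MBPlane, mb_b: MBPlane) -> float:
    # angle modulo 180: ring normals have no physical sign
    c = min(1.0, abs(float(np.dot(mb_a.normal, mb_b.normal))))
    return float(np.degrees(np.arccos(c)))


def _lateral_offset(mb_a: MBPlane, mb_b: MBPlane) -> float:
    d = mb_b.centroid - mb_a.centroid
    la = np.linalg.norm(d - np.dot(d, mb_a.normal) * mb_a.normal)
    lb = np.linalg.norm(d - np.dot(d, mb_b.normal) * mb_b.normal)
    return float(max(la, lb))


def is_stacked(
    mb_a: MBPlane,
    mb_b: MBPlane,
    d_max: float = D_MAX,
    angle_max: float = ANGLE_MAX,
    lateral_max: float = LATERAL_MAX,
) -> bool:
    """Edge criterion of the stacking graph."""
    return (
        interplane_distance(mb_a, mb_b) <= d_max
        and _normal_angle_deg(mb_a, mb_b) <= angle_max
        and _lateral_offset(mb_a, mb_b) <= lateral_max
    )


@dataclass
class Stack:
    member_ids: list[str]
    mean_spacing: float
    orientations: list[str]  # between consecutive members, length size-1

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class StackRecord:
    frame_index: int
    stacks: list[Stack]
    singleton_ids: list[str] = field(default_factory=list)

    @property
    def sizes(self) -> list[int]:
        return [s.size for s in self.stacks]


def detect_stacks(
    traj_or_planes: Trajectory | list[MBPlane],
    frame: int = 0,
    d_max: float = D_MAX,
    angle_max: float = ANGLE_MAX,
    lateral_max: float = LATERAL_MAX,
) -> StackRecord:
    """Partition the MB molecules of one frame into stacks and singletons.

    Stacks are connected components (size >= 2) of the graph whose edges
    satisfy :func:`is_stacked`; members are ordered by projection onto the
    mean stack normal (ties broken by molecule id).
    """
    if isinstance(traj_or_planes, Trajectory):
        planes = frame_planes(traj_or_planes, frame)
    else:
        planes = list(traj_or_planes)
        if planes and not isinstance(planes[0], MBPlane):
            raise TypeError("expected a Trajectory or a list of MBPlane")
    if not planes:
        raise ValueError("frame contains no MB molecules")

    by_id = {p.mol_id: p for p in planes}
    graph = nx.Graph()
    graph.add_nodes_from(by_id)
    for i, a in enumerate(planes):
        for b in planes[i + 1:]:
            if is_stacked(a, b, d_max, angle_max, lateral_max):
                graph.add_edge(a.mol_id, b.mol_id)

    stacks: list[Stack] = []
    singletons: list[str] = []
    for comp in nx.connected_components(graph):
        ids = sorted(comp, key=_natural_key)
        if len(ids) == 1:
            singletons.extend(ids)
            continue
        ordered = _order_along_normal([by_id[i] for i in ids])
        spacings = [
            interplane_distance(ordered[k], ordered[k + 1])
            for k in range(len(ordered) - 1)
        ]
        orients = [
            classify_orientation(ordered[k], ordered[k + 1])
            for k in range(len(ordered) - 1)
        ]
        stacks.append(
            Stack([p.mol_id for p in ordered], float(np.mean(spacings)), orients)
        )
    stacks.sort(key=lambda s: _natural_key(s.member_ids[0]))
    singletons.sort(key=_natural_key)
    frame_index = frame if isinstance(traj_or_planes, Trajectory) else 0
    return StackRecord(frame_index, stacks, singletons)


def _natural_key(mol_id: str):
    digits = "".join(ch for ch in mol_id if ch.isdigit())
    return (int(digits) if digits else 0, mol_id)


def _order_along_normal(planes: list[MBPlane]) -> list[MBPlane]:
    ref = planes[0].normal
    mean_normal = np.zeros(3)
    for p in planes:
        mean_normal += p.normal if np.dot(p.normal, ref) >= 0 else -p.normal
    norm = np.linalg.norm(mean_normal)
    mean_normal = ref if norm == 0 else mean_normal / norm
    keyed = sorted(
        planes,
        key=lambda p: (round(float(np.dot(p.centroid, mean_normal)), 9),
                       _natural_key(p.mol_id)),
    )
    return keyed


@dataclass
class StackSummary:
    """Trajectory-level stacking statistics.

    size_histogram counts stacks (and singletons, size 1) of each size per
    frame; mean_spacing averages over all consecutive stacked pairs, and
    mean_spacing_dimers over pairs in 2-stacks only (the two readings of
    "average distance between adjacent molecules").
    """

    size_histogram: dict[int, float]
    mean_spacing: float
    mean_spacing_dimers: float
    orientation_counts: dict[str, int]
    records: list[StackRecord]

    @property
    def modal_size(self) -> int:
        return max(self.size_histogram, key=lambda s: (self.size_histogram[s], s))


def stack_statistics(
    traj: Trajectory,
    d_max: float = D_MAX,
    angle_max: float = ANGLE_MAX,
    lateral_max: float = LATERAL_MAX,
) -> StackSummary:
    """Per-frame stack detection aggregated over a whole trajectory."""
    if traj.n_frames < 1:
        raise ValueError("empty trajectory")
    records = [
        detect_stacks(traj, f, d_max, angle_max, lateral_max)
        for f in range(traj.n_frames)
    ]
    hist: Counter[int] = Counter()
    orient: Counter[str] = Counter()
    spacings: list[float] = []
    dimer_spacings: list[float] = []
    for rec in records:
        for st in rec.stacks:
            hist[st.size] += 1
            orient.update(st.orientations)
            # the stack mean times its pair count recovers the pair sum, so
            # repeating it per pair keeps the global mean exact
            spacings.extend([st.mean_spacing] * (st.size - 1))
            if st.size == 2:
                dimer_spacings.append(st.mean_spacing)
        if rec.singleton_ids:
            hist[1] += len(rec.singleton_ids)
    n = traj.n_frames
    return StackSummary(
        size_histogram={s: c / n for s, c in sorted(hist.items())},
        mean_spacing=float(np.mean(spacings)) if spacings else float("nan"),
        mean_spacing_dimers=(
            float(np.mean(dimer_spacings)) if dimer_spacings else float("nan")
        ),
        orientation_counts=dict(orient),
        records=records,
    )
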