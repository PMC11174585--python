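"""Skeleton topologies, adjacency normalization and pyramid joint partitions.

A skeleton is an undirected graph over body joints (bones are edges); every
joint carries a self-loop so that its own features always contribute to graph
aggregation and no degree is zero.  A :class:`PartitionScheme` defines the
three pyramid granularities used by the multi-pathway network: global (all
joints), half (upper/lower body) and limb (arms, legs, torso).

Layouts (joint names, bone lists, partition subsets, mirror maps) ship as
YAML files under ``gaitfreq/layouts`` and users may register their own files
with the same schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "SkeletonGraph",
    "PartitionScheme",
    "Layout",
    "build_skeleton_graph",
    "default_partition",
    "subgraph",
    "load_layout",
    "available_layouts",
]

GLOBAL, HALF, LIMB = 0, 1, 2


class LayoutError(ValueError):
    """Unknown layout or malformed layout configuration."""


@dataclass(frozen=True)
class SkeletonGraph:
    """Joint graph with self-loops: adjacency is binary symmetric, diag = 1."""

    n_joints: int
    joint_names: tuple[str, ...]
    edges: tuple[tuple[int, int], ...]  # bone edges, no self-loops
    adjacency: np.ndarray
    degrees: np.ndarray

    def __post_init__(self):
        a = self.adjacency
        if a.shape != (self.n_joints, self.n_joints):
            raise ValueError("adjacency shape mismatch")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if not np.all(np.diag(a) == 1):
            raise ValueError("adjacency must carry self-loops")
        if not np.array_equal(self.degrees, a.sum(axis=1)):
            raise ValueError("degrees must equal adjacency row sums")


@dataclass(frozen=True)
class PartitionScheme:
    """Ordered coarse-to-fine pathways, each a cover of the full joint set."""

    pathways: tuple[tuple[int, tuple[tuple[int, ...], ...]], ...]
    scale_order: tuple[int, ...] = (GLOBAL, HALF, LIMB)
    n_joints: int = 0

    def __post_init__(self):
        full = set(range(self.n_joints))
        for expected, (ph, subsets) in enumerate(self.pathways):
            if ph != expected:
                raise ValueError("pathway ids must be consecutive from 0")
            union = set()
            for sub in subsets:
                union.update(sub)
            if union != full:
                raise ValueError(
                    f"pathway {ph} covers {len(union)}/{self.n_joints} joints"
                )

    def subsets(self, ph: int) -> tuple[tuple[int, ...], ...]:
        return self.pathways[ph][1]

    @property
    def n_pathways(self) -> int:
        return len(self.pathways)


@dataclass(frozen=True)
class Layout:
    """A registered skeleton layout (names, bones, partitions, mirror map)."""

    name: str
    n_joints: int
    joint_names: tuple[str, ...]
    edges: tuple[tuple[int, int], ...]
    half: tuple[tuple[int, ...], ...]
    limb: tuple[tuple[int, ...], ...]
    mirror: dict[int, int] = field(default_factory=dict)
    lateral_channel: int = 0
    center_joints: tuple[int, ...] = (0,)
    scale_joints: tuple[int, int] = (0, 1)
    rest_pose: np.ndarray | None = None  # (V, 3): lateral, vertical, forward
    sides: tuple[str, ...] = ()          # 'L' / 'R' / 'C' per joint
    groups: tuple[str, ...] = ()         # 'arm' / 'leg' / 'torso' / 'head'
    swing_weight: tuple[float, ...] = ()

    def graph(self) -> SkeletonGraph:
        return build_skeleton_graph(list(self.edges), self.n_joints, list(self.joint_names))

    def mirror_permutation(self) -> np.ndarray:
        perm = np.arange(self.n_joints)
        for a, b in self.mirror.items():
            perm[a] = b
        return perm


def build_skeleton_graph(edge_list, n_joints, joint_names=None) -> SkeletonGraph:
    """Build a skeleton graph from bone edges, adding a self-loop per joint.

    Raises ``IndexError`` for out-of-range joint indices and ``ValueError``
    for duplicate or self-referential bone edges.
    """
    if n_joints < 1:
        raise ValueError("n_joints must be positive")
    if not edge_list and n_joints > 1:
        raise ValueError("edge_list may only be empty for a single-joint skeleton")
    seen = set()
    edges = []
    for i, j in edge_list:
        i, j = int(i), int(j)
        if not (0 <= i < n_joints and 0 <= j < n_joints):
            raise IndexError(f"edge ({i}, {j}) out of range for {n_joints} joints")
        if i == j:
            raise ValueError(f"self-loop ({i}, {i}) in edge list; self-loops are implicit")
        key = (min(i, j), max(i, j))
        if key in seen:
            raise ValueError(f"duplicate edge {key}")
        seen.add(key)
        edges.append(key)
    if joint_names is None:
        joint_names = [f"joint_{k}" for k in range(n_joints)]
    elif len(joint_names) != n_joints:
        raise ValueError("joint_names length must equal n_joints")
    adj = np.eye(n_joints, dtype=np.int64)
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1
    return SkeletonGraph(
        n_joints=n_joints,
        joint_names=tuple(joint_names),
        edges=tuple(edges),
        adjacency=adj,
        degrees=adj.sum(axis=1),
    )


def subgraph(graph: SkeletonGraph, joints) -> SkeletonGraph:
    """Induced subgraph on `joints`, indices remapped to 0..k-1."""
    joints = [int(j) for j in joints]
    if not joints:
        raise ValueError("joint list must be nonempty")
    if len(set(joints)) != len(joints):
        raise ValueError("joint list contains duplicates")
    for j in joints:
        if not 0 <= j < graph.n_joints:
            raise IndexError(f"joint {j} out of range")
    remap = {j: k for k, j in enumerate(joints)}
    edges = [
        (remap[i], remap[j])
        for i, j in graph.edges
        if i in remap and j in remap
    ]
    adj = np.eye(len(joints), dtype=np.int64)
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1
    return SkeletonGraph(
        n_joints=len(joints),
        joint_names=tuple(graph.joint_names[j] for j in joints),
        edges=tuple((min(i, j), max(i, j)) for i, j in edges),
        adjacency=adj,
        degrees=adj.sum(axis=1),
    )


# -- layout registry -------------------------------------------------------


def _layout_dir():
    return resources.files("gaitfreq").joinpath("layouts")


def available_layouts() -> list[str]:
    return sorted(p.name[: -len(".yaml")] for p in _layout_dir().iterdir() if p.name.endswith(".yaml"))


def load_layout(name_or_path: str) -> Layout:
    """Load a registered layout by name, or a user YAML file by path."""
    path = Path(str(name_or_path))
    if path.suffix in {".yaml", ".yml"} and path.exists():
        text = path.read_text()
        fallback_name = path.stem
    else:
        res = _layout_dir().joinpath(f"{name_or_path}.yaml")
        if not res.is_file():
            raise LayoutError(
                f"unknown layout {name_or_path!r}; available: {available_layouts()}"
            )
        text = res.read_text()
        fallback_name = str(name_or_path)
    raw = yaml.safe_load(text)
    try:
        mirror_pairs = raw.get("mirror", [])
        mirror: dict[int, int] = {}
        for a, b in mirror_pairs:
            mirror[int(a)] = int(b)
            mirror[int(b)] = int(a)
        return Layout(
            name=raw.get("name", fallback_name),
            n_joints=int(raw["n_joints"]),
            joint_names=tuple(raw["joint_names"]),
            edges=tuple((int(i), int(j)) for i, j in raw["edges"]),
            half=tuple(tuple(int(j) for j in sub) for sub in raw["partitions"]["half"]),
            limb=tuple(tuple(int(j) for j in sub) for sub in raw["partitions"]["limb"]),
            mirror=mirror,
            lateral_channel=int(raw.get("lateral_channel", 0)),
            center_joints=tuple(int(j) for j in raw.get("center_joints", [0])),
            scale_joints=tuple(int(j) for j in raw.get("scale_joints", [0, 1])),
            rest_pose=(
                np.asarray(raw["rest_pose"], dtype=np.float64)
                if "rest_pose" in raw
                else None
            ),
            sides=tuple(raw.get("sides", ())),
            groups=tuple(raw.get("groups", ())),
            swing_weight=tuple(float(w) for w in raw.get("swing_weight", ())),
        )
    except KeyError as exc:
        raise LayoutError(f"layout config missing field {exc}") from exc


def default_partition(graph: SkeletonGraph, layout) -> PartitionScheme:
    """Three-scale partition (global / half / limb) for a registered layout.

    `layout` may be a layout name, a :class:`Layout`, or a mapping with
    ``half`` and ``limb`` subset lists for custom skeletons.
    """
    if isinstance(layout, str):
        layout = load_layout(layout)
    if isinstance(layout, Layout):
        half, limb = layout.half, layout.limb
        if layout.n_joints != graph.n_joints:
            raise LayoutError(
                f"layout {layout.name!r} has {layout.n_joints} joints, graph has {graph.n_joints}"
            )
    elif isinstance(layout, dict):
        try:
            half = tuple(tuple(int(j) for j in s) for s in layout["half"])
            limb = tuple(tuple(int(j) for j in s) for s in layout["limb"])
        except KeyError as exc:
            raise LayoutError(f"custom partition missing subsets: {exc}") from exc
    else:
        raise LayoutError(f"unsupported layout specification: {layout!r}")
    full = (tuple(range(graph.n_joints)),)
    return PartitionScheme(
        pathways=((GLOBAL, full), (HALF, half), (LIMB, limb)),
        n_joints=graph.n_joints,
    )
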