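"""Skeletonization, branch decomposition and the curation contract.

Steps 6-7 of the detection pipeline: the cleaned vesselness mask is thinned
to a one-voxel-wide 3D skeleton (Lee medial-axis thinning), skeleton voxels
inside the cell body are removed, and each connected skeleton component is
decomposed at branch points into simple line segments.

Curation is expressed as an :class:`EditScript` — an ordered list of
``remove`` / ``accept`` / ``merge`` commands that stands in for the manual
step in which spurious detections are deleted and fragments of one
filopodium are joined.  Applying a script turns line segments into
:class:`~filotrack.core.FilopodiumInstance` objects with base→tip
orientation, path lengths and mean direction.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import skeletonize

from .core import FilopodiumInstance, LineSegment, VoxelCalibration

__all__ = [
    "skeletonize_frame",
    "mask_skeleton",
    "extend_skeleton_tips",
    "split_segments",
    "EditCommand",
    "EditScript",
    "auto_accept",
    "apply_edits",
    "save_edits",
    "load_edits",
]


def skeletonize_frame(mask: np.ndarray) -> np.ndarray:
    """Thin a 3D binary mask to its medial axis (Lee's algorithm).

    Every skeleton voxel was foreground in the input, and thinning preserves
    the connected-component count.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros_like(mask)
    return skeletonize(mask, method="lee").astype(bool)


def mask_skeleton(skeleton: np.ndarray, cell_body: np.ndarray) -> np.ndarray:
    """Remove skeleton voxels that lie inside the cell-body mask."""
    skeleton = np.asarray(skeleton, dtype=bool)
    cell_body = np.asarray(cell_body, dtype=bool)
    if skeleton.shape != cell_body.shape:
        raise ValueError(
            f"shape mismatch: skeleton {skeleton.shape} vs cell body {cell_body.shape}"
        )
    return skeleton & ~cell_body


def extend_skeleton_tips(
    skeleton: np.ndarray,
    support: np.ndarray,
    max_extension: int = 8,
) -> np.ndarray:
    """Extend skeleton endpoints along their local direction within ``support``.

    Medial-axis thinning retracts the ends of a filament by roughly its
    radius; this walks each degree-1 endpoint outward along the direction of
    its last few voxels, adding voxels as long as they stay inside the
    supporting mask (and do not run into other skeleton voxels), up to
    ``max_extension`` voxels.  Voxels are only ever added inside ``support``,
    so the extended skeleton remains a subset of the mask it was thinned
    from.
    """
    skeleton = np.asarray(skeleton, dtype=bool)
    support = np.asarray(support, dtype=bool)
    if skeleton.shape != support.shape:
        raise ValueError("skeleton and support shapes differ")
    out = skeleton.copy()
    adj = _adjacency(skeleton)
    shape = np.array(skeleton.shape)
    for v, nbrs in adj.items():
        if len(nbrs) != 1:
            continue
        # estimate the outgoing direction from the last few chain voxels
        chain = [v]
        prev, cur = v, nbrs[0]
        while len(chain) < 5:
            chain.append(cur)
            nxt = [w for w in adj[cur] if w != prev]
            if len(nxt) != 1:
                break
            prev, cur = cur, nxt[0]
        direction = np.asarray(v, dtype=float) - np.asarray(chain[-1], dtype=float)
        norm = np.linalg.norm(direction)
        if norm == 0:
            continue
        direction /= norm
        pos = np.asarray(v, dtype=float)
        last = v
        for _ in range(2 * max_extension):
            pos = pos + 0.5 * direction
            cand = tuple(int(c) for c in np.rint(pos))
            if cand == last:
                continue
            if np.any(np.asarray(cand) < 0) or np.any(np.asarray(cand) >= shape):
                break
            if not support[cand] or skeleton[cand]:
                break
            if out[cand]:
                break
            out[cand] = True
            last = cand
            if sum(abs(a - b) for a, b in zip(cand, v)) >= max_extension:
                break
    return out


# ---------------------------------------------------------------------------
# Branch decomposition
# ---------------------------------------------------------------------------

_OFFSETS = [
    (dz, dy, dx)
    for dz, dy, dx in itertools.product((-1, 0, 1), repeat=3)
    if (dz, dy, dx) != (0, 0, 0)
]


def _adjacency(skeleton: np.ndarray) -> dict[tuple[int, int, int], list[tuple[int, int, int]]]:
    voxels = [tuple(int(c) for c in v) for v in np.argwhere(skeleton)]
    vox_set = set(voxels)
    adj = {}
    for v in sorted(voxels):
        nbrs = []
        for off in _OFFSETS:
            n = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
            if n in vox_set:
                nbrs.append(n)
        adj[v] = sorted(nbrs)
    return adj


def split_segments(skeleton: np.ndarray, frame: int = 0, start_id: int = 0) -> list[LineSegment]:
    """Decompose a thinned skeleton into simple line segments.

    Voxels with three or more 26-neighbors are branch points; each branched
    component splits into the maximal simple paths between branch points and
    endpoints.  The returned paths jointly cover every skeleton voxel that
    belongs to a path of at least two voxels, and distinct paths share only
    branch voxels.  Traversal order is lexicographic in voxel coordinates,
    making the decomposition deterministic.
    """
    skeleton = np.asarray(skeleton, dtype=bool)
    if skeleton.ndim != 3:
        raise ValueError(f"expected a 3D skeleton, got shape {skeleton.shape}")
    adj = _adjacency(skeleton)
    degree = {v: len(nbrs) for v, nbrs in adj.items()}
    visited: set[tuple] = set()

    def edge(a, b):
        return (a, b) if a < b else (b, a)

    def walk(a, b):
        """Follow the chain starting with edge (a, b) through degree-2 voxels."""
        path = [a, b]
        visited.add(edge(a, b))
        prev, cur = a, b
        while degree[cur] == 2:
            nxt = [w for w in adj[cur] if w != prev][0]
            if edge(cur, nxt) in visited:
                break
            visited.add(edge(cur, nxt))
            path.append(nxt)
            prev, cur = cur, nxt
        if path[-1] == path[0]:  # loop closing back onto its start voxel
            path.pop()
        return path

    paths = []
    for v in adj:  # insertion order is lexicographic
        if degree[v] == 2:
            continue
        for n in adj[v]:
            if edge(v, n) not in visited:
                paths.append(walk(v, n))
    # pure cycles: every voxel has degree 2
    for v in adj:
        if degree[v] == 2:
            for n in adj[v]:
                if edge(v, n) not in visited:
                    paths.append(walk(v, n))

    segments = []
    sid = start_id
    for p in paths:
        if len(p) < 2:
            continue
        segments.append(LineSegment(segment_id=sid, frame=frame, path=np.asarray(p, dtype=np.int64)))
        sid += 1
    return segments


# ---------------------------------------------------------------------------
# Edit scripts
# ---------------------------------------------------------------------------

@dataclass
class EditCommand:
    """One curation action: ``remove``, ``accept`` or ``merge``."""

    op: str
    segment_ids: tuple[int, ...]
    instance_id: int | None = None

    def __post_init__(self) -> None:
        self.segment_ids = tuple(int(s) for s in self.segment_ids)
        if self.op not in ("remove", "accept", "merge"):
            raise ValueError(f"unknown edit op {self.op!r}")
        if self.op == "remove" and self.instance_id is not None:
            raise ValueError("remove takes no instance id")
        if self.op == "accept" and len(self.segment_ids) != 1:
            raise ValueError("accept takes exactly one segment id")
        if self.op == "merge" and len(self.segment_ids) < 2:
            raise ValueError("merge needs at least two segment ids")
        if self.op in ("accept", "merge") and self.instance_id is None:
            raise ValueError(f"{self.op} requires an instance id")


@dataclass
class EditScript:
    """An ordered list of edit commands.

    Segments not referenced by any command are kept as singleton instances
    (implicit accept, instance id = segment id), so a script only needs to
    name the segments it changes.  A segment may be consumed by at most one
    command, and merged segments must come from the same frame.
    """

    commands: list[EditCommand] = field(default_factory=list)

    def validate(self, segments: Sequence[LineSegment]) -> None:
        by_id = {s.segment_id: s for s in segments}
        seen: set[int] = set()
        instance_ids: set[int] = set()
        for cmd in self.commands:
            for sid in cmd.segment_ids:
                if sid not in by_id:
                    raise ValueError(f"edit references unknown segment {sid}")
                if sid in seen:
                    raise ValueError(f"segment {sid} consumed by more than one edit")
                seen.add(sid)
            if cmd.op == "merge":
                frames = {by_id[sid].frame for sid in cmd.segment_ids}
                if len(frames) != 1:
                    raise ValueError(
                        f"merge {cmd.segment_ids} spans frames {sorted(frames)}"
                    )
            if cmd.instance_id is not None:
                if cmd.instance_id in instance_ids:
                    raise ValueError(f"instance id {cmd.instance_id} assigned twice")
                instance_ids.add(cmd.instance_id)
        implicit = {s.segment_id for s in segments} - seen
        clash = instance_ids & implicit
        if clash:
            raise ValueError(
                f"instance ids {sorted(clash)} clash with implicitly accepted segments"
            )

    def to_dict(self) -> dict:
        return {
            "format": "filotrack-edits",
            "version": 1,
            "commands": [
                {
                    "op": c.op,
                    "segment_ids": list(c.segment_ids),
                    **({"instance_id": c.instance_id} if c.instance_id is not None else {}),
                }
                for c in self.commands
            ],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "EditScript":
        if doc.get("format") != "filotrack-edits":
            raise ValueError("not a filotrack edit script")
        return cls(commands=[
            EditCommand(
                op=rec["op"],
                segment_ids=tuple(rec["segment_ids"]),
                instance_id=rec.get("instance_id"),
            )
            for rec in doc["commands"]
        ])


def save_edits(script: EditScript, path: str | Path) -> None:
    Path(path).write_text(json.dumps(script.to_dict(), indent=1))


def load_edits(path: str | Path) -> EditScript:
    return EditScript.from_dict(json.loads(Path(path).read_text()))


def auto_accept(segments: Sequence[LineSegment]) -> EditScript:
    """The identity curation: accept every segment as its own instance."""
    return EditScript(commands=[
        EditCommand(op="accept", segment_ids=(s.segment_id,), instance_id=s.segment_id)
        for s in segments
    ])


# ---------------------------------------------------------------------------
# Applying edits
# ---------------------------------------------------------------------------

def _chain_paths(paths: list[np.ndarray], ids: Sequence[int], merge_gap: float) -> np.ndarray:
    """Greedily chain paths by joining their nearest endpoints."""
    chains = [np.asarray(p) for p in paths]
    while len(chains) > 1:
        best = None  # (dist, i, j, flip_i, flip_j)
        for i in range(len(chains)):
            for j in range(i + 1, len(chains)):
                for flip_i, flip_j in itertools.product((False, True), repeat=2):
                    a = chains[i][0] if flip_i else chains[i][-1]
                    b = chains[j][-1] if flip_j else chains[j][0]
                    d = float(np.linalg.norm((a - b).astype(float)))
                    cand = (d, i, j, flip_i, flip_j)
                    if best is None or cand < best:
                        best = cand
        d, i, j, flip_i, flip_j = best
        if d > merge_gap:
            raise ValueError(
                f"segments {tuple(ids)} cannot be chained: nearest endpoints are "
                f"{d:.2f} voxels apart (merge_gap={merge_gap})"
            )
        left = chains[i][::-1] if flip_i else chains[i]
        right = chains[j][::-1] if flip_j else chains[j]
        merged = np.concatenate([left, right])
        chains = [c for k, c in enumerate(chains) if k not in (i, j)] + [merged]
    return chains[0]


def _orient_base_first(
    path: np.ndarray,
    body_distance: np.ndarray | None,
    anchor: np.ndarray,
) -> np.ndarray:
    """Flip the path so that the endpoint nearer the cell body comes first."""
    start, end = path[0], path[-1]
    if body_distance is not None:
        d0 = float(body_distance[tuple(start)])
        d1 = float(body_distance[tuple(end)])
    else:
        d0 = float(np.linalg.norm(start.astype(float) - anchor))
        d1 = float(np.linalg.norm(end.astype(float) - anchor))
    if d1 < d0 or (d1 == d0 and tuple(end) < tuple(start)):
        return path[::-1]
    return path


def apply_edits(
    segments: Sequence[LineSegment],
    edits: EditScript,
    calibration: VoxelCalibration,
    cell_body: np.ndarray | None = None,
    anchor: np.ndarray | None = None,
    merge_gap: float = 5.0,
) -> list[FilopodiumInstance]:
    """Apply a curation script, producing oriented filopodium instances.

    Removed segments are dropped; merged segments are chained into a single
    ordered path by greedy nearest-endpoint joining (an error names the ids
    if the closest endpoints are further than ``merge_gap`` voxels apart).
    The base of each instance is the path endpoint nearest the cell-body
    mask; with no body available, the endpoint nearer ``anchor`` (default:
    the centroid of all segment voxels) is used.
    """
    edits.validate(segments)
    by_id = {s.segment_id: s for s in segments}

    body_distance = None
    if cell_body is not None and np.asarray(cell_body).any():
        body_distance = ndi.distance_transform_edt(~np.asarray(cell_body, dtype=bool))
    if anchor is None and segments:
        allvox = np.concatenate([s.path for s in segments]).astype(float)
        anchor = allvox.mean(axis=0)
    anchor = np.zeros(3) if anchor is None else np.asarray(anchor, dtype=float)

    consumed: set[int] = set()
    results: list[tuple[int, np.ndarray, int]] = []  # (instance_id, raw path, frame)
    for cmd in edits.commands:
        consumed.update(cmd.segment_ids)
        if cmd.op == "remove":
            continue
        frame = by_id[cmd.segment_ids[0]].frame
        if cmd.op == "accept":
            results.append((cmd.instance_id, by_id[cmd.segment_ids[0]].path, frame))
        else:  # merge
            merged = _chain_paths(
                [by_id[sid].path for sid in cmd.segment_ids], cmd.segment_ids, merge_gap
            )
            results.append((cmd.instance_id, merged, frame))
    for sid in sorted(by_id):
        if sid not in consumed:
            results.append((sid, by_id[sid].path, by_id[sid].frame))

    instances = []
    for iid, path, frame in sorted(results, key=lambda r: r[0]):
        oriented = _orient_base_first(path, body_distance, anchor)
        instances.append(
            FilopodiumInstance.from_path(iid, frame, oriented, calibration)
        )
    return instances
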