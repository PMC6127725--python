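"""Greedy score-based linking of filopodium instances across time points.

For each frame, every curated filopodium is compared against the tracks
whose most recent observation falls within the preceding ``lookback_frames``
time points (default 5).  A candidate pair exists when the minimum distance
between any voxel of the current path and any voxel of the track's most
recent path is within ``cutoff_radius_px`` (default 25 pixels, index units).
Each candidate is scored

    S = w_L · M_L + w_D · M_D,           w_L = 0.46,  w_D = 0.6,

where M_L = |L_c − L_p| / max{L_c, L_p} compares path lengths and
M_D = (1 − cos θ)/2 compares the average non-normalized direction vectors.
Candidates are sorted by score (lowest first) and linked greedily, one-to-one
per frame; leftover filopodia start new tracks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .core import FilopodiumInstance, Track, VoxelCalibration

__all__ = [
    "TrackingConfig",
    "LinkCandidate",
    "length_measure",
    "direction_measure",
    "find_candidates",
    "link_frame",
    "track_movie",
]


@dataclass
class TrackingConfig:
    """Linking parameters.

    ``cutoff_radius_px`` is interpreted in raw voxel-index units (the z axis
    unscaled); set ``calibrated_distance`` to measure it in physical units
    instead.  ``candidate_mode`` chooses whether only each track's most
    recent instance in the window ("recent") or every instance in the window
    ("any") generates candidates.
    """

    lookback_frames: int = 5
    cutoff_radius_px: float = 25.0
    weight_length: float = 0.46
    weight_direction: float = 0.6
    calibrated_distance: bool = False
    candidate_mode: str = "recent"  # or "any"

    def __post_init__(self) -> None:
        if self.lookback_frames < 1:
            raise ValueError("lookback_frames must be >= 1")
        if self.cutoff_radius_px <= 0:
            raise ValueError("cutoff_radius_px must be > 0")
        if self.weight_length < 0 or self.weight_direction < 0:
            raise ValueError("weights must be >= 0")
        if self.candidate_mode not in ("recent", "any"):
            raise ValueError("candidate_mode must be 'recent' or 'any'")


@dataclass(frozen=True)
class LinkCandidate:
    """A scored (instance, track) pair within the cutoff radius."""

    instance_id: int
    track_id: int
    m_length: float
    m_direction: float
    score: float


def length_measure(length_current: float, length_previous: float) -> float:
    """Path-length difference measure M_L = |L_c − L_p| / max{L_c, L_p}.

    Symmetric in its arguments and bounded in [0, 1].
    """
    if length_current <= 0 or length_previous <= 0:
        raise ValueError("path lengths must be > 0")
    return abs(length_current - length_previous) / max(length_current, length_previous)


def direction_measure(dir_current: np.ndarray, dir_previous: np.ndarray) -> float:
    """Average-direction measure M_D = (1 − cos θ)/2.

    θ is the angle between the two average non-normalized direction vectors,
    whose magnitudes cancel under the cosine; the measure is 0 for parallel
    and 1 for antiparallel directions.  A zero vector is uninformative and
    scores 0.5 with a warning.
    """
    a = np.asarray(dir_current, dtype=float)
    b = np.asarray(dir_previous, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        warnings.warn("zero direction vector: M_D set to 0.5", stacklevel=2)
        return 0.5
    cos = float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))
    return (1.0 - cos) / 2.0


def _scaled_path(inst: FilopodiumInstance, config: TrackingConfig,
                 calibration: VoxelCalibration | None) -> np.ndarray:
    path = inst.path.astype(float)
    if config.calibrated_distance:
        if calibration is None:
            raise ValueError("calibrated_distance requires a calibration")
        path = path * np.array(calibration.spacing_zyx)
    return path


def score_pair(current: FilopodiumInstance, previous: FilopodiumInstance,
               config: TrackingConfig) -> tuple[float, float, float]:
    """(M_L, M_D, S) for an instance pair."""
    m_l = length_measure(current.path_length_um, previous.path_length_um)
    m_d = direction_measure(current.mean_direction, previous.mean_direction)
    return m_l, m_d, config.weight_length * m_l + config.weight_direction * m_d


def find_candidates(
    current: Sequence[FilopodiumInstance],
    tracks: Sequence[Track],
    frame: int,
    config: TrackingConfig | None = None,
    calibration: VoxelCalibration | None = None,
) -> list[LinkCandidate]:
    """Scored link candidates between this frame's instances and live tracks.

    A track participates if its most recent instance lies in frames
    ``[frame − lookback, frame − 1]``; the pair is a candidate when the
    minimum pairwise voxel distance between the two paths is within the
    cutoff radius.
    """
    config = config or TrackingConfig()
    current = list(current)
    if not current:
        return []

    prev_entries: list[tuple[int, FilopodiumInstance]] = []
    for track in tracks:
        recent_frames = [
            f for f in track.frames if frame - config.lookback_frames <= f < frame
        ]
        if not recent_frames:
            continue
        if config.candidate_mode == "recent":
            recent_frames = [max(recent_frames)]
        for f in recent_frames:
            prev_entries.append((track.track_id, track.instances[f]))
    if not prev_entries:
        return []

    # cheap vectorized prefilter: the minimum pairwise path distance is at
    # least the centroid distance minus both path radii, so pairs beyond
    # cutoff + r_prev + r_cur cannot be candidates
    cur_paths = [_scaled_path(i, config, calibration) for i in current]
    prev_paths = [_scaled_path(p, config, calibration) for _, p in prev_entries]
    cur_cent = np.array([p.mean(axis=0) for p in cur_paths])
    prev_cent = np.array([p.mean(axis=0) for p in prev_paths])
    cur_rad = np.array([np.linalg.norm(p - c, axis=1).max() for p, c in zip(cur_paths, cur_cent)])
    prev_rad = np.array([np.linalg.norm(p - c, axis=1).max() for p, c in zip(prev_paths, prev_cent)])
    cent_dist = np.linalg.norm(prev_cent[:, None, :] - cur_cent[None, :, :], axis=2)
    feasible = cent_dist - prev_rad[:, None] - cur_rad[None, :] <= config.cutoff_radius_px

    candidates = []
    trees: dict[int, cKDTree] = {}
    for pi, ci in np.argwhere(feasible):
        if pi not in trees:
            trees[pi] = cKDTree(prev_paths[pi])
        d = float(trees[pi].query(cur_paths[ci])[0].min())
        if d <= config.cutoff_radius_px:
            track_id, prev = prev_entries[pi]
            inst = current[ci]
            m_l, m_d, s = score_pair(inst, prev, config)
            candidates.append(LinkCandidate(inst.instance_id, track_id, m_l, m_d, s))

    # "any" mode can produce duplicate (instance, track) pairs; keep the best score
    seen: dict[tuple[int, int], LinkCandidate] = {}
    for c in candidates:
        key = (c.instance_id, c.track_id)
        if key not in seen or c.score < seen[key].score:
            seen[key] = c
    return sorted(
        seen.values(),
        key=lambda c: (c.score, c.m_length, c.instance_id, c.track_id),
    )


def link_frame(candidates: Sequence[LinkCandidate]) -> dict[int, int]:
    """Greedy one-to-one matching: ascending score, first come first linked.

    Ties are broken by (M_L, instance id, track id) for determinism.  A pair
    links only if neither its instance nor its track has been linked in this
    frame; the returned mapping is instance id → track id.
    """
    ordered = sorted(
        candidates, key=lambda c: (c.score, c.m_length, c.instance_id, c.track_id)
    )
    linked: dict[int, int] = {}
    used_tracks: set[int] = set()
    for c in ordered:
        if c.instance_id in linked or c.track_id in used_tracks:
            continue
        linked[c.instance_id] = c.track_id
        used_tracks.add(c.track_id)
    return linked


def track_movie(
    instances_per_frame: Mapping[int, Sequence[FilopodiumInstance]]
    | Sequence[Sequence[FilopodiumInstance]],
    config: TrackingConfig | None = None,
    calibration: VoxelCalibration | None = None,
) -> list[Track]:
    """Link a whole movie's curated instances into identity tracks.

    Frames are processed in order; a track may carry gaps of up to
    ``lookback − 1`` frames.  Instances that match no track spawn new tracks
    (in instance-id order, so track ids are deterministic).
    """
    config = config or TrackingConfig()
    if isinstance(instances_per_frame, Mapping):
        frames = sorted(instances_per_frame)
        frame_map = {f: list(instances_per_frame[f]) for f in frames}
    else:
        frame_map = {f: list(insts) for f, insts in enumerate(instances_per_frame)}
        frames = sorted(frame_map)

    tracks: list[Track] = []
    by_id: dict[int, Track] = {}
    next_id = 0
    for f in frames:
        current = sorted(frame_map[f], key=lambda i: i.instance_id)
        if not current:
            continue
        cands = find_candidates(current, tracks, f, config, calibration)
        linked = link_frame(cands)
        for inst in current:
            if inst.instance_id in linked:
                by_id[linked[inst.instance_id]].add(inst)
            else:
                tr = Track(track_id=next_id)
                tr.add(inst)
                tracks.append(tr)
                by_id[next_id] = tr
                next_id += 1
    return tracks
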