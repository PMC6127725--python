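"""End-to-end orchestration: stack in, segments/instances/tracks out."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .core import FilopodiumInstance, LineSegment, TimeLapseStack, Track
from .quantify import FilterConfig
from .segmentation import (
    SegmentationConfig,
    VesselnessParams,
    find_cell_body,
    multiscale_vesselness,
    remove_small_objects,
    segment_pixels,
    segment_vesselness,
)
from .skeleton import (
    EditScript,
    apply_edits,
    auto_accept,
    extend_skeleton_tips,
    mask_skeleton,
    skeletonize_frame,
    split_segments,
)
from .tracking import TrackingConfig, track_movie

__all__ = ["PipelineConfig", "FrameResult", "PipelineResult", "detect_frame", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All stage parameters in one place, with the reference defaults."""

    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    vesselness: VesselnessParams = field(default_factory=VesselnessParams)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    merge_gap: float = 5.0


@dataclass
class FrameResult:
    """Per-frame detection artifacts kept for QC and curation."""

    frame: int
    cell_body: np.ndarray
    skeleton: np.ndarray
    segments: list[LineSegment]


@dataclass
class PipelineResult:
    frames: list[FrameResult]
    instances_per_frame: dict[int, list[FilopodiumInstance]]
    tracks: list[Track]

    @property
    def segments_per_frame(self) -> dict[int, list[LineSegment]]:
        return {fr.frame: fr.segments for fr in self.frames}


def detect_frame(
    volume: np.ndarray,
    t: int,
    config: PipelineConfig,
    spacing: tuple[float, float, float],
) -> FrameResult:
    """Run detection steps 1-7 on one ``(z, y, x)`` frame."""
    seg_cfg = config.segmentation
    foreground = segment_pixels(volume, seg_cfg)
    body = find_cell_body(volume, seg_cfg)
    vfield = multiscale_vesselness(foreground.astype(float), config.vesselness, spacing)
    vmask = segment_vesselness(vfield, seg_cfg)
    vmask = remove_small_objects(vmask, seg_cfg.min_region_voxels)
    skel = skeletonize_frame(vmask)
    skel = mask_skeleton(skel, body)
    # recover the endpoint retraction of thinning: grow tips back along the
    # vesselness mask (never into the cell body)
    skel = extend_skeleton_tips(skel, vmask & ~body)
    segments = split_segments(skel, frame=t)
    return FrameResult(frame=t, cell_body=body, skeleton=skel, segments=segments)


def run_pipeline(
    stack: TimeLapseStack,
    config: PipelineConfig | None = None,
    edit_scripts: Mapping[int, EditScript] | None = None,
) -> PipelineResult:
    """Detect, curate and link filopodia over a whole movie.

    ``edit_scripts`` maps frame index to a curation script; frames without a
    script are auto-accepted (every detected segment becomes its own
    instance), which is the unattended mode.
    """
    config = config or PipelineConfig()
    cal = stack.calibration
    if config.segmentation.anisotropy_correction:
        spacing = cal.aspect_zyx()
    else:
        spacing = (1.0, 1.0, 1.0)

    frames: list[FrameResult] = []
    instances: dict[int, list[FilopodiumInstance]] = {}
    for t in range(stack.frame_count):
        fr = detect_frame(stack.frame(t), t, config, spacing)
        frames.append(fr)
        script = None if edit_scripts is None else edit_scripts.get(t)
        if script is None:
            script = auto_accept(fr.segments)
        instances[t] = apply_edits(
            fr.segments,
            script,
            calibration=cal,
            cell_body=fr.cell_body,
            merge_gap=config.merge_gap,
        )
    tracks = track_movie(instances, config.tracking, cal)
    return PipelineResult(frames=frames, instances_per_frame=instances, tracks=tracks)
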