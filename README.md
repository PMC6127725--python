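# filotrack

Reconstruction, tracking and quantification of **filopodia** — thin,
actin-rich, finger-like protrusions — in time-lapse confocal z-stacks of
cells, built around the geometry of developing *Drosophila* myotube tips:
shallow stacks of 5–7 z-sections (0.7 µm spacing) recorded every 15 s while
the muscle tip probes for its tendon-cell target.

Filopodia are one to two pixels wide, densely packed around a bright cell
body, and too irregular for generic spot or filament trackers.  `filotrack`
implements a semi-automated pipeline for exactly this regime:

1. **Detection** (per frame, steps 1–7):
   binarization by 3-label SLIC-style intensity clustering (no enforced
   connectivity, lowest-mean label = background) → cell-body masking
   (Gaussian blur σ=5, adaptive threshold over a 999×999 Gaussian-weighted
   neighborhood, morphological opening, 5-px disk erosion) → Hessian
   **vesselness** filtering (eigenvalues |λ₁|≤|λ₂|≤|λ₃|,
   V = (1−e^{−r_a²/2α²})·e^{−r_b²/2β²}·(1−e^{−s²/2c²}) with
   r_a=|λ₂|/|λ₃|, r_b=|λ₁|/√|λ₂λ₃|, s=‖H‖_F, zero when λ₂>0 or λ₃>0) →
   SLIC-style segmentation of the vesselness field + binary closing →
   removal of connected regions under 200 voxels → 3D medial-axis
   skeletonization (Lee) → decomposition into line segments at branch
   points.
2. **Curation**: a JSON *edit script* of `remove` / `accept` / `merge`
   commands stands in for the manual step (deleting spurious detections,
   joining fragments of one filopodium); `auto_accept` provides the
   unattended default.
3. **Linking**: for each frame, candidate matches are previous filopodia
   within a 25-pixel cutoff over the preceding five time points, scored by

   &nbsp;&nbsp;&nbsp;&nbsp;S = 0.46·M_L + 0.6·M_D,&nbsp;&nbsp;
   M_L = |L_c−L_p| / max{L_c, L_p},&nbsp;&nbsp;
   M_D = (1−cos θ)/2,

   where L are path lengths and θ is the angle between the average
   non-normalized direction vectors; candidates are sorted by score (lowest
   first) and linked greedily, one-to-one.
4. **Quantification**: tracks are filtered to filopodia that reach ≥ 3 µm
   and exist for ≥ 2 frames; outputs are per-frame counts, maximum length
   per filopodium (over its lifetime), the ECDF of maximum lengths, a
   shifted-exponential fit of the maximum-length distribution, and
   two-group Mann–Whitney comparisons.

A fully ground-truthed **synthetic movie generator** renders body + tubular
protrusions with known identities and lengths under shot noise, so every
stage — and the end-to-end identity/length recovery — is testable without
microscope data.

## Worked example

```python
from filotrack import (SimConfig, simulate_movie, run_pipeline,
                       filter_tracks, score_against_truth)
from filotrack.quantify import count_filopodia
from filotrack import io

stack, truth = simulate_movie(SimConfig(seed=42))   # 60 frames, 6 slices, 8 filopodia
result = run_pipeline(stack)                        # detect + auto-accept + link
kept = filter_tracks(result.tracks)                 # >= 3 um, >= 2 frames
report = score_against_truth(kept, truth)
counts = count_filopodia(kept, total_frames=stack.frame_count)
print(f"tracks: {len(result.tracks)} detected, {len(kept)} pass the 3 um / 2-frame filter")
print(f"mean filopodia per frame: {counts.mean_count:.2f} (distinct: {counts.distinct_tracks})")
print(f"recall {report.recall:.3f}  precision {report.precision:.3f}")
print(f"max-length RMSE {report.max_length_rmse_um:.2f} um")
print(io.track_summary(kept).to_string(index=False))
```

prints

```
tracks: 209 detected, 8 pass the 3 um / 2-frame filter
mean filopodia per frame: 6.57 (distinct: 8)
recall 1.000  precision 0.947
max-length RMSE 0.56 um
 track_id  birth_frame  last_frame  lifetime_frames  max_length_um
        0            0          55               56       5.306564
        1            1          53               53       3.360298
       16            6          54               49       3.677010
       17            6          57               52       5.828370
       21            7          54               47       3.984233
       24            8          53               41       4.184630
       27            8          59               52       6.355964
       29            8          53               44       6.479697
```

All 8 simulated filopodia are recovered as exactly 8 tracks (the other 201
raw tracks are one-or-two-frame noise specks that the ≥ 3 µm / ≥ 2 frame
filter discards — the same exclusion the quantification applies to real
recordings).  "Recall/precision" compare per-frame detections against the
generator's true centerlines; the max-length RMSE compares each recovered
filopodium's lifetime maximum length with truth.

## Command line

```sh
filotrack simulate --out movie.tif --truth truth.csv --seed 1
filotrack segment movie.tif --out segments.json [--dx 0.1 --dy 0.1]
filotrack edit movie.tif segments.json --script edits.json --out instances.json
filotrack link instances.json --out tracks.json
filotrack quantify tracks.json --out summary.csv --report report.json
filotrack run movie.tif --out-dir results/      # unattended end-to-end
```

All stage parameters live in a TOML config (`--config`), with the
reference values as defaults; see `filotrack.config` for the schema.

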