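# polarscope

Analysis toolkit for macrophage-polarization studies: quantitative
proteome classification and label-free motility measurement.

Cultured human macrophages polarize into functionally distinct subtypes
(unstimulated MØ, proinflammatory M1, alternatively activated M2a,
glucocorticoid-deactivated M2c) while keeping a large *core proteome*
stable. polarscope implements the two computational workflows such
studies rely on:

1. **Proteome arm** — multiplexed (TMT-style) protein-abundance tables
   are normalized per sample, expressed as log2 fold change (log2FC)
   against the averaged MØ controls, median-centered, aggregated per
   subtype, and classified per protein × subtype as
   up (mean log2FC ≥ +1), down (≤ −1) or unchanged. Proteins unchanged
   in every subtype form the core proteome; the complement is the
   differential set. Optional filtering against a cell-surface protein
   atlas (CSPA-style list) yields the surfaceome view, and clustering
   leaf order / PCA scores support the usual visualizations.
2. **Imaging arm** — phase-contrast time-lapse videos are drift-corrected
   (translation-only, subpixel), segmented per frame (local-variance
   foreground → Otsu → hole filling; inverted difference-of-Gaussians
   landscape; extended-minima markers; marker-controlled watershed
   restricted to sub-cluster components; 200/2000 px² size classes), and
   detections are linked into tracks by Jaqaman-style linear-assignment
   centroid tracking. Tracks seen in ≥ 5 frames yield mean speed,
   path length, and Euclidean start-to-end distance, summarized per
   imaging field.

Both arms come with synthetic-data generators (`simulate_proteome`,
`simulate_motility_video`) that plant known ground truth — core
fractions and effect sizes, or exact trajectories — so the full chains
are testable end to end. A trapezoidal AUC helper and a
Kruskal–Wallis/Dunn group-comparison wrapper cover the usual functional
readouts (ROS chemiluminescence, per-field motility comparisons).

## Worked example

```python
import polarscope as ps

# --- proteome arm: planted ground truth, full chain, recovery check
matrix, truth = ps.simulate_proteome(
    n_proteins=1000, frac_core=0.5, effect_log2fc=2.0,
    noise_sd=0.3, n_replicates=3, seed=7,
)
result = ps.run_proteome_pipeline(matrix)
core, true_core = set(result["core"]), set(truth.core_ids)
print(f"core proteins called: {len(core)}")
print(f"recall {len(core & true_core) / len(true_core):.3f}, "
      f"precision {len(core & true_core) / len(core):.3f}")

# --- imaging arm: simulate, segment, track, score against truth
stack, vtruth = ps.simulate_motility_video(
    n_cells=10, frames=40, height=512, width=512,
    cell_radius=12, speed=4.0, persistence=0.9, seed=3,
)
labels = ps.segment_stack(stack)
tracks = ps.link_tracks(labels.object_table)
ev = ps.evaluate_against_truth(tracks, vtruth, match_radius=12)
print(f"tracks: {len(tracks)}, purity {ev['purity']:.3f}, "
      f"recovered speed {ev['recovered_mean_speed']:.2f} px/frame")
```

Output:

```
core proteins called: 500
recall 1.000, precision 1.000
tracks: 10, purity 1.000, recovered speed 4.00 px/frame
```

500 of 1000 proteins are called core against a planted fraction of 0.5;
with 3 donors and log2-scale noise sd 0.3, essentially every planted
±2 log2FC effect clears the ±1 cut and essentially no core protein
crosses it. The imaging arm recovers all 10 planted cells into pure
tracks whose mean speed matches the planted 4 px/frame (one frame =
20 min, i.e. 0.2 px/min).

The same workflows run from the shell:

```bash
polarscope simulate-video --n-cells 10 --frames 40 --seed 3 --out sim/
polarscope segment --in sim/video.tif --out seg/
polarscope track --objects seg/objects.csv --out trk/
polarscope summarize --tracks trk/tracks.csv --out summary/
polarscope proteome --abundance a.tsv --design d.tsv --atlas cspa.txt --out prot/
```

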