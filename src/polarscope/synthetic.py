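"""Ground-truth generators for both pipeline arms.

``simulate_proteome`` builds a TMT-like abundance matrix: log-normal
baselines, a planted core fraction with zero effect, subtype-specific
log2 fold-change blocks on the rest, multiplicative log-normal noise and
per-sample loading factors.  ``simulate_motility_video`` renders textured
disks performing a persistent random walk over a noisy background, with
optional touching clusters and global stage drift, recording exact
ground-truth tracks.  Every generator takes an explicit seed and is
byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .proteome import AbundanceMatrix
from .segmentation import ImageStack

__all__ = ["ProteomeTruth", "MotilityTruth", "simulate_proteome", "simulate_motility_video"]


@dataclass
class ProteomeTruth:
    """Planted structure behind a simulated abundance matrix."""

    protein_ids: list
    core_flags: pd.Series  # True where no effect planted
    planted_log2fc: pd.DataFrame  # proteins x subtypes
    surface_flags: pd.Series
    loading_factors: pd.Series  # per sample, > 0
    noise_sd: float

    @property
    def core_ids(self) -> pd.Index:
        return self.core_flags.index[self.core_flags]


@dataclass
class MotilityTruth:
    """Exact trajectories behind a simulated video."""

    tracks: pd.DataFrame  # cell_id, frame, x, y
    cell_radius: float
    speeds: pd.Series  # planted step length per cell, px/frame
    drift: tuple
    cluster_ids: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return self.tracks


def simulate_proteome(
    n_proteins: int = 1000,
    subtypes: tuple = ("M1", "M2a", "M2c"),
    n_replicates: int = 3,
    n_controls: int = 2,
    frac_core: float = 0.5,
    effect_log2fc: float = 2.0,
    noise_sd: float = 0.3,
    loading_spread: float = 0.1,
    frac_surface: float = 0.15,
    baseline_log2_mean: float = 10.0,
    baseline_log2_sd: float = 2.0,
    control_label: str = "M0",
    seed: int = 0,
) -> tuple[AbundanceMatrix, ProteomeTruth]:
    """Simulate a multiplexed abundance matrix with planted polarity effects.

    Core proteins (fraction ``frac_core``) carry zero effect everywhere;
    each remaining protein is assigned one subtype and a ±``effect_log2fc``
    effect there.  A replicate abundance is
    ``baseline * 2**effect * 2**N(0, noise_sd) * loading_factor``;
    control samples carry no effect.  Defaults mirror a three-subtype,
    three-donor, two-control design.
    """
    if n_proteins < 10:
        raise ValueError("n_proteins must be >= 10")
    if not 0 <= frac_core <= 1:
        raise ValueError("frac_core must lie in [0, 1]")
    if n_replicates < 1 or n_controls < 1:
        raise ValueError("n_replicates and n_controls must be positive")
    if not subtypes:
        raise ValueError("subtypes must be nonempty")
    if control_label in subtypes:
        raise ValueError(f"control label {control_label!r} clashes with a subtype")

    rng = np.random.default_rng(seed)
    protein_ids = [f"P{i:05d}" for i in range(n_proteins)]

    n_core = int(round(frac_core * n_proteins))
    core = np.zeros(n_proteins, dtype=bool)
    core[rng.choice(n_proteins, size=n_core, replace=False)] = True

    planted = pd.DataFrame(0.0, index=protein_ids, columns=list(subtypes))
    diff_idx = np.flatnonzero(~core)
    if diff_idx.size:
        assigned = rng.integers(0, len(subtypes), size=diff_idx.size)
        signs = rng.choice([-1.0, 1.0], size=diff_idx.size)
        for row, st, sg in zip(diff_idx, assigned, signs):
            planted.iloc[row, st] = sg * effect_log2fc

    surface = pd.Series(
        rng.random(n_proteins) < frac_surface, index=protein_ids, name="surface"
    )

    sample_ids, sample_subtype, sample_donor, sample_ctrl = [], [], [], []
    for d in range(n_controls):
        sample_ids.append(f"{control_label}_ctrl{d + 1}")
        sample_subtype.append(control_label)
        sample_donor.append(f"donor{d + 1}")
        sample_ctrl.append(True)
    for st in subtypes:
        for d in range(n_replicates):
            sample_ids.append(f"{st}_rep{d + 1}")
            sample_subtype.append(st)
            sample_donor.append(f"donor{d + 1}")
            sample_ctrl.append(False)
    design = pd.DataFrame(
        {"subtype": sample_subtype, "donor": sample_donor, "is_control": sample_ctrl},
        index=pd.Index(sample_ids, name="sample_id"),
    )

    loading = pd.Series(
        rng.uniform(1 - loading_spread, 1 + loading_spread, size=len(sample_ids)),
        index=sample_ids,
        name="loading",
    )

    baseline = 2.0 ** rng.normal(baseline_log2_mean, baseline_log2_sd, size=n_proteins)
    values = np.empty((n_proteins, len(sample_ids)))
    for j, sid in enumerate(sample_ids):
        st = design.loc[sid, "subtype"]
        effect = np.zeros(n_proteins) if design.loc[sid, "is_control"] else planted[st].to_numpy()
        noise = rng.normal(0.0, noise_sd, size=n_proteins) if noise_sd > 0 else 0.0
        values[:, j] = baseline * 2.0 ** (effect + noise) * loading[sid]

    matrix = AbundanceMatrix(
        values=pd.DataFrame(values, index=protein_ids, columns=sample_ids),
        design=design,
    )
    truth = ProteomeTruth(
        protein_ids=protein_ids,
        core_flags=pd.Series(core, index=protein_ids, name="core"),
        planted_log2fc=planted,
        surface_flags=surface,
        loading_factors=loading,
        noise_sd=noise_sd,
    )
    return matrix, truth


def _speckle_disk(radius: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Static textured cell patch and its boolean mask.

    A bright radial dome (the cell body, the blob a band-pass detector
    keys on) plus fine per-pixel speckle giving the high local variance
    that separates cells from the homogeneous background.
    """
    size = 2 * radius + 1
    yy, xx = np.mgrid[:size, :size] - radius
    rr2 = xx**2 + yy**2
    mask = rr2 <= radius**2
    dome = 80.0 * np.exp(-rr2 / (2.0 * (radius / 2.0) ** 2))
    texture = 100.0 + dome + rng.normal(0.0, 8.0, size=(size, size))
    return np.where(mask, texture, 0.0), mask


def simulate_motility_video(
    n_cells: int = 10,
    frames: int = 40,
    height: int = 512,
    width: int = 512,
    cell_radius: int = 12,
    speed: float = 4.0,
    persistence: float = 0.9,
    drift: tuple = (0.0, 0.0),
    cluster_fraction: float = 0.0,
    noise_sd: float = 2.0,
    background: float = 40.0,
    background_texture_sd: float = 3.0,
    seed: int = 0,
    max_place_tries: int = 2000,
) -> tuple[ImageStack, MotilityTruth]:
    """Render a phase-contrast-like stack of moving textured cells.

    Motion is a persistent random walk with exact step length ``speed``:
    each frame the heading is a weighted blend (weight ``persistence``) of
    the previous heading and a uniform random direction.  Cells reflect at
    the image border; truth records the reflected positions.  Cells in the
    cluster fraction are placed touching a partner and co-move with it so
    the pair stays merged.  Global ``drift`` (dx, dy) px/frame shifts the
    rendered scene only; truth tracks are drift-free.

    The background carries a frozen spatial texture (plate debris and
    illumination mottle in a real field) under per-frame temporal noise
    of ``noise_sd``; like everything in the field of view, the texture
    moves with the stage drift, which keeps translation registration
    well-posed exactly as it is on real data.
    """
    if frames < 5:
        raise ValueError("frames must be >= 5")
    if cell_radius < 3:
        raise ValueError("cell_radius must be >= 3 px")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    margin = cell_radius + 2
    if height <= 2 * margin or width <= 2 * margin:
        raise ValueError("image too small for the requested cell radius")

    rng = np.random.default_rng(seed)
    n_cluster = int(round(cluster_fraction * n_cells))
    if n_cluster == 1:
        n_cluster = 2  # a cluster needs a partner

    # --- placement: non-overlapping positions; cluster members touch a partner
    positions = np.zeros((n_cells, 2))
    placed = 0
    tries = 0
    min_sep = 2.0 * cell_radius + 2.0
    while placed < n_cells:
        tries += 1
        if tries > max_place_tries:
            raise ValueError("could not place cells without overlap; reduce n_cells")
        if placed > 0 and placed < n_cluster:
            # attach to the previous cluster member, touching
            ang = rng.uniform(0, 2 * np.pi)
            cand = positions[placed - 1] + 1.8 * cell_radius * np.array(
                [np.cos(ang), np.sin(ang)]
            )
            others = positions[: max(placed - 1, 0)] if placed > 1 else np.empty((0, 2))
        else:
            cand = rng.uniform([margin, margin], [width - margin, height - margin])
            others = positions[:placed]
        if not (margin <= cand[0] <= width - margin and margin <= cand[1] <= height - margin):
            continue
        if others.size and (np.linalg.norm(others - cand, axis=1) < min_sep).any():
            if placed >= n_cluster:  # cluster members are allowed near each other
                continue
            if others.size and (
                np.linalg.norm(others - cand, axis=1) < 1.2 * cell_radius
            ).any():
                continue
        positions[placed] = cand
        placed += 1

    cluster_ids = list(range(n_cluster))
    headings = rng.uniform(0, 2 * np.pi, size=n_cells)
    if n_cluster:
        headings[:n_cluster] = headings[0]  # cluster co-moves

    patches = [_speckle_disk(cell_radius, rng) for _ in range(n_cells)]
    bg_texture = rng.normal(0.0, background_texture_sd, size=(height, width))

    track_rows = []
    stack = np.zeros((frames, height, width), dtype=np.float64)
    pos = positions.copy()
    for t in range(frames):
        # render at drifted positions; the frozen texture drifts too
        ox, oy = drift[0] * t, drift[1] * t
        if ox == 0 and oy == 0:
            tex = bg_texture
        else:
            tex = ndi.shift(bg_texture, (oy, ox), order=1, mode="grid-wrap")
        frame = background + tex + rng.normal(0.0, noise_sd, size=(height, width))
        for i in range(n_cells):
            track_rows.append(
                {"cell_id": i, "frame": t, "x": float(pos[i, 0]), "y": float(pos[i, 1])}
            )
            cx = int(round(pos[i, 0] + ox))
            cy = int(round(pos[i, 1] + oy))
            patch, mask = patches[i]
            r = cell_radius
            y0, y1 = cy - r, cy + r + 1
            x0, x1 = cx - r, cx + r + 1
            py0, px0 = max(0, -y0), max(0, -x0)
            y0, x0 = max(0, y0), max(0, x0)
            y1, x1 = min(height, y1), min(width, x1)
            if y1 <= y0 or x1 <= x0:
                continue
            sub_mask = mask[py0 : py0 + (y1 - y0), px0 : px0 + (x1 - x0)]
            sub_patch = patch[py0 : py0 + (y1 - y0), px0 : px0 + (x1 - x0)]
            region = frame[y0:y1, x0:x1]
            region[sub_mask] = sub_patch[sub_mask]
        stack[t] = frame
        if t == frames - 1:
            break
        # advance the persistent walk
        turn = rng.uniform(0, 2 * np.pi, size=n_cells)
        if n_cluster:
            turn[:n_cluster] = turn[0]
        vx = persistence * np.cos(headings) + (1 - persistence) * np.cos(turn)
        vy = persistence * np.sin(headings) + (1 - persistence) * np.sin(turn)
        norm = np.hypot(vx, vy)
        norm[norm == 0] = 1.0
        headings = np.arctan2(vy / norm, vx / norm)
        step = speed
        pos[:, 0] += step * np.cos(headings)
        pos[:, 1] += step * np.sin(headings)
        # reflect at borders (keep full disk inside the frame)
        for dim, bound in ((0, width), (1, height)):
            low, high = margin, bound - margin
            below = pos[:, dim] < low
            above = pos[:, dim] > high
            pos[below, dim] = 2 * low - pos[below, dim]
            pos[above, dim] = 2 * high - pos[above, dim]
            flip = below | above
            if flip.any():
                if dim == 0:
                    headings[flip] = np.pi - headings[flip]
                else:
                    headings[flip] = -headings[flip]

    truth = MotilityTruth(
        tracks=pd.DataFrame(track_rows, columns=["cell_id", "frame", "x", "y"]),
        cell_radius=float(cell_radius),
        speeds=pd.Series(speed, index=range(n_cells), name="speed"),
        drift=tuple(drift),
        cluster_ids=cluster_ids,
    )
    return ImageStack(frames=stack, frame_interval=20.0), truth
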