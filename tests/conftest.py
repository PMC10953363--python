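import numpy as np
import pandas as pd
import pytest

import polarscope as ps


@pytest.fixture(scope="session")
def canonical_video():
    """Low-density motility video with ground truth (10 cells, 40 frames)."""
    return ps.simulate_motility_video(
        n_cells=10,
        frames=40,
        height=512,
        width=512,
        cell_radius=12,
        speed=4.0,
        persistence=0.9,
        seed=3,
    )


@pytest.fixture(scope="session")
def canonical_labels(canonical_video):
    stack, _ = canonical_video
    return ps.segment_stack(stack)


@pytest.fixture(scope="session")
def canonical_tracks(canonical_labels):
    return ps.link_tracks(canonical_labels.object_table)


@pytest.fixture(scope="session")
def planted_proteome():
    """Planted abundance matrix (1000 proteins, half core) plus pipeline result."""
    matrix, truth = ps.simulate_proteome(
        n_proteins=1000,
        frac_core=0.5,
        effect_log2fc=2.0,
        noise_sd=0.3,
        n_replicates=3,
        seed=7,
    )
    result = ps.run_proteome_pipeline(matrix)
    return matrix, truth, result


@pytest.fixture
def tiny_matrix():
    """4 proteins x 4 samples (2 controls, M1 + M2a), hand-checkable."""
    values = pd.DataFrame(
        {
            "c1": [4.0, 2.0, 1.0, 1.0],
            "c2": [4.0, 2.0, 1.0, 1.0],
            "s1": [16.0, 2.0, 1.0, 0.5],
            "s2": [4.0, 8.0, 1.0, 2.0],
        },
        index=["pA", "pB", "pC", "pD"],
    )
    design = pd.DataFrame(
        {
            "subtype": ["M0", "M0", "M1", "M2a"],
            "donor": ["d1", "d2", "d1", "d1"],
            "is_control": [True, True, False, False],
        },
        index=pd.Index(["c1", "c2", "s1", "s2"], name="sample_id"),
    )
    return ps.AbundanceMatrix(values=values, design=design)


def random_abundance(n_proteins, n_samples, n_controls, rng):
    """Random strictly positive abundance matrix for oracle comparisons."""
    values = pd.DataFrame(
        rng.lognormal(5, 1, size=(n_proteins, n_samples)),
        index=[f"p{i}" for i in range(n_proteins)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    subtypes = ["M0"] * n_controls + [
        f"T{(j - n_controls) % 2}" for j in range(n_controls, n_samples)
    ]
    design = pd.DataFrame(
        {
            "subtype": subtypes,
            "donor": [f"d{j}" for j in range(n_samples)],
            "is_control": [j < n_controls for j in range(n_samples)],
        },
        index=pd.Index(values.columns, name="sample_id"),
    )
    return ps.AbundanceMatrix(values=values, design=design)
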