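"""TMT proteome processing: normalization, fold changes, polarity classification.

The processing chain mirrors the standard isobaric-label workflow for
comparing polarized macrophage subtypes against an unstimulated (MØ)
control:

1. total-abundance normalization per sample (absorbs loading differences),
2. log2 fold change of every non-control sample against the mean of the
   control samples,
3. per-sample median centering of the log2 values,
4. aggregation to per-subtype mean log2FC across donors,
5. threshold classification into up / down / unchanged, from which the
   *core proteome* (unchanged in every subtype) and the differential
   complement are derived,
6. optional restriction to a cell-surface atlas (surfaceome filtering),
7. hierarchical clustering leaf order and PCA scores for visualisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist

__all__ = [
    "AbundanceMatrix",
    "FoldChangeMatrix",
    "PolarityCallTable",
    "SurfaceAtlas",
    "normalize_total_abundance",
    "log2_fold_change_vs_control",
    "median_center",
    "mean_by_subtype",
    "classify_polarity",
    "core_proteome",
    "differential_proteome",
    "venn_overlap",
    "filter_surface",
    "hierarchical_order",
    "pca_scores",
    "run_proteome_pipeline",
]

UP, DOWN, UNCHANGED = "up", "down", "unchanged"

_DESIGN_COLUMNS = ("subtype", "donor", "is_control")


@dataclass
class AbundanceMatrix:
    """Protein abundances (proteins x samples) plus the sample design.

    ``values`` rows are indexed by protein identifier, columns by sample
    identifier.  ``design`` is indexed by sample identifier and carries
    ``subtype``, ``donor`` and ``is_control`` columns.
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate protein identifiers: {dupes}")
        missing = [c for c in _DESIGN_COLUMNS if c not in self.design.columns]
        if missing:
            raise ValueError(f"design is missing columns: {missing}")
        unmapped = [s for s in self.values.columns if s not in self.design.index]
        if unmapped:
            raise ValueError(f"samples absent from design: {unmapped}")
        if self.design.loc[self.values.columns, "subtype"].isna().any():
            raise ValueError("every sample must have a subtype label")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("abundances must be nonnegative")

    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def control_samples(self) -> list[str]:
        d = self.design.loc[self.values.columns]
        return list(d.index[d["is_control"].astype(bool)])

    @property
    def noncontrol_samples(self) -> list[str]:
        d = self.design.loc[self.values.columns]
        return list(d.index[~d["is_control"].astype(bool)])


@dataclass
class FoldChangeMatrix:
    """log2 fold changes vs. the averaged controls.

    ``log2fc`` is proteins x non-control samples.  ``subtype_means``
    (proteins x subtypes) is populated by :func:`mean_by_subtype`.
    ``dropped`` lists proteins removed because their control mean was zero.
    """

    log2fc: pd.DataFrame
    design: pd.DataFrame
    centered: bool = False
    subtype_means: pd.DataFrame | None = None
    dropped: list = field(default_factory=list)
    completeness: pd.DataFrame | None = None


@dataclass
class PolarityCallTable:
    """Per protein x subtype call in {up, down, unchanged}."""

    calls: pd.DataFrame
    up_threshold: float = 1.0
    down_threshold: float = -1.0
    boundary_inclusive: bool = True

    def counts(self) -> pd.DataFrame:
        """Counts of up / down / unchanged per subtype."""
        return self.calls.apply(lambda c: c.value_counts()).reindex(
            [UP, DOWN, UNCHANGED]
        ).fillna(0).astype(int)


@dataclass
class SurfaceAtlas:
    """Whitelist of cell-surface protein identifiers (CSPA-style).

    Matching is case-insensitive on whatever namespace the identifiers
    use (gene symbols by default).
    """

    identifiers: frozenset
    source_label: str = "surface atlas"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "identifiers", frozenset(str(i).upper() for i in self.identifiers)
        )

    def __contains__(self, identifier: str) -> bool:
        return str(identifier).upper() in self.identifiers

    def __len__(self) -> int:
        return len(self.identifiers)


def normalize_total_abundance(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Scale every sample so all column totals equal the mean original total.

    Preserves within-sample proportions exactly; equal-total input is a
    fixed point.
    """
    totals = matrix.values.sum(axis=0)
    zero = totals.index[totals <= 0].tolist()
    if zero:
        raise ValueError(f"zero total abundance in sample(s): {zero}")
    target = float(totals.mean())
    scaled = matrix.values * (target / totals)
    return AbundanceMatrix(values=scaled, design=matrix.design)


def log2_fold_change_vs_control(matrix: AbundanceMatrix) -> FoldChangeMatrix:
    """log2(sample / mean of control samples) for every non-control sample.

    Proteins whose control mean is zero cannot be referenced and are
    dropped; their identifiers are kept in ``dropped``.  Zero abundances in
    non-control samples become missing (NaN) rather than -inf.
    """
    controls = matrix.control_samples
    if not controls:
        raise ValueError("no control samples in design; cannot form fold changes")
    ctrl_mean = matrix.values[controls].mean(axis=1)
    keep = ctrl_mean > 0
    dropped = list(matrix.values.index[~keep])
    values = matrix.values.loc[keep, matrix.noncontrol_samples]
    with np.errstate(divide="ignore"):
        log2fc = np.log2(values.div(ctrl_mean[keep], axis=0))
    log2fc = log2fc.replace(-np.inf, np.nan)
    return FoldChangeMatrix(log2fc=log2fc, design=matrix.design, dropped=dropped)


def median_center(fc: FoldChangeMatrix) -> FoldChangeMatrix:
    """Subtract each sample's median log2FC so every column median is zero."""
    if fc.centered:
        raise ValueError("fold-change matrix is already median-centered")
    centered = fc.log2fc - fc.log2fc.median(axis=0, skipna=True)
    return FoldChangeMatrix(
        log2fc=centered, design=fc.design, centered=True, dropped=list(fc.dropped)
    )


def mean_by_subtype(fc: FoldChangeMatrix) -> FoldChangeMatrix:
    """Aggregate replicate columns to per-subtype arithmetic mean log2FC.

    A protein missing in some replicates uses the mean of the finite ones;
    ``completeness`` records how many finite replicates entered each mean.
    """
    design = fc.design.loc[fc.log2fc.columns]
    subtypes = design["subtype"].unique().tolist()
    means, counts = {}, {}
    for st in subtypes:
        cols = list(design.index[design["subtype"] == st])
        if not cols:  # pragma: no cover - unique() precludes this
            raise ValueError(f"subtype {st!r} has no samples")
        block = fc.log2fc[cols]
        means[st] = block.mean(axis=1, skipna=True)
        counts[st] = block.notna().sum(axis=1)
    return FoldChangeMatrix(
        log2fc=fc.log2fc,
        design=fc.design,
        centered=fc.centered,
        subtype_means=pd.DataFrame(means),
        dropped=list(fc.dropped),
        completeness=pd.DataFrame(counts),
    )


def classify_polarity(
    fc: FoldChangeMatrix,
    up_threshold: float = 1.0,
    down_threshold: float = -1.0,
    boundary_inclusive: bool = True,
) -> PolarityCallTable:
    """Call each protein up / down / unchanged per subtype by mean log2FC.

    With the inclusive boundary (default), ``mean >= up_threshold`` is up
    and ``mean <= down_threshold`` is down; strictly-inside means are
    unchanged.
    """
    if fc.subtype_means is None:
        raise ValueError("subtype means not computed; call mean_by_subtype first")
    if up_threshold <= down_threshold:
        raise ValueError(
            f"up_threshold ({up_threshold}) must exceed down_threshold ({down_threshold})"
        )
    m = fc.subtype_means
    if boundary_inclusive:
        up, down = m >= up_threshold, m <= down_threshold
    else:
        up, down = m > up_threshold, m < down_threshold
    calls = pd.DataFrame(UNCHANGED, index=m.index, columns=m.columns)
    calls = calls.mask(up, UP).mask(down, DOWN)
    return PolarityCallTable(
        calls=calls,
        up_threshold=up_threshold,
        down_threshold=down_threshold,
        boundary_inclusive=boundary_inclusive,
    )


def core_proteome(calls: PolarityCallTable) -> pd.Index:
    """Proteins unchanged in every subtype (the stable core proteome)."""
    stable = (calls.calls == UNCHANGED).all(axis=1)
    return calls.calls.index[stable]


def differential_proteome(calls: PolarityCallTable) -> pd.Index:
    """Proteins up or down in at least one subtype (complement of the core)."""
    return calls.calls.index.difference(core_proteome(calls), sort=False)


def venn_overlap(calls: PolarityCallTable) -> dict:
    """Differential-set overlap structure across subtypes.

    Returns ``per_subtype`` (count of differential proteins per subtype),
    ``exact`` (count differential in exactly that subset of subtypes, keyed
    by frozenset) and ``union`` (total differential proteins).  The exact
    counts partition the union.
    """
    subtypes = list(calls.calls.columns)
    if len(subtypes) < 2:
        raise ValueError("venn overlap requires at least 2 subtypes")
    diff = calls.calls != UNCHANGED
    per_subtype = {st: int(diff[st].sum()) for st in subtypes}
    membership = diff.apply(lambda r: frozenset(c for c in subtypes if r[c]), axis=1)
    membership = membership[membership.map(len) > 0]
    exact = membership.value_counts().to_dict()
    exact = {k: int(v) for k, v in exact.items()}
    return {"per_subtype": per_subtype, "exact": exact, "union": int(len(membership))}


def filter_surface(target, atlas: SurfaceAtlas):
    """Restrict proteins to those present in a surface-protein atlas.

    ``target`` may be a :class:`FoldChangeMatrix` (rows restricted) or any
    iterable of identifiers (a filtered list is returned).  Returns
    ``(filtered, report)`` where report is ``{"retained": r, "total": t}``.
    """
    if len(atlas) == 0:
        raise ValueError("surface atlas is empty")
    if isinstance(target, FoldChangeMatrix):
        ids = target.log2fc.index
        keep = np.array([i in atlas for i in ids])
        report = {"retained": int(keep.sum()), "total": int(len(ids))}
        if report["retained"] == 0:
            warnings.warn("no proteins matched the surface atlas", stacklevel=2)
        filtered = FoldChangeMatrix(
            log2fc=target.log2fc.loc[keep],
            design=target.design,
            centered=target.centered,
            subtype_means=(
                None if target.subtype_means is None else target.subtype_means.loc[keep]
            ),
            dropped=list(target.dropped),
        )
        return filtered, report
    ids = list(target)
    kept = [i for i in ids if i in atlas]
    report = {"retained": len(kept), "total": len(ids)}
    if report["retained"] == 0 and report["total"] > 0:
        warnings.warn("no proteins matched the surface atlas", stacklevel=2)
    return kept, report


def hierarchical_order(
    fc: FoldChangeMatrix,
    linkage_method: str = "complete",
    metric: str = "euclidean",
) -> np.ndarray:
    """Leaf order of proteins under agglomerative clustering.

    Clusters the per-subtype mean log2FC profiles (falling back to the
    per-sample matrix when means are absent) and returns the dendrogram
    leaf permutation, the order heatmap rows are drawn in.
    """
    data = fc.subtype_means if fc.subtype_means is not None else fc.log2fc
    x = data.to_numpy(dtype=float)
    if x.shape[0] == 1:
        return np.array([0])
    if not np.isfinite(x).all():
        raise ValueError("non-finite values; aggregate or drop incomplete proteins first")
    z = sch.linkage(pdist(x, metric=metric), method=linkage_method)
    return np.asarray(sch.leaves_list(z))


def pca_scores(fc: FoldChangeMatrix, k: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores on the first ``k`` principal components.

    Samples are observations, proteins features; features are centered
    across samples before the decomposition.  Sign convention: each
    component is flipped so its largest-magnitude protein loading is
    positive, making scores deterministic.  Returns ``(scores,
    explained_variance_ratio)``.
    """
    x = fc.log2fc.to_numpy(dtype=float).T  # samples x proteins
    n = x.shape[0]
    if n < 2:
        raise ValueError("PCA requires at least 2 samples")
    x = x - x.mean(axis=0, keepdims=True)
    if not np.isfinite(x).all():
        raise ValueError("non-finite values; drop incomplete proteins before PCA")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size and s[0] > 0 else 0
    if k > rank:
        warnings.warn(f"k={k} exceeds rank {rank}; truncating", stacklevel=2)
        k = max(rank, 1)
    for j in range(k):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    scores = u[:, :k] * s[:k]
    total_var = (s**2).sum()
    evr = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    cols = [f"PC{j + 1}" for j in range(k)]
    return pd.DataFrame(scores, index=fc.log2fc.columns, columns=cols), evr


def run_proteome_pipeline(
    matrix: AbundanceMatrix,
    up_threshold: float = 1.0,
    down_threshold: float = -1.0,
    boundary_inclusive: bool = True,
    atlas: SurfaceAtlas | None = None,
) -> dict:
    """Full chain: normalize -> log2FC -> center -> aggregate -> classify.

    Returns a dict with the aggregated :class:`FoldChangeMatrix` (``fc``),
    the :class:`PolarityCallTable` (``calls``), ``core`` / ``differential``
    identifier indexes, ``venn`` overlap counts (when >=2 subtypes), and,
    if an atlas is given, the surfaceome-restricted ``surface_fc`` /
    ``surface_calls`` plus the ``surface_report`` retained/total counts.
    """
    fc = mean_by_subtype(
        median_center(log2_fold_change_vs_control(normalize_total_abundance(matrix)))
    )
    calls = classify_polarity(fc, up_threshold, down_threshold, boundary_inclusive)
    out = {
        "fc": fc,
        "calls": calls,
        "core": core_proteome(calls),
        "differential": differential_proteome(calls),
    }
    if calls.calls.shape[1] >= 2:
        out["venn"] = venn_overlap(calls)
    if atlas is not None:
        surface_fc, report = filter_surface(fc, atlas)
        out["surface_fc"] = surface_fc
        out["surface_report"] = report
        if len(surface_fc.log2fc):
            out["surface_calls"] = classify_polarity(
                surface_fc, up_threshold, down_threshold, boundary_inclusive
            )
    return out
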