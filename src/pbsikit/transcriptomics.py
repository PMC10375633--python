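"""Region-level expression processing and spatial association.

Covers scaled-robust-sigmoid normalization, coordinate-based assignment of
expression samples to parcellation regions, region-level aggregation, the
Benjamini-Hochberg step-up FDR procedure, and per-gene Spearman association
between expression and a per-region difference map.

Caveat: associations are plain rank correlations across regions; no
spatial-autocorrelation-preserving null model is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "srs_normalize",
    "assign_samples_to_regions",
    "aggregate_region_expression",
    "bh_fdr",
    "associate_delta_expression",
]


def srs_normalize(values) -> np.ndarray:
    """Scaled robust sigmoid: sigmoid((x - median) / (IQR / 1.35)), min-max
    rescaled to [0, 1]. Monotone; outlier-resistant via median/IQR."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("at least 3 values required")
    if not np.isfinite(x).all():
        raise ValueError("non-finite expression values")
    med = np.median(x)
    iqr = stats.iqr(x)
    if iqr == 0:
        raise ValueError("zero IQR: degenerate distribution, cannot normalize")
    s = 1.0 / (1.0 + np.exp(-(x - med) / (iqr / 1.35)))
    return (s - s.min()) / (s.max() - s.min())


def assign_samples_to_regions(
    sample_coords,
    region_voxels: dict[str, np.ndarray],
    max_distance: float = 3.0,
) -> list[str | None]:
    """Assign each sample to the region with the nearest voxel within
    ``max_distance`` mm (inclusive); ties go to the earlier region in the
    mapping's order. Unassignable samples get ``None``."""
    coords = np.asarray(sample_coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("sample coordinates must be an (n, 3) array")
    if not np.isfinite(coords).all():
        raise ValueError("non-finite sample coordinates")
    if not region_voxels:
        raise ValueError("empty region voxel mapping")
    labels = list(region_voxels)
    voxel_arrays = []
    for lab in labels:
        v = np.asarray(region_voxels[lab], dtype=float)
        if v.size == 0:
            raise ValueError(f"region {lab!r} has an empty voxel set")
        voxel_arrays.append(v.reshape(-1, 3))

    out: list[str | None] = []
    for c in coords:
        best_label, best_d = None, np.inf
        for lab, vox in zip(labels, voxel_arrays):
            d = np.sqrt(((vox - c) ** 2).sum(axis=1)).min()
            if d < best_d:  # strict: ties keep the earlier label
                best_d, best_label = d, lab
        out.append(best_label if best_d <= max_distance else None)
    return out


def aggregate_region_expression(
    sample_expression,
    assignment: list[str | None],
    gene_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Mean expression per region over assigned samples.

    ``sample_expression`` is samples x genes. Returns a genes x regions
    DataFrame (regions in first-assignment order) and the list of samples'
    regions that received no sample is implicit: unassigned samples are
    simply dropped and their count returned via the second element.
    """
    expr = np.asarray(sample_expression, dtype=float)
    if expr.ndim != 2:
        raise ValueError("sample expression must be 2-D (samples x genes)")
    if expr.shape[0] != len(assignment):
        raise ValueError("assignment length must match sample count")
    if gene_ids is None:
        gene_ids = [f"G{i:05d}" for i in range(expr.shape[1])]
    by_region: dict[str, list[int]] = {}
    dropped = []
    for i, lab in enumerate(assignment):
        if lab is None:
            dropped.append(i)
        else:
            by_region.setdefault(lab, []).append(i)
    cols = {lab: expr[idx].mean(axis=0) for lab, idx in by_region.items()}
    df = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    return df, [str(i) for i in dropped]


def bh_fdr(p_values, threshold: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and rejection set.

    q_(i) = min_{j >= i} (m * p_(j) / j), capped at 1; a hypothesis is
    rejected iff its q-value is below ``threshold``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be 1-D")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, q < threshold


@dataclass
class AssociationResult:
    table: pd.DataFrame       # gene_id, rho, p, q, significant
    regions_used: list[str]
    fdr_threshold: float

    @property
    def significant_genes(self) -> list[str]:
        return self.table.loc[self.table["significant"], "gene_id"].tolist()


def _spearman_vs_vector(expr: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-row Spearman of ``expr`` (genes x regions) against
    ``target``; two-sided p via the t approximation. Constant rows get
    rho = nan, p = 1 (never significant)."""
    n = target.size
    tr = stats.rankdata(target)
    tr = (tr - tr.mean()) / tr.std()
    gr = stats.rankdata(expr, axis=1)
    sd = gr.std(axis=1)
    constant = sd == 0
    sd[constant] = 1.0
    gz = (gr - gr.mean(axis=1, keepdims=True)) / sd[:, None]
    rho = gz @ tr / n
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(t), 0.0, p)  # |rho| == 1 -> p = 0
    rho[constant] = np.nan
    p[constant] = 1.0
    return rho, p


def associate_delta_expression(
    delta: pd.Series,
    expression: pd.DataFrame,
    fdr: float = 0.05,
    min_regions: int = 10,
) -> AssociationResult:
    """Per-gene Spearman association between expression and a per-region
    difference map, with BH-FDR control across genes.

    ``delta`` is indexed by region label; ``expression`` is genes x regions.
    The association uses the intersection of region labels.
    """
    if not isinstance(delta, pd.Series):
        raise TypeError("delta must be a pandas Series indexed by region label")
    common = [r for r in expression.columns if r in set(delta.index)]
    if len(common) < min_regions:
        unmatched = sorted(set(expression.columns) ^ set(delta.index))
        raise ValueError(
            f"only {len(common)} common regions (< {min_regions}); "
            f"unmatched labels: {unmatched[:20]}"
        )
    d = delta.loc[common].to_numpy(dtype=float)
    if np.ptp(d) == 0:
        raise ValueError("delta map is constant over the common regions")
    expr = expression.loc[:, common].to_numpy(dtype=float)
    if not np.isfinite(expr).all():
        raise ValueError("non-finite expression values")
    rho, p = _spearman_vs_vector(expr, d)
    q, reject = bh_fdr(p, threshold=fdr)
    table = pd.DataFrame(
        {
            "gene_id": expression.index.astype(str),
            "rho": rho,
            "p": p,
            "q": q,
            "significant": reject,
        }
    ).reset_index(drop=True)
    return AssociationResult(table=table, regions_used=common, fdr_threshold=fdr)
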