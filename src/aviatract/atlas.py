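"""Bundle atlas assembly (Step 3) and line-level group comparison.

Inter-subject clusters are selected into named bundles by anatomical
pass-through constraints (include/exclude region labels on the template
label volume) and aggregated into a population atlas with per-bundle
subject provenance.  Fiber densities per region can be compared between
two selection lines (e.g. short vs long tonic immobility) with Welch
t-tests.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cluster_inter import CentroidSet, InterCluster
from .core import points_to_voxels

__all__ = [
    "ROIConstraint",
    "Bundle",
    "BundleAtlas",
    "select_bundle",
    "assemble_atlas",
    "compare_lines",
]

log = logging.getLogger(__name__)


@dataclass
class ROIConstraint:
    """Anatomical selection rule for one bundle."""

    name: str
    include: list[int]  # label ids the centroid must pass through (all)
    exclude: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.include) & set(self.exclude):
            raise ValueError("include and exclude regions must be disjoint")


@dataclass
class Bundle:
    """A named bundle: the inter-subject clusters selected by one ROI rule."""

    name: str
    clusters: list[InterCluster]
    centroid_indices: np.ndarray
    subjects: np.ndarray
    region: str = ""

    @property
    def n_centroids(self) -> int:
        return int(len(self.centroid_indices))


@dataclass
class BundleAtlas:
    """Population bundle atlas with per-bundle provenance manifest."""

    bundles: list[Bundle]

    def manifest(self) -> dict:
        return {
            b.name: {
                "region": b.region,
                "n_clusters": len(b.clusters),
                "n_centroids": b.n_centroids,
                "subjects": [str(s) for s in b.subjects],
            }
            for b in self.bundles
        }


def select_bundle(
    clusters: list[InterCluster],
    cs: CentroidSet,
    roi: ROIConstraint,
    labels: np.ndarray,
    affine: np.ndarray,
    region: str = "",
) -> Bundle:
    """Select inter-subject clusters whose centroids satisfy an ROI rule.

    A cluster is selected when its member centroids jointly pass through
    every include region (at least one point in each) and no centroid
    point falls in any exclude region.  Selected clusters are merged
    under the bundle name; an empty selection yields an empty bundle
    with a warning.
    """
    labels = np.asarray(labels)
    shape = np.asarray(labels.shape)
    selected: list[InterCluster] = []
    member_idx: list[int] = []
    for cl in clusters:
        hit = set()
        excluded = False
        for i in cl.member_indices:
            vox = np.clip(points_to_voxels(cs.points[i], affine), 0, shape - 1)
            lab = labels[vox[:, 0], vox[:, 1], vox[:, 2]]
            hit.update(np.unique(lab).tolist())
            if np.isin(lab, roi.exclude).any():
                excluded = True
                break
        if excluded:
            continue
        if all(r in hit for r in roi.include):
            selected.append(cl)
            member_idx.extend(cl.member_indices.tolist())
    if not selected:
        log.warning("select_bundle: no cluster matched ROI constraint '%s'", roi.name)
    subs = (
        np.unique(cs.subject_ids[np.asarray(member_idx, dtype=int)])
        if member_idx
        else np.asarray([])
    )
    return Bundle(roi.name, selected, np.asarray(sorted(member_idx), dtype=int), subs, region)


def assemble_atlas(bundles: list[Bundle]) -> BundleAtlas:
    """Aggregate named bundles into the population atlas."""
    names = [b.name for b in bundles]
    if len(set(names)) != len(names):
        raise ValueError("bundle names must be unique")
    seen: dict[int, str] = {}
    for b in bundles:
        for i in b.centroid_indices:
            if i in seen:
                log.info(
                    "assemble_atlas: centroid %d in bundles '%s' and '%s'",
                    i, seen[i], b.name,
                )
            seen[int(i)] = b.name
    return BundleAtlas(list(bundles))


def compare_lines(
    densities: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Welch two-sample t-tests of per-region fiber densities between lines.

    ``densities`` needs columns ``subject``, ``line`` (two levels, e.g.
    STI/LTI), ``region`` and ``density`` (fibers per in-mask voxel).
    Returns one row per region with the t statistic, the two-sided p
    value and a significance flag at ``alpha``.
    """
    lines = sorted(densities["line"].unique())
    if len(lines) != 2:
        raise ValueError("exactly two lines are required")
    rows = []
    for region, grp in densities.groupby("region", sort=True):
        a = grp.loc[grp["line"] == lines[0], "density"].to_numpy(dtype=float)
        b = grp.loc[grp["line"] == lines[1], "density"].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"region '{region}': both groups need >= 2 subjects")
        t, pval = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "region": region,
                "line_a": lines[0],
                "line_b": lines[1],
                "mean_a": a.mean(),
                "mean_b": b.mean(),
                "t": float(t),
                "p": float(pval),
                "significant": bool(pval < alpha),
            }
        )
    return pd.DataFrame(rows)
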