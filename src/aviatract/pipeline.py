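"""End-to-end synthetic pipeline driver.

Runs phantom generation, denoising, local modeling, SRD tractography,
the pooled length window, both clustering levels and atlas assembly for
a cohort of synthetic subjects, fully deterministic given the root seed
(stage seeds are derived by stage-name hashing).
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import BundleAtlas, ROIConstraint, assemble_atlas, select_bundle
from .cluster_inter import (
    CentroidSet,
    affinity_matrix,
    hdbscan_interclusters,
    presence_filter,
)
from .cluster_intra import Centroid, cluster_subject, split_by_region
from .config import PipelineConfig, derive_seed
from .core import Tractogram
from .gradients import make_gradient_scheme
from .local_models import fit_aqbi, gfa_map, percentile_threshold
from .phantom import (
    REGION_CBL,
    REGION_INT,
    REGION_LH,
    REGION_RH,
    GroundTruth,
    build_phantom,
    default_phantom_spec,
    simulate_dwi,
)
from .preprocess import DWIStack, nlm_denoise
from .tracking import population_length_window, seed_voxels, track_srd

__all__ = ["RunLog", "PipelineResult", "run_pipeline", "region_fiber_densities"]

log = logging.getLogger(__name__)

_REGION_CODE = {"LH": REGION_LH, "RH": REGION_RH, "INT": REGION_INT, "CBL": REGION_CBL}


@dataclass
class RunLog:
    """Structured per-stage records (counts in/out, discards, seeds)."""

    records: list[dict] = field(default_factory=list)

    def add(self, stage: str, **fields) -> None:
        self.records.append({"stage": stage, **fields})

    def to_json(self, path=None) -> str:
        s = json.dumps(self.records, indent=2, default=str)
        if path is not None:
            Path(path).write_text(s)
        return s


@dataclass
class PipelineResult:
    """Everything the synthetic end-to-end run produces."""

    atlas: BundleAtlas
    runlog: RunLog
    centroid_set: CentroidSet
    length_window: tuple[float, float]
    gfa_threshold: float
    tractograms: list[Tractogram]
    truths: list[GroundTruth]
    centroids_per_subject: list[list[Centroid]]

    def signature(self) -> str:
        """Hash of the atlas manifest and all centroid coordinates.

        Bit-identical reruns under the same config produce the same
        signature.
        """
        h = hashlib.sha256()
        h.update(json.dumps(self.atlas.manifest(), sort_keys=True).encode())
        h.update(np.ascontiguousarray(self.centroid_set.points).tobytes())
        return h.hexdigest()


def _subject_spec(config: PipelineConfig, s: int):
    spec = default_phantom_spec(
        seed=derive_seed(config.seed, f"phantom:{s}"), snr=config.snr
    )
    return replace(spec, grid_shape=tuple(config.grid_shape), voxel_size=config.voxel_size)


def run_pipeline(config: PipelineConfig | None = None, output_dir=None) -> PipelineResult:
    """Run the full synthetic cohort pipeline.

    The tracking regularization factor is recomputed as the cohort
    average of each subject's 98th GFA percentile, mirroring the way the
    published factor (0.12) was obtained.
    """
    config = config or PipelineConfig()
    runlog = RunLog()
    scheme = make_gradient_scheme(
        config.acquisition.n_dirs,
        config.acquisition.n_b0,
        config.acquisition.b,
        seed=derive_seed(config.seed, "scheme"),
    )
    runlog.add("scheme", n_volumes=len(scheme), b=scheme.b)

    truths: list[GroundTruth] = []
    odfs = []
    gfas = []
    thresholds = []
    for s in range(config.n_subjects):
        spec = _subject_spec(config, s)
        truth = build_phantom(spec)
        data = simulate_dwi(truth, spec, scheme)
        dwi = DWIStack(data, spec.affine, scheme, truth.brain_mask)
        dwi = nlm_denoise(
            dwi,
            patch_radius=config.denoise.patch_radius,
            search_radius=config.denoise.search_radius,
        )
        odf = fit_aqbi(dwi, config.model.sh_order, config.model.sh_lambda)
        gfa = gfa_map(odf)
        thr = percentile_threshold(gfa, truth.brain_mask, config.model.gfa_percentile)
        truths.append(truth)
        odfs.append(odf)
        gfas.append(gfa)
        thresholds.append(thr)
        runlog.add(
            "model", subject=s, n_mask_voxels=int(truth.brain_mask.sum()), gfa_p98=thr
        )

    theta = float(np.mean(thresholds))
    runlog.add("gfa_threshold", cohort_mean_p98=theta)

    tractograms: list[Tractogram] = []
    for s in range(config.n_subjects):
        params = replace(
            config.tracking,
            gfa_reg_threshold=theta,
            rng_seed=derive_seed(config.seed, f"seeds:{s}"),
        )
        seeds = seed_voxels(truths[s].brain_mask, config.voxel_size, params)
        t = track_srd(odfs[s], gfas[s], truths[s].brain_mask, seeds, params)
        t.provenance["subject"] = s
        tractograms.append(t)
        runlog.add(
            "track", subject=s, n_seeds=len(seeds), n_streamlines=len(t),
            n_dropped=t.provenance["n_dropped"],
        )

    window = population_length_window(tractograms, *config.length_window_pcts)
    runlog.add("length_window", l_min=window[0], l_max=window[1])

    all_centroids: list[Centroid] = []
    subject_of_centroid: list[int] = []
    centroids_per_subject: list[list[Centroid]] = []
    for s in range(config.n_subjects):
        clusters, centroids = cluster_subject(
            tractograms[s],
            truths[s].region_labels,
            window,
            n_ranges=config.intra.n_length_ranges,
            min_density=config.intra.min_density_fibers,
            mean_parcel_size=config.intra.mean_parcel_size,
            dendrogram_cut=config.intra.dendrogram_cut,
            min_frac=config.intra.min_fiber_fraction,
            min_members=config.intra.min_cluster_members,
            centroid_resample=config.intra.centroid_resample,
            subject_id=str(s),
            seed=derive_seed(config.seed, f"intra:{s}"),
        )
        centroids_per_subject.append(centroids)
        all_centroids.extend(centroids)
        subject_of_centroid.extend([s] * len(centroids))
        runlog.add("cluster_intra", subject=s, n_clusters=len(clusters))

    # identity registration: the synthetic cohort shares the template grid
    cs = CentroidSet.from_streamlines(
        [c.points for c in all_centroids],
        np.asarray(subject_of_centroid),
        n_points=config.inter.n_points,
        regions=np.asarray([c.cluster.region for c in all_centroids]),
        cluster_refs=list(all_centroids),
    )
    aff = affinity_matrix(cs, config.inter)
    inter = hdbscan_interclusters(aff, cs, config.inter)
    kept = presence_filter(inter, config.n_subjects, config.inter)
    runlog.add("cluster_inter", n_centroids=len(cs), n_clusters=len(inter), n_kept=len(kept))

    spec0 = _subject_spec(config, 0)
    rois = [
        ROIConstraint(b.name, include=[_REGION_CODE[b.region]]) for b in spec0.bundles
    ]
    labels = truths[0].region_labels
    bundles = [
        select_bundle(kept, cs, roi, labels, truths[0].affine, region=spec0.bundles[i].region)
        for i, roi in enumerate(rois)
    ]
    bundles = [b for b in bundles if b.n_centroids > 0]
    atlas = assemble_atlas(bundles)
    runlog.add("atlas", n_bundles=len(atlas.bundles))

    result = PipelineResult(
        atlas, runlog, cs, window, theta, tractograms, truths, centroids_per_subject
    )
    if output_dir is not None:
        _write_outputs(result, config, Path(output_dir))
    return result


def _write_outputs(result: PipelineResult, config: PipelineConfig, outdir: Path) -> None:
    from .io import save_tractogram

    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "atlas_manifest.json").write_text(
        json.dumps(result.atlas.manifest(), indent=2)
    )
    result.runlog.to_json(outdir / "runlog.json")
    shape = tuple(config.grid_shape)
    for b in result.atlas.bundles:
        t = Tractogram(
            [result.centroid_set.points[i] for i in b.centroid_indices],
            result.tractograms[0].affine,
            {"bundle": b.name},
        )
        save_tractogram(outdir / f"bundle_{b.name}.trk", t, shape)


def region_fiber_densities(
    tractograms: list[Tractogram],
    region_labels_per_subject: list[np.ndarray],
    masks: list[np.ndarray],
    lines: list[str],
) -> pd.DataFrame:
    """Per-subject, per-region fiber densities (fibers per in-mask voxel).

    Output is the long-format table consumed by
    :func:`aviatract.atlas.compare_lines`.
    """
    rows = []
    for s, (t, labels, mask) in enumerate(
        zip(tractograms, region_labels_per_subject, masks)
    ):
        part = split_by_region(t, labels)
        for region, fidx in part.subsets.items():
            code = _REGION_CODE[region]
            n_vox = int(((labels == code) & mask).sum())
            if region == "INT":  # interhemispheric fibers span both hemispheres
                n_vox = int(mask.sum())
            rows.append(
                {
                    "subject": s,
                    "line": lines[s],
                    "region": region,
                    "density": len(fidx) / max(n_vox, 1),
                }
            )
    return pd.DataFrame(rows)
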