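"""Pipeline configuration: every stage parameter in one serializable object.

Defaults reproduce the published processing chain: 75+5 volumes at
b = 4500 s/mm², SH order 8 with lambda = 0.006, 8 seeds/voxel, 30°
aperture, 50 µm step, regularization factor 0.12, [0.1, 100] mm length
range, 2/98% pooled length window with 8 ranges, 5-fiber density
threshold, 27-voxel parcels, 31% trajectory fraction, 5-member minimum,
and the 21-point / nf 4.0 / CAMD 2.0 / sigma² 1600 / 0.01 / 0.4 / 50%
inter-subject settings.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

from .cluster_inter import InterParams
from .tracking import TrackingParams

__all__ = ["IntraParams", "PipelineConfig", "derive_seed"]


def derive_seed(root_seed: int, stage: str) -> int:
    """Stage seed derived from the root seed by stage-name hashing (< 2^31)."""
    h = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") & 0x7FFFFFFF


@dataclass
class IntraParams:
    """Step-1 (intra-subject) clustering parameters."""

    n_length_ranges: int = 8
    min_density_fibers: int = 5
    mean_parcel_size: int = 27
    dendrogram_cut: float = 0.9
    min_fiber_fraction: float = 0.31
    min_cluster_members: int = 5
    centroid_resample: int = 21
    # Inert caps on density-mask size per clustering unit; off by default.
    max_unit_voxels: int | None = None
    min_unit_voxels: int | None = None


@dataclass
class AcquisitionParams:
    """Synthetic acquisition geometry (single-shell HARDI)."""

    n_dirs: int = 75
    n_b0: int = 5
    b: float = 4500.0


@dataclass
class DenoiseParams:
    patch_radius: int = 1
    search_radius: int = 3
    h_factor: float = 1.5  # h = h_factor * estimated sigma


@dataclass
class ModelParams:
    sh_order: int = 8
    sh_lambda: float = 0.006
    gfa_percentile: float = 98.0


@dataclass
class PipelineConfig:
    """All stage parameters plus seeds for the end-to-end synthetic run."""

    n_subjects: int = 6
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size: float = 0.2
    snr: float | None = 30.0
    seed: int = 0
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    denoise: DenoiseParams = field(default_factory=DenoiseParams)
    model: ModelParams = field(default_factory=ModelParams)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    length_window_pcts: tuple[float, float] = (2.0, 98.0)
    intra: IntraParams = field(default_factory=IntraParams)
    inter: InterParams = field(default_factory=InterParams)

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as f:
                f.write(s)
        return s

    @classmethod
    def from_json(cls, source) -> "PipelineConfig":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            d = json.loads(source)
        else:
            with open(source) as f:
                d = json.load(f)
        return cls(
            n_subjects=d["n_subjects"],
            grid_shape=tuple(d["grid_shape"]),
            voxel_size=d["voxel_size"],
            snr=d["snr"],
            seed=d["seed"],
            acquisition=AcquisitionParams(**d["acquisition"]),
            denoise=DenoiseParams(**d["denoise"]),
            model=ModelParams(**d["model"]),
            tracking=TrackingParams(
                **{**d["tracking"], "length_range": tuple(d["tracking"]["length_range"])}
            ),
            length_window_pcts=tuple(d["length_window_pcts"]),
            intra=IntraParams(**d["intra"]),
            inter=InterParams(**d["inter"]),
        )
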