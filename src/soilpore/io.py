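"""Reading and writing volumes, masks, configs, and provenance records.

Grayscale volumes and label masks travel as multi-page TIFF (one page per
z-slice) — the export format of scanner reconstruction software — either a
single file or a directory of per-slice TIFFs ordered by their numeric
suffix.  Ground truth, configuration and provenance are JSON/YAML sidecars.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .volume import GrayscaleVolume, Phase, PhaseMask

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "PipelineConfig",
    "write_provenance",
]

_SLICE_INDEX = re.compile(r"(\d+)(?=\.[^.]+$)")


def _slice_files(directory: Path) -> list[Path]:
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
    if not files:
        raise FileNotFoundError(f"no TIFF slices in {directory}")
    indexed = []
    for p in files:
        m = _SLICE_INDEX.search(p.name)
        if not m:
            raise ValueError(f"slice file {p.name} has no numeric index before its extension")
        indexed.append((int(m.group(1)), p))
    indexed.sort()
    indices = [i for i, _ in indexed]
    expected = list(range(indices[0], indices[0] + len(indices)))
    if indices != expected:
        missing = sorted(set(expected) - set(indices))
        raise ValueError(f"slice index gap in {directory}: missing indices {missing}")
    return [p for _, p in indexed]


def read_volume(path: "str | Path", voxel_size_um: float, bit_depth: "int | None" = None) -> GrayscaleVolume:
    """Read a multi-page TIFF or a directory of per-slice TIFFs.

    The voxel size always comes from the caller/config, never TIFF tags;
    if resolution tags are present and disagree, a warning is raised.
    Mixed slice shapes or dtypes in a directory are an error listing the
    offending files.
    """
    path = Path(path)
    if path.is_dir():
        files = _slice_files(path)
        slices = [tifffile.imread(f) for f in files]
        shapes = {s.shape for s in slices}
        dtypes = {s.dtype for s in slices}
        if len(shapes) > 1 or len(dtypes) > 1:
            offenders = [
                f"{f.name}: shape={s.shape} dtype={s.dtype}" for f, s in zip(files, slices)
            ]
            raise ValueError("inconsistent slices:\n" + "\n".join(offenders))
        data = np.stack(slices, axis=0)
    else:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        _warn_on_tag_mismatch(path, voxel_size_um)
    if data.dtype == np.uint8:
        depth = 8
    elif data.dtype == np.uint16:
        depth = 16
    else:
        raise ValueError(f"unsupported TIFF dtype {data.dtype}; need uint8 or uint16")
    if bit_depth is not None and bit_depth != depth:
        raise ValueError(f"config bit_depth {bit_depth} != TIFF dtype ({depth}-bit)")
    return GrayscaleVolume(data, voxel_size_um, depth, {"source": str(path)})


def _warn_on_tag_mismatch(path: Path, voxel_size_um: float) -> None:
    try:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            res = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
            if res is None or unit is None:
                return
            num, den = res.value
            if num == 0:
                return
            unit_um = {2: 25400.0, 3: 10000.0}.get(int(getattr(unit.value, "value", unit.value)))
            if unit_um is None:
                return
            tag_vox = den / num * unit_um
            if abs(tag_vox - voxel_size_um) / voxel_size_um > 0.01:
                warnings.warn(
                    f"TIFF resolution tag implies {tag_vox:.3f} µm/voxel but config says "
                    f"{voxel_size_um:.3f}; using the config value"
                )
    except Exception:  # malformed tags never block reading
        return


def write_volume(v: GrayscaleVolume, path: "str | Path") -> Path:
    """Write a grayscale volume as a multi-page TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(v.voxels))
    return path


def write_mask(mask: PhaseMask, path: "str | Path") -> Path:
    """Write a phase mask as 8-bit TIFF plus a JSON label-legend sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, mask.labels)
    legend = {p.name.lower(): int(p.value) for p in Phase}
    sidecar = path.with_suffix(".labels.json")
    sidecar.write_text(json.dumps({"legend": legend, "voxel_size_um": mask.voxel_size_um,
                                   "meta": _jsonable(mask.meta)}, indent=2))
    return path


def read_mask(path: "str | Path") -> PhaseMask:
    path = Path(path)
    labels = tifffile.imread(path)
    sidecar = path.with_suffix(".labels.json")
    info = json.loads(sidecar.read_text())
    return PhaseMask(labels, info["voxel_size_um"], info.get("meta", {}))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs; loadable from YAML."""

    input: "str | None" = None          # TIFF path/dir; None when a phantom spec is given
    input_after: "str | None" = None    # optional paired after-growth scan
    voxel_size_um: float = 18.2
    bulk_density_g_cm3: "float | None" = None
    particle_density_g_cm3: float = 2.6
    # preprocessing
    background_degree: int = 3
    median_radius_vox: int = 2
    saturated_pct: float = 0.6
    roi_size_vox: "tuple[int, int, int] | None" = None
    # segmentation
    t_low: "float | None" = None
    t_high: "float | None" = None
    window_vox: int = 2
    stone_t: "float | None" = None
    stone_min_volume_mm3: float = 10.0
    # PSD
    psd_max_radius_um: float = 150.0
    # POM (section optional: None disables the POM stage)
    pom_t_low: "float | None" = None
    pom_t_high: "float | None" = None
    pom_open_steps: int = 2
    pom_gauss_sigma_vox: float = 1.0
    pom_min_volume_mm3: float = 0.018
    pom_match_radius_mm: float = 0.5
    shell_distances_mm: tuple[float, ...] = (1.0, 5.0, 8.0)
    # run
    output_dir: str = "soilpore_out"
    seed: int = 0

    def validate(self) -> None:
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be > 0")
        if self.bulk_density_g_cm3 is not None and not (
            0 < self.bulk_density_g_cm3 < self.particle_density_g_cm3
        ):
            raise ValueError("bulk density must lie in (0, particle density)")
        if self.input is not None and not Path(self.input).exists():
            raise FileNotFoundError(self.input)
        if self.input_after is not None and not Path(self.input_after).exists():
            raise FileNotFoundError(self.input_after)

    @property
    def pom_enabled(self) -> bool:
        return self.pom_t_low is not None and self.pom_t_high is not None

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.roi_size_vox is not None:
            cfg.roi_size_vox = tuple(int(x) for x in cfg.roi_size_vox)
        cfg.shell_distances_mm = tuple(float(x) for x in cfg.shell_distances_mm)
        return cfg

    def to_dict(self) -> dict:
        return _jsonable(asdict(self))


def write_provenance(config: PipelineConfig, out_dir: "str | Path", extra: "dict | None" = None) -> Path:
    """Machine-readable record of a run: config, package version, seed."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    record = {
        "package": "soilpore",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
    }
    if extra:
        record.update(_jsonable(extra))
    path = out / "provenance.json"
    path.write_text(json.dumps(record, indent=2, sort_keys=True))
    return path
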