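"""End-to-end pipeline: preprocess → segment → pore metrics → POM.

Given a :class:`~soilpore.io.PipelineConfig`, :func:`run_pipeline` executes
every stage in the fixed order, logs parameters, and writes deterministic
CSV reports (headers carry units) plus a provenance record.  A paired
after-growth scan additionally produces the fragment-matched decomposition
table.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import io, pom as pom_mod, pore_metrics, preprocess, segment
from .volume import GrayscaleVolume, Phase, PhaseMask

__all__ = ["run_pipeline", "analyze_volume"]

log = logging.getLogger(__name__)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        return wrapper
    return deco


@_stage("preprocess")
def _preprocess(vol: GrayscaleVolume, cfg: io.PipelineConfig) -> GrayscaleVolume:
    return preprocess.preprocess_chain(
        vol,
        degree=cfg.background_degree,
        median_radius=cfg.median_radius_vox,
        saturated_pct=cfg.saturated_pct,
        roi_size_vox=cfg.roi_size_vox,
    )


@_stage("segment")
def _segment(vol: GrayscaleVolume, cfg: io.PipelineConfig) -> PhaseMask:
    params = segment.SegmentationParams(
        t_low=cfg.t_low,
        t_high=cfg.t_high,
        window_vox=cfg.window_vox,
        stone_t=cfg.stone_t,
        stone_min_volume_mm3=cfg.stone_min_volume_mm3,
    )
    mask = segment.segment_solid_pore(vol, params)
    mask = segment.segment_stones(vol, params, base=mask)
    return segment.stone_free_basis(mask)


def analyze_volume(vol: GrayscaleVolume, cfg: io.PipelineConfig):
    """Preprocess, segment and measure one scan; returns (processed, mask,
    PoreSummary, PoreSizeDistribution)."""
    proc = _preprocess(vol, cfg)
    mask = _segment(proc, cfg)
    summary = pore_metrics.pore_summary(
        mask, cfg.bulk_density_g_cm3, cfg.particle_density_g_cm3
    )
    psd = pore_metrics.pore_size_distribution(
        mask, pore_metrics.default_bin_edges_um(cfg.voxel_size_um, cfg.psd_max_radius_um)
    )
    return proc, mask, summary, psd


def _summary_frame(summary: pore_metrics.PoreSummary, label: str) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "scan": label,
                "total_porosity_frac": summary.total_porosity,
                "visible_porosity_frac": summary.visible_porosity,
                "sub_resolution_porosity_frac": summary.sub_resolution_porosity,
                "connectivity_frac": summary.connectivity_fraction,
                "interface_area_mm2": summary.interface_area_mm2,
                "interface_area_mm2_per_mm3": summary.interface_area_per_mm3,
                "euler_number": summary.euler_number,
                "pore_volume_mm3": summary.pore_volume_mm3,
            }
        ]
    )


def _psd_frame(psd: pore_metrics.PoreSizeDistribution, label: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "scan": label,
            "bin_lo_um": psd.bin_radii_um[:-1],
            "bin_hi_um": psd.bin_radii_um[1:],
            "volume_fraction": psd.volume_fraction,
        }
    )


def _pom_frame(seg: pom_mod.PomSegmentation, label: str) -> pd.DataFrame:
    rows = [
        {
            "scan": label,
            "fragment_id": f.id,
            "voxel_count": f.voxel_count,
            "volume_mm3": f.volume_mm3,
            "centroid_z_um": f.centroid_um[0],
            "centroid_y_um": f.centroid_um[1],
            "centroid_x_um": f.centroid_um[2],
            "mean_gray": f.mean_gray,
        }
        for f in seg.fragments
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "scan", "fragment_id", "voxel_count", "volume_mm3",
            "centroid_z_um", "centroid_y_um", "centroid_x_um", "mean_gray",
        ],
    )


def run_pipeline(cfg: io.PipelineConfig, volume: "GrayscaleVolume | None" = None,
                 volume_after: "GrayscaleVolume | None" = None) -> dict[str, Path]:
    """Run every configured stage; returns the written report paths.

    Volumes may be passed in memory (phantom workflows) or read from
    ``cfg.input`` / ``cfg.input_after``.  Outputs are deterministic for a
    fixed config and seed.
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if volume is None:
        if cfg.input is None:
            raise ValueError("config has no input and no volume was passed")
        volume = io.read_volume(cfg.input, cfg.voxel_size_um)
    if volume_after is None and cfg.input_after is not None:
        volume_after = io.read_volume(cfg.input_after, cfg.voxel_size_um)

    paths: dict[str, Path] = {}
    proc_b, mask_b, summary_b, psd_b = analyze_volume(volume, cfg)
    summaries = [_summary_frame(summary_b, "before")]
    psds = [_psd_frame(psd_b, "before")]

    pom_b = pom_a = None
    if cfg.pom_enabled:
        pom_b = pom_mod.segment_pom(
            proc_b, cfg.pom_t_low, cfg.pom_t_high,
            open_steps=cfg.pom_open_steps,
            gauss_sigma_vox=cfg.pom_gauss_sigma_vox,
            min_volume_mm3=cfg.pom_min_volume_mm3,
            exclude=mask_b.phase(Phase.EXCLUDED),
        )

    if volume_after is not None:
        proc_a, mask_a, summary_a, psd_a = analyze_volume(volume_after, cfg)
        summaries.append(_summary_frame(summary_a, "after"))
        psds.append(_psd_frame(psd_a, "after"))
        if cfg.pom_enabled:
            pom_a = pom_mod.segment_pom(
                proc_a, cfg.pom_t_low, cfg.pom_t_high,
                open_steps=cfg.pom_open_steps,
                gauss_sigma_vox=cfg.pom_gauss_sigma_vox,
                min_volume_mm3=cfg.pom_min_volume_mm3,
                exclude=mask_a.phase(Phase.EXCLUDED),
            )

    paths["metrics"] = out / "metrics.csv"
    pd.concat(summaries, ignore_index=True).to_csv(paths["metrics"], index=False, float_format="%.8g")
    paths["psd"] = out / "psd.csv"
    pd.concat(psds, ignore_index=True).to_csv(paths["psd"], index=False, float_format="%.8g")

    if pom_b is not None:
        frames = [_pom_frame(pom_b, "before")]
        if pom_a is not None:
            frames.append(_pom_frame(pom_a, "after"))
        paths["pom"] = out / "pom.csv"
        pd.concat(frames, ignore_index=True).to_csv(paths["pom"], index=False, float_format="%.8g")

    if pom_b is not None and pom_a is not None:
        reference = mask_b.n_basis_voxels
        changes = pom_mod.compare_pom(pom_b, pom_a, reference, cfg.pom_match_radius_mm)
        rows = []
        for ch in changes:
            row = {
                "fragment_id": ch.fragment_id,
                "a_b_pct": ch.a_b_pct,
                "a_a_pct": ch.a_a_pct,
                "loss_pct": ch.loss_pct,
                "status": ch.status,
            }
            if ch.status != "unmatched_before":
                profile = pom_mod.shell_pore_fraction(
                    pom_b.fragment_mask(ch.fragment_id),
                    mask_b.phase(Phase.PORE),
                    cfg.voxel_size_um,
                    distances_mm=cfg.shell_distances_mm,
                    excluded_mask=mask_b.phase(Phase.EXCLUDED),
                    fragment_id=ch.fragment_id,
                )
                for d, f in zip(profile.shell_distances_mm, profile.pore_fraction_per_shell):
                    row[f"shell_{d:g}mm_pore_frac"] = f
            rows.append(row)
        paths["pom_compare"] = out / "pom_compare.csv"
        pd.DataFrame(rows).to_csv(paths["pom_compare"], index=False, float_format="%.8g")

    paths["provenance"] = io.write_provenance(cfg, out, {"stages": sorted(paths)})
    log.info("pipeline complete: %s", {k: str(v) for k, v in paths.items()})
    return paths
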