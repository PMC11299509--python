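"""End-to-end orchestration: synthetic study runs, group comparison and
reporting, with versioned CSV outputs and a machine-readable manifest.

The central entry point is :func:`run_pipeline`, driven by a
:class:`RunConfig`; :func:`run_synthetic_study` is the library-level core
that generates paired synthetic cohorts for a named preset, pushes both
arms through the 3D / 2D / qPCR stages and compares the arms metric by
metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as olio
from .core import LACUNA_MAX_UM3, NOISE_MAX_UM3
from .groupstats import GroupComparison, compare_groups
from .lacunae3d import analyze_volume
from .lcn2d import analyze_field
from .presets import (
    PRESET_NAMES,
    paired_field_specs,
    paired_volume_specs,
    qpcr_preset,
)
from .qpcr import delta_delta_ct
from .synthetic import Field2DSpec, Volume3DSpec, generate_ct_table, generate_field2d, generate_volume

log = logging.getLogger(__name__)

STAGES = ("generate", "lacunae3d", "lcn2d", "qpcr", "compare", "all")


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run."""

    stage: str = "all"
    preset: str = "u266_vs_nsg"
    seed: int = 0
    n_pairs: int = 10
    fields_per_sample: int = 3
    voxel_size_um: float = 0.65
    pixel_size_um: float = 0.5
    noise_max_um3: float = NOISE_MAX_UM3
    lacuna_max_um3: float = LACUNA_MAX_UM3
    angle_window_deg: float = 20.0
    ct_noise_sd: float = 0.0
    input_paths: tuple[str, ...] = ()
    output_dir: str | None = None

    def validate(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; choose from {STAGES}")
        if self.preset not in PRESET_NAMES:
            raise ValueError(
                f"unknown preset {self.preset!r}; choose from {PRESET_NAMES}"
            )
        if not 0 < self.noise_max_um3 <= self.lacuna_max_um3:
            raise ValueError("volume bands must satisfy 0 < noise_max <= lacuna_max")
        if not 0.0 < self.angle_window_deg < 90.0:
            raise ValueError("angle window must lie in (0, 90) degrees")
        if self.n_pairs < 1 or self.fields_per_sample < 1:
            raise ValueError("n_pairs and fields_per_sample must be >= 1")
        if self.voxel_size_um <= 0 or self.pixel_size_um <= 0:
            raise ValueError("voxel and pixel sizes must be positive")


@dataclass
class StudyResult:
    """Collected outputs of a synthetic end-to-end run."""

    lacunar: pd.DataFrame  # per seed x arm: density, mean volume, ...
    fields: pd.DataFrame  # per seed x arm: area fraction, length, alignment
    qpcr: pd.DataFrame  # per-gene fold changes
    comparisons: list[GroupComparison] = field(default_factory=list)

    def comparison_table(self) -> pd.DataFrame:
        return pd.DataFrame([c.as_dict() for c in self.comparisons])


def _seed_stream(seed: int, n: int, salt: int) -> list[int]:
    """Distinct deterministic sub-seeds below 2^31."""
    ss = np.random.SeedSequence([seed, salt])
    return [int(s) % (2**31) for s in ss.generate_state(n, np.uint64)]


def run_lacunae3d_arm(
    specs: list[Volume3DSpec], compute_sphericity: bool = True
) -> pd.DataFrame:
    rows = []
    for i, spec in enumerate(specs):
        vol, _truth = generate_volume(spec)
        res = analyze_volume(vol, compute_sphericity=compute_sphericity)
        row = {"replicate": i, **res.metrics.as_dict()}
        rows.append(row)
    return pd.DataFrame(rows)


def run_lcn2d_arm(
    specs: list[Field2DSpec], angle_window_deg: float = 20.0
) -> pd.DataFrame:
    """One sample = several fields; lengths pool over fields, area averages."""
    per_field = []
    for spec in specs:
        fld, _truth = generate_field2d(spec)
        fa = analyze_field(fld, window_deg=angle_window_deg)
        per_field.append(fa)
    lengths = pd.concat([fa.traces["length_um"] for fa in per_field], ignore_index=True)
    return pd.DataFrame(
        [
            {
                "lcn_area_fraction_pct": float(
                    np.mean([fa.area_fraction_pct for fa in per_field])
                ),
                "mean_canaliculus_length_um": float(lengths.mean())
                if len(lengths)
                else float("nan"),
                "aligned_fraction": float(
                    np.nanmean([fa.aligned_fraction for fa in per_field])
                ),
                "n_canaliculi": int(len(lengths)),
            }
        ]
    )


def run_synthetic_study(config: RunConfig) -> StudyResult:
    """Generate paired cohorts for the configured preset and analyze both arms.

    Per replicate pair one 3D volume per arm is analyzed; the 2D stage
    uses ``fields_per_sample`` fields per arm per replicate (lengths from
    3 lacunae per field, as in the experimental protocol). The qPCR stage
    runs once on a preset Ct table.
    """
    config.validate()
    lac_rows = []
    fld_rows = []
    vol_seeds = _seed_stream(config.seed, config.n_pairs, 1)
    fld_seeds = _seed_stream(config.seed, config.n_pairs, 2)
    for i in range(config.n_pairs):
        naive_spec, tumor_spec = paired_volume_specs(config.preset, vol_seeds[i])
        for arm, spec in (("naive", naive_spec), ("tumor", tumor_spec)):
            vol, _ = generate_volume(spec)
            res = analyze_volume(vol)
            lac_rows.append({"seed": i, "arm": arm, **res.metrics.as_dict()})
        base_naive, base_tumor = paired_field_specs(config.preset, fld_seeds[i])
        for arm, base in (("naive", base_naive), ("tumor", base_tumor)):
            specs = [
                replace(base, seed=base.seed + 1000 * (j + 1))
                for j in range(config.fields_per_sample)
            ]
            df = run_lcn2d_arm(specs, config.angle_window_deg)
            fld_rows.append({"seed": i, "arm": arm, **df.iloc[0].to_dict()})
    lacunar = pd.DataFrame(lac_rows)
    fields = pd.DataFrame(fld_rows)

    ct = generate_ct_table(
        qpcr_preset(ct_noise_sd=config.ct_noise_sd, seed=_seed_stream(config.seed, 1, 3)[0])
    )
    qres = delta_delta_ct(ct)

    comparisons = []
    for metric in ("density_per_mm3", "mean_volume_um3", "proportion_pct", "mean_sphericity"):
        a = lacunar.loc[lacunar["arm"] == "naive", metric].dropna()
        b = lacunar.loc[lacunar["arm"] == "tumor", metric].dropna()
        if len(a) >= 2 and len(b) >= 2:
            comparisons.append(compare_groups(a, b, metric=metric))
    for metric in ("mean_canaliculus_length_um", "lcn_area_fraction_pct", "aligned_fraction"):
        a = fields.loc[fields["arm"] == "naive", metric].dropna()
        b = fields.loc[fields["arm"] == "tumor", metric].dropna()
        if len(a) >= 2 and len(b) >= 2:
            comparisons.append(compare_groups(a, b, metric=metric))
    return StudyResult(lacunar, fields, qres, comparisons)


def run_pipeline(config: RunConfig) -> StudyResult:
    """Run the configured stage(s); write CSVs and a manifest when an
    output directory is set. Invalid configuration fails before compute."""
    config.validate()
    result = run_synthetic_study(config)
    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        outputs = [
            olio.write_table(outdir / "lacunar_metrics.csv", result.lacunar),
            olio.write_table(outdir / "lcn_fields.csv", result.fields),
            olio.write_table(outdir / "qpcr_fold_changes.csv", result.qpcr, index=True),
            olio.write_table(outdir / "group_comparisons.csv", result.comparison_table()),
        ]
        olio.write_manifest(
            outdir / "manifest.json",
            parameters=config,
            inputs=[],
            outputs=outputs,
        )
    return result
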