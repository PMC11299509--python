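"""Named study presets: paired generator specs encoding the printed group
effect sizes of the two myeloma models.

``u266_vs_nsg`` (extensive disease vs naive):

* lacunar density x 0.80 (about a 20% reduction)
* mean lacunar volume x 2.0
* mean canaliculus length x (1 - 0.291)
* LCN area fraction x (1 - 0.242)
* angular dispersion about the vertical x 2 (direction of the published
  change; its magnitude is not printed, so a clearly detectable doubling
  of the spread is used)

``5tgm1_vs_bkal`` (mild disease vs naive):

* mean canaliculus length x (1 - 0.304); all other parameters unchanged.

qPCR preset: per-gene fold changes relative to Gapdh, stored as printed
and converted to ddCt = -log2(fold change).
"""

from __future__ import annotations

import math
from dataclasses import replace

from .synthetic import CtPreset, Field2DSpec, Volume3DSpec

#: printed fold changes (tumor vs naive) for the PLR qPCR panel
QPCR_FOLD_CHANGES: dict[str, float] = {
    "Dmp1": 0.49,
    "MMP13": 4.9,
    "Ctsk": 3.2,
    "Acp5": 7.7,
    "MMP2": 1.74,
    "Sost": 1.0,
}

#: multiplicative tumor-vs-naive effects per preset; keys absent => x 1.0
PRESET_EFFECTS: dict[str, dict[str, float]] = {
    "u266_vs_nsg": {
        "density_ratio": 0.80,
        "mean_volume_ratio": 2.0,
        "length_ratio": 1.0 - 0.291,
        "area_fraction_ratio": 1.0 - 0.242,
        "angle_sd_factor": 2.0,
    },
    "5tgm1_vs_bkal": {
        "length_ratio": 1.0 - 0.304,
    },
}

PRESET_NAMES = tuple(PRESET_EFFECTS)


def _effects(preset: str) -> dict[str, float]:
    try:
        return PRESET_EFFECTS[preset]
    except KeyError:
        raise KeyError(
            f"unknown preset {preset!r}; available: {', '.join(PRESET_EFFECTS)}"
        ) from None


def paired_volume_specs(
    preset: str, seed: int, base: Volume3DSpec | None = None
) -> tuple[Volume3DSpec, Volume3DSpec]:
    """(naive, tumor) 3D specs for one seeded replicate pair."""
    eff = _effects(preset)
    naive = base if base is not None else Volume3DSpec()
    naive = replace(naive, seed=2 * seed)
    tumor = replace(
        naive,
        seed=2 * seed + 1,
        lacuna_density_per_mm3=naive.lacuna_density_per_mm3
        * eff.get("density_ratio", 1.0),
        lacuna_volume_mean_um3=naive.lacuna_volume_mean_um3
        * eff.get("mean_volume_ratio", 1.0),
    )
    return naive, tumor


def paired_field_specs(
    preset: str, seed: int, base: Field2DSpec | None = None
) -> tuple[Field2DSpec, Field2DSpec]:
    """(naive, tumor) 2D field specs for one seeded replicate pair."""
    eff = _effects(preset)
    naive = base if base is not None else Field2DSpec()
    naive = replace(naive, seed=2 * seed)
    angle_sd = naive.canaliculus_angle_sd_deg
    if angle_sd is not None:
        angle_sd = angle_sd * eff.get("angle_sd_factor", 1.0)
    target = naive.target_lcn_area_fraction
    if target is not None:
        target = target * eff.get("area_fraction_ratio", 1.0)
    tumor = replace(
        naive,
        seed=2 * seed + 1,
        canaliculus_length_mean_um=naive.canaliculus_length_mean_um
        * eff.get("length_ratio", 1.0),
        canaliculus_angle_sd_deg=angle_sd,
        target_lcn_area_fraction=target,
    )
    return naive, tumor


def qpcr_preset(
    ct_noise_sd: float = 0.0, seed: int = 0, n_tumor: int = 8, n_naive: int = 3
) -> CtPreset:
    """The six-gene PLR panel as a Ct-table preset (ddCt = -log2 fold)."""
    genes = {g: -math.log2(fc) for g, fc in QPCR_FOLD_CHANGES.items()}
    return CtPreset(
        genes=genes,
        ct_noise_sd=ct_noise_sd,
        seed=seed,
        n_tumor=n_tumor,
        n_naive=n_naive,
    )
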