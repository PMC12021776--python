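"""Per-case feature assembly: whole tumor + habitat subregions, both phases.

Column naming is ``{phase}_{region}_{family}_{feature}`` with phase in
{A, V} and region in {whole, sub1, sub2, sub3}.  The whole tumor yields
first-order (18) + shape (14) + texture (73) = 105 features per phase
(210 total, the conventional-radiomics set); each subregion yields
first-order + texture = 91 per phase (546 over 3 subregions x 2 phases,
the habitat-radiomics set); the union is 756 columns.  Shape features are
phase-independent but are reported under both phases, mirroring a
per-phase extraction run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..preprocessing import DEFAULT_BIN_WIDTH, DualPhaseCase, discretize
from ..habitats import HabitatLabelMap
from .firstorder import FIRST_ORDER_NAMES, first_order
from .shape import SHAPE_NAMES, shape
from .texture import TEXTURE_FAMILIES, texture

__all__ = [
    "FeatureConfig",
    "extract_case",
    "extract_table",
    "feature_columns",
    "split_feature_sets",
]

PHASES = ("A", "V")
SUBREGIONS = ("sub1", "sub2", "sub3")
SMALL_REGION_VOXELS = 5


@dataclass(frozen=True)
class FeatureConfig:
    """Feature families and discretization settings.

    The texture composition (22 + 16 + 16 + 14 + 5 = 73) is config-visible:
    alternative sets can be declared by overriding ``texture_families``.
    """

    bin_width: float = DEFAULT_BIN_WIDTH
    families_whole: tuple[str, ...] = ("firstorder", "shape", "texture")
    families_subregion: tuple[str, ...] = ("firstorder", "texture")
    texture_families: tuple[str, ...] = ("glcm", "glrlm", "glszm", "gldm", "ngtdm")
    n_subregions: int = 3

    @property
    def texture_names(self) -> list[str]:
        """Flat ``family_Feature`` names of the configured texture set."""
        return [
            f"{fam}_{name}"
            for fam in self.texture_families
            for name in TEXTURE_FAMILIES[fam]
        ]

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "bin_width": self.bin_width,
                "families_whole": self.families_whole,
                "families_subregion": self.families_subregion,
                "texture_families": self.texture_families,
                "n_subregions": self.n_subregions,
            },
            sort_keys=True,
            default=list,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


DEFAULT_CONFIG = FeatureConfig()


def feature_columns(config: FeatureConfig = DEFAULT_CONFIG, which: str = "combined") -> list[str]:
    """Deterministic column order for ``which`` in {'CR', 'HR', 'combined'}."""
    cols: list[str] = []

    def region_cols(region: str, families) -> list[str]:
        out = []
        for phase in PHASES:
            for fam in families:
                if fam == "firstorder":
                    out += [f"{phase}_{region}_firstorder_{n}" for n in FIRST_ORDER_NAMES]
                elif fam == "shape":
                    out += [f"{phase}_{region}_shape_{n}" for n in SHAPE_NAMES]
                elif fam == "texture":
                    out += [f"{phase}_{region}_{n}" for n in config.texture_names]
                else:
                    raise ValueError(f"unknown family {fam!r}")
        return out

    if which in ("CR", "combined"):
        cols += region_cols("whole", config.families_whole)
    if which in ("HR", "combined"):
        for i in range(1, config.n_subregions + 1):
            cols += region_cols(f"sub{i}", config.families_subregion)
    if which not in ("CR", "HR", "combined"):
        raise ValueError(f"unknown feature set {which!r}")
    return cols


def split_feature_sets(columns) -> dict[str, list[str]]:
    """Partition column names into the CR (whole) and HR (subregion) sets."""
    cr = [c for c in columns if c.split("_", 2)[1] == "whole"]
    hr = [c for c in columns if c.split("_", 2)[1].startswith("sub")]
    return {"CR": cr, "HR": hr, "combined": cr + hr}


def _region_features(
    case: DualPhaseCase, region_mask: np.ndarray, region: str, families, config: FeatureConfig
) -> dict[str, float]:
    out: dict[str, float] = {}
    voxel_volume = case.grid.voxel_volume
    for phase, volume in (("A", case.arterial), ("V", case.venous)):
        values = volume[region_mask]
        disc = discretize(values, config.bin_width)
        # scatter levels into a compact bounding box for the matrix builders
        zz, yy, xx = np.nonzero(region_mask)
        box = np.zeros(
            (zz.max() - zz.min() + 1, yy.max() - yy.min() + 1, xx.max() - xx.min() + 1),
            dtype=np.int64,
        )
        box[zz - zz.min(), yy - yy.min(), xx - xx.min()] = disc.levels
        for fam in families:
            if fam == "firstorder":
                vals = first_order(values, disc, voxel_volume)
                out.update({f"{phase}_{region}_firstorder_{k}": v for k, v in vals.items()})
            elif fam == "shape":
                vals = shape(region_mask, case.grid.spacing)
                out.update({f"{phase}_{region}_shape_{k}": v for k, v in vals.items()})
            elif fam == "texture":
                tex = texture(box, disc.level_count, families=config.texture_families)
                for tfam, feats in tex.items():
                    out.update(
                        {f"{phase}_{region}_{tfam}_{k}": v for k, v in feats.items()}
                    )
    return out


def extract_case(
    case: DualPhaseCase,
    habitat_map: HabitatLabelMap | None = None,
    config: FeatureConfig = DEFAULT_CONFIG,
    which: str = "combined",
) -> tuple[pd.Series, list[str]]:
    """Extract one FeatureTable row; returns (row, flags).

    ``which`` selects the emitted column set: 'CR' (whole tumor only, 210),
    'HR' (subregions only, 546) or 'combined' (756).  Subregions with fewer
    than 5 voxels are still computed but flagged ``small_region``.
    """
    flags: list[str] = []
    row: dict[str, float] = {}
    mask = case.mask.astype(bool)

    if which in ("CR", "combined"):
        row.update(_region_features(case, mask, "whole", config.families_whole, config))

    if which in ("HR", "combined"):
        if habitat_map is None:
            raise ValueError("habitat_map required for subregion features")
        if habitat_map.k != config.n_subregions:
            raise ValueError(
                f"habitat map has {habitat_map.k} subregions, config expects {config.n_subregions}"
            )
        for i in range(1, config.n_subregions + 1):
            sub_mask = habitat_map.region_mask(i)
            n_vox = int(sub_mask.sum())
            if n_vox == 0:
                raise ValueError(f"subregion {i} is empty")
            if n_vox < SMALL_REGION_VOXELS:
                flags.append(f"small_region:sub{i}")
            row.update(
                _region_features(case, sub_mask, f"sub{i}", config.families_subregion, config)
            )

    cols = feature_columns(config, which)
    series = pd.Series(row, name=case.case_id).reindex(cols)
    if series.isna().any():
        missing = series.index[series.isna()].tolist()
        raise RuntimeError(f"feature assembly produced missing columns: {missing[:5]}")
    return series, flags


def extract_table(
    cases,
    habitat_maps=None,
    config: FeatureConfig = DEFAULT_CONFIG,
    which: str = "combined",
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Extract a cases x features table; returns (table, per-case flags)."""
    rows, all_flags = [], {}
    maps = habitat_maps if habitat_maps is not None else [None] * len(cases)
    for case, hmap in zip(cases, maps):
        row, flags = extract_case(case, hmap, config, which)
        rows.append(row)
        if flags:
            all_flags[case.case_id] = flags
    table = pd.DataFrame(rows)
    table.index.name = "case_id"
    table.attrs["config_hash"] = config.config_hash()
    return table, all_flags
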