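"""Temporal-overlap refugia: suitability that persists across time frames.

A long-term stable refugium for one species is the set of cells predicted
suitable in *every* scenario of a time combination (strict intersection,
including every circulation-model variant of each period). Five standard
combinations are assessed: present with all past models, present with the
2070 models of each emission pathway, and present with past plus each
pathway. Per-species intersections are stacked into refugia richness maps,
and summarized as area (km², latitude-corrected) and as the fraction lying
outside a protected-area mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_eval import UndefinedResultError
from .raster_core import AlignmentError, RasterLayer, cell_area_km2
from .richness_maps import stack_binary_maps

__all__ = [
    "CombinationSpec",
    "standard_combinations",
    "COMBINATION_NAMES",
    "intersect_species_maps",
    "stack_refugia",
    "refugia_area",
    "reserve_gap_fraction",
]

COMBINATION_NAMES = (
    "Present-Past",
    "Present-Future RCP 2.6",
    "Present-Future RCP 8.5",
    "Present-Past-Future RCP 2.6",
    "Present-Past-Future RCP 8.5",
)


@dataclass(frozen=True)
class CombinationSpec:
    """A named time combination: the scenario ids whose binary maps are
    intersected. The present scenario is always a member."""

    name: str
    scenario_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not any("present" in s for s in self.scenario_ids):
            raise ValueError(f"combination {self.name!r} must include the present")


def standard_combinations(
    present: str = "present",
    past: tuple[str, ...] = (
        "MH-CCSM4",
        "MH-MIROC-ESM",
        "MH-MPI",
        "LGM-CCSM4",
        "LGM-MIROC-ESM",
        "LGM-MPI",
    ),
    future_rcp26: tuple[str, ...] = (
        "2070-CCSM-RCP2.6",
        "2070-GFDL-RCP2.6",
        "2070-MPI-RCP2.6",
    ),
    future_rcp85: tuple[str, ...] = (
        "2070-CCSM-RCP8.5",
        "2070-GFDL-RCP8.5",
        "2070-MPI-RCP8.5",
    ),
) -> dict[str, CombinationSpec]:
    """The five standard time combinations over a 13-scenario registry
    (present; 3 circulation models × {mid-Holocene, LGM}; 3 circulation
    models × 2 pathways for 2070)."""
    return {
        "Present-Past": CombinationSpec("Present-Past", (present, *past)),
        "Present-Future RCP 2.6": CombinationSpec(
            "Present-Future RCP 2.6", (present, *future_rcp26)
        ),
        "Present-Future RCP 8.5": CombinationSpec(
            "Present-Future RCP 8.5", (present, *future_rcp85)
        ),
        "Present-Past-Future RCP 2.6": CombinationSpec(
            "Present-Past-Future RCP 2.6", (present, *past, *future_rcp26)
        ),
        "Present-Past-Future RCP 8.5": CombinationSpec(
            "Present-Past-Future RCP 8.5", (present, *past, *future_rcp85)
        ),
    }


def intersect_species_maps(
    maps_by_scenario: dict[str, RasterLayer], combination: CombinationSpec
) -> RasterLayer:
    """Strict AND of one species' binary maps over the combination's
    scenarios; a cell is 1 iff suitable in every member. Nodata anywhere
    propagates as nodata."""
    missing = [s for s in combination.scenario_ids if s not in maps_by_scenario]
    if missing:
        raise KeyError(f"missing scenario map(s): {missing}")
    maps = [maps_by_scenario[s] for s in combination.scenario_ids]
    spec = maps[0].spec
    for m in maps[1:]:
        if m.spec != spec:
            raise AlignmentError("scenario maps are misaligned")
    arr = np.stack([m.values for m in maps])
    nodata = spec.nodata_value
    any_nd = np.any(arr == nodata, axis=0)
    out = np.where(np.all(arr == 1.0, axis=0), 1.0, 0.0)
    out[any_nd] = nodata
    return RasterLayer(spec, out, name=f"refugium:{combination.name}")


def stack_refugia(per_species_maps: list[RasterLayer]) -> RasterLayer:
    """Cellwise sum of per-species intersected maps: the number of species
    whose suitable area persists in every member scenario."""
    out = stack_binary_maps(per_species_maps)
    out.name = "refugia_richness"
    return out


def refugia_area(layer: RasterLayer) -> float:
    """Total km² of cells with value >= 1 (binary map or thresholded
    refugia richness), latitude-corrected per cell row."""
    spec = layer.spec
    lats = spec.cell_center_latitudes()
    row_area = np.array(
        [cell_area_km2(lat, spec.cell_size, spec.cell_size) for lat in lats]
    )
    counted = layer.valid_mask & (layer.values >= 1.0)
    return float((counted * row_area[:, None]).sum())


def reserve_gap_fraction(refugia: RasterLayer, reserves: RasterLayer) -> float:
    """Fraction of refugium area lying outside the protected-area mask
    (area-weighted). Undefined when the refugium is empty."""
    if refugia.spec != reserves.spec:
        raise AlignmentError("refugia and reserve maps are misaligned")
    total = refugia_area(refugia)
    if total == 0:
        raise UndefinedResultError("refugium is empty; gap fraction undefined")
    outside_vals = np.where(
        (reserves.values == 1.0), 0.0, refugia.values
    )
    outside_vals[~refugia.valid_mask] = refugia.spec.nodata_value
    outside = RasterLayer(refugia.spec, outside_vals)
    return refugia_area(outside) / total
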