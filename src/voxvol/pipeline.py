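"""End-to-end calculation: structure + parameters -> full result set."""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .cavity import CavityRecord
from .chemio import Structure
from .gridcore import CalcParams, VoxelGrid
from .measure import (SurfaceReport, VolumeReport, compute_surfaces,
                      default_mc_table, tally_volumes)
from .typing_engine import run_single_probe, run_two_probe

log = logging.getLogger(__name__)

__all__ = ["CalcResult", "run_calculation"]


@dataclass
class CalcResult:
    """Everything a finished calculation produced."""

    structure: Structure
    params: CalcParams
    grid: VoxelGrid
    cavities: list[CavityRecord]
    volumes: VolumeReport
    surfaces: SurfaceReport | None


def run_calculation(structure: Structure, params: CalcParams) -> CalcResult:
    """Run typing, cavity segmentation, volume tallies and (optionally)
    surface areas for one structure."""
    params.validate()
    log.info("typing %d atoms on a %.3g A grid (%s mode)",
             len(structure.atoms), params.grid_resolution,
             "two-probe" if params.two_probe else "single-probe")
    if params.two_probe:
        grid, records = run_two_probe(structure, params)
    else:
        grid, records = run_single_probe(structure, params)
    log.info("found %d cavity component(s)", len(records))
    volumes = tally_volumes(grid, records, structure.total_weight)
    surfaces = None
    if params.compute_surfaces:
        log.info("computing marching-cube surface areas")
        surfaces = compute_surfaces(grid, records, default_mc_table(),
                                    structure.total_weight,
                                    two_probe=params.two_probe)
    return CalcResult(structure=structure, params=params, grid=grid,
                      cavities=records, volumes=volumes, surfaces=surfaces)
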