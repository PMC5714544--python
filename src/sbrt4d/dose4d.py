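"""Warp per-phase dose to the end-of-exhale reference frame and accumulate.

Accumulation uses pull-back sampling (the "simple voxel warping"
approach): the warped dose at reference voxel x is the trilinear sample
of the phase dose at x + u(x), where u is the displacement field that
carries reference points into the phase.  Samples falling outside the
phase grid contribute zero and are counted in the log.  No energy/mass
remapping is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .dose_engines import DoseGrid

__all__ = ["PhaseDoseSet", "warp_dose", "accumulate", "dose_difference_map"]

log = logging.getLogger(__name__)


@dataclass
class PhaseDoseSet:
    """Per-phase dose grids (shared GridSpec) with phase weights."""

    doses: list[DoseGrid]
    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.doses) != len(self.weights):
            raise ValueError("one weight per phase dose required")
        grid = self.doses[0].grid
        if any(d.grid != grid for d in self.doses):
            raise ValueError("all phase doses must share one GridSpec")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("phase weights must sum to 1")


def warp_dose(dose_phase: DoseGrid, dvf_to_ref: np.ndarray) -> DoseGrid:
    """Pull a phase dose back onto the reference frame.

    ``dvf_to_ref`` is the (nx, ny, nz, 3) displacement in mm on the
    reference grid: reference point x corresponds to x + u(x) in the
    phase.  An identically-zero field returns the input values bit-exact.
    """
    dvf = np.asarray(dvf_to_ref, dtype=float)
    grid = dose_phase.grid
    if dvf.shape != grid.shape + (3,):
        raise ValueError(f"DVF shape {dvf.shape} does not match grid {grid.shape}")
    if not np.any(dvf):
        return DoseGrid(dose_phase.values.copy(), grid)
    base = np.indices(grid.shape, dtype=float)
    shift = np.moveaxis(dvf, -1, 0) / np.asarray(grid.spacing)[:, None, None, None]
    coords = base + shift
    out_of_grid = np.any((coords < 0) | (coords > (np.asarray(grid.shape) - 1)[:, None, None, None]), axis=0)
    n_out = int(out_of_grid.sum())
    if n_out:
        log.debug("warp_dose: %d displaced samples fell outside the grid (zero-filled)", n_out)
    warped = ndimage.map_coordinates(dose_phase.values, coords, order=1, cval=0.0)
    return DoseGrid(warped, grid)


def accumulate(phase_doses: PhaseDoseSet, dvfs: list[np.ndarray], reference_phase: int = 0) -> DoseGrid:
    """Weighted sum of pulled-back phase doses on the reference frame.

    The reference phase contributes unwarped.
    """
    if len(dvfs) != len(phase_doses.doses):
        raise ValueError("one DVF per phase required")
    grid = phase_doses.doses[0].grid
    total = np.zeros(grid.shape)
    for p, (dose, w) in enumerate(zip(phase_doses.doses, phase_doses.weights)):
        if p == reference_phase:
            total += w * dose.values
        else:
            total += w * warp_dose(dose, dvfs[p]).values
    return DoseGrid(total, grid)


def dose_difference_map(dose_a: DoseGrid, dose_b: DoseGrid) -> np.ndarray:
    """Signed per-voxel difference a - b (e.g. directly-optimized minus recalculated)."""
    if dose_a.grid != dose_b.grid:
        raise ValueError("dose grids must share one GridSpec")
    return dose_a.values - dose_b.values
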