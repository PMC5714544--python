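"""Two contrasting per-phase dose calculators sharing one beam model.

``RayTracingEPL`` is a correction-based engine: the dose at a point is
the product of measured-beam factors — tissue-phantom ratio looked up at
the radiological (equivalent-path-length) depth, an off-center ratio,
and inverse square — so heterogeneity only enters through the depth
scaling along the ray.  It assumes charged-particle equilibrium and has
no lateral transport.

``KernelSurrogate`` plays the role of the gold-standard engine: the same
primary energy released along each ray is redistributed laterally with a
Gaussian kernel whose physical width scales inversely with local mass
density, sigma(x) = sigma0 / rho(x) (clipped to [sigma0, sigma_max]).
In low-density lung the kernel is wide, so dose near soft-tissue/lung
interfaces is depressed on the dense side — the lateral electronic
disequilibrium signature that correction-based engines miss.  A seeded
statistical-noise model with per-voxel relative SD proportional to
1/dose emulates Monte-Carlo uncertainty: relative SD sigma_at_dmax at
the maximum-dose voxel, i.e. a uniform absolute SD of
sigma_at_dmax * Dmax on voxels with nonzero dose.

Both engines evaluate the primary on a beam-aligned lattice with rays
parallel to the central axis (the cone half-angle at SAD 800 mm is ~2
degrees, so the parallel-ray radiological depth error is negligible);
divergence is retained in the off-axis scaling and inverse-square
factors.  The exact per-ray line integral is available separately as
:func:`radiological_depth` (Siddon voxel traversal) and serves as the
independent oracle for the lattice computation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.special import erfc

from .beams import Beam, BeamSet
from .phantom4d import GridSpec

__all__ = [
    "AIR",
    "SOFT_TISSUE",
    "BONE",
    "BeamModel",
    "UncertaintySpec",
    "DoseGrid",
    "UncertaintyGrid",
    "RayTracingEPL",
    "KernelSurrogate",
    "assign_material",
    "radiological_depth",
    "epl_dose",
    "mc_surrogate_dose",
    "uncertainty_map",
    "apply_statistical_noise",
]

# material labels (piecewise density rule)
AIR, SOFT_TISSUE, BONE = 0, 1, 2
DENSITY_AIR_MAX = 0.1  # g/cc, exclusive
DENSITY_BONE_MIN = 1.125  # g/cc, exclusive
MATERIAL_NAMES = {AIR: "air", SOFT_TISSUE: "soft tissue", BONE: "bone"}


def assign_material(density_grid: np.ndarray) -> np.ndarray:
    """Label voxels air / soft tissue / bone from mass density.

    air if rho < 0.1 g/cc, soft tissue if 0.1 <= rho <= 1.125, bone if
    rho > 1.125 (both boundaries inclusive to soft tissue).
    """
    rho = np.asarray(density_grid)
    if (rho < 0).any():
        raise ValueError("density must be nonnegative")
    labels = np.full(rho.shape, SOFT_TISSUE, dtype=np.uint8)
    labels[rho < DENSITY_AIR_MAX] = AIR
    labels[rho > DENSITY_BONE_MIN] = BONE
    return labels


@dataclass(frozen=True)
class UncertaintySpec:
    """Statistical-noise level: relative SD at the maximum dose voxel."""

    sigma_at_dmax: float
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.sigma_at_dmax < 1.0):
            raise ValueError("sigma_at_dmax must be in [0, 1)")


@dataclass
class DoseGrid:
    """Scalar dose per voxel (cGy) on a regular grid."""

    values: np.ndarray
    grid: GridSpec

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError("dose array shape must match the grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose must be finite")

    @property
    def dmax(self) -> float:
        return float(self.values.max())


@dataclass
class UncertaintyGrid:
    """Per-voxel relative statistical dose uncertainty (fraction)."""

    values: np.ndarray
    grid: GridSpec
    sigma_at_dmax: float = 0.0


@dataclass(frozen=True)
class BeamModel:
    """Tabulated broad-beam data: TPR vs radiological depth, erf-edge OCR.

    The default TPR table rises over the build-up region to 1 at
    ``dmax_cm`` and decays exponentially with effective attenuation
    ``mu_eff_per_mm`` beyond it; calibration is 1 cGy/MU at dmax with
    the target at SAD.  Measured tables can be injected from CSV.
    """

    tpr_depth_cm: np.ndarray
    tpr_values: np.ndarray
    dmax_cm: float = 1.5
    penumbra_sigma_mm: float = 3.0
    calibration_cgy_per_mu: float = 1.0
    output_factors: tuple[float, ...] = ()  # per collimator id; empty -> all 1.0
    ocr_offset_mm: np.ndarray | None = None  # optional table: r - R (mm at SAD)
    ocr_values: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "tpr_depth_cm", np.asarray(self.tpr_depth_cm, dtype=float))
        object.__setattr__(self, "tpr_values", np.asarray(self.tpr_values, dtype=float))
        if not np.isclose(self.tpr(self.dmax_cm), 1.0, atol=1e-6):
            raise ValueError("TPR(dmax) must be 1")

    @classmethod
    def default(
        cls,
        dmax_cm: float = 1.5,
        mu_eff_per_mm: float = 0.005,
        max_depth_cm: float = 60.0,
        penumbra_sigma_mm: float = 3.0,
        **kwargs,
    ) -> "BeamModel":
        depth = np.arange(0.0, max_depth_cm + 1e-9, 0.05)
        rel = np.clip(depth / dmax_cm, 0.0, None)
        buildup = rel * (2.0 - rel)  # parabolic build-up peaking at dmax
        tail = np.exp(-mu_eff_per_mm * 10.0 * (depth - dmax_cm))
        tpr = np.where(depth < dmax_cm, buildup, tail)
        return cls(depth, tpr, dmax_cm=dmax_cm, penumbra_sigma_mm=penumbra_sigma_mm, **kwargs)

    def tpr(self, depth_cm) -> np.ndarray:
        d = np.asarray(depth_cm, dtype=float)
        if np.any(d > self.tpr_depth_cm[-1] + 1e-9):
            raise ValueError(
                f"TPR table covers depths to {self.tpr_depth_cm[-1]:.1f} cm; "
                f"requested {float(np.max(d)):.1f} cm"
            )
        return np.interp(d, self.tpr_depth_cm, self.tpr_values)

    def ocr(self, r_mm_at_sad, aperture_radius_mm: float) -> np.ndarray:
        """Off-center ratio vs off-axis distance scaled to SAD, OCR(0) = 1."""
        r = np.asarray(r_mm_at_sad, dtype=float)
        if self.ocr_offset_mm is not None:
            vals = np.interp(r - aperture_radius_mm, self.ocr_offset_mm, self.ocr_values)
            norm = np.interp(-aperture_radius_mm, self.ocr_offset_mm, self.ocr_values)
            return vals / norm
        s = np.sqrt(2.0) * self.penumbra_sigma_mm
        vals = 0.5 * erfc((r - aperture_radius_mm) / s)
        norm = 0.5 * erfc(-aperture_radius_mm / s)
        return vals / norm

    def output_factor(self, collimator_id: int) -> float:
        if not self.output_factors:
            return 1.0
        return float(self.output_factors[collimator_id])

    # -- CSV interfaces -----------------------------------------------------
    def tpr_to_csv(self, path: str | Path) -> None:
        np.savetxt(path, np.column_stack([self.tpr_depth_cm, self.tpr_values]),
                   delimiter=",", header="depth_cm,TPR", comments="")

    @classmethod
    def tpr_from_csv(cls, path: str | Path, **kwargs) -> "BeamModel":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(data[:, 0], data[:, 1], **kwargs)


# ---------------------------------------------------------------------------
# exact ray tracing (oracle path)

def radiological_depth(density_grid: np.ndarray, grid: GridSpec, source, point) -> float:
    """Water-equivalent depth (cm) from source to point: exact line integral
    of density over the voxels the segment traverses (Siddon traversal)."""
    rho = np.asarray(density_grid, dtype=float)
    src = np.asarray(source, dtype=float)
    pt = np.asarray(point, dtype=float)
    lo, hi = grid.bounding_box()
    if np.all(src >= lo) and np.all(src <= hi):
        raise ValueError("source must lie outside the grid (beams originate outside the body)")
    if np.any(pt < lo) or np.any(pt > hi):
        raise ValueError("point must lie inside the grid")
    seg = pt - src
    length = float(np.linalg.norm(seg))
    if length == 0:
        return 0.0
    # parametric crossings with all voxel boundary planes per axis
    ts = [0.0, 1.0]
    for ax in range(3):
        if abs(seg[ax]) < 1e-12:
            continue
        n_planes = grid.shape[ax] + 1
        planes = lo[ax] + np.arange(n_planes) * grid.spacing[ax]
        t = (planes - src[ax]) / seg[ax]
        ts.extend(t[(t > 0.0) & (t < 1.0)].tolist())
    ts = np.unique(np.asarray(ts))
    mids = (ts[:-1] + ts[1:]) / 2.0
    pts = src[None, :] + mids[:, None] * seg[None, :]
    inside = np.all((pts >= lo) & (pts <= hi), axis=1)
    idx = np.clip(
        np.floor((pts - lo) / np.asarray(grid.spacing)).astype(int),
        0,
        np.asarray(grid.shape) - 1,
    )
    seg_len = (ts[1:] - ts[:-1]) * length
    vals = np.where(inside, rho[idx[:, 0], idx[:, 1], idx[:, 2]], 0.0)
    return float(np.sum(vals * seg_len) / 10.0)  # mm * g/cc -> water-equivalent cm


# ---------------------------------------------------------------------------
# beam-aligned lattice engines

def _beam_frame(beam: Beam) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    d = beam.direction_arr
    helper = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return e1, e2, d


@dataclass
class _BeamField:
    """Dose of one unit-weight beam sampled on a beam-aligned lattice."""

    source: np.ndarray
    e1: np.ndarray
    e2: np.ndarray
    dhat: np.ndarray
    u0: float
    du: float
    w0: float
    dw: float
    values: np.ndarray  # (nu, nu, nw)

    def sample(self, points_world: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_world, dtype=float))
        q = pts - self.source
        iu = (q @ self.e1 - self.u0) / self.du
        iv = (q @ self.e2 - self.u0) / self.du
        iw = (q @ self.dhat - self.w0) / self.dw - 0.5
        nu, _, nw = self.values.shape
        inside = (iu > -1) & (iu < nu) & (iv > -1) & (iv < nu) & (iw > -1) & (iw < nw)
        out = np.zeros(len(pts))
        if inside.any():
            out[inside] = ndimage.map_coordinates(
                self.values, [iu[inside], iv[inside], iw[inside]], order=1, cval=0.0
            )
        return out


class RayTracingEPL:
    """Equivalent-path-length ray-tracing engine (strictly local)."""

    name = "EPL"

    def __init__(
        self,
        beam_model: BeamModel | None = None,
        step_w_mm: float = 3.0,
        lateral_spacing_mm: float = 3.5,
    ):
        self.beam_model = beam_model or BeamModel.default()
        self.step_w_mm = float(step_w_mm)
        self.lateral_spacing_mm = float(lateral_spacing_mm)

    # margin beyond the field edge that must be sampled laterally
    def _lateral_margin_mm(self) -> float:
        return 3.0 * self.beam_model.penumbra_sigma_mm

    def _lattice(self, beam: Beam, density_grid: np.ndarray, grid: GridSpec, roi=None):
        bm = self.beam_model
        e1, e2, dhat = _beam_frame(beam)
        src = beam.source_arr
        lo, hi = grid.bounding_box() if roi is None else roi
        corners = np.array([[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1]) for z in (lo[2], hi[2])])
        wc = (corners - src) @ dhat
        w_start = max(float(wc.min()), 1.0)
        w_end = float(wc.max())
        if w_end <= w_start:
            raise ValueError("beam does not reach the grid")
        dw = self.step_w_mm
        nw = int(np.ceil((w_end - w_start) / dw))
        w = w_start + (np.arange(nw) + 0.5) * dw

        du = self.lateral_spacing_mm
        field_r = beam.aperture_radius_mm * w_end / beam.sad_mm
        half = field_r + self._lateral_margin_mm()
        nu_half = int(np.ceil(half / du))
        uv = (np.arange(2 * nu_half + 1) - nu_half) * du
        u0 = float(uv[0])

        # fractional voxel indices of the lattice, built per axis to avoid a
        # (nu, nu, nw, 3) temporary
        origin = np.asarray(grid.origin)
        spacing = np.asarray(grid.spacing)
        coords = [
            (
                src[ax]
                + uv[:, None, None] * e1[ax]
                + uv[None, :, None] * e2[ax]
                + w[None, None, :] * dhat[ax]
                - origin[ax]
            )
            / spacing[ax]
            for ax in range(3)
        ]
        rho = ndimage.map_coordinates(
            np.asarray(density_grid, dtype=np.float32), coords, order=1, cval=0.0
        )

        # midpoint cumulative radiological depth along each parallel ray (cm)
        depth = (np.cumsum(rho, axis=2, dtype=np.float32) - rho / 2.0) * np.float32(dw / 10.0)
        inv_w = beam.sad_mm / w
        r_sad = np.sqrt(uv[:, None] ** 2 + uv[None, :] ** 2)[:, :, None] * inv_w[None, None, :]
        primary = (
            bm.calibration_cgy_per_mu
            * bm.output_factor(beam.collimator_id)
            * bm.tpr(depth)
            * bm.ocr(r_sad, beam.aperture_radius_mm)
            * inv_w[None, None, :] ** 2
        ).astype(np.float32)
        geom = (src, e1, e2, dhat, u0, du, w_start, dw)
        return geom, primary, rho

    def beam_field(self, beam: Beam, density_grid: np.ndarray, grid: GridSpec, roi=None) -> _BeamField:
        geom, primary, rho = self._lattice(beam, density_grid, grid, roi)
        return _BeamField(*geom, self._transport(primary, rho, self.lateral_spacing_mm))

    def _transport(self, primary: np.ndarray, rho: np.ndarray, du: float) -> np.ndarray:
        return primary  # no lateral coupling

    def point_dose(self, beam: Beam, density_grid: np.ndarray, grid: GridSpec, points) -> np.ndarray:
        """Dose per unit beam weight (cGy/MU) at arbitrary world points."""
        return self.beam_field(beam, density_grid, grid).sample(points)

    def beamset_point_dose(self, beamset: BeamSet, density_grid, grid, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        total = np.zeros(len(pts))
        for beam, w in zip(beamset.beams, beamset.weights):
            if w <= 0:
                continue
            total += w * self.point_dose(beam, density_grid, grid, pts)
        return total

    def dose(self, beamset: BeamSet, density_grid, grid: GridSpec, calc_mask=None) -> DoseGrid:
        values = np.zeros(grid.shape)
        mask = np.ones(grid.shape, dtype=bool) if calc_mask is None else np.asarray(calc_mask, dtype=bool)
        idx = np.argwhere(mask)
        pts = grid.voxel_centers(idx)
        # the lattice may be trimmed to the evaluated region plus everything
        # upstream that can attenuate (any nonzero density)
        roi = roi_bounds(grid, mask | (np.asarray(density_grid) > 0)) if calc_mask is not None else None
        total = np.zeros(len(pts))
        for beam, w in zip(beamset.beams, beamset.weights):
            if w <= 0:
                continue
            total += w * self.beam_field(beam, density_grid, grid, roi).sample(pts)
        values[mask] = total
        return DoseGrid(values, grid)


class KernelSurrogate(RayTracingEPL):
    """Deterministic kernel-superposition surrogate with 1/dose noise.

    Primary energy (primary dose times local density) is redistributed
    laterally with Gaussians of width sigma0/rho, discretized into
    ``n_sigma_bins`` geometric levels between sigma0 and sigma_max.
    ``sigma0_mm = 0`` disables the redistribution, making the engine
    numerically identical to the ray-tracing result (a null-difference
    control); negative values are rejected.  ``bias_cgy`` is a constant
    offset subtracted from accumulated dose inside ``bias_mask`` by the
    4D pipeline — a controllable engine discrepancy for parameter
    recovery, never part of per-beam influence columns.
    """

    name = "MCSUR"

    def __init__(
        self,
        beam_model: BeamModel | None = None,
        sigma0_mm: float = 3.0,
        sigma_max_mm: float = 9.0,
        n_sigma_bins: int = 4,
        rho_floor: float = 0.05,
        bias_cgy: float = 0.0,
        bias_mask: np.ndarray | None = None,
        step_w_mm: float = 3.0,
        lateral_spacing_mm: float = 3.5,
        spread_truncate_sigmas: float = 2.5,
    ):
        if sigma0_mm < 0:
            raise ValueError("sigma0_mm must be >= 0")
        if sigma_max_mm < sigma0_mm:
            raise ValueError("sigma_max_mm must be >= sigma0_mm")
        super().__init__(beam_model, step_w_mm, lateral_spacing_mm)
        self.sigma0_mm = float(sigma0_mm)
        self.sigma_max_mm = float(sigma_max_mm)
        self.n_sigma_bins = int(n_sigma_bins)
        self.rho_floor = float(rho_floor)
        self.bias_cgy = float(bias_cgy)
        self.bias_mask = bias_mask
        self.spread_truncate_sigmas = float(spread_truncate_sigmas)

    def _lateral_margin_mm(self) -> float:
        spread = self.spread_truncate_sigmas * self.sigma_max_mm if self.sigma0_mm > 0 else 0.0
        return 3.0 * self.beam_model.penumbra_sigma_mm + spread

    def beam_field_pair(
        self, beam: Beam, density_grid: np.ndarray, grid: GridSpec, roi=None
    ) -> tuple[_BeamField, _BeamField]:
        """(ray-tracing field, surrogate field) from one shared lattice pass."""
        geom, primary, rho = self._lattice(beam, density_grid, grid, roi)
        epl = _BeamField(*geom, primary)
        sur = _BeamField(*geom, self._transport(primary, rho, self.lateral_spacing_mm))
        return epl, sur

    def _sigma_levels(self) -> np.ndarray:
        if self.sigma_max_mm == self.sigma0_mm or self.n_sigma_bins == 1:
            return np.array([self.sigma0_mm])
        return np.geomspace(self.sigma0_mm, self.sigma_max_mm, self.n_sigma_bins)

    def _rho_bin_edges(self) -> np.ndarray:
        """Density thresholds between adjacent sigma levels (descending rho)."""
        levels = self._sigma_levels()
        mids = np.sqrt(levels[:-1] * levels[1:])  # geometric midpoints in sigma
        return self.sigma0_mm / mids  # sigma = sigma0/rho is decreasing in rho

    def _transport(self, primary: np.ndarray, rho: np.ndarray, du: float) -> np.ndarray:
        if self.sigma0_mm == 0.0:
            return primary
        rho_f = np.maximum(rho, np.float32(self.rho_floor))
        levels = self._sigma_levels()
        # voxel -> nearest sigma level (in log sigma), via density thresholds
        bins = len(levels) - 1 - np.searchsorted(np.sort(self._rho_bin_edges()), rho_f)
        energy = primary * rho
        received = np.zeros_like(energy)
        for k, level in enumerate(levels):
            sel = bins == k
            if not sel.any():
                continue
            part = np.where(sel, energy, np.float32(0.0))
            s = level / du
            part = ndimage.gaussian_filter1d(part, s, axis=0, mode="constant")
            part = ndimage.gaussian_filter1d(part, s, axis=1, mode="constant")
            received += part
        return received / rho_f

    def dose(
        self,
        beamset: BeamSet,
        density_grid,
        grid: GridSpec,
        calc_mask=None,
        uncertainty: UncertaintySpec | None = None,
    ) -> tuple[DoseGrid, UncertaintyGrid | None]:
        clean = super().dose(beamset, density_grid, grid, calc_mask)
        unc = None
        if uncertainty is not None and clean.dmax > 0:
            unc = uncertainty_map(clean, uncertainty)
            if uncertainty.sigma_at_dmax > 0:
                clean = DoseGrid(apply_statistical_noise(clean.values, uncertainty), grid)
        return clean, unc


def roi_bounds(grid: GridSpec, mask: np.ndarray, margin_mm: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
    """World bounding box of a mask (used to trim beam lattices to the body)."""
    idx = np.argwhere(np.asarray(mask, dtype=bool))
    if len(idx) == 0:
        return grid.bounding_box()
    sp = np.asarray(grid.spacing)
    lo = grid.voxel_centers(idx.min(axis=0)) - sp / 2 - margin_mm
    hi = grid.voxel_centers(idx.max(axis=0)) + sp / 2 + margin_mm
    glo, ghi = grid.bounding_box()
    return np.maximum(lo, glo), np.minimum(hi, ghi)


# ---------------------------------------------------------------------------
# statistical noise and uncertainty

def apply_statistical_noise(dose_values: np.ndarray, spec: UncertaintySpec) -> np.ndarray:
    """Seeded multiplicative Gaussian noise, relative SD = sigma*Dmax/D(x).

    Equivalent to adding i.i.d. absolute noise of SD sigma_at_dmax*Dmax on
    every voxel with nonzero dose; zero-dose voxels stay zero and the
    result is clipped at zero (dose cannot be negative).
    """
    values = np.asarray(dose_values, dtype=np.float64)
    dmax = float(values.max())
    if spec.sigma_at_dmax == 0.0 or dmax == 0.0:
        return values.copy()
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.sigma_at_dmax * dmax, values.shape)
    return np.clip(np.where(values > 0, values + noise, 0.0), 0.0, None)


def uncertainty_map(dose: DoseGrid, spec: UncertaintySpec) -> UncertaintyGrid:
    """Relative statistical uncertainty per voxel: sigma*Dmax/max(D, eps)."""
    dmax = dose.dmax
    if dmax <= 0:
        raise ValueError("uncertainty map undefined for an all-zero dose grid")
    eps = 1e-6 * dmax
    rel = spec.sigma_at_dmax * dmax / np.maximum(dose.values, eps)
    return UncertaintyGrid(rel, dose.grid, spec.sigma_at_dmax)


# ---------------------------------------------------------------------------
# functional wrappers

def epl_dose(
    beamset: BeamSet,
    density_grid,
    grid: GridSpec,
    calc_mask=None,
    beam_model: BeamModel | None = None,
    **engine_kwargs,
) -> DoseGrid:
    return RayTracingEPL(beam_model, **engine_kwargs).dose(beamset, density_grid, grid, calc_mask)


def mc_surrogate_dose(
    beamset: BeamSet,
    density_grid,
    grid: GridSpec,
    calc_mask=None,
    uncertainty: UncertaintySpec | None = None,
    beam_model: BeamModel | None = None,
    **engine_kwargs,
) -> tuple[DoseGrid, UncertaintyGrid | None]:
    engine = KernelSurrogate(beam_model, **engine_kwargs)
    return engine.dose(beamset, density_grid, grid, calc_mask, uncertainty)
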