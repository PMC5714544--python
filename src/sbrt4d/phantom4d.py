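"""Synthetic 4D breathing thorax phantoms with ground-truth deformation fields.

A phantom is a voxelized thorax on a regular grid: a water-density body,
a low-density lung compartment, an ellipsoidal soft-tissue tumor (GTV)
that rides a 1-cos breathing trajectory, and tubular organs at risk
(cord with an optional bony shield, esophagus, air-filled trachea).
Each breathing cycle is discretized into ``n_phases`` equal time bins;
phase 0 is the end-of-exhale (EOE) reference on which all structure
masks live.  The inhale motion stretches the lung along the motion axis
(diaphragm excursion) and the lung density is rescaled each phase so
that total lung mass is conserved.  The displacement fields that carry
reference-frame points into each phase are analytic (rigid tumor
translation with a smooth falloff to zero at the chest wall), so dose
warping can be tested against closed forms.

Axes convention: x = lateral, y = superior-inferior (principal motion),
z = anterior(+)/posterior(-).  All lengths mm, densities g/cc.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "GridSpec",
    "StructureSet",
    "PhantomConfig",
    "CohortConfig",
    "Phase4DStudy",
    "make_phantom",
    "make_cohort",
    "expand_margin",
    "save_study",
    "load_study",
]

#: canonical structure names, in reporting order
STRUCTURE_NAMES = ("GTV", "PTV", "lung", "cord", "esophagus", "trachea", "body")
OAR_NAMES = ("cord", "esophagus", "trachea")


@dataclass(frozen=True)
class GridSpec:
    """Regular 3D grid: ``world = origin + index * spacing`` (voxel centers)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError(f"grid shape must be 3 positive counts, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"grid spacings must be > 0, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @classmethod
    def centered(cls, shape, spacing) -> "GridSpec":
        """Grid whose voxel-center cloud is symmetric about the world origin."""
        shape = tuple(int(n) for n in shape)
        spacing = tuple(float(s) for s in spacing)
        origin = tuple(-(n - 1) * s / 2.0 for n, s in zip(shape, spacing))
        return cls(shape, spacing, origin)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical size of the voxel-center bounding box per axis."""
        return tuple((n - 1) * s for n, s in zip(self.shape, self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return np.meshgrid(*(self.axis_coords(a) for a in range(3)), indexing="ij")

    def voxel_centers(self, index_array: np.ndarray) -> np.ndarray:
        """World coordinates (N,3) of integer voxel indices (N,3)."""
        idx = np.asarray(index_array, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of world points (N,3)."""
        p = np.asarray(points, dtype=float)
        return (p - np.asarray(self.origin)) / np.asarray(self.spacing)

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """Voxel-volume bounding box (lo, hi) in world mm (half-voxel beyond centers)."""
        sp = np.asarray(self.spacing)
        lo = np.asarray(self.origin) - sp / 2.0
        hi = np.asarray(self.origin) + (np.asarray(self.shape) - 0.5) * sp
        return lo, hi

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff


@dataclass
class StructureSet:
    """Named binary masks on the reference (EOE) grid."""

    masks: dict[str, np.ndarray]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def names(self):
        return list(self.masks)

    def validate(self) -> None:
        for name in STRUCTURE_NAMES:
            if name not in self.masks:
                raise ValueError(f"missing structure mask {name!r}")
        gtv, ptv, body = self["GTV"], self["PTV"], self["body"]
        if not (gtv & ~ptv).sum() == 0:
            raise ValueError("GTV must be contained in PTV")
        if not (ptv & ~body).sum() == 0:
            raise ValueError("PTV must be contained in body")
        for name in OAR_NAMES:
            if (self[name] & gtv).any():
                raise ValueError(f"GTV overlaps OAR {name!r}")


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and material parameters of one synthetic patient.

    Defaults follow a small-FOV thorax: water body, 0.25 g/cc lung,
    soft-tissue tumor, optional 1.6 g/cc vertebral shield around the cord.
    """

    grid: GridSpec = field(default_factory=lambda: GridSpec.centered((48, 48, 48), (3.0, 3.0, 3.0)))
    n_phases: int = 10
    gtv_volume_cc: float = 10.2
    amplitude_mm: float = 7.0  # peak-to-peak breathing amplitude of the GTV centroid
    motion_direction: tuple[float, float, float] = (0.0, -1.0, 0.0)  # inferior at inhale
    gtv_center: tuple[float, float, float] | None = None  # None -> lung center
    ptv_margin_mm: float = 5.0
    lung_density: float = 0.25
    soft_tissue_density: float = 1.0
    bone_density: float = 1.6
    air_density: float = 0.05
    cord_shield: bool = True
    breathing_lung_expansion: bool = True
    lung_mass_tolerance: float = 0.01
    # anatomy (mm); body is an elliptic cylinder along y
    body_semiaxes_xz: tuple[float, float] = (68.0, 52.0)
    lung_center: tuple[float, float, float] = (-34.0, 0.0, 0.0)  # tumor-bearing lung
    lung_semiaxes: tuple[float, float, float] = (28.0, 48.0, 30.0)
    right_lung_center: tuple[float, float, float] = (36.0, 0.0, 0.0)
    right_lung_semiaxes: tuple[float, float, float] = (26.0, 48.0, 28.0)
    cord_xz: tuple[float, float] = (0.0, -42.0)
    cord_radius_mm: float = 4.0
    cord_shield_radius_mm: float = 9.0
    esophagus_xz: tuple[float, float] = (2.0, -24.0)
    esophagus_radius_mm: float = 4.5
    trachea_xz: tuple[float, float] = (2.0, -8.0)
    trachea_radius_mm: float = 6.0  # outer wall radius; the mask is the wall
    trachea_lumen_radius_mm: float = 3.5  # air-filled lumen inside the wall

    def gtv_radius_mm(self) -> float:
        return float((3.0 * self.gtv_volume_cc * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0))


@dataclass(frozen=True)
class CohortConfig:
    """Sampling ranges for a synthetic patient cohort."""

    n_patients: int = 10
    gtv_volume_range_cc: tuple[float, float] = (0.6, 77.4)
    amplitude_range_mm: tuple[float, float] = (1.0, 22.5)
    # (total dose cGy, fractions) with assignment probability of the first entry
    prescriptions: tuple[tuple[float, int], tuple[float, int]] = ((6000.0, 3), (4800.0, 4))
    first_prescription_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for rng_ in (self.gtv_volume_range_cc, self.amplitude_range_mm):
            lo, hi = rng_
            if not (0 < lo <= hi):
                raise ValueError(f"range must be positive and ordered, got {rng_}")


@dataclass
class Phase4DStudy:
    """One synthetic 4D patient: per-phase density, analytic DVFs, masks.

    ``dvf_to_ref[p]`` holds per-voxel displacement u(x) in mm on the
    reference grid such that reference point x corresponds to x + u(x)
    in phase p.  Phase 0 (EOE) is the reference and its field is zero.
    """

    grid: GridSpec
    n_phases: int
    density: list[np.ndarray]
    dvf_to_ref: list[np.ndarray]
    phase_weights: np.ndarray
    structures: StructureSet
    gtv_displacement_mm: np.ndarray  # (n_phases, 3)
    meta: dict = field(default_factory=dict)

    reference_phase: int = 0

    def validate(self, lung_mass_tolerance: float = 0.01) -> None:
        if abs(float(self.phase_weights.sum()) - 1.0) > 1e-9:
            raise ValueError("phase weights must sum to 1")
        if any((d < 0).any() for d in self.density):
            raise ValueError("density must be nonnegative")
        if np.abs(self.dvf_to_ref[self.reference_phase]).max() != 0.0:
            raise ValueError("reference-phase DVF must be identically zero")
        masses = self.lung_mass_g()
        drift = (masses.max() - masses.min()) / masses.mean()
        if drift > lung_mass_tolerance:
            raise ValueError(f"lung mass drift {drift:.3%} exceeds tolerance")
        self.structures.validate()

    def lung_mass_g(self) -> np.ndarray:
        """Total lung mass per phase (g), summed over the per-phase lung region."""
        vv = self.grid.voxel_volume_cc
        out = []
        for p in range(self.n_phases):
            lung = self.meta["phase_lung_masks"][p]
            out.append(float(self.density[p][lung].sum()) * vv)
        return np.asarray(out)


def _ellipsoid_mask(grid: GridSpec, center, semiaxes) -> np.ndarray:
    x, y, z = grid.meshgrid()
    cx, cy, cz = center
    ax, ay, az = semiaxes
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def _cylinder_mask(grid: GridSpec, xz_center, radius, y_range=None) -> np.ndarray:
    x, y, z = grid.meshgrid()
    cx, cz = xz_center
    m = (x - cx) ** 2 + (z - cz) ** 2 <= radius**2
    if y_range is not None:
        m &= (y >= y_range[0]) & (y <= y_range[1])
    return m


def _ball_structuring_element(margin_mm: float, spacing) -> np.ndarray:
    """Discrete ball of physical radius ``margin_mm`` (anisotropic spacing)."""
    radii = [int(np.floor(margin_mm / s + 1e-9)) for s in spacing]
    grids = np.meshgrid(*(np.arange(-r, r + 1) for r in radii), indexing="ij")
    dist2 = sum((g * s) ** 2 for g, s in zip(grids, spacing))
    return dist2 <= margin_mm**2 + 1e-9


def expand_margin(mask: np.ndarray, margin_mm: float, spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Dilate a binary mask by a discrete ball of the given physical radius."""
    if margin_mm < 0:
        raise ValueError("margin must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if margin_mm == 0:
        return mask.copy()
    extent = [n * s for n, s in zip(mask.shape, spacing)]
    if margin_mm > max(extent):
        raise ValueError(f"margin {margin_mm} mm exceeds grid extent {max(extent)} mm")
    selem = _ball_structuring_element(margin_mm, spacing)
    return ndimage.binary_dilation(mask, structure=selem)


def _breathing_displacements(amplitude_mm: float, n_phases: int) -> np.ndarray:
    """1-cos trajectory over equal time bins: 0 at EOE, peak-to-peak amplitude."""
    t = np.arange(n_phases) / n_phases
    return amplitude_mm / 2.0 * (1.0 - np.cos(2.0 * np.pi * t))


def make_phantom(config: PhantomConfig, seed: int | None = None) -> Phase4DStudy:
    """Build one seeded 4D breathing phantom.

    The seed jitters the GTV position inside the feasible region of the
    lung; everything else is deterministic given the configuration.
    Raises if the GTV would overlap an OAR or leave the lung at any phase.
    """
    if config.n_phases < 2:
        raise ValueError("n_phases must be >= 2")
    grid = config.grid
    r_gtv = config.gtv_radius_mm()
    amp = float(config.amplitude_mm)
    mdir = np.asarray(config.motion_direction, dtype=float)
    if not np.isclose(np.linalg.norm(mdir), 1.0):
        raise ValueError("motion_direction must be a unit vector")
    if np.sum(np.abs(mdir) > 1e-12) != 1:
        raise ValueError("motion_direction must be axis-aligned")
    maxis = int(np.argmax(np.abs(mdir)))

    lung_c = np.asarray(config.lung_center, dtype=float)
    lung_a = np.asarray(config.lung_semiaxes, dtype=float)

    # GTV placement: default at lung center, optionally jittered by the seed
    # within the box that keeps the whole trajectory inside the lung.
    if config.gtv_center is not None:
        gtv_c = np.asarray(config.gtv_center, dtype=float)
    else:
        gtv_c = lung_c.copy()
        if seed is not None:
            rng = np.random.default_rng(seed)
            slack = lung_a - r_gtv - 2.0  # mm of free play per axis
            slack[maxis] = max(slack[maxis] - amp, 0.0)
            slack = np.maximum(slack, 0.0) * 0.5
            gtv_c = lung_c + rng.uniform(-slack, slack)

    disp = _breathing_displacements(amp, config.n_phases)
    # lung stretch per phase: the boundary opposite to the motion direction
    # (diaphragm) follows the full excursion, the apex stays fixed.
    densities: list[np.ndarray] = []
    phase_lung_masks: list[np.ndarray] = []
    gtv_disp_vec = np.outer(disp, mdir)

    # reference structures (phase 0, d=0)
    gtv_ref = _ellipsoid_mask(grid, gtv_c, (r_gtv,) * 3)
    if gtv_ref.sum() == 0:
        raise ValueError("GTV too small for the grid resolution")
    x, y, z = grid.meshgrid()
    body = (x / config.body_semiaxes_xz[0]) ** 2 + (z / config.body_semiaxes_xz[1]) ** 2 <= 1.0
    cord = _cylinder_mask(grid, config.cord_xz, config.cord_radius_mm)
    shield = _cylinder_mask(grid, config.cord_xz, config.cord_shield_radius_mm) & ~cord
    esophagus = _cylinder_mask(grid, config.esophagus_xz, config.esophagus_radius_mm)
    trachea_outer = _cylinder_mask(grid, config.trachea_xz, config.trachea_radius_mm, y_range=(0.0, np.inf))
    trachea_lumen = _cylinder_mask(grid, config.trachea_xz, config.trachea_lumen_radius_mm, y_range=(0.0, np.inf))
    trachea = trachea_outer & ~trachea_lumen  # contour the wall, not the air column
    cord &= body
    shield &= body
    esophagus &= body
    trachea &= body
    trachea_lumen &= body

    for name, mask in (("cord", cord), ("esophagus", esophagus), ("trachea", trachea)):
        if (mask & gtv_ref).any():
            raise ValueError(f"GTV overlaps OAR {name!r}")

    rlung_c = np.asarray(config.right_lung_center, dtype=float)
    rlung_a = np.asarray(config.right_lung_semiaxes, dtype=float)
    n_lung_ref = None
    for p in range(config.n_phases):
        d = disp[p]
        if config.breathing_lung_expansion:
            # apex fixed, diaphragm-side boundary follows the excursion
            c_p = lung_c + (d / 2.0) * mdir
            a_p = lung_a.copy()
            a_p[maxis] += d / 2.0
            rc_p = rlung_c + (d / 2.0) * mdir
            ra_p = rlung_a.copy()
            ra_p[maxis] += d / 2.0
        else:
            c_p, a_p = lung_c, lung_a
            rc_p, ra_p = rlung_c, rlung_a
        left_region = _ellipsoid_mask(grid, c_p, a_p) & body
        lung_region = left_region | (_ellipsoid_mask(grid, rc_p, ra_p) & body)
        lo, hi = grid.bounding_box()
        c_gtv_p = gtv_c + gtv_disp_vec[p]
        if np.any(c_gtv_p - r_gtv < lo) or np.any(c_gtv_p + r_gtv > hi):
            raise ValueError(
                f"GTV (r={r_gtv:.1f} mm) leaves the lung/grid at phase {p} "
                f"(amplitude {amp:.1f} mm)"
            )
        gtv_p = _ellipsoid_mask(grid, c_gtv_p, (r_gtv,) * 3)
        if (gtv_p & ~left_region).any():
            raise ValueError(
                f"GTV (r={r_gtv:.1f} mm) leaves the lung at phase {p} "
                f"(amplitude {amp:.1f} mm)"
            )
        lung_p = lung_region & ~gtv_p
        n_lung = int(lung_p.sum())
        if n_lung_ref is None:
            n_lung_ref = n_lung
        rho_lung = config.lung_density * n_lung_ref / n_lung  # mass conservation

        rho = np.zeros(grid.shape, dtype=np.float64)
        rho[body] = config.soft_tissue_density
        rho[lung_p] = rho_lung
        rho[gtv_p] = config.soft_tissue_density
        if config.cord_shield:
            rho[shield] = config.bone_density
        rho[cord] = config.soft_tissue_density
        rho[esophagus] = config.soft_tissue_density
        rho[trachea] = config.soft_tissue_density
        rho[trachea_lumen] = config.air_density
        densities.append(rho)
        phase_lung_masks.append(lung_p)

    ptv = expand_margin(gtv_ref, config.ptv_margin_mm, grid.spacing) & body
    ptv |= gtv_ref
    lung_struct = phase_lung_masks[0]
    structures = StructureSet(
        {
            "GTV": gtv_ref,
            "PTV": ptv,
            "lung": lung_struct,
            "cord": cord,
            "esophagus": esophagus,
            "trachea": trachea,
            "body": body,
        }
    )

    # analytic DVFs: rigid GTV translation, smooth falloff to zero at the
    # lung boundary, zero outside the lung compartment.
    lung_all = phase_lung_masks[0] | gtv_ref
    sp = grid.spacing
    d_gtv = ndimage.distance_transform_edt(~gtv_ref, sampling=sp)
    d_bnd = ndimage.distance_transform_edt(lung_all, sampling=sp)
    with np.errstate(invalid="ignore"):
        w = np.where(lung_all, d_bnd / np.maximum(d_bnd + d_gtv, 1e-9), 0.0)
    w[gtv_ref] = 1.0

    dvfs: list[np.ndarray] = []
    for p in range(config.n_phases):
        if p == 0:
            dvfs.append(np.zeros(grid.shape + (3,), dtype=np.float32))
        else:
            u = (w[..., None] * gtv_disp_vec[p]).astype(np.float32)
            dvfs.append(u)

    study = Phase4DStudy(
        grid=grid,
        n_phases=config.n_phases,
        density=densities,
        dvf_to_ref=dvfs,
        phase_weights=np.full(config.n_phases, 1.0 / config.n_phases),
        structures=structures,
        gtv_displacement_mm=gtv_disp_vec,
        meta={
            "gtv_volume_cc": config.gtv_volume_cc,
            "amplitude_mm": amp,
            "gtv_center_mm": [float(v) for v in gtv_c],
            "gtv_radius_mm": r_gtv,
            "phase_lung_masks": phase_lung_masks,
            "seed": seed,
        },
    )
    study.validate(config.lung_mass_tolerance)
    return study


def make_cohort(cohort: CohortConfig, base_config: PhantomConfig | None = None) -> list[Phase4DStudy]:
    """Sample a deterministic cohort of phantoms.

    GTV volumes are drawn log-uniform over the configured range (tumor
    volumes span two orders of magnitude), motion amplitudes uniform,
    prescriptions assigned by the configured proportion.  Per-patient
    seeds are derived from the master seed by a fixed offset.
    """
    base = base_config or PhantomConfig()
    rng = np.random.default_rng(cohort.seed)
    lo_v, hi_v = cohort.gtv_volume_range_cc
    lo_a, hi_a = cohort.amplitude_range_mm
    volumes = np.exp(rng.uniform(np.log(lo_v), np.log(hi_v), cohort.n_patients))
    amplitudes = rng.uniform(lo_a, hi_a, cohort.n_patients)
    pick_first = rng.random(cohort.n_patients) < cohort.first_prescription_fraction

    studies = []
    for i in range(cohort.n_patients):
        cfg = dataclasses.replace(base, gtv_volume_cc=float(volumes[i]), amplitude_mm=float(amplitudes[i]))
        patient_seed = (cohort.seed + 1009 * (i + 1)) % (2**31)
        study = make_phantom(cfg, seed=patient_seed)
        rx = cohort.prescriptions[0] if pick_first[i] else cohort.prescriptions[1]
        study.meta.update(
            patient_id=i,
            prescription_cgy=float(rx[0]),
            fractions=int(rx[1]),
        )
        studies.append(study)
    return studies


# ---------------------------------------------------------------------------
# NIfTI / JSON I/O

def save_study(study: Phase4DStudy, outdir: str | Path) -> None:
    """Write a study as NIfTI volumes (one per phase / component) plus JSON."""
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aff = study.grid.affine()
    for p in range(study.n_phases):
        nib.save(nib.Nifti1Image(study.density[p].astype(np.float32), aff), outdir / f"density_phase{p:02d}.nii")
        nib.save(nib.Nifti1Image(study.dvf_to_ref[p].astype(np.float32), aff), outdir / f"dvf_phase{p:02d}.nii")
        nib.save(
            nib.Nifti1Image(study.meta["phase_lung_masks"][p].astype(np.uint8), aff),
            outdir / f"lungmask_phase{p:02d}.nii",
        )
    for name, mask in study.structures.masks.items():
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), aff), outdir / f"mask_{name}.nii")
    meta = {k: v for k, v in study.meta.items() if k != "phase_lung_masks"}
    info = {
        "grid": {"shape": study.grid.shape, "spacing": study.grid.spacing, "origin": study.grid.origin},
        "n_phases": study.n_phases,
        "phase_weights": study.phase_weights.tolist(),
        "gtv_displacement_mm": study.gtv_displacement_mm.tolist(),
        "meta": meta,
    }
    (outdir / "study.json").write_text(json.dumps(info, indent=2))


def load_study(indir: str | Path) -> Phase4DStudy:
    import nibabel as nib

    indir = Path(indir)
    info = json.loads((indir / "study.json").read_text())
    grid = GridSpec(tuple(info["grid"]["shape"]), tuple(info["grid"]["spacing"]), tuple(info["grid"]["origin"]))
    n_phases = info["n_phases"]
    density, dvfs, lung_masks = [], [], []
    for p in range(n_phases):
        density.append(np.asarray(nib.load(indir / f"density_phase{p:02d}.nii").dataobj, dtype=np.float64))
        dvfs.append(np.asarray(nib.load(indir / f"dvf_phase{p:02d}.nii").dataobj, dtype=np.float32))
        lung_masks.append(np.asarray(nib.load(indir / f"lungmask_phase{p:02d}.nii").dataobj) > 0)
    masks = {name: np.asarray(nib.load(indir / f"mask_{name}.nii").dataobj) > 0 for name in STRUCTURE_NAMES}
    meta = dict(info["meta"])
    meta["phase_lung_masks"] = lung_masks
    return Phase4DStudy(
        grid=grid,
        n_phases=n_phases,
        density=density,
        dvf_to_ref=dvfs,
        phase_weights=np.asarray(info["phase_weights"]),
        structures=StructureSet(masks),
        gtv_displacement_mm=np.asarray(info["gtv_displacement_mm"]),
        meta=meta,
    )
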