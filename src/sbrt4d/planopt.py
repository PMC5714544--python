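"""Sequential prioritized optimization of beam weights on 4D accumulated dose.

Because accumulated dose is linear in beam weights, each clinical
objective in the sequence is solved as a linear program over the dose
influence matrix (voxels x beams, cGy per MU of 4D-accumulated dose):
target coverage first, then target minimum dose, then one organ at a
time, finally total monitor units.  After each step the achieved value
is frozen as a constraint (within its allowed relaxation) for all later
steps, so earlier priorities can never silently degrade.  Infeasible
steps are skipped with a logged reason and the previous solution kept.
A tiny total-MU term breaks ties among degenerate optima so the solver
output is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .beams import BeamSet, shift_aperture, shift_beamset
from .dose4d import PhaseDoseSet, accumulate
from .dose_engines import (
    DoseGrid,
    KernelSurrogate,
    UncertaintyGrid,
    UncertaintySpec,
    roi_bounds,
    uncertainty_map,
)
from .dvh_stats import index_d
from .phantom4d import Phase4DStudy

__all__ = [
    "ObjectiveStep",
    "Prescription",
    "Plan",
    "VoxelSample",
    "default_steps",
    "default_caps",
    "sample_voxels",
    "influence_matrix",
    "sequential_optimize",
    "normalize_to_coverage",
    "compute_4d_dose",
    "recalc_plan",
]

log = logging.getLogger(__name__)

STEP_KINDS = (
    "maximize_coverage",
    "maximize_min_dose",
    "minimize_max_dose",
    "minimize_mean_dose",
    "minimize_V_D",
    "minimize_total_mu",
)


@dataclass(frozen=True)
class ObjectiveStep:
    kind: str
    structure: str | None = None
    level_cgy: float | None = None  # prescription level / V_D threshold
    relaxation: float = 0.0  # allowed degradation of the achieved value

    def __post_init__(self):
        if self.kind not in STEP_KINDS:
            raise ValueError(f"unknown objective kind {self.kind!r}")
        if self.relaxation < 0:
            raise ValueError("relaxation must be >= 0")


@dataclass(frozen=True)
class Prescription:
    total_cgy: float
    fractions: int
    coverage_fraction: float = 0.95

    def __post_init__(self):
        if not (0.0 < self.coverage_fraction <= 1.0):
            raise ValueError("coverage fraction must be in (0, 1]")
        if self.total_cgy <= 0 or self.fractions < 1:
            raise ValueError("invalid prescription")


@dataclass
class Plan:
    """Beam weights plus the engine they were scored with and the 4D dose."""

    beamset: BeamSet
    engine_name: str
    prescription: Prescription
    provenance: str  # 4EPLopt | 4MCrecal | 4MCopt
    dose: DoseGrid | None = None
    uncertainty: UncertaintyGrid | None = None
    meta: dict = field(default_factory=dict)


def default_steps(prescription: Prescription, lung_v_level_cgy: float = 2000.0) -> list[ObjectiveStep]:
    """Priority order: PTV coverage, PTV min dose, target conformity
    (maximum-dose homogenization), serial organs, lung V20, monitor units."""
    rx = prescription.total_cgy
    return [
        ObjectiveStep("maximize_coverage", "PTV", rx, relaxation=0.0),
        ObjectiveStep("maximize_min_dose", "PTV", rx, relaxation=0.005 * rx),
        ObjectiveStep("minimize_max_dose", "PTV", relaxation=0.01 * rx),
        ObjectiveStep("minimize_max_dose", "cord", relaxation=10.0),
        ObjectiveStep("minimize_max_dose", "esophagus", relaxation=10.0),
        ObjectiveStep("minimize_max_dose", "trachea", relaxation=10.0),
        ObjectiveStep("minimize_V_D", "lung", lung_v_level_cgy, relaxation=5.0),
        ObjectiveStep("minimize_total_mu"),
    ]


def default_caps(prescription: Prescription) -> dict[str, float]:
    """Hard maximum-dose caps (cGy) enforced in every step."""
    rx = prescription.total_cgy
    return {
        "PTV": 1.6 * rx,
        "body": 1.6 * rx,
        "cord": 1800.0,
        "esophagus": 2700.0,
        "trachea": 3000.0,
    }


@dataclass
class VoxelSample:
    """Sampled reference-grid voxels and per-structure row positions."""

    indices: np.ndarray  # (N, 3) integer voxel indices
    rows: dict[str, np.ndarray]


def sample_voxels(
    study: Phase4DStudy,
    seed: int = 0,
    max_ptv: int = 500,
    max_oar: int = 120,
    max_lung: int = 250,
    max_body: int = 150,
) -> VoxelSample:
    """Seeded voxel subsample keeping the LP desk-scale.

    All PTV voxels are used up to a cap; organs at risk, lung, and a body
    shell (everything else) are randomly subsampled.
    """
    rng = np.random.default_rng(seed)
    structures = study.structures
    caps = {
        "PTV": max_ptv,
        "cord": max_oar,
        "esophagus": max_oar,
        "trachea": max_oar,
        "lung": max_lung,
        "body": max_body,
    }
    blocks, rows, start = [], {}, 0
    taken = np.zeros(study.grid.shape, dtype=bool)
    for name, cap in caps.items():
        mask = structures[name].copy()
        if name == "body":
            mask &= ~taken
        else:
            taken |= mask
        idx = np.argwhere(mask)
        if len(idx) == 0:
            rows[name] = np.arange(0)
            continue
        if len(idx) > cap:
            sel = rng.choice(len(idx), size=cap, replace=False)
            sel.sort()
            idx = idx[sel]
        blocks.append(idx)
        rows[name] = np.arange(start, start + len(idx))
        start += len(idx)
    return VoxelSample(np.concatenate(blocks, axis=0), rows)


def influence_matrix(
    beamset: BeamSet,
    study: Phase4DStudy,
    engine,
    sample: VoxelSample | np.ndarray,
) -> np.ndarray:
    """4D dose per unit beam weight at sampled reference voxels.

    Column b accumulates the per-phase dose of unit-weight beam b, with
    the aperture shifted by the phase GTV displacement, pulled back to
    the reference frame by sampling at the displaced voxel positions.
    Statistical noise is never applied here.
    """
    indices = sample.indices if isinstance(sample, VoxelSample) else np.asarray(sample)
    if len(indices) == 0:
        raise ValueError("empty voxel sample")
    grid = study.grid
    pts = grid.voxel_centers(indices)
    ii, jj, kk = indices[:, 0], indices[:, 1], indices[:, 2]
    warped_pts = [
        pts + study.dvf_to_ref[p][ii, jj, kk].astype(float) for p in range(study.n_phases)
    ]
    roi = roi_bounds(grid, study.structures["body"])
    A = np.zeros((len(indices), len(beamset)))
    for p in range(study.n_phases):
        w_p = study.phase_weights[p]
        disp = study.gtv_displacement_mm[p]
        density = study.density[p]
        for b, beam in enumerate(beamset.beams):
            fld = engine.beam_field(shift_aperture(beam, disp), density, grid, roi)
            A[:, b] += w_p * fld.sample(warped_pts[p])
    return A


def influence_matrix_pair(
    beamset: BeamSet,
    study: Phase4DStudy,
    surrogate: KernelSurrogate,
    sample: VoxelSample | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Ray-tracing and surrogate influence matrices from one lattice pass.

    Equivalent to calling :func:`influence_matrix` once per engine (the
    surrogate engine computes the ray-tracing primary internally), at
    roughly half the cost.
    """
    indices = sample.indices if isinstance(sample, VoxelSample) else np.asarray(sample)
    if len(indices) == 0:
        raise ValueError("empty voxel sample")
    grid = study.grid
    pts = grid.voxel_centers(indices)
    ii, jj, kk = indices[:, 0], indices[:, 1], indices[:, 2]
    roi = roi_bounds(grid, study.structures["body"])
    A_epl = np.zeros((len(indices), len(beamset)))
    A_sur = np.zeros((len(indices), len(beamset)))
    for p in range(study.n_phases):
        w_p = study.phase_weights[p]
        disp = study.gtv_displacement_mm[p]
        density = study.density[p]
        warped = pts + study.dvf_to_ref[p][ii, jj, kk].astype(float)
        for b, beam in enumerate(beamset.beams):
            f_epl, f_sur = surrogate.beam_field_pair(shift_aperture(beam, disp), density, grid, roi)
            A_epl[:, b] += w_p * f_epl.sample(warped)
            A_sur[:, b] += w_p * f_sur.sample(warped)
    return A_epl, A_sur


# ---------------------------------------------------------------------------
# LP assembly

def _achieved(A: np.ndarray, rows: dict, step: ObjectiveStep, w: np.ndarray) -> float:
    if step.kind == "minimize_total_mu":
        return float(w.sum())
    d = A[rows[step.structure]] @ w
    if step.kind == "maximize_coverage":
        return float(np.maximum(step.level_cgy - d, 0.0).mean())
    if step.kind == "maximize_min_dose":
        dmin = float(d.min())
        return min(dmin, step.level_cgy) if step.level_cgy is not None else dmin
    if step.kind == "minimize_max_dose":
        return float(d.max())
    if step.kind == "minimize_mean_dose":
        return float(d.mean())
    if step.kind == "minimize_V_D":
        return float(np.maximum(d - step.level_cgy, 0.0).mean())
    raise ValueError(step.kind)


class _LPAssembler:
    """Collects A_ub x <= b_ub blocks over variables [w, aux...]."""

    def __init__(self, n_b: int):
        self.n_b = n_b
        self.n_aux = 0
        self._blocks: list[tuple[sparse.csr_matrix, int, sparse.csr_matrix | None, np.ndarray]] = []
        self.c_aux: list[tuple[int, np.ndarray]] = []

    def new_aux(self, k: int) -> int:
        off = self.n_aux
        self.n_aux += k
        return off

    def add(self, w_block, b, aux_offset: int = 0, aux_block=None):
        w_block = sparse.csr_matrix(np.atleast_2d(w_block))
        if aux_block is not None:
            aux_block = sparse.csr_matrix(aux_block)
        self._blocks.append((w_block, aux_offset, aux_block, np.atleast_1d(np.asarray(b, dtype=float))))

    def assemble(self, c_w: np.ndarray):
        n = self.n_b + self.n_aux
        mats, bs = [], []
        for w_block, off, aux_block, b in self._blocks:
            m = w_block.shape[0]
            parts = [w_block]
            if self.n_aux:
                left = sparse.csr_matrix((m, off))
                if aux_block is not None:
                    right = sparse.csr_matrix((m, self.n_aux - off - aux_block.shape[1]))
                    parts += [left, aux_block, right]
                else:
                    parts += [sparse.csr_matrix((m, self.n_aux))]
            mats.append(sparse.hstack(parts, format="csr"))
            bs.append(b)
        A_ub = sparse.vstack(mats, format="csr")
        b_ub = np.concatenate(bs)
        c = np.zeros(n)
        c[: self.n_b] = c_w
        for off, vec in self.c_aux:
            c[self.n_b + off : self.n_b + off + len(vec)] = vec
        return c, A_ub, b_ub


def _add_hinge_block(lp: _LPAssembler, A_s: np.ndarray, level: float, sense: str):
    """Aux h >= max(0, +/-(A_s w - level)); returns (offset, m)."""
    m = A_s.shape[0]
    off = lp.new_aux(m)
    eye = -sparse.identity(m, format="csr")
    if sense == "under":  # h_i >= level - d_i
        lp.add(-A_s, -level * np.ones(m), off, eye)
    else:  # h_i >= d_i - level
        lp.add(A_s, level * np.ones(m), off, eye)
    return off, m


def _build_step_lp(A, rows, step, caps, frozen, mu_tiebreak):
    n_b = A.shape[1]
    lp = _LPAssembler(n_b)
    c_w = np.full(n_b, mu_tiebreak)

    for name, cap in caps.items():
        r = rows.get(name)
        if r is None or len(r) == 0:
            continue
        lp.add(A[r], cap * np.ones(len(r)))

    for prev, achieved in frozen:
        bound = achieved + prev.relaxation + 1e-9
        r = rows[prev.structure] if prev.structure else None
        if prev.kind == "maximize_coverage":
            off, m = _add_hinge_block(lp, A[r], prev.level_cgy, "under")
            ones = sparse.csr_matrix(np.ones((1, m)))
            lp.add(np.zeros((1, n_b)), [m * bound], off, ones)
        elif prev.kind == "maximize_min_dose":
            floor = max(achieved - prev.relaxation - 1e-9, 0.0)
            lp.add(-A[r], -floor * np.ones(len(r)))
        elif prev.kind == "minimize_max_dose":
            lp.add(A[r], bound * np.ones(len(r)))
        elif prev.kind == "minimize_mean_dose":
            lp.add(A[r].mean(axis=0), [bound])
        elif prev.kind == "minimize_V_D":
            off, m = _add_hinge_block(lp, A[r], prev.level_cgy, "over")
            ones = sparse.csr_matrix(np.ones((1, m)))
            lp.add(np.zeros((1, n_b)), [m * bound], off, ones)
        elif prev.kind == "minimize_total_mu":
            lp.add(np.ones((1, n_b)), [bound])

    if step.kind == "maximize_coverage":
        r = rows[step.structure]
        off, m = _add_hinge_block(lp, A[r], step.level_cgy, "under")
        lp.c_aux.append((off, np.full(m, 1.0 / m)))
    elif step.kind == "maximize_min_dose":
        r = rows[step.structure]
        off = lp.new_aux(1)
        ones = sparse.csr_matrix(np.ones((len(r), 1)))
        lp.add(-A[r], np.zeros(len(r)), off, ones)  # t - d_i <= 0
        if step.level_cgy is not None:  # ceiling: raise the floor only to the level
            lp.add(np.zeros((1, n_b)), [step.level_cgy], off, sparse.csr_matrix([[1.0]]))
        lp.c_aux.append((off, np.array([-1.0])))
    elif step.kind == "minimize_max_dose":
        r = rows[step.structure]
        off = lp.new_aux(1)
        ones = -sparse.csr_matrix(np.ones((len(r), 1)))
        lp.add(A[r], np.zeros(len(r)), off, ones)  # d_i - t <= 0
        lp.c_aux.append((off, np.array([1.0])))
    elif step.kind == "minimize_mean_dose":
        r = rows[step.structure]
        c_w = c_w + np.asarray(A[r].mean(axis=0)).ravel()
    elif step.kind == "minimize_V_D":
        r = rows[step.structure]
        off, m = _add_hinge_block(lp, A[r], step.level_cgy, "over")
        lp.c_aux.append((off, np.full(m, 1.0 / m)))
    elif step.kind == "minimize_total_mu":
        c_w = c_w + 1.0

    return lp.assemble(c_w)


def sequential_optimize(
    influence: np.ndarray,
    structure_rows: dict[str, np.ndarray],
    steps: list[ObjectiveStep],
    prescription: Prescription,
    caps: dict[str, float] | None = None,
    mu_tiebreak: float = 1e-6,
) -> tuple[np.ndarray, list[dict]]:
    """Run the prioritized step sequence; returns (weights, step log)."""
    if not steps:
        raise ValueError("steps must be nonempty")
    A = np.asarray(influence, dtype=float)
    n_b = A.shape[1]
    caps = default_caps(prescription) if caps is None else caps
    frozen: list[tuple[ObjectiveStep, float]] = []
    w = np.zeros(n_b)
    step_log: list[dict] = []
    for step in steps:
        step_ = step
        if step.kind == "maximize_coverage" and step.level_cgy is None:
            step_ = replace(step, level_cgy=prescription.total_cgy)
        skipped = None
        r = structure_rows.get(step_.structure) if step_.structure else None
        if step_.structure is not None and (r is None or len(r) == 0):
            skipped = "structure has no sampled voxels"
        else:
            c, A_ub, b_ub = _build_step_lp(A, structure_rows, step_, caps, frozen, mu_tiebreak)
            res = linprog(c, A_ub=A_ub, b_ub=b_ub, method="highs")
            if not res.success:
                skipped = f"infeasible or failed LP ({res.message})"
        if skipped is not None:
            log.warning("optimization step %s/%s skipped: %s", step_.kind, step_.structure, skipped)
            step_log.append({"kind": step_.kind, "structure": step_.structure, "status": "skipped", "reason": skipped})
            continue
        w = np.clip(res.x[:n_b], 0.0, None)
        achieved = _achieved(A, structure_rows, step_, w)
        frozen.append((step_, achieved))
        step_log.append({"kind": step_.kind, "structure": step_.structure, "status": "ok", "achieved": achieved})
    return w, step_log


def normalize_to_coverage(
    weights: np.ndarray,
    influence_target_rows: np.ndarray,
    prescription: Prescription,
) -> np.ndarray:
    """Scale weights so the target D_{coverage} equals the prescription dose."""
    d = np.asarray(influence_target_rows) @ weights
    dv = index_d(d, prescription.coverage_fraction * 100.0)
    if dv <= 0:
        log.warning("coverage normalization skipped: D%.0f%% is zero", prescription.coverage_fraction * 100)
        return weights.copy()
    return weights * (prescription.total_cgy / dv)


# ---------------------------------------------------------------------------
# 4D dose of a weighted beam set

def compute_4d_dose(
    study: Phase4DStudy,
    beamset: BeamSet,
    engine,
    calc_mask=None,
    uncertainty: UncertaintySpec | None = None,
) -> tuple[DoseGrid, UncertaintyGrid | None]:
    """Per-phase dose with tracking shifts, pulled back and accumulated.

    Statistical noise (if requested and the engine supports it) is drawn
    independently per phase with seeds derived from the spec seed.  A
    kernel-surrogate bias, if configured, applies once to the accumulated
    reference-frame dose.
    """
    grid = study.grid
    doses = []
    for p in range(study.n_phases):
        bs_p = shift_beamset(beamset, study.gtv_displacement_mm[p])
        if isinstance(engine, KernelSurrogate):
            spec_p = None
            if uncertainty is not None:
                spec_p = UncertaintySpec(uncertainty.sigma_at_dmax, (uncertainty.seed + 7919 * p) % 2**31)
            d_p, _ = engine.dose(bs_p, study.density[p], grid, calc_mask, spec_p)
        else:
            d_p = engine.dose(bs_p, study.density[p], grid, calc_mask)
        doses.append(d_p)
    acc = accumulate(PhaseDoseSet(doses, study.phase_weights), study.dvf_to_ref, study.reference_phase)
    if isinstance(engine, KernelSurrogate) and engine.bias_cgy != 0.0 and engine.bias_mask is not None:
        values = acc.values.copy()
        values[engine.bias_mask] = np.clip(values[engine.bias_mask] - engine.bias_cgy, 0.0, None)
        acc = DoseGrid(values, grid)
    unc = None
    if uncertainty is not None and acc.dmax > 0:
        unc = uncertainty_map(acc, uncertainty)
    return acc, unc


def recalc_plan(
    plan: Plan,
    study: Phase4DStudy,
    engine,
    uncertainty: UncertaintySpec | None = None,
    calc_mask=None,
    provenance: str | None = None,
) -> Plan:
    """Recompute the frozen plan's 4D dose with another engine.

    Beam weights are never changed; only the dose, engine tag, and
    provenance are updated (final-calculation settings apply here).
    """
    dose, unc = compute_4d_dose(study, plan.beamset, engine, calc_mask, uncertainty)
    return Plan(
        beamset=plan.beamset.with_weights(plan.beamset.weights.copy()),
        engine_name=getattr(engine, "name", "unknown"),
        prescription=plan.prescription,
        provenance=provenance or f"recalc[{getattr(engine, 'name', '?')}]",
        dose=dose,
        uncertainty=unc,
        meta=dict(plan.meta),
    )
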