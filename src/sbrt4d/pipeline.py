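"""Full three-arm study: 4EPLopt -> 4MCrecal -> 4MCopt -> DPE/OCE statistics.

For every synthetic patient the pipeline optimizes beam weights against
the 4D-accumulated dose with the ray-tracing engine (4EPLopt), freezes
the weights and recalculates the 4D dose with the kernel surrogate
(4MCrecal, the dose-prediction-error comparison), and independently
re-optimizes with the surrogate in the loop (4MCopt, the
optimization-convergence-error comparison).  DVH indices of the three
arms feed the paired interval-growing equivalence tests and a
Table-style summary of reference means, minimal equivalence intervals,
and their percent of the reference.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dvh_stats
from .beams import generate_candidates
from .dose4d import dose_difference_map
from .dose_engines import BeamModel, KernelSurrogate, RayTracingEPL, UncertaintySpec
from .dvh_stats import (
    REPORT_INDICES,
    EquivalenceResult,
    equivalence_interval,
    evaluate_indices,
    index_label,
    normalized_index,
    spearman_vs_volume,
)
from .phantom4d import CohortConfig, GridSpec, Phase4DStudy, PhantomConfig, make_cohort
from .planopt import (
    Plan,
    Prescription,
    compute_4d_dose,
    default_steps,
    influence_matrix,
    influence_matrix_pair,
    normalize_to_coverage,
    recalc_plan,
    sample_voxels,
    sequential_optimize,
)

__all__ = ["StudyConfig", "StudyReport", "PatientResult", "run_study", "run_patient", "make_table2"]

log = logging.getLogger(__name__)

ARMS = ("4EPLopt", "4MCrecal", "4MCopt")
ERROR_TYPES = ("DPE", "OCE")
TABLE2_COLUMNS = [
    "index",
    "dpe_reference",
    "dpe_interval",
    "dpe_interval_pct",
    "oce_reference",
    "oce_interval",
    "oce_interval_pct",
]


@dataclass
class StudyConfig:
    """Everything needed to reproduce a study from a seed."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    # candidate beam geometry
    n_nodes: int = 150
    collimator_scale: tuple[float, ...] = (0.9, 1.35)  # aperture radius / PTV radius
    min_aperture_mm: float = 5.0
    sad_mm: float = 800.0
    # beam model / engines
    dmax_cm: float = 1.5
    mu_eff_per_mm: float = 0.005
    penumbra_sigma_mm: float = 3.0
    sigma0_mm: float = 3.0
    sigma_max_mm: float = 9.0
    n_sigma_bins: int = 4
    mc_bias_cgy: float = 0.0  # constant surrogate bias inside the PTV (control runs)
    # lattice resolution used for the study-scale dose computations
    step_w_mm: float = 3.0
    lateral_spacing_mm: float = 4.0
    spread_truncate_sigmas: float = 2.0
    # optimization voxel sampling
    max_ptv: int = 350
    max_oar: int = 80
    max_lung: int = 180
    max_body: int = 100
    # final calculation
    final_sigma_at_dmax: float = 0.01
    # equivalence testing
    step_d_cgy: float = 1.0  # 0.01 Gy
    step_v_pct: float = 0.01
    alpha: float = 0.05
    tolerance_pct: float = 3.0

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyConfig":
        d = json.loads(Path(path).read_text())
        phantom = d.pop("phantom", None)
        cohort = d.pop("cohort", None)
        cfg = cls(**{k: (tuple(v) if isinstance(v, list) else v) for k, v in d.items()})
        if phantom is not None:
            g = phantom.pop("grid")
            grid = GridSpec(tuple(g["shape"]), tuple(g["spacing"]), tuple(g["origin"]))
            phantom = {k: (tuple(v) if isinstance(v, list) else v) for k, v in phantom.items()}
            cfg.phantom = PhantomConfig(grid=grid, **phantom)
        if cohort is not None:
            cohort = {k: (_tuplify(v) if isinstance(v, list) else v) for k, v in cohort.items()}
            cfg.cohort = CohortConfig(**cohort)
        return cfg

    def beam_model(self) -> BeamModel:
        return BeamModel.default(
            dmax_cm=self.dmax_cm,
            mu_eff_per_mm=self.mu_eff_per_mm,
            penumbra_sigma_mm=self.penumbra_sigma_mm,
        )

    def engines(self, bias_mask=None):
        bm = self.beam_model()
        epl = RayTracingEPL(bm, step_w_mm=self.step_w_mm, lateral_spacing_mm=self.lateral_spacing_mm)
        mc = KernelSurrogate(
            bm,
            sigma0_mm=self.sigma0_mm,
            sigma_max_mm=self.sigma_max_mm,
            n_sigma_bins=self.n_sigma_bins,
            bias_cgy=self.mc_bias_cgy,
            bias_mask=bias_mask if self.mc_bias_cgy else None,
            step_w_mm=self.step_w_mm,
            lateral_spacing_mm=self.lateral_spacing_mm,
            spread_truncate_sigmas=self.spread_truncate_sigmas,
        )
        return epl, mc


def _tuplify(v):
    return tuple(_tuplify(x) if isinstance(x, list) else x for x in v)


@dataclass
class PatientResult:
    patient_id: int
    gtv_volume_cc: float
    amplitude_mm: float
    prescription: Prescription
    indices: dict[str, dict[str, float]]  # arm -> index label -> value
    plans: dict[str, Plan]
    step_logs: dict[str, list]


@dataclass
class StudyReport:
    per_patient: pd.DataFrame
    equivalence: pd.DataFrame
    table2: pd.DataFrame
    spearman_r_gtv_d98: float
    counts_within_tolerance: dict[str, int]
    n_patients: int
    failures: list[dict]


def run_patient(study: Phase4DStudy, config: StudyConfig) -> PatientResult:
    grid = study.grid
    structures = study.structures
    rx = Prescription(study.meta["prescription_cgy"], study.meta["fractions"])
    patient_seed = int(study.meta.get("seed") or 0)

    gtv_idx = np.argwhere(structures["GTV"])
    centroid = grid.voxel_centers(gtv_idx).mean(axis=0)
    ptv_pts = grid.voxel_centers(np.argwhere(structures["PTV"]))
    r_ptv = float(np.linalg.norm(ptv_pts - centroid, axis=1).max())
    radii = [max(s * r_ptv, config.min_aperture_mm) for s in config.collimator_scale]
    beamset = generate_candidates(config.n_nodes, radii, centroid, config.sad_mm)

    epl, mc = config.engines(bias_mask=structures["PTV"])
    sample = sample_voxels(
        study,
        seed=patient_seed + 1,
        max_ptv=config.max_ptv,
        max_oar=config.max_oar,
        max_lung=config.max_lung,
        max_body=config.max_body,
    )
    steps = default_steps(rx)
    body = structures["body"]

    A_epl, A_sur = influence_matrix_pair(beamset, study, mc, sample)

    def _optimize(A):
        w, slog = sequential_optimize(A, sample.rows, steps, rx)
        w = normalize_to_coverage(w, A[sample.rows["PTV"]], rx)
        w[w < 1e-9 * max(w.max(), 1e-30)] = 0.0
        return w, slog

    w_epl, log_epl = _optimize(A_epl)
    bs_epl = beamset.with_weights(w_epl)
    dose_eplopt, _ = _as_pair(compute_4d_dose(study, bs_epl, epl, body))
    plan_eplopt = Plan(bs_epl, epl.name, rx, "4EPLopt", dose=dose_eplopt)

    plan_recal = recalc_plan(
        plan_eplopt,
        study,
        mc,
        uncertainty=UncertaintySpec(config.final_sigma_at_dmax, (patient_seed + 101) % 2**31),
        calc_mask=body,
        provenance="4MCrecal",
    )

    w_mc, log_mc = _optimize(A_sur)
    bs_mc = beamset.with_weights(w_mc)
    dose_mcopt, unc_mcopt = compute_4d_dose(
        study,
        bs_mc,
        mc,
        body,
        uncertainty=UncertaintySpec(config.final_sigma_at_dmax, (patient_seed + 202) % 2**31),
    )
    plan_mcopt = Plan(bs_mc, mc.name, rx, "4MCopt", dose=dose_mcopt, uncertainty=unc_mcopt)

    plans = {"4EPLopt": plan_eplopt, "4MCrecal": plan_recal, "4MCopt": plan_mcopt}
    indices = {arm: evaluate_indices(plan.dose, structures) for arm, plan in plans.items()}
    return PatientResult(
        patient_id=int(study.meta.get("patient_id", 0)),
        gtv_volume_cc=float(study.meta["gtv_volume_cc"]),
        amplitude_mm=float(study.meta["amplitude_mm"]),
        prescription=rx,
        indices=indices,
        plans=plans,
        step_logs={"4EPLopt": log_epl, "4MCopt": log_mc},
    )


def _as_pair(result):
    if isinstance(result, tuple):
        return result
    return result, None


def _per_patient_frame(results: list[PatientResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        for structure, kind, level in REPORT_INDICES:
            label = index_label(structure, kind, level)
            v_epl = res.indices["4EPLopt"][label]
            v_recal = res.indices["4MCrecal"][label]
            v_mcopt = res.indices["4MCopt"][label]
            rows.append(
                {
                    "patient": res.patient_id,
                    "gtv_volume_cc": res.gtv_volume_cc,
                    "prescription_cgy": res.prescription.total_cgy,
                    "index": label,
                    "kind": kind,
                    "4EPLopt": v_epl,
                    "4MCrecal": v_recal,
                    "4MCopt": v_mcopt,
                    "DPE": dvh_stats.dpe(v_recal, v_epl),
                    "OCE": dvh_stats.oce(v_mcopt, v_recal),
                    "dpe_normalized": normalized_index(v_epl, v_recal) if v_recal > 0 else np.nan,
                    "oce_normalized": normalized_index(v_recal, v_mcopt) if v_mcopt > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def _equivalence_frame(per_patient: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    rows = []
    for structure, kind, level in REPORT_INDICES:
        label = index_label(structure, kind, level)
        sub = per_patient[per_patient["index"] == label]
        step = config.step_d_cgy if kind == "D" else config.step_v_pct
        for err in ERROR_TYPES:
            if err == "DPE":
                ref, test = sub["4MCrecal"].to_numpy(), sub["4EPLopt"].to_numpy()
            else:
                ref, test = sub["4MCopt"].to_numpy(), sub["4MCrecal"].to_numpy()
            if len(ref) < 2:  # a paired test needs a cohort
                eq = EquivalenceResult(label, float("nan"), float(np.mean(ref)), float("nan"), False, len(ref))
            else:
                eq: EquivalenceResult = equivalence_interval(
                    ref, test, step=step, alpha=config.alpha, tolerance_pct=config.tolerance_pct, index=label
                )
            rows.append(
                {
                    "index": label,
                    "error": err,
                    "reference_mean": eq.reference_mean,
                    "interval": eq.delta,
                    "interval_pct": round(eq.percent_of_reference, 1),
                    "clinically_significant": eq.clinically_significant,
                    "n": eq.n,
                }
            )
    return pd.DataFrame(rows)


def make_table2(report_or_rows) -> pd.DataFrame:
    """Summary table: reference means, equivalence intervals, percent columns.

    Accepts a :class:`StudyReport`, the long-format equivalence frame it
    contains, or a list of dicts with keys ``index, dpe_reference,
    dpe_interval, oce_reference, oce_interval`` (e.g. published summary
    statistics).  Percent columns are 100*interval/reference rounded to
    one decimal.  All five report indices must be present.
    """
    if isinstance(report_or_rows, StudyReport):
        eq = report_or_rows.equivalence
        wide = {}
        for _, row in eq.iterrows():
            entry = wide.setdefault(row["index"], {"index": row["index"]})
            key = row["error"].lower()
            entry[f"{key}_reference"] = row["reference_mean"]
            entry[f"{key}_interval"] = row["interval"]
        rows = list(wide.values())
    elif isinstance(report_or_rows, pd.DataFrame):
        rows = report_or_rows.to_dict("records")
    else:
        rows = [dict(r) for r in report_or_rows]

    expected = [index_label(s, k, l) for s, k, l in REPORT_INDICES]
    have = {r["index"] for r in rows}
    missing = [label for label in expected if label not in have]
    if missing:
        raise ValueError(f"missing indices in summary: {missing}")

    out = []
    for label in expected:
        r = next(row for row in rows if row["index"] == label)
        rec = {"index": label}
        for err in ("dpe", "oce"):
            ref = float(r[f"{err}_reference"])
            interval = float(r[f"{err}_interval"])
            rec[f"{err}_reference"] = ref
            rec[f"{err}_interval"] = interval
            rec[f"{err}_interval_pct"] = round(100.0 * interval / ref, 1)
        out.append(rec)
    return pd.DataFrame(out, columns=TABLE2_COLUMNS)


def run_study(config: StudyConfig, outdir: str | Path | None = None) -> StudyReport:
    """Execute the three-arm scheme for the whole cohort and summarize.

    Fully reproducible from (config, seed): the cohort, voxel samples,
    and every noise realization derive from the cohort seed.  Patients
    whose pipeline fails are excluded and reported.
    """
    studies = make_cohort(config.cohort, config.phantom)
    results: list[PatientResult] = []
    failures: list[dict] = []
    for study in studies:
        pid = study.meta.get("patient_id")
        try:
            results.append(run_patient(study, config))
        except Exception as exc:  # noqa: BLE001 - per-patient isolation is intentional
            log.exception("patient %s failed", pid)
            failures.append({"patient": pid, "error": str(exc)})
    if not results:
        raise RuntimeError("all patients failed")

    per_patient = _per_patient_frame(results)
    equivalence = _equivalence_frame(per_patient, config)
    table2 = make_table2_from_equivalence(equivalence)

    gtv_label = index_label("GTV", "D", 98.0)
    gtv = per_patient[per_patient["index"] == gtv_label]
    dpe_magnitude = (gtv["dpe_normalized"] - 1.0).abs().to_numpy()
    try:
        spearman_r = spearman_vs_volume(dpe_magnitude, gtv["gtv_volume_cc"].to_numpy())
    except ValueError:
        spearman_r = float("nan")

    tol = config.tolerance_pct / 100.0
    counts = {
        "DPE_within_tolerance": int(((per_patient["dpe_normalized"] - 1.0).abs() <= tol).sum()),
        "OCE_within_tolerance": int(((per_patient["oce_normalized"] - 1.0).abs() <= tol).sum()),
        "total_indices": int(len(per_patient)),
    }

    report = StudyReport(
        per_patient=per_patient,
        equivalence=equivalence,
        table2=table2,
        spearman_r_gtv_d98=spearman_r,
        counts_within_tolerance=counts,
        n_patients=len(results),
        failures=failures,
    )
    if outdir is not None:
        write_outputs(report, results, config, outdir)
    return report


def make_table2_from_equivalence(equivalence: pd.DataFrame) -> pd.DataFrame:
    wide = {}
    for _, row in equivalence.iterrows():
        entry = wide.setdefault(row["index"], {"index": row["index"]})
        key = row["error"].lower()
        entry[f"{key}_reference"] = row["reference_mean"]
        entry[f"{key}_interval"] = row["interval"]
    return make_table2(list(wide.values()))


def write_outputs(report: StudyReport, results: list[PatientResult], config: StudyConfig, outdir) -> None:
    """Report CSVs, plan JSONs, dose / uncertainty / difference NIfTIs."""
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.per_patient.to_csv(outdir / "per_patient_indices.csv", index=False)
    report.equivalence.to_csv(outdir / "equivalence.csv", index=False)
    report.table2.to_csv(outdir / "table2.csv", index=False)
    config.to_json(outdir / "study_config.json")
    summary = {
        "n_patients": report.n_patients,
        "spearman_r_gtv_d98": report.spearman_r_gtv_d98,
        "counts_within_tolerance": report.counts_within_tolerance,
        "failures": report.failures,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    for res in results:
        pdir = outdir / f"patient{res.patient_id:03d}"
        pdir.mkdir(exist_ok=True)
        aff = res.plans["4EPLopt"].dose.grid.affine()
        for arm, plan in res.plans.items():
            nib.save(nib.Nifti1Image(plan.dose.values.astype(np.float32), aff), pdir / f"dose_{arm}.nii")
            (pdir / f"plan_{arm}.json").write_text(
                json.dumps(
                    {
                        "provenance": plan.provenance,
                        "engine": plan.engine_name,
                        "prescription_cgy": plan.prescription.total_cgy,
                        "fractions": plan.prescription.fractions,
                        "weights": plan.beamset.weights.tolist(),
                    },
                    indent=2,
                )
            )
            if plan.uncertainty is not None:
                nib.save(
                    nib.Nifti1Image(plan.uncertainty.values.astype(np.float32), aff),
                    pdir / f"uncertainty_{arm}.nii",
                )
        diff = dose_difference_map(res.plans["4MCopt"].dose, res.plans["4MCrecal"].dose)
        nib.save(nib.Nifti1Image(diff.astype(np.float32), aff), pdir / "diff_4MCopt_minus_4MCrecal.nii")
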