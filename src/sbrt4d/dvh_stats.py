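"""DVH indices, dose-error statistics, and the interval-growing equivalence test.

D_v is the minimum dose to the hottest v% of a structure and V_D the
percent volume receiving at least D.  The dose prediction error (DPE)
of an index is the value in the gold-standard recalculation minus the
value the optimizing engine reported; the optimization convergence
error (OCE) is the directly gold-standard-optimized value minus the
recalculated one.  Equivalence margins are found by growing a symmetric
interval around zero mean paired difference in fixed steps (0.01 Gy for
dose indices) until a paired TOST declares equivalence at level alpha;
the margin as a percent of the reference mean is compared against a 3%
clinical tolerance (strict inequality).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dose_engines import DoseGrid

__all__ = [
    "DVHCurve",
    "EquivalenceResult",
    "cumulative_dvh",
    "index_d",
    "index_v",
    "evaluate_indices",
    "dpe",
    "oce",
    "normalized_index",
    "spearman_vs_volume",
    "equivalence_interval",
    "clinical_significance",
]

#: (structure, index kind, level) evaluated in cohort reports
REPORT_INDICES = (
    ("GTV", "D", 98.0),
    ("cord", "D", 2.0),
    ("trachea", "D", 2.0),
    ("esophagus", "D", 2.0),
    ("lung", "V", 2000.0),  # V20Gy
)


def index_label(structure: str, kind: str, level: float) -> str:
    if kind == "D":
        return f"{structure} D{level:g}%"
    return f"{structure} V{level / 100.0:g}Gy"


@dataclass
class DVHCurve:
    """Cumulative DVH: volume fraction receiving at least each dose level."""

    dose_cgy: np.ndarray  # ascending, uniform step
    volume_fraction: np.ndarray

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.dose_cgy, self.volume_fraction]),
            delimiter=",",
            header="dose_cGy,volume_fraction",
            comments="",
        )


@dataclass
class EquivalenceResult:
    index: str
    delta: float  # minimal equivalence margin (cGy for D, percentage points for V)
    reference_mean: float
    percent_of_reference: float
    clinically_significant: bool
    n: int


def _masked_doses(dose, mask=None) -> np.ndarray:
    if isinstance(dose, DoseGrid):
        values = dose.values
    else:
        values = np.asarray(dose, dtype=float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.sum() == 0:
            raise ValueError("empty structure mask")
        values = values[mask]
    return np.ravel(values)


def cumulative_dvh(dose, mask=None, bin_width_cgy: float = 10.0) -> DVHCurve:
    """V(d) = fraction of structure voxels with dose >= d, at uniform bin edges."""
    d = _masked_doses(dose, mask)
    if d.size == 0:
        raise ValueError("empty structure mask")
    top = float(d.max()) + bin_width_cgy
    edges = np.arange(0.0, top + bin_width_cgy, bin_width_cgy)
    frac = (d[None, :] >= edges[:, None]).mean(axis=1)
    frac[0] = 1.0  # every voxel receives at least 0
    return DVHCurve(edges, frac)


def index_d(curve_or_doses, v_percent: float, mask=None) -> float:
    """D_v: largest dose level covering at least v% of the structure (cGy).

    Computed from exact voxel quantiles: with the doses sorted
    descending, D_v is the ceil(v*n/100)-th largest value, linearly
    interpolated for fractional positions.
    """
    if not (0.0 < v_percent <= 100.0):
        raise ValueError("v_percent must be in (0, 100]")
    if isinstance(curve_or_doses, DVHCurve):
        curve = curve_or_doses
        covered = curve.volume_fraction >= v_percent / 100.0 - 1e-12
        return float(curve.dose_cgy[covered][-1]) if covered.any() else 0.0
    d = np.sort(_masked_doses(curve_or_doses, mask))[::-1]
    n = d.size
    pos = v_percent / 100.0 * n - 1.0  # 0-based fractional rank
    if pos <= 0:
        return float(d[0])
    lo = int(np.floor(pos))
    frac = pos - lo
    if lo >= n - 1:
        return float(d[-1])
    return float(d[lo] + frac * (d[lo + 1] - d[lo]))


def index_v(curve_or_doses, dose_level_cgy: float, mask=None) -> float:
    """V_D: percent of the structure receiving at least the dose level."""
    if dose_level_cgy < 0:
        raise ValueError("dose level must be >= 0")
    if isinstance(curve_or_doses, DVHCurve):
        curve = curve_or_doses
        return float(np.interp(dose_level_cgy, curve.dose_cgy, curve.volume_fraction) * 100.0)
    d = _masked_doses(curve_or_doses, mask)
    return float((d >= dose_level_cgy).mean() * 100.0)


def evaluate_indices(dose: DoseGrid, structures) -> dict[str, float]:
    """The report panel: GTV D98%, cord/trachea/esophagus D2%, lung V20Gy."""
    out = {}
    for structure, kind, level in REPORT_INDICES:
        mask = structures[structure]
        if kind == "D":
            out[index_label(structure, kind, level)] = index_d(dose.values, level, mask)
        else:
            out[index_label(structure, kind, level)] = index_v(dose.values, level, mask)
    return out


def dpe(index_recal: float, index_eplopt: float) -> float:
    """Dose prediction error: gold-standard recalculation minus optimizer value."""
    return index_recal - index_eplopt


def oce(index_mcopt: float, index_recal: float) -> float:
    """Optimization convergence error: directly optimized minus recalculated."""
    return index_mcopt - index_recal


def normalized_index(test: float, reference: float) -> float:
    if reference <= 0:
        raise ValueError("reference index must be > 0")
    return test / reference


def spearman_vs_volume(values, gtv_volumes_cc) -> float:
    """Spearman rank correlation of a per-patient quantity with GTV volume."""
    values = np.asarray(values, dtype=float)
    volumes = np.asarray(gtv_volumes_cc, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 patients")
    if np.ptp(values) == 0 or np.ptp(volumes) == 0:
        return float("nan")
    r, _ = stats.spearmanr(values, volumes)
    return float(r)


def _tost_equivalent(diffs: np.ndarray, delta: float, alpha: float) -> bool:
    """Both one-sided paired t-tests reject at alpha: -delta < mean < delta."""
    n = diffs.size
    mean = diffs.mean()
    sd = diffs.std(ddof=1)
    if sd == 0.0:
        return abs(mean) < delta
    se = sd / np.sqrt(n)
    p_lower = stats.t.sf((mean + delta) / se, df=n - 1)  # H0: mu <= -delta
    p_upper = stats.t.cdf((mean - delta) / se, df=n - 1)  # H0: mu >= +delta
    return max(p_lower, p_upper) < alpha


def equivalence_interval(
    ref_values,
    test_values,
    step: float = 1.0,
    alpha: float = 0.05,
    tolerance_pct: float = 3.0,
    index: str = "",
) -> EquivalenceResult:
    """Minimal symmetric margin at which paired TOST declares equivalence.

    The margin starts at zero and grows in fixed steps (the default 1 cGy
    corresponds to 0.01 Gy for dose indices; V-type indices use 0.01
    percentage points) until both one-sided paired t-tests reject at
    ``alpha``.  If the paired differences have zero variance the
    degenerate rule applies: equivalence holds iff |mean| < margin.
    """
    ref = np.asarray(ref_values, dtype=float)
    test = np.asarray(test_values, dtype=float)
    if ref.shape != test.shape:
        raise ValueError("ref and test values must be paired (equal length)")
    if ref.size < 2:
        raise ValueError("need at least 2 pairs")
    if step <= 0:
        raise ValueError("step must be > 0")
    diffs = test - ref
    n = diffs.size
    mean = diffs.mean()
    sd = diffs.std(ddof=1)
    if sd == 0.0:
        k = int(np.floor(abs(mean) / step + 1e-12)) + 1
        delta = k * step
    else:
        se = sd / np.sqrt(n)
        upper = abs(mean) + stats.t.ppf(1.0 - alpha, n - 1) * se + 2.0 * step
        deltas = step * np.arange(0, int(np.ceil(upper / step)) + 2)
        t_lo = (mean + deltas) / se
        t_hi = (mean - deltas) / se
        ok = (stats.t.sf(t_lo, n - 1) < alpha) & (stats.t.cdf(t_hi, n - 1) < alpha)
        if not ok.any():  # pragma: no cover - bound above guarantees a hit
            raise RuntimeError("equivalence margin scan did not terminate")
        delta = float(deltas[np.argmax(ok)])
    ref_mean = float(ref.mean())
    if ref_mean <= 0:
        pct = float("nan")
        significant = True
    else:
        pct = 100.0 * delta / ref_mean
        significant = clinical_significance(pct, tolerance_pct)
    return EquivalenceResult(index, float(delta), ref_mean, pct, significant, n)


def clinical_significance(percent_interval: float, tolerance: float = 3.0) -> bool:
    """Clinically significant iff the percent interval strictly exceeds tolerance."""
    if percent_interval < 0:
        raise ValueError("percent interval must be >= 0")
    return percent_interval > tolerance
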