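"""Paired per-case differences, cohort summaries, and the Wilcoxon test.

The cohort endpoint mirrors the clinical question: for each case, every
DVH metric is computed under both dose-calculation schemes (D_m,m and
D_w,w, same engine, same plan, same seed) and the per-case percent
difference (w - m)/m * 100 is formed; the cohort is summarized by the
median and range of those per-case differences (median of differences,
not difference of medians) and tested with the Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .dvh import StructureMask, dhi, evaluate_metric, structure_doses
from .engine import run_simulation
from .errors import (DegenerateTestError, EmptyCohortError,
                     UndefinedMetricError)

__all__ = [
    "PairedMetricSet",
    "percent_difference",
    "cohort_summary",
    "wilcoxon_signed_rank",
    "run_case",
    "summarize_cohort",
]

#: (structure key, report label, metric) rows emitted per case
CASE_METRICS = (
    ("body", "Body", "DHI"),
    ("ctv", "CTV", "D100%"),
    ("ptv_eval", "PTV", "V200%"),
    ("ptv_eval", "PTV", "V100%"),
    ("ptv_eval", "PTV", "V90%"),
    ("ptv_eval", "PTV", "D90%"),
    ("lung", "Lungs", "D0.1cm3"),
    ("chest_wall", "Chest Wall", "D0.1cm3"),
    ("skin", "Skin", "D0.1cm3"),
)


@dataclass
class PairedMetricSet:
    """Per-case paired metric rows: one row per (structure, metric)."""

    case_id: str
    rows: pd.DataFrame  # columns: structure, metric, value_mm, value_ww, pct_diff

    def __post_init__(self) -> None:
        required = {"structure", "metric", "value_mm", "value_ww",
                    "pct_diff"}
        if not required.issubset(self.rows.columns):
            raise ValueError(f"rows must have columns {sorted(required)}")


def percent_difference(value_mm: float, value_ww: float) -> float:
    """(w - m)/m * 100: positive when the all-water calculation
    overestimates the heterogeneous one."""
    if value_mm == 0:
        raise UndefinedMetricError("percent difference undefined for "
                                   "value_mm = 0")
    return (value_ww - value_mm) / value_mm * 100.0


def cohort_summary(values) -> tuple[float, float, float]:
    """Sample median (even-n midpoint convention) and inclusive range."""
    v = np.asarray(list(values), float)
    if v.size == 0:
        raise EmptyCohortError("empty cohort")
    return float(np.median(v)), float(v.min()), float(v.max())


def _exact_sign_distribution(ranks2: np.ndarray) -> np.ndarray:
    """Distribution of 2*W over all sign assignments (counts), by DP.

    ``ranks2`` are the doubled ranks (integers even with mid-ranks for
    ties).  Entry s of the result counts sign vectors with 2*W = s.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts += shifted
    return counts


def wilcoxon_signed_rank(
    differences,
    zero_method: str = "wilcox",
    exact_max_n: int = 20,
) -> tuple[float, float]:
    """Wilcoxon signed-rank test: (W, two-sided p).

    Zeros are discarded (classic convention; ``zero_method='pratt'`` keeps
    them for ranking).  |differences| are ranked with mid-ranks for ties
    and W is the sum of positive-difference ranks.  For n <= ``exact_max_n``
    the p-value is exact over all 2^n sign assignments
    (p = min(1, 2 * min(P(W' <= W), P(W' >= W)))); beyond that a normal
    approximation with tie-corrected variance and continuity correction
    is used.
    """
    d = np.asarray(list(differences), float)
    if zero_method not in ("wilcox", "pratt"):
        raise ValueError("zero_method must be 'wilcox' or 'pratt'")
    if zero_method == "wilcox":
        d = d[d != 0.0]
        if d.size == 0:
            raise DegenerateTestError("all differences are zero")
        ranks = rankdata(np.abs(d))
    else:
        if not np.any(d != 0.0):
            raise DegenerateTestError("all differences are zero")
        ranks_all = rankdata(np.abs(d))
        ranks = ranks_all[d != 0.0]
        d = d[d != 0.0]
    w = float(ranks[d > 0].sum())
    n = d.size

    if n <= exact_max_n:
        ranks2 = np.rint(2.0 * ranks).astype(np.int64)
        counts = _exact_sign_distribution(ranks2)
        total = counts.sum()
        w2 = int(round(2.0 * w))
        p_le = counts[: w2 + 1].sum() / total
        p_ge = counts[w2:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return w, float(p)

    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if sigma2 <= 0:
        raise DegenerateTestError("zero variance (all ranks tied)")
    delta = w - mu
    cc = 0.5 * np.sign(delta)
    z = (delta - cc) / np.sqrt(sigma2)
    return w, float(min(1.0, 2.0 * norm.sf(abs(z))))


def run_case(
    bundle,
    n_histories: int = 1_000_000,
    n_batches: int = 10,
    seed: int = 0,
    spectrum=None,
) -> PairedMetricSet:
    """Simulate one case under both schemes and emit paired metric rows.

    Runs the engine twice — unbound water (D_w,w) and heterogeneous
    (D_m,m) — with the same plan, spectrum, history count and seed, then
    evaluates the reported DVH metric set on each dose grid.
    """
    from .source import load_ir192_spectrum
    from .synthetic import case_phantoms

    if spectrum is None:
        spectrum = load_ir192_spectrum()
    ph_mm, ph_ww = case_phantoms(bundle)
    presc = bundle.plan.prescription_dose
    vvox = ph_mm.voxel_volume_cm3

    values = {}
    for label, ph in (("mm", ph_mm), ("ww", ph_ww)):
        grid = run_simulation(ph, bundle.plan, spectrum, n_histories,
                              n_batches=n_batches, seed=seed)
        for skey, sname, metric in CASE_METRICS:
            mask: StructureMask = bundle.structures[skey]
            if metric == "DHI":
                val = dhi(grid, mask, presc)
            else:
                doses = structure_doses(grid, mask)
                val = evaluate_metric(doses, metric, presc,
                                      voxel_volume_cm3=vvox)
            values[(sname, metric, label)] = val

    rows = []
    for skey, sname, metric in CASE_METRICS:
        vm = values[(sname, metric, "mm")]
        vw = values[(sname, metric, "ww")]
        rows.append({
            "structure": sname, "metric": metric,
            "value_mm": vm, "value_ww": vw,
            "pct_diff": percent_difference(vm, vw),
        })
    return PairedMetricSet(case_id=bundle.case_id, rows=pd.DataFrame(rows))


def run_cohort(
    n_cases: int,
    master_seed: int,
    n_histories: int = 1_000_000,
    n_batches: int = 10,
    voxel_size_mm: float = 2.0,
) -> list[PairedMetricSet]:
    """Generate a synthetic cohort and run the paired comparison per case.

    Case anatomy comes from the synthetic generator seeded by
    ``master_seed``; each case is simulated under both schemes with a
    per-case transport seed derived from the master seed.
    """
    from .synthetic import build_case, generate_cohort

    results = []
    for i, params in enumerate(generate_cohort(n_cases, master_seed,
                                               voxel_size_mm)):
        bundle = build_case(params, case_id=f"case{i:03d}")
        results.append(run_case(bundle, n_histories=n_histories,
                                n_batches=n_batches,
                                seed=(master_seed * 1009 + i) % (2 ** 31)))
    return results


def summarize_cohort(cases: list[PairedMetricSet]):
    """Cohort tables from per-case paired rows.

    Returns ``(per_case, by_scheme, differences)``:

    * ``per_case`` — all rows, one per (case, structure, metric);
    * ``by_scheme`` — median and range of each metric under each scheme;
    * ``differences`` — median and range of the per-case percent
      differences plus the Wilcoxon two-sided p-value per metric
      (median of per-case differences, not difference of medians).
    """
    if not cases:
        raise EmptyCohortError("no cases")
    per_case = pd.concat(
        [c.rows.assign(case=c.case_id) for c in cases], ignore_index=True)

    scheme_rows = []
    diff_rows = []
    for (structure, metric), grp in per_case.groupby(
            ["structure", "metric"], sort=False):
        med_m, lo_m, hi_m = cohort_summary(grp["value_mm"])
        med_w, lo_w, hi_w = cohort_summary(grp["value_ww"])
        scheme_rows.append({
            "structure": structure, "metric": metric,
            "median_mm": med_m, "min_mm": lo_m, "max_mm": hi_m,
            "median_ww": med_w, "min_ww": lo_w, "max_ww": hi_w,
        })
        med_d, lo_d, hi_d = cohort_summary(grp["pct_diff"])
        diffs = grp["value_ww"].to_numpy() - grp["value_mm"].to_numpy()
        try:
            _, p = wilcoxon_signed_rank(diffs)
        except DegenerateTestError:
            p = np.nan
        diff_rows.append({
            "structure": structure, "metric": metric,
            "median_diff_pct": med_d, "min_diff_pct": lo_d,
            "max_diff_pct": hi_d, "wilcoxon_p": p,
        })
    return per_case, pd.DataFrame(scheme_rows), pd.DataFrame(diff_rows)
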