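"""Cohort execution and statistics over the amplification array.

The study design is a full factorial sweep: 3 longitudinal PU diameters x
5 bladder-neck diameters x 14 transverse PU diameters = 210 cases.  Each
case is meshed, solved and reduced to a :class:`~lutflow.postprocess.CaseResult`;
the cohort is then summarized the way the clinical-modelling literature
reports it: counts and percentages of vortex-positive cases per LD-PU group,
median/IQR of the observables split by vortex status, Mann-Whitney U
comparison of MV-EUO between vortex and non-vortex strata, per-group OLS
regression of vortex size on the diameter ratios, and the minimum diameter
ratios at which a vortex still occurs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .flow_solver import (BoundarySet, FluidProperties, NumericsConfig,
                          SolverError, solve_steady_flow)
from .geometry import GeometrySpec, amplification_array, assemble_domain
from .meshing import triangulate
from .postprocess import CaseResult, summarize_case

__all__ = [
    "run_case",
    "run_cohort",
    "results_frame",
    "CohortSummary",
    "summarize_groups",
    "mann_whitney_u",
    "regress_tdv",
    "vortex_thresholds",
]


def run_case(spec: GeometrySpec, element_budget: int = 25000,
             cfg: NumericsConfig | None = None,
             fluid: FluidProperties | None = None,
             bc: BoundarySet | None = None,
             initial=None, return_state: bool = False,
             half: bool = True):
    """Mesh and solve one case; returns a CaseResult (and state if asked)."""
    cfg = cfg or NumericsConfig()
    fluid = fluid or FluidProperties()
    bc = bc or BoundarySet()
    # production solves exploit the mirror symmetry of the geometry: the
    # right half-domain at matching resolution, i.e. half the element budget
    # (budgets are always quoted as full-domain equivalents)
    domain = assemble_domain(spec, half=half)
    budget = max(1000, element_budget // 2) if half else element_budget
    mesh = triangulate(domain, budget)
    try:
        sol = solve_steady_flow(mesh, fluid, bc, cfg, initial=initial)
    except SolverError:
        if initial is not None:
            # a warm start mapped from a different geometry can destabilize;
            # retry cold before reporting failure
            sol = solve_steady_flow(mesh, fluid, bc, cfg)
        else:
            raise
    result = summarize_case(spec, sol, mesh, domain)
    if return_state:
        return result, sol, mesh, domain
    return result


def run_cohort(specs: Iterable[GeometrySpec] | None = None,
               cfg: NumericsConfig | None = None,
               element_budget: int = 2500,
               warm_chain: bool = True,
               progress: bool = False) -> list[CaseResult]:
    """Solve every case of the cohort (default: the full 210-case array).

    Cases are independent; they are executed in case-id order and, when
    ``warm_chain`` is on, each solve is warm-started from the previous case
    of the same subgroup (same LD-PU and TD-BN), which shares most of its
    geometry.  Failures are recorded as non-converged results, never raised.
    """
    specs = list(specs) if specs is not None else amplification_array()
    cfg = cfg or NumericsConfig()
    results: list[CaseResult] = []
    prev_sol = None
    prev_key = None
    for i, spec in enumerate(specs):
        key = (spec.ld_pu, spec.td_bn)
        initial = prev_sol if (warm_chain and key == prev_key) else None
        try:
            result, sol, _, _ = run_case(
                spec, element_budget, cfg, initial=initial, return_state=True)
            if not result.converged:
                # a cold restart with a longer iteration allowance resolves
                # the occasional case where the warm transient eats the
                # budget; deterministic either way
                from dataclasses import replace as _replace

                cfg_retry = _replace(cfg, max_iter=int(cfg.max_iter * 1.5))
                result, sol, _, _ = run_case(
                    spec, element_budget, cfg_retry, return_state=True)
            prev_sol = sol if sol.converged else None
        except SolverError:
            from .geometry import rpu_ratios
            r1, r2 = rpu_ratios(spec)
            result = CaseResult(case_id=spec.case_id, ld_pu=spec.ld_pu,
                                td_bn=spec.td_bn, td_pu=spec.td_pu,
                                rpu1=r1, rpu2=r2, converged=False,
                                n_elements=0, n_iter=0)
            prev_sol = None
        prev_key = key
        results.append(result)
        if progress:
            print(f"[{i + 1}/{len(specs)}] {result.case_id} "
                  f"conv={result.converged} vortex={result.vortex}",
                  flush=True)
    return results


def results_frame(results: Sequence[CaseResult]) -> pd.DataFrame:
    """Cohort results as a tidy DataFrame, one row per case."""
    return pd.DataFrame([r.as_dict() for r in results])


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

GROUP_OF_LD = {3.6: "I", 3.8: "II", 4.0: "III"}


def _median_iqr(x: pd.Series) -> tuple[float, float, float] | None:
    """Median and quartiles with linear interpolation between order stats."""
    x = x.dropna()
    if len(x) == 0:
        return None
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return float(med), float(q1), float(q3)


def mann_whitney_u(sample_a: Sequence[float],
                   sample_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (U statistic of sample_a, p-value).

    Exact enumeration for small samples (min side <= 8, no ties), otherwise
    the tie-corrected normal approximation.  If every value is tied across
    both samples the test is degenerate and p = 1 is returned.
    """
    from scipy.stats import mannwhitneyu

    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    if np.all(a == a[0]) and np.all(b == a[0]):
        return float(len(a) * len(b) / 2.0), 1.0
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) \
        else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def regress_tdv(results: Sequence[CaseResult] | pd.DataFrame,
                which_rpu: str = "rpu1") -> pd.DataFrame:
    """Per-group OLS regression of TD-V on a diameter ratio (vortex cases).

    Returns one row per LD-PU group plus an "all" row with slope, intercept,
    and R^2; groups with fewer than 3 vortex-positive points are flagged
    (``fit`` False) and carry NaNs.
    """
    if which_rpu not in ("rpu1", "rpu2"):
        raise ValueError("which_rpu must be 'rpu1' or 'rpu2'")
    df = results if isinstance(results, pd.DataFrame) else results_frame(results)
    df = df[df["converged"] & df["vortex"].fillna(False)]
    rows = []
    from scipy.stats import linregress

    groups = [(g, sub) for g, sub in df.groupby(df["ld_pu_cm"].map(GROUP_OF_LD))]
    groups.append(("all", df))
    for gname, sub in groups:
        sub = sub.dropna(subset=["td_v_cm", which_rpu])
        if len(sub) < 3:
            rows.append({"group": gname, "n": len(sub), "fit": False,
                         "slope": np.nan, "intercept": np.nan, "r2": np.nan})
            continue
        fit = linregress(sub[which_rpu], sub["td_v_cm"])
        rows.append({"group": gname, "n": len(sub), "fit": True,
                     "slope": float(fit.slope),
                     "intercept": float(fit.intercept),
                     "r2": float(fit.rvalue ** 2)})
    return pd.DataFrame(rows)


def vortex_thresholds(results: Sequence[CaseResult] | pd.DataFrame) -> dict:
    """Minimum RPU-1 / RPU-2 among vortex-positive cases, with the nearest
    vortex-negative neighbours for context."""
    df = results if isinstance(results, pd.DataFrame) else results_frame(results)
    df = df[df["converged"]]
    pos = df[df["vortex"].fillna(False)]
    neg = df[~df["vortex"].fillna(False)]
    if len(pos) == 0:
        return {"min_rpu1": None, "min_rpu2": None, "flagged": True}
    out = {
        "min_rpu1": float(pos["rpu1"].min()),
        "min_rpu2": float(pos["rpu2"].min()),
        "flagged": False,
    }
    below1 = neg[neg["rpu1"] < out["min_rpu1"]]
    below2 = neg[neg["rpu2"] < out["min_rpu2"]]
    out["nearest_nonvortex_rpu1"] = float(below1["rpu1"].max()) if len(below1) else None
    out["nearest_nonvortex_rpu2"] = float(below2["rpu2"].max()) if len(below2) else None
    return out


@dataclass
class CohortSummary:
    """Group-level summary table plus the threshold and test results."""

    table: pd.DataFrame
    thresholds: dict
    mw_mv_euo: dict        # per group and overall: {"U": ..., "p": ...}
    n_total: int
    n_converged: int


def summarize_groups(results: Sequence[CaseResult] | pd.DataFrame) -> CohortSummary:
    """Build the group-characteristics table of the cohort.

    Rows: case counts, vortex/non-vortex counts with percentages, median
    (IQR) of TD-V (reported in mm, as is conventional for these magnitudes),
    RPU-1/RPU-2 and MV-EUO split by vortex status; Mann-Whitney comparison
    of MV-EUO between the strata per group and overall.  Empty strata yield
    absent (NaN) entries, never fabricated zeros.
    """
    df = results if isinstance(results, pd.DataFrame) else results_frame(results)
    if len(df) == 0:
        raise ValueError("no results to summarize")
    conv = df[df["converged"]].copy()
    conv["group"] = conv["ld_pu_cm"].map(GROUP_OF_LD)
    cols = {}
    mw = {}
    group_frames = [(g, conv[conv["group"] == g]) for g in ("I", "II", "III")]
    group_frames.append(("all", conv))
    for gname, sub in group_frames:
        pos = sub[sub["vortex"].fillna(False)]
        neg = sub[~sub["vortex"].fillna(False)]
        n = len(sub)
        col = {
            "cases": n,
            "vortex_n": len(pos),
            "vortex_pct": 100.0 * len(pos) / n if n else np.nan,
            "non_vortex_n": len(neg),
            "non_vortex_pct": 100.0 * len(neg) / n if n else np.nan,
        }
        for label, series in (
                ("td_v_mm", pos["td_v_cm"] * 10.0),
                ("rpu1_vortex", pos["rpu1"]),
                ("rpu1_non_vortex", neg["rpu1"]),
                ("rpu2_vortex", pos["rpu2"]),
                ("rpu2_non_vortex", neg["rpu2"]),
                ("mv_euo_vortex_m_s", pos["mv_euo_m_s"]),
                ("mv_euo_non_vortex_m_s", neg["mv_euo_m_s"])):
            mi = _median_iqr(series)
            if mi is None:
                col[f"{label}_median"] = np.nan
                col[f"{label}_q1"] = np.nan
                col[f"{label}_q3"] = np.nan
            else:
                col[f"{label}_median"], col[f"{label}_q1"], col[f"{label}_q3"] = mi
        if len(pos) and len(neg):
            u, p = mann_whitney_u(pos["mv_euo_m_s"].dropna(),
                                  neg["mv_euo_m_s"].dropna())
            mw[gname] = {"U": u, "p": p}
            col["mw_p_mv_euo"] = p
        else:
            col["mw_p_mv_euo"] = np.nan
        cols[gname] = col
    table = pd.DataFrame(cols)
    return CohortSummary(table=table, thresholds=vortex_thresholds(conv),
                         mw_mv_euo=mw, n_total=len(df), n_converged=len(conv))
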