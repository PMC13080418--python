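"""End-to-end inventory comparison: the five-stage pipeline plus bootstrap.

Stages: (1) explained covariance of the polychoric matrix, (2) parallel
analysis on pretreatment scores and on change scores, (3) bifactor EFA
with bi-geomin rotation and a stability screen, (4) marginalization of the
specific factors, (5) Fisher-information statistics with nonparametric
bootstrap percentile confidence intervals.  A sensitivity run repeats
everything on the reduced pool that keeps only the embedded short-form
items of the longest inventory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from . import information as im
from .bifactor import (
    fit_bifactor,
    general_factor_covariance_share,
    stability_screen,
)
from .dimensionality import (
    change_scores,
    explained_covariance,
    parallel_analysis,
)
from .polychoric import polychoric_matrix
from .projection import marginalize_solution
from .types import BifactorSolution, ItemSpec, ResponseMatrix

INVENTORIES = ("CORE_OM", "CORE_10", "PHQ9", "OASIS", "AUDIT_C")


@dataclass
class PipelineConfig:
    n_factors: int | str = "auto"       # "auto" -> parallel analysis
    pa_n_random: int = 100
    pa_criterion: str = "mean"
    geomin_epsilon: float = 0.01
    n_starts: int = 30
    dense_threshold: float = 0.20
    min_count: int = 3
    excluded_items: list[str] = field(default_factory=list)
    bootstrap_B: int = 1000
    bootstrap_n_starts: int = 2
    bounds: tuple[float, float] = im.DEFAULT_BOUNDS
    n_nodes: int = im.DEFAULT_NODES
    run_change_scores: bool = True
    seed: int = 0


@dataclass
class BootstrapResult:
    statistic: str
    point: float
    ci_low: float
    ci_high: float
    B: int
    skewed: bool


@dataclass
class PipelineReport:
    config: PipelineConfig
    poly: object
    variance: object
    pa_pre: object
    variance_change: object
    pa_change: object
    solution: BifactorSolution
    excluded_items: list[str]
    general_share: float
    marginal_items: list
    profile: im.InformationProfile
    events: list[str] = field(default_factory=list)

    def comparison_table(self) -> pd.DataFrame:
        return self.profile.comparison_table()


def inventory_membership(specs: list[ItemSpec],
                         retained: list[str]) -> dict[str, list[str]]:
    """Inventory -> retained member item ids, plus the full pool as ALL."""
    keep = set(retained)
    out: dict[str, list[str]] = {}
    for inv in INVENTORIES:
        if inv == "CORE_10":
            ids = [s.item_id for s in specs if s.in_core10]
        else:
            ids = [s.item_id for s in specs if s.inventory.value == inv]
        ids = [i for i in ids if i in keep]
        if ids:
            out[inv] = ids
    out["ALL"] = [i for i in retained]
    return out


def _seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_pipeline(
    pre: ResponseMatrix,
    post: ResponseMatrix | None,
    cfg: PipelineConfig,
) -> PipelineReport:
    """Execute stages 1-5 on a pre(/post) cohort and assemble the report."""
    events: list[str] = []
    seed_pa, seed_pa_chg, seed_rot, _ = _seeds(cfg.seed, 4)
    if cfg.excluded_items:
        keep = [i for i in pre.item_ids if i not in set(cfg.excluded_items)]
        pre = pre.subset(keep)
        post = post.subset(keep) if post is not None else None
        events.append(f"excluded by config: {sorted(cfg.excluded_items)}")

    poly = polychoric_matrix(pre, min_count=cfg.min_count)
    if poly.smoothed:
        events.append("polychoric matrix smoothed to PSD")
    variance = explained_covariance(poly.matrix())
    pa_pre = parallel_analysis(
        pre, n_random=cfg.pa_n_random, criterion=cfg.pa_criterion,
        seed=seed_pa, method="polychoric",
    )

    variance_change = pa_change = None
    if post is not None and cfg.run_change_scores:
        delta = change_scores(pre, post)
        R_delta = delta.corr(min_periods=2).to_numpy()
        variance_change = explained_covariance(R_delta)
        pa_change = parallel_analysis(
            delta, n_random=cfg.pa_n_random, criterion=cfg.pa_criterion,
            seed=seed_pa_chg, method="pearson",
        )

    k = pa_pre.n_factors if cfg.n_factors == "auto" else int(cfg.n_factors)
    if k < 2:
        raise ValueError(f"pipeline needs k >= 2 factors, got {k}")
    solution = fit_bifactor(
        poly.corr, k, epsilon=cfg.geomin_epsilon, n_starts=cfg.n_starts,
        seed=seed_rot, dense_threshold=cfg.dense_threshold,
    )
    dropped = stability_screen(solution)
    if dropped:
        events.append(f"stability screen excluded: {dropped}")
        keep = [i for i in pre.item_ids if i not in set(dropped)]
        pre = pre.subset(keep)
        poly = polychoric_matrix(pre, min_count=cfg.min_count)
        solution = fit_bifactor(
            poly.corr, k, epsilon=cfg.geomin_epsilon, n_starts=cfg.n_starts,
            seed=seed_rot, dense_threshold=cfg.dense_threshold,
        )
        solution.excluded_items = dropped

    share = general_factor_covariance_share(solution)
    marginal_items = marginalize_solution(solution, poly)
    membership = inventory_membership(pre.items, pre.item_ids)
    profile = im.build_profile(
        marginal_items, membership, bounds=cfg.bounds, n_nodes=cfg.n_nodes
    )
    return PipelineReport(
        config=cfg, poly=poly, variance=variance, pa_pre=pa_pre,
        variance_change=variance_change, pa_change=pa_change,
        solution=solution, excluded_items=list(dropped),
        general_share=share, marginal_items=marginal_items,
        profile=profile, events=events,
    )


# ---------------------------------------------------------------------------
# bootstrap

def tucker_congruence(x: np.ndarray, y: np.ndarray) -> float:
    denom = np.sqrt((x @ x) * (y @ y))
    return float(x @ y / denom) if denom > 0 else 0.0


def align_to_reference(
    loadings: pd.DataFrame, factor_corr: np.ndarray, reference: pd.DataFrame
) -> tuple[pd.DataFrame, np.ndarray, float]:
    """Permute/sign-flip factors to maximize congruence with a reference.

    Columns are matched by maximal absolute Tucker congruence (Hungarian
    assignment on the shared items) and sign-corrected.  Returns the
    aligned loadings, aligned factor correlations and the mean absolute
    congruence of the matched general column.
    """
    shared = reference.index.intersection(loadings.index)
    X = reference.loc[shared].to_numpy()
    Y = loadings.loc[shared].to_numpy()
    k = X.shape[1]
    C = np.zeros((k, k))
    for a in range(k):
        for b in range(k):
            C[a, b] = tucker_congruence(X[:, a], Y[:, b])
    row, col = linear_sum_assignment(-np.abs(C))
    perm = col[np.argsort(row)]
    signs = np.sign(C[np.arange(k), perm])
    signs[signs == 0] = 1.0
    aligned = loadings.iloc[:, perm] * signs[None, :]
    aligned.columns = reference.columns
    Phi = factor_corr[np.ix_(perm, perm)] * np.outer(signs, signs)
    return aligned, Phi, float(abs(C[0, perm[0]]))


def _profile_stats(profile: im.InformationProfile,
                   ranking: list[str]) -> dict[str, float]:
    stats: dict[str, float] = {}
    for inv in profile.total_test_info.index:
        stats[f"total_info[{inv}]"] = float(profile.total_test_info[inv])
        stats[f"averaged_info[{inv}]"] = float(
            profile.averaged_total_test_info[inv]
        )
    for a, b in zip(ranking[:-1], ranking[1:]):
        if a in profile.averaged_total_test_info and b in profile.averaged_total_test_info:
            stats[f"diff_averaged[{a}-{b}]"] = float(
                profile.averaged_total_test_info[a]
                - profile.averaged_total_test_info[b]
            )
    return stats


def bootstrap(
    pre: ResponseMatrix,
    cfg: PipelineConfig,
    report: PipelineReport,
    B: int | None = None,
    seed: int | None = None,
) -> tuple[list[BootstrapResult], list[str], float]:
    """Nonparametric percentile bootstrap of the information statistics.

    Persons are resampled with replacement; polychorics through the
    information profile are recomputed per resample with the factor count
    fixed at the point estimate's k; each resample's rotated factors are
    aligned to the point-estimate loadings by congruence matching before
    statistics are read off.  Items degenerating to a single observed
    category in a resample are dropped from that resample and the event
    logged.  Returns the results, the event log and the mean Tucker
    congruence of the aligned general factor across resamples.
    """
    B = cfg.bootstrap_B if B is None else B
    if B < 1:
        raise ValueError("bootstrap needs B >= 1")
    seed = cfg.seed if seed is None else seed
    k = report.solution.k
    retained = list(report.solution.loadings.index)
    base = pre.subset(retained)
    ranking = list(
        report.profile.averaged_total_test_info
        .drop(labels=["ALL", "AUDIT_C"], errors="ignore")
        .sort_values(ascending=False).index
    )
    point = _profile_stats(report.profile, ranking)

    rng = np.random.default_rng(seed)
    rot_seeds = _seeds(seed + 1, B)
    rows = []
    events: list[str] = []
    congruences = []
    n = base.n_persons
    for b in range(B):
        take = rng.integers(0, n, size=n)
        df = base.data.iloc[take].reset_index(drop=True)
        df.index = np.arange(1, n + 1)
        df.index.name = "person_id"
        sample = ResponseMatrix(df, list(base.items))
        drop = [
            iid for iid in sample.item_ids
            if np.unique(
                sample.data[iid].dropna().to_numpy()
            ).size < 2
        ]
        if drop:
            events.append(f"resample {b}: dropped degenerate items {drop}")
            sample = sample.subset([i for i in sample.item_ids if i not in drop])
        poly_b = polychoric_matrix(sample, min_count=cfg.min_count)
        sol_b = fit_bifactor(
            poly_b.corr, k, epsilon=cfg.geomin_epsilon,
            n_starts=cfg.bootstrap_n_starts, seed=rot_seeds[b],
            dense_threshold=cfg.dense_threshold,
        )
        aligned, Phi_b, cong = align_to_reference(
            sol_b.loadings, sol_b.factor_corr, report.solution.loadings
        )
        congruences.append(cong)
        sol_b = BifactorSolution(
            loadings=aligned, factor_corr=Phi_b, uniqueness=sol_b.uniqueness,
            rotation_criterion_value=sol_b.rotation_criterion_value,
            n_starts=sol_b.n_starts, converged=sol_b.converged,
        )
        marg_b = marginalize_solution(sol_b, poly_b)
        membership = inventory_membership(sample.items, sample.item_ids)
        prof_b = im.build_profile(
            marg_b, membership, bounds=cfg.bounds, n_nodes=cfg.n_nodes
        )
        rows.append(_profile_stats(prof_b, ranking))

    boot = pd.DataFrame(rows)
    results = []
    for name, est in point.items():
        if name not in boot:
            continue
        lo, hi = np.percentile(boot[name].dropna(), [2.5, 97.5])
        width = hi - lo
        skewed = bool(
            width > 0 and not (lo + width / 3 <= est <= hi - width / 3)
        )
        results.append(BootstrapResult(
            statistic=name, point=float(est), ci_low=float(lo),
            ci_high=float(hi), B=B, skewed=skewed,
        ))
    mean_congruence = float(np.mean(congruences)) if congruences else np.nan
    return results, events, mean_congruence


def core10_sensitivity(
    pre: ResponseMatrix, post: ResponseMatrix | None, cfg: PipelineConfig
) -> PipelineReport:
    """Re-run the pipeline excluding long-form-only CORE-OM items."""
    keep = [
        s.item_id for s in pre.items
        if s.inventory.value != "CORE_OM" or s.in_core10
    ]
    return run_pipeline(
        pre.subset(keep), post.subset(keep) if post is not None else None, cfg
    )


# ---------------------------------------------------------------------------
# report output

def write_report(report: PipelineReport, out_dir,
                 boot: list[BootstrapResult] | None = None) -> None:
    """Write the CSV/JSON bundle of a pipeline run."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.variance.scree_table().to_csv(out / "scree_pretreatment.csv", index=False)
    if report.variance_change is not None:
        report.variance_change.scree_table().to_csv(
            out / "scree_change_scores.csv", index=False
        )
    report.solution.loadings.to_csv(out / "loadings.csv")
    pd.DataFrame(report.solution.factor_corr).to_csv(
        out / "factor_correlations.csv", index=False
    )
    rows = []
    for it in report.marginal_items:
        row = {"item": it.item_id, "a": it.a, "metric": it.metric}
        for c, bc in enumerate(it.b, start=1):
            row[f"b{c}"] = bc
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "marginal_parameters.csv", index=False)

    curves = report.profile.point_test_info.T
    curves.index.name = "theta"
    sem = report.profile.stdem.T
    sem.columns = [f"stdem_{c}" for c in sem.columns]
    pd.concat([curves, sem], axis=1).to_csv(out / "information_curves.csv")
    report.comparison_table().to_csv(out / "comparison_table.csv")

    summary = {
        "first_pc_pct": float(report.variance.pct_explained[0]),
        "pc_ratio_first_second": float(report.variance.ratio_first_to_second),
        "suggested_factors_pre": int(report.pa_pre.n_factors),
        "suggested_factors_change": (
            int(report.pa_change.n_factors) if report.pa_change else None
        ),
        "k_fitted": int(report.solution.k),
        "general_covariance_share_pct": float(report.general_share),
        "excluded_items": report.excluded_items,
        "total_test_information": {
            str(k): float(v) for k, v in report.profile.total_test_info.items()
        },
        "averaged_total_test_information": {
            str(k): float(v)
            for k, v in report.profile.averaged_total_test_info.items()
        },
        "events": report.events,
        "seed": report.config.seed,
    }
    if boot:
        summary["bootstrap"] = [asdict(r) for r in boot]
    with open(out / "information_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
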