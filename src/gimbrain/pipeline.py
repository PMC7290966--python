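"""End-to-end per-subject and per-cohort analysis orchestration.

Per subject: normalize the connectome, sweep a temperature grid with
repeated random starts, locate Tc at the susceptibility peak, compute
the Mantel correlation of run-averaged simulated FC with each scan's
empirical FC across the grid, pick T* and the best scan, record the
direct SC-FC baseline, and estimate dimensionality from the configured
FC source.

Per cohort: run every subject (failures isolated per subject), then the
group-comparison battery on each outcome: controls-vs-patients Welch t,
four-level one-way ANOVA, patient-group-vs-HC post-hoc Welch t with
Benjamini-Hochberg adjustment, and a paired t between the two scans' T*
within controls and within patients.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ._seeds import derive_seed
from . import cohort_stats
from .criticality import (
    default_temperature_grid,
    find_critical_temperature,
    temperature_sweep,
)
from .dimensionality import DimensionalityEstimate, subject_dimensionality
from .fc import (
    CorrelationMatrix,
    average_fc_over_runs,
    direct_sc_fc_correlation,
    pearson_correlation_matrix,
    select_best_scan,
    tstar_from_fc_curve,
)
from .io import SubjectRecord, load_subject, read_manifest, write_results_table
from .ising import CouplingMatrix, SimulationParams, normalize_coupling

__all__ = ["AnalysisConfig", "SubjectResult", "run_subject", "run_cohort"]

OUTCOMES = ("Tc", "T_star", "best_r", "direct_r", "D")


@dataclass(frozen=True)
class AnalysisConfig:
    """Resolved settings for one analysis run (serializable to YAML)."""

    n_temperatures: int = 20
    n_runs: int = 10
    n_equil_sweeps: int = 1000
    n_samples: int = 1000
    sample_interval_sweeps: int = 2
    smooth_window: int = 3
    mantel_permutations: int = 10_000
    dim_n_bins: int = 12
    dim_min_pairs_per_bin: int = 3
    dim_eta: float = 0.0
    dim_fc_source: str = "simulated_at_Tc"
    distance_map: str = "reciprocal"
    master_seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def sim_params(self, temperature: float = 1.0, seed: int = 0) -> SimulationParams:
        return SimulationParams(
            temperature=temperature,
            n_equil_sweeps=self.n_equil_sweeps,
            n_samples=self.n_samples,
            sample_interval_sweeps=self.sample_interval_sweeps,
            seed=seed,
        )


@dataclass(frozen=True)
class SubjectResult:
    subject_id: str
    group: str
    Tc: float
    tstar_per_scan: dict  # scan label -> (T_star, best_r)
    best_scan: str
    T_star: float
    best_r: float
    direct_r: float
    dimensionality: DimensionalityEstimate
    temperatures: np.ndarray
    seed: int

    def to_row(self) -> dict:
        row = {
            "subject_id": self.subject_id,
            "group": self.group,
            "Tc": self.Tc,
            "best_scan": self.best_scan,
            "T_star": self.T_star,
            "best_r": self.best_r,
            "direct_r": self.direct_r,
            "gamma": self.dimensionality.gamma,
            "D": self.dimensionality.D,
            "dim_fit_r2": self.dimensionality.fit_r2,
            "dim_fc_source": self.dimensionality.fc_source,
            "seed": self.seed,
        }
        for label in ("t1", "t2"):
            ts = self.tstar_per_scan.get(label)
            row[f"T_star_{label}"] = ts[0] if ts else float("nan")
            row[f"best_r_{label}"] = ts[1] if ts else float("nan")
        return row


def run_subject(record: SubjectRecord, config: AnalysisConfig) -> SubjectResult:
    """Full single-subject analysis; deterministic given (record, config)."""
    coupling = (
        record.connectome
        if record.connectome.normalization == "max_one"
        else normalize_coupling(record.connectome.J)
    )
    seed = derive_seed(config.master_seed, "subject", record.subject_id)
    grid = default_temperature_grid(coupling, config.n_temperatures)
    params = config.sim_params(seed=seed)
    curve, traces = temperature_sweep(
        coupling,
        grid,
        params,
        n_runs=config.n_runs,
        master_seed=seed,
        seed_context=(record.subject_id,),
        retain_traces=True,
    )
    crit = find_critical_temperature(curve, smooth_window=config.smooth_window)

    # run-averaged simulated FC per grid temperature, reusing sweep traces
    sim_fcs: list[CorrelationMatrix] = []
    for ti in range(grid.shape[0]):
        fcs = [
            pearson_correlation_matrix(
                traces[(ti, run)].samples.astype(float), kind="simulated"
            )
            for run in range(config.n_runs)
        ]
        sim_fcs.append(average_fc_over_runs(fcs))

    per_scan = {}
    tstar_results = {}
    empirical_fcs = {}
    for scan in record.bold_scans:
        emp = pearson_correlation_matrix(scan.values, kind="empirical")
        empirical_fcs[scan.scan_label] = emp
        res = tstar_from_fc_curve(sim_fcs, emp, grid)
        tstar_results[scan.scan_label] = res
        per_scan[scan.scan_label] = (res.T_star, res.best_r)
    if not tstar_results:
        raise ValueError(f"subject {record.subject_id} has no BOLD scans")
    best = select_best_scan(tstar_results)
    best_res = tstar_results[best]
    direct_r = direct_sc_fc_correlation(coupling, empirical_fcs[best])

    tc_idx = int(np.argmin(np.abs(grid - crit.Tc)))
    source = config.dim_fc_source
    if source == "simulated_at_Tc":
        dim_fc = sim_fcs[tc_idx]
    elif source == "simulated_at_Tstar":
        ts_idx = int(np.argmin(np.abs(grid - best_res.T_star)))
        dim_fc = sim_fcs[ts_idx]
    elif source == "empirical":
        dim_fc = empirical_fcs[best]
    else:
        raise ValueError(f"unknown dim_fc_source {source!r}")
    dim = subject_dimensionality(
        coupling,
        dim_fc,
        fc_source=source,
        n_bins=config.dim_n_bins,
        min_pairs_per_bin=config.dim_min_pairs_per_bin,
        eta=config.dim_eta,
        distance_map=config.distance_map,
    )
    return SubjectResult(
        subject_id=record.subject_id,
        group=record.group,
        Tc=crit.Tc,
        tstar_per_scan=per_scan,
        best_scan=best,
        T_star=best_res.T_star,
        best_r=best_res.best_r,
        direct_r=direct_r,
        dimensionality=dim,
        temperatures=grid,
        seed=seed,
    )


def _next_run_dir(out_dir: Path) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    k = 1
    while (out_dir / f"run-{k:04d}").exists():
        k += 1
    run_dir = out_dir / f"run-{k:04d}"
    run_dir.mkdir()
    return run_dir


def _stat_rows(results: list[SubjectResult]) -> tuple[list[dict], list[dict]]:
    """Group-comparison battery on per-subject outcomes.

    Returns (comparison rows, warning rows).
    """
    by_group: dict[str, list[SubjectResult]] = {}
    for r in results:
        by_group.setdefault(r.group, []).append(r)
    warnings: list[dict] = []
    hc = by_group.get("HC", [])
    patient_groups = {g: by_group[g] for g in ("VS_UWS", "MCS_MINUS", "MCS_PLUS") if g in by_group}
    patients = [r for g in patient_groups.values() for r in g]
    eligible = [g for g, rs in by_group.items() if len(rs) >= 2]
    if len(hc) < 2 or len(patients) < 2 or len(eligible) < 2:
        warnings.append(
            {
                "warning": "group statistics skipped",
                "reason": f"need >= 2 groups with >= 2 subjects (have {[(g, len(rs)) for g, rs in by_group.items()]})",
            }
        )
        return [], warnings

    def values(rs: list[SubjectResult], outcome: str) -> np.ndarray:
        rows = [r.to_row() for r in rs]
        return np.array([row[outcome] for row in rows], dtype=float)

    def row_from(res: cohort_stats.GroupComparisonResult, outcome: str, test: str) -> dict:
        df = res.df
        return {
            "outcome": outcome,
            "test": test,
            "comparison": res.comparison_label,
            "statistic": res.statistic,
            "df1": df[0] if isinstance(df, tuple) else df,
            "df2": df[1] if isinstance(df, tuple) else float("nan"),
            "p": res.p_two_tailed,
            "p_adjusted": res.adjusted_p if res.adjusted_p is not None else float("nan"),
        }

    rows: list[dict] = []
    for outcome in OUTCOMES:
        try:
            res = cohort_stats.welch_t_test(
                values(hc, outcome), values(patients, outcome), label="HC_vs_patients"
            )
            rows.append(row_from(res, outcome, "welch_t"))
        except ValueError as err:
            warnings.append({"warning": f"welch_t skipped for {outcome}", "reason": str(err)})
        anova_groups = [values(by_group[g], outcome) for g in sorted(by_group) if len(by_group[g]) >= 2]
        if len(anova_groups) >= 2:
            try:
                res = cohort_stats.one_way_anova(anova_groups, label="group_main_effect")
                rows.append(row_from(res, outcome, "anova"))
            except ValueError as err:
                warnings.append({"warning": f"anova skipped for {outcome}", "reason": str(err)})
        posthoc_input = {g: values(rs, outcome) for g, rs in patient_groups.items() if len(rs) >= 2}
        if posthoc_input and len(hc) >= 2:
            try:
                for res in cohort_stats.posthoc_vs_control(values(hc, outcome), posthoc_input):
                    rows.append(row_from(res, outcome, "posthoc_welch_t"))
            except ValueError as err:
                warnings.append({"warning": f"posthoc skipped for {outcome}", "reason": str(err)})

    # paired t between the two scans' T*, controls and patients separately
    for cohort_name, rs in (("HC", hc), ("patients", patients)):
        both = [r for r in rs if "t1" in r.tstar_per_scan and "t2" in r.tstar_per_scan]
        if len(both) < 2:
            warnings.append(
                {"warning": f"paired t skipped for {cohort_name}", "reason": "fewer than 2 two-scan subjects"}
            )
            continue
        t1 = np.array([r.tstar_per_scan["t1"][0] for r in both])
        t2 = np.array([r.tstar_per_scan["t2"][0] for r in both])
        try:
            res = cohort_stats.paired_t_test(t1, t2, label=f"{cohort_name}_t1_vs_t2")
            rows.append(row_from(res, "T_star_scan", "paired_t"))
        except ValueError as err:
            warnings.append({"warning": f"paired t skipped for {cohort_name}", "reason": str(err)})
    return rows, warnings


def run_cohort(
    subjects: list[SubjectRecord] | str | Path,
    config: AnalysisConfig,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the full pipeline over a cohort; per-subject failures isolated.

    ``subjects`` is either a list of loaded records or a manifest path.
    With ``out_dir``, results are written into a fresh ``run-XXXX``
    directory (never overwriting a previous run): the resolved config,
    per-subject results TSV, comparison tables, and a JSON-lines event
    log.
    """
    log: list[dict] = []

    def event(kind: str, **info) -> None:
        log.append({"time": time.time(), "event": kind, **info})

    if isinstance(subjects, (str, Path)):
        entries = read_manifest(subjects)
        records = []
        for entry in entries:
            try:
                records.append(load_subject(entry))
            except Exception as err:  # noqa: BLE001 - failure isolation
                event("subject_load_failed", subject_id=entry.subject_id, error=str(err))
    else:
        records = list(subjects)

    results: list[SubjectResult] = []
    failures: list[dict] = []
    for record in records:
        try:
            res = run_subject(record, config)
            results.append(res)
            event("subject_done", subject_id=record.subject_id, Tc=res.Tc, T_star=res.T_star)
        except Exception as err:  # noqa: BLE001 - failure isolation
            failure = {"subject_id": record.subject_id, "error": str(err)}
            failures.append(failure)
            event("subject_failed", **failure)

    stat_rows, warnings = _stat_rows(results)
    for w in warnings:
        event("stats_warning", **w)

    report = {
        "subject_rows": [r.to_row() for r in results],
        "comparison_rows": stat_rows,
        "warnings": warnings,
        "failures": failures,
        "n_subjects": len(results),
    }

    if out_dir is not None:
        run_dir = _next_run_dir(Path(out_dir))
        config.to_yaml(run_dir / "config.yaml")
        if report["subject_rows"]:
            write_results_table(report["subject_rows"], run_dir / "subjects.tsv")
        if stat_rows:
            write_results_table(stat_rows, run_dir / "comparisons.tsv")
        with open(run_dir / "events.jsonl", "w") as fh:
            for entry in log:
                fh.write(json.dumps(entry) + "\n")
        with open(run_dir / "report.json", "w") as fh:
            json.dump(
                {k: v for k, v in report.items() if k != "subject_rows"}, fh, indent=2, default=str
            )
        report["run_dir"] = str(run_dir)
    return report
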