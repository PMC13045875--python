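"""End-to-end orchestration: simulate/extract -> harmonize -> adjust ->
correlate -> fit -> report.

Three input modes:

* ``synthetic`` — generate a cohort with :mod:`twindti.cohort` (seeded,
  bit-reproducible);
* ``from_table`` — start from a long regional CSV plus a roster CSV;
* ``from_correlations`` — start from an already-computed correlation CSV
  (columns region, metric, r_mz, n_mz, r_dz, n_dz), e.g. a published
  table, and run only the biometric stage.

Every run writes the correlation table, the component table, the combined
report, a rendered text summary, and a JSON manifest (config, seed,
package version, SHA-256 of each artifact).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .biometric import FitInput, broad_sense_G, fit_components_ml, select_model
from .cohort import (
    SimulationConfig,
    build_roster,
    retained_pairs,
    roster_from_frame,
    roster_to_frame,
    simulate_regional_values,
)
from .combat import harmonize_table
from .twinstats import (
    adjust_age_sex,
    correlation_table,
    round_half_up,
    summarize_metric_correlations,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "fit_correlation_table", "render_report"]

NEAR_ZERO_G = 0.05  # report flag: heritability indistinguishable from zero


@dataclass
class PipelineConfig:
    mode: str = "synthetic"  # synthetic | from_table | from_correlations
    out_dir: str | Path = "twindti_out"
    seed: int = 0
    harmonize: bool = True
    table_path: str | Path | None = None
    roster_path: str | Path | None = None
    correlations_path: str | Path | None = None
    simulation: SimulationConfig | None = None
    round_digits: int = 2

    def validate(self) -> None:
        modes = ("synthetic", "from_table", "from_correlations")
        if self.mode not in modes:
            raise ValueError(f"mode must be one of {modes}")
        if self.mode == "from_table" and not (self.table_path and self.roster_path):
            raise ValueError("from_table mode needs table_path and roster_path")
        if self.mode == "from_correlations" and not self.correlations_path:
            raise ValueError("from_correlations mode needs correlations_path")


def fit_correlation_table(corr: pd.DataFrame) -> pd.DataFrame:
    """Biometric stage: one ACE/ADE ML fit per correlation row.

    Input columns: region, metric, r_mz, n_mz, r_dz, n_dz (extra columns
    pass through).  Output adds model, A, C, D, A_plus_D, G, E, total.
    """
    rows = []
    for row in corr.itertuples(index=False):
        model = select_model(row.r_mz, row.r_dz)
        comp = fit_components_ml(
            FitInput(r_mz=row.r_mz, n_mz=int(row.n_mz), r_dz=row.r_dz, n_dz=int(row.n_dz)),
            model,
            region=row.region,
            metric=row.metric,
        )
        rows.append(
            {
                "region": row.region,
                "metric": row.metric,
                "r_mz": row.r_mz,
                "n_mz": int(row.n_mz),
                "r_dz": row.r_dz,
                "n_dz": int(row.n_dz),
                "p": getattr(row, "p", float("nan")),
                "model": model,
                "A": comp.A,
                "C": comp.C,
                "D": comp.D,
                "A_plus_D": comp.A + comp.D if model == "ADE" else float("nan"),
                "G": broad_sense_G(comp),
                "E": comp.E,
                "total": comp.total,
                "constrained": comp.constrained,
            }
        )
    return pd.DataFrame(rows)


def render_report(report: pd.DataFrame, round_digits: int = 2) -> str:
    """Plain-text summary: per-metric correlation means/ranges, regions with
    r_DZ > r_MZ (inverse pattern), and regions with G <= 0.05."""
    if report.empty:
        raise ValueError("empty report table")
    rd = lambda x: round_half_up(x, round_digits)  # noqa: E731
    lines = ["Twin correlation summary (mean [min, max] across regions)"]
    for metric, grp in report.groupby("metric", sort=False):
        m_mz = summarize_metric_correlations(grp["r_mz"])
        m_dz = summarize_metric_correlations(grp["r_dz"])
        lines.append(
            f"  {metric}: MZ {m_mz[0]:.2f} [{m_mz[1]:.2f}, {m_mz[2]:.2f}]"
            f"  DZ {m_dz[0]:.2f} [{m_dz[1]:.2f}, {m_dz[2]:.2f}]"
        )
    inverse = report[report["r_dz"] > report["r_mz"]]
    lines.append("Regions with r_DZ > r_MZ (inverse pattern):")
    if inverse.empty:
        lines.append("  none")
    for metric, grp in inverse.groupby("metric", sort=False):
        lines.append(f"  {metric}: " + ", ".join(grp["region"]))
    low_g = report[report["G"] <= NEAR_ZERO_G]
    lines.append(f"Regions with G <= {NEAR_ZERO_G} (negligible genetic contribution):")
    if low_g.empty:
        lines.append("  none")
    for metric, grp in low_g.groupby("metric", sort=False):
        lines.append(
            f"  {metric}: "
            + ", ".join(f"{r.region} (G={rd(r.G):.2f})" for r in grp.itertuples())
        )
    return "\n".join(lines) + "\n"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """Run all enabled stages; write artifacts + manifest; return the report."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage_log: list[dict] = []
    artifacts: dict[str, Path] = {}

    def stage(name):
        def wrap(fn):
            start = time.time()
            try:
                res = fn()
            except Exception as exc:  # annotate failures with the stage name
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            stage_log.append({"stage": name, "seconds": round(time.time() - start, 3)})
            return res

        return wrap

    if config.mode == "from_correlations":
        corr = stage("load_correlations")(
            lambda: pd.read_csv(config.correlations_path)
        )
    else:
        if config.mode == "synthetic":
            sim = config.simulation or SimulationConfig(seed=config.seed)
            roster = stage("simulate_roster")(lambda: build_roster(sim))
            table = stage("simulate_values")(
                lambda: simulate_regional_values(roster, sim)
            )
            roster_frame = roster_to_frame(retained_pairs(roster))
        else:
            table = stage("load_table")(lambda: pd.read_csv(config.table_path))
            roster_frame = stage("load_roster")(lambda: pd.read_csv(config.roster_path))
            if "excluded_reason" in roster_frame.columns:
                roster_frame = roster_frame[roster_frame["excluded_reason"] == "none"]
            roster_from_frame(roster_frame)  # validates records
        roster_frame.to_csv(out_dir / "roster.csv", index=False)
        artifacts["roster"] = out_dir / "roster.csv"

        if config.harmonize:
            table, models = stage("harmonize")(
                lambda: harmonize_table(table, roster_frame)
            )
            for metric, model in models.items():
                p = out_dir / f"combat_model_{metric}.json"
                model.to_json(p)
                artifacts[f"combat_model_{metric}"] = p
        resid = stage("adjust_age_sex")(lambda: adjust_age_sex(table, roster_frame))
        corr = stage("correlate")(lambda: correlation_table(resid, roster_frame))

    corr_path = out_dir / "correlations.csv"
    corr.to_csv(corr_path, index=False)
    artifacts["correlations"] = corr_path

    report = stage("fit_components")(lambda: fit_correlation_table(corr))
    comp_path = out_dir / "components.csv"
    report.to_csv(comp_path, index=False)
    artifacts["components"] = comp_path

    rd = config.round_digits
    printed = report.copy()
    for col in ("r_mz", "r_dz", "A", "C", "D", "A_plus_D", "G", "E", "total"):
        printed[col] = printed[col].map(
            lambda v: round_half_up(v, rd) if pd.notna(v) else v
        )
    printed["p"] = printed["p"].map(lambda v: round_half_up(v, 4) if pd.notna(v) else v)
    report_path = out_dir / "report.csv"
    printed.to_csv(report_path, index=False)
    artifacts["report"] = report_path

    summary = stage("render_report")(lambda: render_report(report, rd))
    summary_path = out_dir / "summary.txt"
    summary_path.write_text(summary)
    artifacts["summary"] = summary_path

    manifest = {
        "package": "twindti",
        "version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "harmonize": config.harmonize,
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(config).items()
            if k != "simulation"
        },
        "stages": stage_log,
        "n_report_rows": int(len(report)),
        "n_constrained_fits": int(report["constrained"].sum()),
        "artifacts": {k: {"path": p.name, "sha256": _sha256(p)} for k, p in artifacts.items()},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    log.info("pipeline finished in %.2fs: %d rows", time.time() - t0, len(report))
    return report
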