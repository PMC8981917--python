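"""End-to-end experiment orchestration: traces -> mechanics -> statistics.

A YAML experiment config lists groups of trace/geometry files plus a shared
drag baseline and protocol.  Each specimen is analysed to its mechanical
endpoints; endpoints are then compared across groups (normality-gated
ANOVA/Tukey or Kruskal-Wallis/Conover) and correlated across specimens with
Spearman/Bonferroni.  Every exclusion and routing decision is logged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, groupstats, mechanics, traceio
from .morphometry import SpecimenGeometry, read_geometry
from .traceio import TensileTrace, TestProtocol

__all__ = ["ExperimentConfig", "ExperimentResult", "load_config", "run_experiment", "write_outputs"]

ENDPOINTS = ["uts_mpa", "mtm_mpa", "failure_strain"]


@dataclass
class GroupSpec:
    label: str
    traces: list[Path]
    geometries: list[Path]
    baseline: Path | None = None  # overrides the experiment-level baseline


@dataclass
class ExperimentConfig:
    protocol: TestProtocol
    groups: list[GroupSpec]
    baseline: Path | None = None
    area_convention: str = "minimum"
    stress_convention: str = "engineering"
    stats_method: str = "auto"  # auto | anova | kw
    seed: int = 0
    source_text: str = ""

    def validate(self) -> None:
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError(f"group labels are not unique: {labels}")
        for g in self.groups:
            if len(g.traces) != len(g.geometries):
                raise ValueError(
                    f"group {g.label!r}: {len(g.traces)} traces vs "
                    f"{len(g.geometries)} geometries"
                )
            for p in [*g.traces, *g.geometries, g.baseline or self.baseline]:
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(f"group {g.label!r}: missing file {p}")

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.source_text.encode()).hexdigest()[:12]


@dataclass
class ExperimentResult:
    summary: pd.DataFrame
    comparisons: dict[str, groupstats.GroupComparison]
    correlation: groupstats.CorrelationMatrix | None
    log: list[dict] = field(default_factory=list)

    @property
    def report(self) -> str:
        lines = [
            "# Experiment report",
            "",
            f"ringmech version: {__version__}",
            f"specimens analysed: {len(self.summary)}",
            "",
            "## Group comparisons",
        ]
        for endpoint, comp in self.comparisons.items():
            lines.append(
                f"- {endpoint}: {comp.method}, statistic={comp.statistic:.4g}, "
                f"p={comp.p_value:.4g}, letters={comp.letters}"
            )
        lines.append("")
        lines.append("## Log")
        for entry in self.log:
            lines.append(f"- {json.dumps(entry, sort_keys=True)}")
        return "\n".join(lines) + "\n"


def load_config(path) -> ExperimentConfig:
    """Load an experiment YAML; relative paths resolve against the config file."""
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) or {}
    base = path.parent

    def resolve(p):
        return None if p is None else (base / p)

    protocol = data.get("protocol", {})
    if isinstance(protocol, str):
        protocol = traceio.read_protocol(base / protocol)
    else:
        protocol = TestProtocol(**protocol)
    groups = [
        GroupSpec(
            label=g["label"],
            traces=[resolve(t) for t in g["traces"]],
            geometries=[resolve(t) for t in g["geometries"]],
            baseline=resolve(g.get("baseline")),
        )
        for g in data.get("groups", [])
    ]
    cfg = ExperimentConfig(
        protocol=protocol,
        groups=groups,
        baseline=resolve(data.get("baseline")),
        area_convention=data.get("area_convention", "minimum"),
        stress_convention=data.get("stress_convention", "engineering"),
        stats_method=data.get("stats_method", "auto"),
        seed=int(data.get("seed", 0)),
        source_text=text,
    )
    cfg.validate()
    return cfg


def _analyse_specimen(
    trace_path: Path,
    geom_path: Path,
    baseline: TensileTrace | None,
    cfg: ExperimentConfig,
    group: str,
    log: list[dict],
) -> dict | None:
    trace = traceio.read_trace(trace_path)
    geometry = read_geometry(geom_path)
    a0 = geometry.a0(cfg.area_convention)
    try:
        summary, curve = mechanics.analyze_trace(
            trace,
            baseline,
            cfg.protocol,
            a0,
            area_convention=cfg.area_convention,
            stress_convention=cfg.stress_convention,
        )
    except (mechanics.NeverInTensionError, mechanics.CurveTooShortError, ValueError) as exc:
        log.append(
            {
                "event": "specimen_excluded",
                "specimen_id": trace.specimen_id,
                "group": group,
                "reason": str(exc),
            }
        )
        return None
    if not summary.failure_detected:
        log.append(
            {
                "event": "no_failure_detected",
                "specimen_id": trace.specimen_id,
                "group": group,
                "note": "retained for MTM; excluded from UTS/failure statistics",
            }
        )
    return {
        "specimen_id": trace.specimen_id,
        "group": group,
        "uts_mpa": summary.uts,
        "mtm_mpa": summary.mtm,
        "failure_strain": summary.failure_strain,
        "strain_at_uts": summary.strain_at_uts,
        "failure_detected": summary.failure_detected,
        "a0_mm2": a0,
        "area_convention": cfg.area_convention,
        "gauge_length_mm": curve.gauge_length,
        "stress_convention": cfg.stress_convention,
    }


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Analyse every specimen, then run the per-endpoint statistics battery.

    Specimens failing validation are excluded and logged; more than 50%
    exclusions aborts.  Specimens without a detected failure keep their MTM
    but are dropped from UTS/failure-strain statistics.
    """
    cfg.validate()
    log: list[dict] = [
        {
            "event": "run_started",
            "version": __version__,
            "config_hash": cfg.config_hash,
            "area_convention": cfg.area_convention,
            "stress_convention": cfg.stress_convention,
            "stats_method": cfg.stats_method,
            "seed": cfg.seed,
        }
    ]
    shared_baseline = (
        traceio.read_trace(cfg.baseline, is_baseline=True) if cfg.baseline else None
    )
    rows, n_total = [], 0
    for g in cfg.groups:
        baseline = (
            traceio.read_trace(g.baseline, is_baseline=True)
            if g.baseline
            else shared_baseline
        )
        for tp, gp in zip(g.traces, g.geometries):
            n_total += 1
            row = _analyse_specimen(tp, gp, baseline, cfg, g.label, log)
            if row is not None:
                rows.append(row)
    if n_total and len(rows) < 0.5 * n_total:
        raise RuntimeError(
            f"{n_total - len(rows)} of {n_total} specimens excluded (> 50%)"
        )
    summary = pd.DataFrame(rows)

    comparisons: dict[str, groupstats.GroupComparison] = {}
    if len(summary) and summary["group"].nunique() >= 2:
        for endpoint in ENDPOINTS:
            sub = summary
            if endpoint in ("uts_mpa", "failure_strain"):
                sub = summary[summary["failure_detected"]]
            counts = sub.groupby("group")["specimen_id"].count()
            if (counts < 3).any() or len(counts) < 2:
                log.append({"event": "comparison_skipped", "endpoint": endpoint,
                            "reason": "fewer than 3 specimens in some group"})
                continue
            table = sub.rename(columns={endpoint: "value"})[["group", "value"]]
            comp = groupstats.compare(table, method=cfg.stats_method)
            comparisons[endpoint] = comp
            log.append(
                {"event": "comparison", "endpoint": endpoint, "method": comp.method,
                 "p": comp.p_value, "letters": comp.letters}
            )

    correlation = None
    if len(summary) >= 3:
        wide_cols = [c for c in ENDPOINTS + ["a0_mm2", "day", "collagen_ug"] if c in summary]
        correlation = groupstats.spearman_matrix(summary[wide_cols])
    return ExperimentResult(summary=summary, comparisons=comparisons,
                            correlation=correlation, log=log)


def write_outputs(result: ExperimentResult, out_dir) -> dict[str, Path]:
    """Write summary.csv, stats.json, correlations.csv and report.md."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["summary"] = out_dir / "summary.csv"
    result.summary.to_csv(paths["summary"], index=False, float_format="%.12g")
    paths["stats"] = out_dir / "stats.json"
    with open(paths["stats"], "w") as fh:
        json.dump(
            {k: v.to_dict() for k, v in result.comparisons.items()},
            fh, indent=2, sort_keys=True,
        )
    if result.correlation is not None:
        paths["correlations"] = out_dir / "correlations.csv"
        corr = result.correlation
        long = []
        for i, a in enumerate(corr.variables):
            for j, b in enumerate(corr.variables):
                if j <= i:
                    continue
                long.append(
                    {"var_a": a, "var_b": b,
                     "rho": corr.rho.iloc[i, j],
                     "p_raw": corr.p_raw.iloc[i, j],
                     "p_bonferroni": corr.p_adjusted.iloc[i, j]}
                )
        pd.DataFrame(long).to_csv(paths["correlations"], index=False, float_format="%.12g")
    paths["report"] = out_dir / "report.md"
    paths["report"].write_text(result.report)
    return paths
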