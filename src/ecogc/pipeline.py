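"""End-to-end orchestration: classify, normalize, compare, ANOVA, convergence.

``run_all`` executes every stage on the configured inputs (or on
synthetic tables when no input paths are given), logging record counts
in and out of each filter, and writes a machine-readable ``report.json``
plus a human-readable ``report.md`` and plot-ready per-group TSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bootstrap_anova import AnovaResult, run_two_way
from .cds_expression import (
    IsochoreBinning,
    assign_bins,
    attach_expression,
    expression_by_bin,
    filter_cds,
    read_cds_fasta,
)
from .convergence import ConvergenceResult, run_convergence
from .group_stats import (
    mann_whitney,
    normality_screen,
    one_tailed_mr_gill_comparison,
    phylo_signal_screen,
)
from .metabolic_norm import BoltzmannParams, normalize_dataset
from .species_io import (
    DEFAULT_EXCLUSIONS,
    TraitDataset,
    Variable,
    apply_exclusions,
    collapse_dataset,
    partition_groups,
    read_trait_table,
)
from .synthetic import SyntheticSpec, generate_trait_dataset

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ReportBundle", "run_all", "render_table1", "load_config"]

GROUP_ORDER = ("FWNM", "FWM", "SWNM", "SWM")


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    inputs: dict = field(default_factory=dict)  # variable name -> table path
    exclusions_path: str | None = None
    use_default_exclusions: bool = True
    activation_energy: float = 0.65
    boltzmann_k: float = 8.62e-5
    anova_resamples: int = 1000
    ss_type: str = "II"
    seed: int = 42
    convergence_focal: str = "SWM"
    convergence_permutations: int = 10_000
    cds_fasta: str | None = None
    expression_table: str | None = None
    isochore_cutpoints: tuple | None = None
    main_bins: tuple = ("H1", "H2")
    synthetic: dict | None = None  # per-variable SyntheticSpec kwargs
    out_dir: str = "ecogc_out"
    column_map: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON run configuration."""
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**data)
    if cfg.isochore_cutpoints is not None:
        cfg.isochore_cutpoints = tuple(cfg.isochore_cutpoints)
    cfg.main_bins = tuple(cfg.main_bins)
    return cfg


@dataclass
class ReportBundle:
    medians: dict                 # variable -> group -> median (4 x k table)
    counts: dict                  # variable -> record-count audit trail
    salinity_tests: dict          # variable -> RankTestResult
    migration_tests: dict
    normality: dict               # variable -> (W, p)
    phylo_screen: dict            # variable -> verdict
    anova: dict                   # variable -> AnovaResult
    convergence: ConvergenceResult | None
    expression: Any | None
    version: str
    config_hash: str
    seed: int


def _load_datasets(config: RunConfig) -> tuple[dict[str, TraitDataset], dict]:
    """Load (or synthesize), exclude, collapse and audit each trait table."""
    exclusions = set(DEFAULT_EXCLUSIONS) if config.use_default_exclusions else set()
    if config.exclusions_path:
        extra = Path(config.exclusions_path).read_text(encoding="utf-8").splitlines()
        exclusions |= {line.strip() for line in extra if line.strip()}

    datasets: dict[str, TraitDataset] = {}
    counts: dict[str, dict] = {}
    for var in Variable:
        ds = None
        if var.value in config.inputs:
            ds = read_trait_table(
                config.inputs[var.value],
                var,
                columns=config.column_map or None,
                allow_replicates=True,
            )
        elif config.synthetic is not None:
            kwargs = dict(config.synthetic.get(var.value, config.synthetic.get("all", {})))
            kwargs.setdefault("seed", config.seed + list(Variable).index(var))
            ds = generate_trait_dataset(SyntheticSpec(**kwargs), var)
        if ds is None:
            continue
        audit = {"read": len(ds)}
        ds = collapse_dataset(ds)
        audit["after_replicate_collapse"] = len(ds)
        ds = apply_exclusions(ds, exclusions)
        audit["after_exclusions"] = len(ds)
        datasets[var.value] = ds
        counts[var.value] = audit
        logger.info("%s dataset: %s", var.value, audit)
    if not datasets:
        raise ValueError("no inputs configured and no synthetic spec given")
    return datasets, counts


def run_all(config: RunConfig, write: bool = True) -> ReportBundle:
    """Execute every stage; any stage error aborts, naming the stage."""
    stage = "load"
    try:
        datasets, counts = _load_datasets(config)

        stage = "normalize"
        params = BoltzmannParams(E=config.activation_energy, k=config.boltzmann_k)
        if "MR" in datasets:
            datasets["MR"] = normalize_dataset(datasets["MR"], params)

        stage = "partition"
        partitions = {
            var: partition_groups(ds, mode="four_way")
            for var, ds in datasets.items()
        }
        medians = {
            var: {
                g: (float(np.median(vals)) if vals else None)
                for g, vals in cells.items()
            }
            for var, cells in partitions.items()
        }

        stage = "two-group tests"
        salinity_tests, migration_tests = {}, {}
        for var, ds in datasets.items():
            sal = partition_groups(ds, mode="salinity")
            mig = partition_groups(ds, mode="migration")
            salinity_tests[var] = mann_whitney(
                sal["FW"], sal["SW"], alternative="two_sided"
            )
            # one-tailed (M > NM) for MR and Gill, declared a priori
            if var in ("MR", "Gill"):
                migration_tests[var] = one_tailed_mr_gill_comparison(
                    mig["M"], mig["NM"]
                )
            else:
                migration_tests[var] = mann_whitney(
                    mig["M"], mig["NM"], alternative="two_sided"
                )

        stage = "normality screen"
        normality = {
            var: normality_screen(ds.values()) for var, ds in datasets.items()
        }

        stage = "phylogenetic screen"
        phylo = {var: phylo_signal_screen(ds) for var, ds in datasets.items()}

        stage = "bootstrap ANOVA"
        anova: dict[str, AnovaResult] = {}
        for var, ds in datasets.items():
            anova[var] = run_two_way(
                ds,
                b=config.anova_resamples,
                seed=config.seed,
                ss_type=config.ss_type,
            )

        stage = "convergence"
        convergence = None
        if len(partitions) >= 2:
            convergence = run_convergence(
                partitions,
                focal_group=config.convergence_focal,
                n_perm=config.convergence_permutations,
                seed=config.seed,
            )

        stage = "expression"
        expression = None
        if config.cds_fasta and config.expression_table:
            if config.isochore_cutpoints is None:
                raise ValueError(
                    "isochore_cutpoints are required for the expression stage"
                )
            records = read_cds_fasta(config.cds_fasta)
            kept, rejected = filter_cds(records)
            logger.info(
                "expression stage: %d CDS read, %d kept, %d rejected",
                len(records), len(kept), len(rejected),
            )
            expr_df = pd.read_csv(config.expression_table, sep=None, engine="python")
            expr_map = dict(zip(expr_df["cds_id"], expr_df["expression"]))
            binning = IsochoreBinning(cutpoints=tuple(config.isochore_cutpoints))
            kept = attach_expression(assign_bins(kept, binning), expr_map)
            expression = expression_by_bin(kept, main_bins=tuple(config.main_bins))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = ReportBundle(
        medians=medians,
        counts=counts,
        salinity_tests=salinity_tests,
        migration_tests=migration_tests,
        normality=normality,
        phylo_screen={var: r.verdict for var, r in phylo.items()},
        anova=anova,
        convergence=convergence,
        expression=expression,
        version=__version__,
        config_hash=config.config_hash(),
        seed=config.seed,
    )
    if write:
        _write_report(report, partitions, config)
    return report


def _jsonify(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return None  # bootstrap null distributions are omitted from JSON
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def report_to_dict(report: ReportBundle) -> dict:
    d = _jsonify(report)
    for var, res in d.get("anova", {}).items():
        for key in ("null_f_a", "null_f_b", "null_f_ab"):
            res.pop(key, None)
    return d


def _write_report(report: ReportBundle, partitions: dict, config: RunConfig) -> None:
    out = Path(config.out_dir)
    (out / "tables").mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(
        json.dumps(report_to_dict(report), indent=2, sort_keys=True)
    )
    (out / "report.md").write_text(render_report_md(report))
    for var, cells in partitions.items():
        rows = [
            {"group": g, "value": v} for g in GROUP_ORDER for v in cells.get(g, [])
        ]
        pd.DataFrame(rows).to_csv(
            out / "tables" / f"groups_{var}.tsv", sep="\t", index=False
        )
    logger.info("report written to %s", out)


def render_table1(report: ReportBundle, decimals: int = 2) -> str:
    """Render the per-group medians table (Gill, MR, GC columns).

    Missing variables leave explicit gaps; full precision lives in the
    JSON report, this rendering rounds for display only.
    """
    cols = ["Gill", "MR", "GC"]
    lines = ["group\t" + "\t".join(cols)]
    for g in GROUP_ORDER:
        cells = []
        for var in cols:
            med = report.medians.get(var, {}).get(g)
            cells.append("-" if med is None else f"{med:.{decimals}f}")
        lines.append(g + "\t" + "\t".join(cells))
    return "\n".join(lines) + "\n"


def render_report_md(report: ReportBundle) -> str:
    md = [
        "# ecogc analysis report",
        "",
        f"version {report.version}, config {report.config_hash}, seed {report.seed}",
        "",
        "## Group medians",
        "",
        "```",
        render_table1(report).rstrip(),
        "```",
        "",
        "## Dataset sizes",
        "",
    ]
    for var, audit in report.counts.items():
        md.append(f"- {var}: {audit}")
    md += ["", "## Two-group Mann-Whitney tests", ""]
    for var in report.salinity_tests:
        s = report.salinity_tests[var]
        m = report.migration_tests[var]
        md.append(
            f"- {var}: FW vs SW two-sided p = {s.p_value:.3g}; "
            f"M vs NM ({m.alternative}) p = {m.p_value:.3g}"
        )
    md += ["", "## Normality (Shapiro-Wilk) and order-level screen", ""]
    for var, (w, p) in report.normality.items():
        md.append(
            f"- {var}: W = {w:.4f}, p = {p:.3g}; "
            f"order-level screen: {report.phylo_screen[var]}"
        )
    md += ["", "## Bootstrap two-way ANOVA", ""]
    for var, a in report.anova.items():
        md.append(
            f"- {var} (Type {a.ss_type}, B = {a.b_resamples}): "
            f"salinity F = {a.f_a:.3f} p = {a.p_a:.3g}; "
            f"migration F = {a.f_b:.3f} p = {a.p_b:.3g}; "
            f"interaction F = {a.f_ab:.3f} p = {a.p_ab:.3g}"
        )
    if report.convergence is not None:
        c = report.convergence
        md += [
            "",
            "## Convergence across variables",
            "",
            f"- top group per variable: {c.observed_top}",
            f"- all match focal group {c.focal_group!r}: {c.all_match}",
            f"- exact p (prespecified) = {c.p_exact_prespecified:.6g}; "
            f"exact p (any) = {c.p_exact_any:.6g}; "
            f"permutation p = {c.p_permutation} "
            f"({c.n_permutations} permutations)",
        ]
    if report.expression is not None:
        e = report.expression
        md += [
            "",
            "## Expression by isochore bin",
            "",
            f"- Kruskal-Wallis H = {e.kw_h:.4f}, p = {e.kw_p:.3g}",
            f"- bin counts: {e.bin_counts}",
        ]
        if e.main_bin_test is not None:
            md.append(
                f"- {e.main_bins[0]} vs {e.main_bins[1]} Mann-Whitney "
                f"p = {e.main_bin_test.p_value:.3g}"
            )
    return "\n".join(md) + "\n"
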