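"""End-to-end experiment drivers: simulation -> masking -> metrics -> stats.

Three designs are supported, mirroring the experiments the metrics were
built for:

* clustering — CV of a fluorophore channel across heat-stress conditions
  that differ in clustered-signal fraction f;
* colocalization — above-threshold R between two fluorophore channels
  across conditions that differ in shared-foci fraction rho;
* qPCR — relative expression of target genes, treated vs matched-timepoint
  control.

Per-stack aggregates (not per-section values) are the unit entering group
statistics.  Every run writes delimited-text tables first, figures second,
and a JSON run log carrying the config hash and master seed so identical
inputs reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .image_io import ZStack, read_stack, write_results
from .masking import UnanalyzableStackError, make_cytoplasm_masks
from .metrics import stack_cv, stack_pcc
from .stats import GroupComparison, compare_groups
from .expression import relative_expression

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    """One experiment: input source, channel roles and analysis parameters.

    ``conditions`` maps condition label to the generator's effect parameter
    (clustered-signal fraction f for clustering runs, shared-foci fraction
    rho for colocalization runs); when ``input_glob`` is given, stacks are
    read from disk instead and condition labels come from their metadata.
    """

    kind: str = "clustering"  # clustering | coloc | qpcr
    out_dir: str = "results"
    seed: int = 0
    conditions: dict[str, float] = field(
        default_factory=lambda: {"control": 0.1, "HS37_1h": 0.5, "HS37_24h": 0.3}
    )
    n_replicates: int = 25
    input_glob: str | None = None
    # channel roles
    dapi: str = "DAPI"
    primary: str = "GFP"
    secondary: str = "RFP"
    # masking
    tau: float = 0.01
    dilation: int = 2
    background_method: str = "outside_median"
    # metrics
    threshold_method: str = "otsu"
    pixel_rule: str = "union"
    cv_section_policy: str = "nucleus_free"
    pcc_section_policy: str = "all"
    # stats
    alpha: float = 0.05
    min_group_size: int = 25
    parametric: bool = False
    # qPCR design
    genes: list[str] = field(default_factory=lambda: ["ALBA1", "ALBA4", "ALBA6"])
    fold_changes: dict[str, float] = field(default_factory=dict)  # "gene|timepoint" -> fold
    reference_genes: list[str] = field(default_factory=lambda: ["GAPC1", "EIF1a4"])
    timepoints: list[str] = field(default_factory=lambda: ["1h", "24h"])
    n_bio: int = 4
    n_tech: int = 2
    noise_sd: float = 0.1
    ct_table_path: str | None = None
    # synthetic-source overrides (see synthetic.spec_from_dict)
    base_spec: dict[str, Any] = field(default_factory=dict)
    # outputs
    make_plots: bool = True

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (presentation fields
        like the output directory do not change results, so they are left
        out: reruns into different directories stay comparable)."""
        d = self.to_dict()
        for presentation in ("out_dir", "make_plots"):
            d.pop(presentation, None)
        canonical = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _resolve_stacks(config: ExperimentConfig) -> list[tuple[ZStack, Any]]:
    if config.input_glob:
        paths = sorted(Path().glob(config.input_glob))
        if not paths:
            raise FileNotFoundError(f"no stacks match {config.input_glob!r}")
        return [(read_stack(p), None) for p in paths]
    if len(config.conditions) < 2:
        raise ValueError("at least two conditions are required for a group comparison")
    base = synthetic.spec_from_dict(config.base_spec) if config.base_spec else synthetic.SyntheticSpec()
    key = "f_by_condition" if config.kind == "clustering" else "rho_by_condition"
    return synthetic.generate_condition_series(
        base,
        **{key: config.conditions},
        n_replicates=config.n_replicates,
        seed=config.seed,
    )


def _write_log(config: ExperimentConfig, out: Path, extra: dict) -> dict:
    log = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "master_seed": config.seed,
        **extra,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True, default=str))
    return log


def _boxplot(groups: dict[str, list[float]], labels: dict, ylabel: str, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.6 * len(groups) + 1.5, 4))
    names = list(groups)
    ax.boxplot([groups[g] for g in names], tick_labels=names)
    top = max(max(v) for v in groups.values())
    for i, ((a, b), lab) in enumerate(labels.items()):
        ia, ib = names.index(a) + 1, names.index(b) + 1
        y = top * (1.05 + 0.08 * i)
        ax.plot([ia, ib], [y, y], color="black", lw=0.8)
        ax.text((ia + ib) / 2, y, lab, ha="center", va="bottom", fontsize=9)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _run_imaging(config: ExperimentConfig, metric: str) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stacks = _resolve_stacks(config)
    rows = []
    excluded = []
    for stack, _truth in stacks:
        try:
            masks = make_cytoplasm_masks(
                stack,
                dapi=config.dapi,
                signal=config.primary,
                tau=config.tau,
                dilation=config.dilation,
                background_method=config.background_method,
            )
            if metric == "cv":
                prof = stack_cv(stack, masks, config.primary)
                rows.append(
                    {
                        "sample_id": prof.sample_id,
                        "condition": prof.condition,
                        "replicate": stack.replicate,
                        "metric": "cv",
                        "channel": prof.channel,
                        "n_sections": prof.n_sections_included,
                        "section_values": prof.section_cvs,
                        "aggregate": prof.aggregate,
                    }
                )
            else:
                res = stack_pcc(
                    stack,
                    masks,
                    pair=(config.primary, config.secondary),
                    method=config.threshold_method,
                    rule=config.pixel_rule,
                    section_policy=config.pcc_section_policy,
                )
                rows.append(
                    {
                        "sample_id": res.sample_id,
                        "condition": res.condition,
                        "replicate": stack.replicate,
                        "metric": "pcc",
                        "channel": "+".join(res.channel_pair),
                        "n_sections": len(res.section_rs),
                        "section_values": res.section_rs,
                        "aggregate": res.aggregate,
                    }
                )
        except (UnanalyzableStackError, ValueError) as exc:
            logger.warning("stack %s excluded: %s", stack.sample_id, exc)
            excluded.append({"sample_id": stack.sample_id, "condition": stack.condition, "reason": str(exc)})

    table = pd.DataFrame(rows)
    if table.empty:
        raise UnanalyzableStackError("no analyzable stacks")
    groups = {c: g["aggregate"].tolist() for c, g in table.groupby("condition", sort=False)}
    empty = [c for c in config.conditions if config.input_glob is None and c not in groups]
    if empty:
        raise UnanalyzableStackError(f"condition(s) with no analyzable stacks: {empty}")
    comparison = compare_groups(
        groups,
        alpha=config.alpha,
        metric=metric,
        parametric=config.parametric,
        min_group_size=config.min_group_size,
    )

    name = "cv_results" if metric == "cv" else "coloc_results"
    table_out = table.copy()
    table_out.insert(0, "config_hash", config.config_hash())
    table_out.insert(1, "master_seed", config.seed)
    write_results(table_out, out / f"{name}.csv")
    comp_frame = comparison.to_frame()
    comp_frame.insert(0, "config_hash", config.config_hash())
    comp_frame.insert(1, "master_seed", config.seed)
    write_results(comp_frame, out / "comparison.csv")
    if config.make_plots:
        ylabel = "coefficient of variation" if metric == "cv" else "above-threshold Pearson R"
        _boxplot(groups, comparison.labels, ylabel, out / f"{name}_boxplot.png")
    log = _write_log(
        config,
        out,
        {
            "n_stacks": len(stacks),
            "n_analyzed": len(rows),
            "excluded": excluded,
            "omnibus_p": comparison.omnibus_p,
        },
    )
    return {
        "results": table,
        "comparison": comparison,
        "groups": groups,
        "excluded": excluded,
        "run_log": log,
        "out_dir": out,
    }


def run_clustering_experiment(config: ExperimentConfig) -> dict:
    """CV clustering analysis across conditions; returns the report bundle."""
    return _run_imaging(config, "cv")


def run_coloc_experiment(config: ExperimentConfig) -> dict:
    """Above-threshold-R colocalization analysis across conditions."""
    if not config.secondary:
        raise ValueError("colocalization requires a secondary channel")
    return _run_imaging(config, "pcc")


def run_qpcr_experiment(config: ExperimentConfig) -> dict:
    """Relative-expression analysis of a measured or simulated Ct table."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.ct_table_path:
        from .image_io import read_ct_table

        table = read_ct_table(config.ct_table_path)
        truth = None
    else:
        folds = {}
        for key, fold in config.fold_changes.items():
            gene, tp = key.split("|")
            folds[(gene, tp)] = float(fold)
        table, truth = synthetic.generate_ct_table(
            genes=config.genes,
            timepoints=config.timepoints,
            fold_changes=folds,
            n_bio=config.n_bio,
            n_tech=config.n_tech,
            noise_sd=config.noise_sd,
            seed=config.seed,
            reference_genes=tuple(config.reference_genes),
        )
    result = relative_expression(
        table, reference_genes=tuple(config.reference_genes[:2]), alpha=config.alpha
    )
    summary = result.summary.copy()
    summary.insert(0, "config_hash", config.config_hash())
    summary.insert(1, "master_seed", config.seed)
    write_results(summary, out / "expression_summary.csv")
    write_results(result.replicates, out / "expression_replicates.csv")
    if config.make_plots:
        _qpcr_plot(result, out / "expression_plot.png")
    log = _write_log(config, out, {"n_rows": len(table), "genes": list(result.summary["gene"].unique())})
    return {"result": result, "table": table, "truth": truth, "run_log": log, "out_dir": out}


def _qpcr_plot(result, path: Path) -> None:
    """Replicate dots with group means as open rings and standard-error bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    reps = result.replicates
    treated = reps[reps["treatment"] == "treated"]
    keys = sorted({(g, t) for g, t in zip(treated["gene"], treated["timepoint"])})
    fig, ax = plt.subplots(figsize=(1.0 * len(keys) + 2, 4))
    rng = np.random.default_rng(0)
    for i, (g, t) in enumerate(keys):
        vals = treated[(treated["gene"] == g) & (treated["timepoint"] == t)][
            "relative_expression"
        ].to_numpy()
        ax.plot(i + rng.uniform(-0.12, 0.12, vals.size), vals, "o", ms=4, alpha=0.7)
        ax.errorbar(
            i, vals.mean(), yerr=vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0,
            fmt="o", mfc="none", mec="black", ms=9, ecolor="black", capsize=3,
        )
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xticks(range(len(keys)), [f"{g}\n{t}" for g, t in keys], fontsize=8)
    ax.set_ylabel("relative expression (treated / control)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
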