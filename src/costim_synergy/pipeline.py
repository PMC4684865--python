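"""End-to-end pipeline: simulate -> preprocess -> DE -> recruitment ->
synergy -> network classification, from a single config.

Every run is reproducible from the config alone: all randomness derives
from the global seed, the JSON run report embeds a hash of the canonical
config, and repeated runs produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .diffexpr import Cutoffs, de_test, top_k_mean_fc, upregulated_set, write_de_table
from .netreg import classify_nodes, read_edge_list, read_universe, set_coverage, write_node_classes
from .preprocess import preprocess_arrays, read_design, read_spot_table, write_expr_matrix
from .recruitment import membership_table, recruitment_report
from .simdata import SimConfig, simulate_arrays, simulate_network, simulate_truth, write_network, write_simulation
from .synergy import synergy_table, validate_reference_panel, write_synergy_table

logger = logging.getLogger(__name__)

TREATMENTS = ("ligand_a", "ligand_b", "combo")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Flat run configuration (usually loaded from YAML).

    When ``simulate`` is true a synthetic experiment is generated from
    ``sim``; otherwise spot tables are read from ``spot_dir`` +
    ``design_path``.  With neither, the expression stages are skipped and
    the synergy stage validates the packaged 62-gene reference panel.
    """

    outdir: str = "costim_run"
    seed: int = 0
    simulate: bool = True
    sim: SimConfig | None = None
    spot_dir: str | None = None
    design_path: str | None = None
    # preprocessing
    low_threshold: float = 100.0
    span: float = 0.3
    min_fraction: float = 0.5
    floor: float = 1.0
    background: str | None = "auto"
    # testing / cutoffs
    cutoffs: Cutoffs = field(default_factory=Cutoffs)
    equal_var: bool = True
    # synergy
    synergy_threshold: float = 1.5
    synergy_tolerance: float = 0.1
    synergy_all_genes: bool = False
    # network
    edges_path: str | None = None
    universe_path: str | None = None
    netreg_mode: str = "direct"
    net_n_major: int = 4
    net_n_minor: int = 6
    net_coverage_major: float = 0.40
    net_coverage_minor: float = 0.15
    net_sparse_rate: float = 0.02
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.simulate and self.sim is None:
            self.sim = SimConfig(seed=self.seed)
        if self.sim is not None and self.sim.seed != self.seed:
            self.sim = dataclasses.replace(self.sim, seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("sim", None)
        cutoffs = raw.pop("cutoffs", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.sim = SimConfig(**{**sim, "seed": cfg.seed})
        if cutoffs is not None:
            cfg.cutoffs = Cutoffs(**cutoffs)
        return cfg

    def canonical(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, sort_keys=True, default=str))

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.canonical(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineError(name, exc) from exc
        return wrapped
    return deco


@_stage("simulate")
def _simulate(cfg: RunConfig, outdir: Path):
    truth = simulate_truth(cfg.sim)
    tables, design = simulate_arrays(truth, cfg.sim)
    write_simulation(truth, tables, design, outdir / "sim")
    return truth, tables, design


@_stage("load")
def _load(cfg: RunConfig):
    design = read_design(cfg.design_path)
    spot_dir = Path(cfg.spot_dir)
    tables = [read_spot_table(spot_dir / f"array_{aid}.tsv", array_id=aid)
              for aid in design["array_id"]]
    return tables, design


@_stage("preprocess")
def _preprocess(cfg: RunConfig, tables, outdir: Path):
    matrix = preprocess_arrays(
        tables, background=cfg.background, floor=cfg.floor,
        low_threshold=cfg.low_threshold, span=cfg.span,
        min_fraction=cfg.min_fraction)
    write_expr_matrix(matrix, outdir / "expression_matrix.tsv")
    return matrix


@_stage("detest")
def _detest(cfg: RunConfig, matrix, design, outdir: Path):
    results = {}
    for cond in TREATMENTS:
        res = de_test(matrix, design, cond, equal_var=cfg.equal_var)
        write_de_table(res, outdir / f"de_{cond}.tsv")
        results[cond] = res
    return results


@_stage("recruit")
def _recruit(cfg: RunConfig, results, outdir: Path):
    report = recruitment_report(results["ligand_a"], results["ligand_b"],
                                results["combo"], cutoffs=cfg.cutoffs)
    members = membership_table(results["ligand_a"], results["ligand_b"],
                               results["combo"], cutoffs=cfg.cutoffs)
    pd.DataFrame([report.to_dict()]).to_csv(
        outdir / "recruitment_summary.tsv", sep="\t", index=False)
    members.to_csv(outdir / "membership.tsv", sep="\t")
    return report


@_stage("synergy")
def _synergy(cfg: RunConfig, results, combo_strict, outdir: Path):
    eligible = None if cfg.synergy_all_genes else combo_strict
    records = synergy_table(results["ligand_a"], results["ligand_b"],
                            results["combo"], eligible=eligible,
                            threshold=cfg.synergy_threshold)
    write_synergy_table(records, outdir / "synergy.tsv")
    return records


@_stage("netreg")
def _netreg(cfg: RunConfig, universe, outdir: Path):
    if cfg.edges_path:
        declared = read_universe(cfg.universe_path) if cfg.universe_path else None
        network = read_edge_list(cfg.edges_path, declared)
    elif universe is not None and len(universe) >= cfg.net_n_major + cfg.net_n_minor:
        network = simulate_network(
            sorted(universe), cfg.net_n_major, cfg.net_n_minor,
            cfg.net_coverage_major, cfg.net_coverage_minor,
            seed=cfg.seed, sparse_rate=cfg.net_sparse_rate)
        write_network(network, outdir / "network_edges.tsv")
    else:
        logger.info("no edge list and no usable universe; skipping netreg")
        return None, None
    classes = classify_nodes(network, mode=cfg.netreg_mode)
    write_node_classes(classes, outdir / "node_classes.tsv")
    majors = list(classes.index[classes["klass"] == "major"])
    major_cov = set_coverage(network, majors, mode=cfg.netreg_mode)
    return classes, major_cov


def run_pipeline(config: RunConfig) -> dict:
    """Run all configured stages; return (and write) the JSON run report."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "package_version": __version__,
        "config_hash": config.hash(),
        "config": config.canonical(),
        "stages": {},
    }

    results = None
    combo_strict: set | None = None
    if config.simulate:
        truth, tables, design = _simulate(config, outdir)
        report["stages"]["simulate"] = {
            "n_genes": config.sim.n_genes,
            "n_arrays": len(tables),
            "class_counts": pd.Series(truth.synergy_class)
                              .value_counts().sort_index().to_dict(),
        }
    elif config.spot_dir and config.design_path:
        tables, design = _load(config)
        report["stages"]["load"] = {"n_arrays": len(tables)}
    else:
        tables = design = None

    if tables is not None:
        matrix = _preprocess(config, tables, outdir)
        report["stages"]["preprocess"] = {
            "n_genes_retained": int(matrix.values.shape[0]),
            "n_arrays": int(matrix.values.shape[1]),
            "provenance": matrix.provenance,
        }
        results = _detest(config, matrix, design, outdir)
        report["stages"]["detest"] = {
            cond: {
                "n_tested": int(len(res)),
                "top_k_mean_fold_change": round(
                    top_k_mean_fc(res, k=config.cutoffs.top_k), 6),
            }
            for cond, res in results.items()
        }
        venn_report = _recruit(config, results, outdir)
        combo_strict = upregulated_set(results["combo"],
                                       config.cutoffs.strict_alpha)
        report["stages"]["recruit"] = venn_report.to_dict()

        records = _synergy(config, results, combo_strict, outdir)
        report["stages"]["synergy"] = {
            "n_scored": int(len(records)),
            "n_synergistic": int(records["is_synergistic"].sum()),
            "threshold": config.synergy_threshold,
        }
    else:
        panel_report = validate_reference_panel(tolerance=config.synergy_tolerance)
        panel_report.to_csv(outdir / "reference_panel_validation.tsv", sep="\t")
        report["stages"]["synergy"] = {
            "mode": "reference_panel_validation",
            "n_genes": int(len(panel_report)),
            "n_passed": int(panel_report["passed"].sum()),
            "max_abs_diff": float(panel_report["abs_diff"].max()),
            "tolerance": config.synergy_tolerance,
        }

    classes, major_cov = _netreg(config, combo_strict, outdir)
    if classes is not None:
        report["stages"]["netreg"] = {
            "mode": config.netreg_mode,
            "class_counts": classes["klass"].value_counts().sort_index().to_dict(),
            "major_set_coverage": (round(major_cov, 6)
                                   if major_cov is not None else None),
        }

    report_path = outdir / "run_report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("run report written to %s", report_path)
    return report
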