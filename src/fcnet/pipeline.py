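"""End-to-end orchestration: cohort -> networks -> metrics -> inference.

The analysis stage mirrors the standard resting-state workflow: per-subject
Pearson connectivity; density sweep endpoints either fixed or derived from
the data (smallest grid density with every subject connected; largest edge
fraction at which every retained edge is FDR-significant for every subject,
floored to the grid); nested binary networks over the sweep; nodal degree
and local efficiency plus global C and L (normalized against
degree-preserving rewired ensembles); trapezoidal AUC over the sweep;
group permutation tests with BH-FDR over nodes; and within-group Pearson
correlations between behavior and the network summaries of the nodes that
show group differences.

Seeds are split per stage from the root seed with a counter scheme
(``default_rng([seed, stage, unit])``) so stages can be rerun independently
and the whole run is reproducible from the config alone.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .cohort import CONTROL, TRAINED, CohortSpec, SubjectRecord, generate_cohort
from .connectivity import (
    ConnectivityMatrix,
    DensitySweep,
    build_sweep_networks,
    find_max_density_fdr,
    find_min_connected_density,
    pearson_connectivity,
)
from .metrics import (
    characteristic_path_length,
    clustering_coefficient,
    degree,
    local_efficiency,
)
from .nulls import normalized_global_metrics
from .stats import (
    behavior_correlation,
    curve_auc,
    fdr_bh,
    permutation_group_test,
    permutation_group_test_matrix,
)

logger = logging.getLogger(__name__)

NODAL_METRICS = ("degree", "local_efficiency")

__all__ = ["RunConfig", "AnalysisResult", "analyze_cohort",
           "run_simulate", "run_analyze", "run_report", "render_report"]

# stage ids for the seed counter scheme
_STAGE_NULLS = 1
_STAGE_PERM = 2


@dataclass
class RunConfig:
    """Configuration of a full run; serializable to/from YAML."""

    data_dir: str = "data"
    out_dir: str = "results"
    manifest: str | None = None
    cohort: CohortSpec = field(default_factory=CohortSpec)
    sweep_mode: str = "fixed"  # "fixed" uses d_min/d_max; "rules" derives them
    d_min: float = 0.245
    d_max: float = 0.300
    step: float = 0.005
    edge_fdr_q: float = 0.05
    ensemble_size: int = 1000
    n_perm: int = 10000
    q_fdr: float = 0.05
    behavior_alpha: float = 0.05
    ranking: str = "signed"
    efficiency_variant: str = "harmonic"
    null_model: str = "rewire"
    include_globals: bool = True  # skip C/L (and normalization) if False
    save_connectivity: bool = False  # write per-subject r matrices as TSV
    seed: int = 42

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["cohort"] = yaml.safe_load(fio.spec_to_yaml(self.cohort))
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text)
        if "cohort" in d and d["cohort"] is not None:
            d["cohort"] = CohortSpec(**d["cohort"])
        return cls(**d)

    @classmethod
    def load(cls, path: Path) -> "RunConfig":
        return cls.from_yaml(Path(path).read_text())


@dataclass
class AnalysisResult:
    sweep: DensitySweep
    auc: pd.DataFrame
    comparisons: pd.DataFrame
    behavior: pd.DataFrame
    report: dict


def _resolve_sweep(cms: list[ConnectivityMatrix], config: RunConfig) -> tuple[DensitySweep, dict]:
    info: dict = {"mode": config.sweep_mode}
    if config.sweep_mode == "fixed":
        sweep = DensitySweep(config.d_min, config.d_max, config.step)
    elif config.sweep_mode == "rules":
        d_min = find_min_connected_density(cms, config.step, config.ranking)
        frac = find_max_density_fdr(cms, config.edge_fdr_q)
        d_max = round(int(frac / config.step) * config.step, 10)
        info.update(min_connected_density=d_min, max_fdr_fraction=frac,
                    d_max_on_grid=d_max)
        if d_max < d_min:
            raise ValueError(
                f"derived endpoints are inconsistent: min-connected density "
                f"{d_min} exceeds FDR-based maximum {d_max}"
            )
        sweep = DensitySweep(d_min, d_max, config.step)
    else:
        raise ValueError("sweep_mode must be 'fixed' or 'rules'")
    info["densities"] = [float(d) for d in sweep.densities]
    return sweep, info


def _subject_curves(
    record: SubjectRecord,
    cm: ConnectivityMatrix,
    sweep: DensitySweep,
    config: RunConfig,
    subject_index: int,
) -> tuple[dict, dict]:
    """Nodal and global metric curves over the sweep for one subject."""
    nets = build_sweep_networks(cm, sweep, ranking=config.ranking)
    n_nodes = cm.n_regions
    n_d = len(sweep)
    nodal = {m: np.empty((n_d, n_nodes)) for m in NODAL_METRICS}
    glob: dict[str, np.ndarray] = {}
    if config.include_globals:
        glob = {m: np.empty(n_d) for m in ("C", "L")}
        if config.ensemble_size > 0:
            glob["C_nor"] = np.empty(n_d)
            glob["L_nor"] = np.empty(n_d)
    for di, net in enumerate(nets):
        nodal["degree"][di] = degree(net)
        nodal["local_efficiency"][di] = local_efficiency(
            net, variant=config.efficiency_variant)
        if not config.include_globals:
            continue
        _, C = clustering_coefficient(net)
        L, connected = characteristic_path_length(net)
        if not connected:
            logger.warning("subject %s disconnected at density %.3f",
                           record.subject_id, net.density)
        glob["C"][di], glob["L"][di] = C, L
        if config.ensemble_size > 0:
            rng = np.random.default_rng(
                [config.seed, _STAGE_NULLS, subject_index, di])
            c_nor, l_nor = normalized_global_metrics(
                net, ensemble_size=config.ensemble_size, rng=rng,
                null_model=config.null_model)
            glob["C_nor"][di], glob["L_nor"][di] = c_nor, l_nor
    return nodal, glob


def analyze_cohort(
    records: list[SubjectRecord],
    config: RunConfig | None = None,
) -> AnalysisResult:
    """Run the full inferential chain on an in-memory cohort."""
    config = config or RunConfig()
    if not records:
        raise ValueError("empty cohort")
    groups = [r.group for r in records]
    if set(groups) != {TRAINED, CONTROL}:
        raise ValueError(f"cohort must contain both groups {TRAINED!r}/{CONTROL!r}")

    logger.info("connectivity: %d subjects", len(records))
    cms = [pearson_connectivity(r) for r in records]
    sweep, sweep_info = _resolve_sweep(cms, config)
    logger.info("sweep: %d densities in [%.3f, %.3f]",
                len(sweep), sweep.densities[0], sweep.densities[-1])

    nodal_auc: dict[str, list] = {m: [] for m in NODAL_METRICS}
    global_auc: dict[str, list] = {}
    for si, (rec, cm) in enumerate(zip(records, cms)):
        nodal, glob = _subject_curves(rec, cm, sweep, config, si)
        for m in NODAL_METRICS:
            nodal_auc[m].append(curve_auc(nodal[m].T, sweep.densities))
        for m, vals in glob.items():
            global_auc.setdefault(m, []).append(curve_auc(vals, sweep.densities))

    n_nodes = cms[0].n_regions
    is_a = np.array([g == TRAINED for g in groups])
    scores = np.array([r.behavior_score for r in records])

    auc_rows = []
    for m in NODAL_METRICS:
        arr = np.asarray(nodal_auc[m])  # (n_subjects, n_nodes)
        for si, rec in enumerate(records):
            for node in range(n_nodes):
                auc_rows.append((rec.subject_id, rec.group, m, node, arr[si, node]))
    for m, vals in global_auc.items():
        for si, rec in enumerate(records):
            auc_rows.append((rec.subject_id, rec.group, m, "global", vals[si]))
    auc_table = pd.DataFrame(
        auc_rows, columns=["subject_id", "group", "metric", "node", "auc"])

    # group comparisons: nodal metrics each FDR-corrected over their 90 nodes,
    # global metrics corrected as their own small family
    rng_perm = np.random.default_rng([config.seed, _STAGE_PERM])
    comp_rows = []
    nodal_sig: dict[str, np.ndarray] = {}
    for m in NODAL_METRICS:
        arr = np.asarray(nodal_auc[m])
        obs, p = permutation_group_test_matrix(
            arr[is_a], arr[~is_a], n_perm=config.n_perm, rng=rng_perm)
        sig = fdr_bh(p, q=config.q_fdr)
        nodal_sig[m] = sig
        for node in range(n_nodes):
            comp_rows.append((m, node, obs[node], p[node], bool(sig[node])))
    global_p = {}
    for m, vals in global_auc.items():
        vals = np.asarray(vals)
        res = permutation_group_test(vals[is_a], vals[~is_a],
                                     n_perm=config.n_perm, rng=rng_perm,
                                     metric=m)
        global_p[m] = res
    gsig = fdr_bh([global_p[m].p_two_tailed for m in global_auc],
                  q=config.q_fdr)
    for (m, res), s in zip(global_p.items(), gsig):
        comp_rows.append((m, "global", res.observed_diff, res.p_two_tailed, bool(s)))
    comparisons = pd.DataFrame(
        comp_rows,
        columns=["metric", "node", "observed_diff", "p", "fdr_significant"])

    # behavior correlations at nodes showing group differences, per group
    behav_rows = []
    for m in NODAL_METRICS:
        arr = np.asarray(nodal_auc[m])
        for node in np.flatnonzero(nodal_sig[m]):
            for gname, mask in ((TRAINED, is_a), (CONTROL, ~is_a)):
                try:
                    r, p = behavior_correlation(arr[mask, node], scores[mask])
                except ValueError:
                    continue
                behav_rows.append(
                    (m, int(node), gname, r, p, p < config.behavior_alpha,
                     int(mask.sum())))
    behavior = pd.DataFrame(
        behav_rows,
        columns=["metric", "node", "group", "r", "p", "significant", "n"])
    if len(behavior):
        behavior["p_fdr_significant"] = False
        mask = fdr_bh(behavior["p"].to_numpy(), q=config.q_fdr)
        behavior["p_fdr_significant"] = mask

    group_summary = {
        m: {
            g: {
                "mean": float(np.asarray(global_auc[m])[is_a if g == TRAINED else ~is_a].mean()),
                "sd": float(np.asarray(global_auc[m])[is_a if g == TRAINED else ~is_a].std(ddof=1)),
            }
            for g in (TRAINED, CONTROL)
        }
        for m in global_auc
    }
    report = {
        "config": yaml.safe_load(config.to_yaml()),
        "sweep": sweep_info,
        "n_subjects": {TRAINED: int(is_a.sum()), CONTROL: int((~is_a).sum())},
        "global_auc": group_summary,
        "global_comparisons": {
            m: {"observed_diff": res.observed_diff, "p": res.p_two_tailed,
                "fdr_significant": bool(s)}
            for (m, res), s in zip(global_p.items(), gsig)
        },
        "significant_nodes": {
            m: [int(i) for i in np.flatnonzero(nodal_sig[m])]
            for m in NODAL_METRICS
        },
    }
    return AnalysisResult(sweep=sweep, auc=auc_table, comparisons=comparisons,
                          behavior=behavior, report=report)


# ---------------------------------------------------------------------------
# disk-facing commands (used by the CLI)

def run_simulate(config: RunConfig) -> Path:
    """Generate the synthetic cohort and write it under ``data_dir``."""
    records, manifest = generate_cohort(config.cohort)
    out = Path(config.data_dir)
    fio.write_cohort(records, manifest, out, spec=config.cohort)
    logger.info("wrote %d subjects to %s", len(records), out)
    return out


def run_analyze(config: RunConfig) -> AnalysisResult:
    """Load the cohort from disk, analyze, and write tables + JSON report."""
    records, _ = fio.read_cohort(Path(config.data_dir),
                                 Path(config.manifest) if config.manifest else None)
    result = analyze_cohort(records, config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.save_connectivity:
        conn_dir = out / "connectivity"
        conn_dir.mkdir(exist_ok=True)
        for rec in records:
            cm = pearson_connectivity(rec)
            np.savetxt(conn_dir / f"{rec.subject_id}_r.tsv", cm.r,
                       delimiter="\t", fmt="%.6f")
    result.auc.to_csv(out / "auc.tsv", sep="\t", index=False)
    result.comparisons.to_csv(out / "comparisons.tsv", sep="\t", index=False)
    result.behavior.to_csv(out / "behavior.tsv", sep="\t", index=False)
    fio.write_json_report(result.report, out / "report.json")
    return result


def render_report(out_dir: Path) -> str:
    """Human-readable summary of an analysis output directory."""
    import json

    out = Path(out_dir)
    if not (out / "report.json").exists():
        raise FileNotFoundError(f"no report.json in {out}; run analyze first")
    report = json.loads((out / "report.json").read_text())
    comparisons = pd.read_csv(out / "comparisons.tsv", sep="\t")
    behavior_path = out / "behavior.tsv"
    behavior = pd.read_csv(behavior_path, sep="\t") if behavior_path.exists() else pd.DataFrame()

    lines = []
    lines.append("Group comparison of network topology (AUC over density sweep)")
    lines.append(f"  subjects: {report['n_subjects']}")
    dens = report["sweep"]["densities"]
    lines.append(f"  densities: {dens[0]:.3f}..{dens[-1]:.3f} ({len(dens)} points)")
    lines.append("")
    lines.append("Global metrics, AUC mean +/- SD per group:")
    for m, per_group in report["global_auc"].items():
        comp = report["global_comparisons"][m]
        flag = "*" if comp["fdr_significant"] else ""
        lines.append(
            f"  {m:6s} trained {per_group['trained']['mean']:.3f} +/- "
            f"{per_group['trained']['sd']:.3f} | control "
            f"{per_group['control']['mean']:.3f} +/- {per_group['control']['sd']:.3f}"
            f"  (p={comp['p']:.4f}{flag})"
        )
    lines.append("")
    for m in NODAL_METRICS:
        lines.append(f"Nodes with FDR-significant group difference in {m}:")
        sub = comparisons[(comparisons.metric == m) & (comparisons.node != "global")]
        sig = sub[sub.fdr_significant].sort_values(["p", "node"])
        if len(sig) == 0:
            lines.append("  none")
        else:
            for row in sig.itertuples():
                lines.append(f"  node {row.node:>4} diff={row.observed_diff:+.4f} "
                             f"p={row.p:.4f}")
        lines.append("")
    lines.append("Brain-behavior correlations at significant nodes (per group):")
    if len(behavior) == 0:
        lines.append("  none")
    else:
        for row in behavior.itertuples():
            star = "*" if row.significant else ""
            lines.append(f"  {row.metric} node {row.node} [{row.group}] "
                         f"r={row.r:+.3f} p={row.p:.4f}{star} (n={row.n})")
    return "\n".join(lines) + "\n"


def run_report(config: RunConfig) -> str:
    text = render_report(Path(config.out_dir))
    path = Path(config.out_dir) / "summary.txt"
    path.write_text(text)
    return text
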