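"""End-to-end orchestration: simulate/load -> filter -> risk -> biclusters
-> replication -> CoRisk.

Each stage reads its inputs from, and writes its outputs to, the run's
output directory as plain-text files, so the chained stages equal one
``run_pipeline`` call and any stage can be re-run in isolation.  All
stochastic stages take explicit seeds from the config; identical config
(and seeds) gives byte-identical result files.  Wall-clock stage timings
go to the log only, keeping the result files deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import bicluster as bc
from . import corisk as cn
from . import replication as rm
from . import risk as rq
from .cohort import CohortMatrix, read_cohort, write_cohort
from .errors import ComputationError, DataValidationError
from .synthetic import Block, SynthConfig, generate_cohort, medicare_like, write_truth

log = logging.getLogger("corisk")


def _json_default(obj):
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _dump(payload, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, default=_json_default)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclasses.dataclass
class CohortSource:
    """Exactly one of a CSV path or a synthetic-cohort config."""

    path: str | None = None
    synth: SynthConfig | None = None

    def __post_init__(self) -> None:
        if (self.path is None) == (self.synth is None):
            raise DataValidationError(
                "each cohort needs exactly one of `path` or `synth`"
            )


@dataclasses.dataclass
class PipelineConfig:
    training: CohortSource
    replication: CohortSource
    alpha: float = 0.05
    prevalence_threshold: float = 0.01
    prevalence_mode: str = "individual"
    p_method: str = "fisher"
    bicluster_seed: int = 0
    bicluster_restarts: int = 20
    bicluster_max_communities: int | None = None
    modularity_permutations: int = 1000
    modularity_null: str = "density"
    ri_permutations: int = 1000
    ri_seed: int = 0
    layout_factor: float = 0.5
    layout_seed: int = 0
    write_figure: bool = False
    outdir: str = "corisk_out"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise DataValidationError("alpha must lie in (0, 1)")
        if not 0 < self.prevalence_threshold < 1:
            raise DataValidationError("prevalence_threshold must lie in (0, 1)")
        for name in ("modularity_permutations", "ri_permutations",
                     "bicluster_restarts"):
            if getattr(self, name) < 1:
                raise DataValidationError(f"{name} must be >= 1")
        if self.layout_factor < 0:
            raise DataValidationError("layout_factor must be non-negative")


def _synth_from_dict(d: dict) -> SynthConfig:
    d = dict(d)
    preset = d.pop("preset", None)
    if preset in ("medicare-like", "medicare_like"):
        return medicare_like(**d)
    if preset is not None:
        raise DataValidationError(f"unknown synth preset {preset!r}")
    if "blocks" in d:
        d["block_spec"] = [
            Block(tuple(b[0]), b[1], b[2]) for b in d.pop("blocks")
        ]
    if "pair_log_or" in d:
        names = d["comorbidity_names"]
        k = len(names)
        mat = np.zeros((k, k))
        for a, b, v in d.pop("pair_log_or"):
            i, j = names.index(a), names.index(b)
            mat[i, j] = mat[j, i] = float(v)
        d["planted_log_or"] = mat
    return SynthConfig(**d)


def load_config(path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise DataValidationError(f"{path}: config must be a mapping")

    def source(key: str) -> CohortSource:
        if key not in raw:
            raise DataValidationError(f"{path}: missing `{key}` cohort")
        sect = raw[key]
        if "path" in sect:
            return CohortSource(path=sect["path"])
        if "synth" in sect:
            return CohortSource(synth=_synth_from_dict(sect["synth"]))
        raise DataValidationError(f"{path}: `{key}` needs `path` or `synth`")

    prev = raw.get("prevalence", {})
    bic = raw.get("bicluster", {})
    ri = raw.get("ri", {})
    layout = raw.get("layout", {})
    return PipelineConfig(
        training=source("training"),
        replication=source("replication"),
        alpha=raw.get("alpha", 0.05),
        prevalence_threshold=prev.get("threshold", 0.01),
        prevalence_mode=prev.get("mode", "individual"),
        p_method=raw.get("p_method", "fisher"),
        bicluster_seed=bic.get("seed", 0),
        bicluster_restarts=bic.get("restarts", 20),
        bicluster_max_communities=bic.get("max_communities"),
        modularity_permutations=bic.get("permutations", 1000),
        modularity_null=bic.get("null", "density"),
        ri_permutations=ri.get("permutations", 1000),
        ri_seed=ri.get("seed", 0),
        layout_factor=layout.get("factor", 0.5),
        layout_seed=layout.get("seed", 0),
        write_figure=raw.get("figure", False),
        outdir=raw.get("outdir", "corisk_out"),
    )


def _stage(name: str):
    """Log entry/exit + wall time; wrap failures with the stage name."""
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except (DataValidationError, ComputationError) as exc:
                raise type(exc)(f"stage {name}: {exc}") from exc
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return out
        wrapper.__name__ = fn.__name__
        return wrapper
    return deco


@_stage("simulate")
def stage_simulate(config: PipelineConfig) -> None:
    """Materialize synthetic cohorts (no-op for path-backed cohorts)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    for label, src in (("train", config.training),
                       ("replication", config.replication)):
        if src.synth is None:
            continue
        cohort, truth = generate_cohort(src.synth)
        write_cohort(cohort, out / f"{label}.csv")
        write_truth(truth, out / f"{label}_truth.json")
        log.info("simulated %s cohort: %d cases, %d controls, %d comorbidities",
                 label, cohort.n_cases, cohort.n_controls,
                 cohort.n_comorbidities)


def _load(config: PipelineConfig, label: str) -> CohortMatrix:
    src = config.training if label == "train" else config.replication
    path = src.path if src.path else Path(config.outdir) / f"{label}.csv"
    if not Path(path).exists():
        raise DataValidationError(
            f"cohort file {path} not found (run the simulate stage first?)"
        )
    return read_cohort(path)


def _filter(config: PipelineConfig, cohort: CohortMatrix, label: str):
    n0 = cohort.n_patients
    cohort = rq.filter_zero_comorbidity_patients(cohort)
    n1 = cohort.n_patients
    cohort, removed = rq.filter_low_prevalence(
        cohort, config.prevalence_threshold, config.prevalence_mode
    )
    log.info(
        "%s cohort filters: %d patients -> %d (zero-comorbidity removed) "
        "-> %d (after dropping %d low-prevalence comorbidities)",
        label, n0, n1, cohort.n_patients, len(removed),
    )
    return cohort, {"initial": n0, "after_zero_filter": n1,
                    "after_prevalence_filter": cohort.n_patients,
                    "comorbidities_removed": removed}


@_stage("risk")
def stage_risk(config: PipelineConfig) -> dict:
    """Filters + pairwise overall/directionality tests + replication."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results = {}
    accounting = {}
    for label in ("train", "replication"):
        cohort, counts = _filter(config, _load(config, label), label)
        accounting[label] = counts
        write_cohort(cohort, out / f"{label}_filtered.csv")
        pairs = rq.pairwise_overall_test(cohort, config.alpha, config.p_method)
        sig = [p for p in pairs if p.significant_overall]
        rq.pairwise_directionality_test(cohort, sig, config.alpha,
                                        config.p_method)
        results[label] = pairs
        log.info("%s: %d/%d pairs significant overall", label, len(sig),
                 len(pairs))
    replicated = rq.replicate_pairs(results["train"], results["replication"])
    log.info("replicated pairs: %d (%d unique comorbidities)",
             len(replicated.pairs), len(replicated.unique_comorbidities))
    for label in ("train", "replication"):
        table = rq.results_to_table(results[label], replicated)
        table.to_csv(out / f"risk_{label}.tsv", sep="\t", index=False)
    payload = {
        "pairs": [
            {
                "a": a, "b": b,
                "pattern": tr.direction_pattern,
                "or_overall_train": tr.overall.or_point,
                "or_overall_replication": re.overall.or_point,
            }
            for a, b, tr, re in replicated.pairs
        ],
        "unique_comorbidities": sorted(replicated.unique_comorbidities),
        "filter_accounting": accounting,
    }
    _dump(payload, out / "replicated_pairs.json")
    return payload


def _load_replicated(outdir) -> rq.ReplicatedPairSet:
    path = Path(outdir) / "replicated_pairs.json"
    if not path.exists():
        raise DataValidationError(f"{path} not found (run the risk stage first?)")
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    pairs = []
    for rec in payload["pairs"]:
        tr = rq.PairRiskResult(
            rec["a"], rec["b"],
            rq.OrResult(rec["or_overall_train"], float("nan"), float("nan"),
                        float("nan")),
            significant_overall=True, direction_pattern=rec["pattern"],
        )
        re = rq.PairRiskResult(
            rec["a"], rec["b"],
            rq.OrResult(rec["or_overall_replication"], float("nan"),
                        float("nan"), float("nan")),
            significant_overall=True, direction_pattern=rec["pattern"],
        )
        pairs.append((rec["a"], rec["b"], tr, re))
    return rq.ReplicatedPairSet(pairs, set(payload["unique_comorbidities"]))


@_stage("bicluster")
def stage_bicluster(config: PipelineConfig) -> dict:
    """Bipartite networks over the replicated comorbidities + biclusters."""
    out = Path(config.outdir)
    replicated = _load_replicated(out)
    if not replicated.unique_comorbidities:
        raise ComputationError("no replicated comorbidities to bicluster")
    comorbs = sorted(replicated.unique_comorbidities)
    summary = {}
    for label in ("train", "replication"):
        cohort = read_cohort(out / f"{label}_filtered.csv")
        graph = bc.build_bipartite(cohort, comorbs, cases_only=True)
        partition = bc.find_biclusters(
            graph, seed=config.bicluster_seed,
            restarts=config.bicluster_restarts,
            max_communities=config.bicluster_max_communities,
        )
        sig = bc.modularity_significance(
            graph, partition.q, config.modularity_permutations,
            seed=config.bicluster_seed, restarts=config.bicluster_restarts,
            max_communities=config.bicluster_max_communities,
            null=config.modularity_null,
        )
        bc.write_edgelist(graph, out / f"edgelist_{label}.tsv")
        bc.write_partition(partition, out / f"partition_{label}.tsv")
        n_biclusters = len({
            partition.community_of[c] for c in graph.comorbidity_nodes
        })
        rec = {
            "n_patient_nodes": len(graph.patient_nodes),
            "n_comorbidity_nodes": len(graph.comorbidity_nodes),
            "m": graph.m,
            "n_communities": partition.n_communities,
            "n_biclusters": n_biclusters,
            "q": partition.q,
            "modularity": dataclasses.asdict(sig),
        }
        _dump(rec, out / f"modularity_{label}.json")
        log.info("%s network: %d patients, Q=%.3f (random %.3f [%.3f], p=%.4g)",
                 label, len(graph.patient_nodes), partition.q,
                 sig.random_mean, sig.random_sd, sig.p_value)
        summary[label] = rec
    return summary


@_stage("replicate")
def stage_replicate(config: PipelineConfig) -> dict:
    """Rand index of comorbidity-node partitions between the two years."""
    out = Path(config.outdir)
    replicated = _load_replicated(out)
    comorbs = sorted(replicated.unique_comorbidities)
    parts = []
    for label in ("train", "replication"):
        path = out / f"partition_{label}.tsv"
        if not path.exists():
            raise DataValidationError(
                f"{path} not found (run the bicluster stage first?)")
        full = bc.read_partition(path)
        parts.append({c: full[c] for c in comorbs})
    res = rm.ri_significance(
        parts[0], parts[1], config.ri_permutations, seed=config.ri_seed
    )
    rec = dataclasses.asdict(res)
    rec["adjusted_rand_index"] = rm.adjusted_rand_index(parts[0], parts[1])
    _dump(rec, out / "ri.json")
    log.info("comorbidity co-occurrence RI=%.3f (random %.3f [%.3f], p=%.4g)",
             res.ri, res.random_mean, res.random_sd, res.p_value)
    return rec


@_stage("corisk")
def stage_corisk(config: PipelineConfig) -> dict:
    """Merge risk arrows onto the training network; classify, test, layout."""
    out = Path(config.outdir)
    replicated = _load_replicated(out)
    comorbs = sorted(replicated.unique_comorbidities)
    cohort = read_cohort(out / "train_filtered.csv")
    graph = bc.build_bipartite(cohort, comorbs, cases_only=True)
    partition_map = bc.read_partition(out / "partition_train.tsv")
    partition = bc.BiclusterPartition(
        partition_map, len(set(partition_map.values())),
        bc.barber_modularity(graph, partition_map),
    )
    single = rq.single_comorbidity_or(cohort.subset_comorbidities(comorbs),
                                      config.alpha)
    net = cn.build_corisk(graph, partition, replicated, single)
    _, counts = cn.classify_inner_outer(net)
    het = cn.heterogeneity_chi_square(counts)
    cn.inner_outer_table(counts).to_csv(out / "inner_outer.tsv", sep="\t")
    _dump({
        "chi2": het.chi2, "df": het.df, "p_value": het.p_value,
        "n": het.n, "counts": het.counts.tolist(),
    }, out / "heterogeneity.json")
    hubs = cn.detect_asymmetric_hubs(net)
    net.coordinates = cn.explode_layout(net, config.layout_factor,
                                        config.layout_seed)
    cn.export_network(net, "graphml", out / "corisk.graphml")
    cn.export_network(net, "json", out / "corisk.json")
    if config.write_figure:
        cn.plot_network(net, out / "corisk.svg")
    log.info("CoRisk: %d risk arrows, chi2(%d)=%.1f p=%.3g, hubs=%s",
             len(net.risk_edges), het.df, het.chi2, het.p_value,
             [h[0] for h in hubs])
    return {
        "n_risk_edges": len(net.risk_edges),
        "asymmetric_hubs": [list(h) for h in hubs],
        "heterogeneity": {"chi2": het.chi2, "df": het.df,
                          "p_value": het.p_value, "n": het.n},
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in order and write ``report.json``.

    The report echoes the parameters and seeds, the filter-step patient
    accounting, and every stage's headline numbers.  It is deterministic
    for a fixed config; timings appear only in the log.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage_simulate(config)
    risk = stage_risk(config)
    report: dict = {
        "parameters": {
            "alpha": config.alpha,
            "prevalence_threshold": config.prevalence_threshold,
            "prevalence_mode": config.prevalence_mode,
            "p_method": config.p_method,
            "bicluster_seed": config.bicluster_seed,
            "bicluster_restarts": config.bicluster_restarts,
            "modularity_permutations": config.modularity_permutations,
            "modularity_null": config.modularity_null,
            "ri_permutations": config.ri_permutations,
            "ri_seed": config.ri_seed,
            "layout_factor": config.layout_factor,
            "layout_seed": config.layout_seed,
        },
        "filter_accounting": risk["filter_accounting"],
        "replicated_pairs": risk["pairs"],
        "unique_comorbidities": risk["unique_comorbidities"],
    }
    if risk["unique_comorbidities"]:
        report["bicluster"] = stage_bicluster(config)
        report["rand_index"] = stage_replicate(config)
        report["corisk"] = stage_corisk(config)
    else:
        log.warning("no replicated pairs: skipping network stages")
        report["bicluster"] = None
    _dump(report, out / "report.json")
    return report
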