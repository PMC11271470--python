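"""End-to-end orchestration of the analysis stages.

``run_pipeline`` sequences: cohort simulation (or loading user tables) ->
relative abundances -> alpha/beta diversity with group tests -> JSD + PAM
enterotyping with CH-index k selection, driver and signature taxa ->
per-age enterotype proportions and Markov transition model -> per-cluster
co-occurrence networks with robustness curves -> microbiota age
regression.  Every intermediate table is written as TSV into the output
directory and listed, with the global seed and a parameter hash, in
``manifest.yaml``; re-running with the same configuration reproduces all
files byte for byte.

The single global seed fans out to per-stage child seeds derived from the
stage name, so stages can be re-run in isolation without disturbing each
other's random streams.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from enterodyn import agemodel as am
from enterodyn import diversity as dv
from enterodyn import dynamics as dyn
from enterodyn import enterotype as et
from enterodyn import io as eio
from enterodyn import network as nw
from enterodyn import synth
from enterodyn.io import logger

ALL_STAGES = ("simulate", "diversity", "enterotype", "dynamics", "network", "agemodel")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class PipelineConfig:
    """Everything needed to run the pipeline reproducibly."""

    outdir: str = "enterodyn_out"
    seed: int = 1
    counts_path: str | None = None
    metadata_path: str | None = None
    # synthetic cohort (used when counts_path is None)
    n_subjects: int = 400
    n_taxa: int = 50
    dominance: float = 0.45
    concentration: float = 150.0
    schedule: tuple = synth.DEFAULT_SCHEDULE
    phenotype_effect: float = 5.0
    # table filtering
    min_prevalence: float = 0.0
    min_mean_abund: float = 0.0
    # diversity
    n_perm: int = 999
    # enterotype
    pseudocount: float = 1e-6
    k_min: int = 2
    k_max: int = 10
    # dynamics
    smoothing: float = 0.0
    n_boot: int = 0  # 0 = skip bootstrap CIs
    # network
    r_thresh: float = 0.5
    p_thresh: float = 0.05
    net_min_prevalence: float = 0.2
    removal_reps: int = 100
    # agemodel
    ntree: int = 1000
    mtry: int | None = None
    n_perm_reps: int = 5
    importance_top_n: int = 20

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        if "schedule" in raw:
            raw["schedule"] = tuple(raw["schedule"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["schedule"] = list(self.schedule)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def param_hash(self) -> str:
        data = asdict(self)
        data["schedule"] = list(self.schedule)
        return hashlib.sha256(
            json.dumps(data, sort_keys=True).encode()
        ).hexdigest()[:16]


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage child seed (stage-name CRC folded into the seed)."""
    return (int(global_seed) * 2654435761
            + zlib.crc32(stage.encode())) % (2**31 - 1)


def _write(frame: pd.DataFrame, path: Path, manifest: dict, index_label=None) -> None:
    frame.to_csv(path, sep="\t", index_label=index_label,
                 index=index_label is not None, float_format="%.10g")
    manifest["files"][path.name] = hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _load_inputs(cfg: PipelineConfig, out: Path, manifest: dict):
    if cfg.counts_path is not None:
        counts = eio.read_count_table(cfg.counts_path)
        if cfg.metadata_path is None:
            raise PipelineError("simulate: metadata_path required with counts_path")
        meta = eio.read_metadata(cfg.metadata_path)
        eio.check_metadata_covers(counts, meta)
        for col in ("subject", "age"):
            if col not in meta.columns:
                raise PipelineError(f"simulate: metadata missing column {col!r}")
        return counts, meta, None
    ccfg = synth.CohortConfig(
        n_subjects=cfg.n_subjects,
        schedule=tuple(cfg.schedule),
        phenotype_effect=cfg.phenotype_effect,
        seed=stage_seed(cfg.seed, "simulate"),
    )
    counts, meta, traj, pheno, _profiles = synth.simulate_cohort(
        ccfg, G=cfg.n_taxa, dominance=cfg.dominance,
        concentration=cfg.concentration,
    )
    eio.write_count_table(counts, out / "counts.tsv")
    manifest["files"]["counts.tsv"] = hashlib.sha256(
        (out / "counts.tsv").read_bytes()
    ).hexdigest()[:16]
    _write(meta, out / "metadata.tsv", manifest, index_label="sample")
    _write(traj.to_frame(), out / "true_trajectories.tsv", manifest)
    _write(pheno, out / "phenotypes.tsv", manifest, index_label="subject")
    return counts, meta, pheno


def _trajectories_from_labels(meta: pd.DataFrame, labels: pd.Series) -> synth.TrajectorySet:
    """Assemble per-subject ordered state sequences from sample metadata."""
    schedule = tuple(sorted(meta["age"].unique()))
    subjects = tuple(pd.unique(meta["subject"]))
    pos = {a: t for t, a in enumerate(schedule)}
    states = np.full((len(subjects), len(schedule)), synth.MISSING, dtype=int)
    sub_idx = {s: i for i, s in enumerate(subjects)}
    for sample, row in meta.iterrows():
        states[sub_idx[row["subject"]], pos[row["age"]]] = int(labels[sample])
    return synth.TrajectorySet(subjects=subjects, states=states, schedule=schedule)


def run_pipeline(cfg: PipelineConfig, stages=ALL_STAGES) -> dict:
    """Run the selected stages in canonical order; return the result bundle.

    Outputs land in ``cfg.outdir``.  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": cfg.seed,
        "param_hash": cfg.param_hash(),
        "stages": list(stages),
        "stage_seeds": {s: stage_seed(cfg.seed, s) for s in ALL_STAGES},
        "files": {},
    }
    bundle: dict = {}

    try:
        counts, meta, pheno = _load_inputs(cfg, out, manifest)
    except (eio.TableFormatError, synth.ConfigurationError, OSError) as exc:
        raise PipelineError(f"simulate: {exc}") from exc
    bundle["counts"], bundle["metadata"] = counts, meta
    rel = eio.to_relative(counts, cfg.min_prevalence, cfg.min_mean_abund)
    bundle["relative"] = rel
    _write(rel, out / "relative_abundance.tsv", manifest, index_label="taxon")
    ages = meta.loc[counts.columns, "age"].to_numpy()

    if "diversity" in stages:
        try:
            alpha = dv.alpha_diversity_table(counts)
            _write(alpha, out / "alpha_diversity.tsv", manifest, index_label="sample")
            seed = stage_seed(cfg.seed, "diversity")
            tests = {
                "kruskal_chao1_by_age": dv.kruskal_dunn(alpha["chao1"], ages),
                "kruskal_shannon_by_age": dv.kruskal_dunn(alpha["shannon"], ages),
            }
            bc = dv.bray_curtis(rel)
            eio.write_distance_matrix(bc.data, list(rel.columns),
                                      out / "bray_curtis.tsv")
            manifest["files"]["bray_curtis.tsv"] = hashlib.sha256(
                (out / "bray_curtis.tsv").read_bytes()
            ).hexdigest()[:16]
            tests["anosim_age"] = dv.anosim(bc, ages, n_perm=cfg.n_perm, seed=seed)
            _write(dv.results_to_frame(tests), out / "diversity_tests.tsv", manifest)
            if pheno is not None:
                tests["anova_bw_by_group"] = dv.one_way_anova(
                    pheno["bw_final"], pheno["group"]
                )
                _write(dv.results_to_frame(tests), out / "diversity_tests.tsv",
                       manifest)
            bundle["alpha"], bundle["beta"], bundle["diversity_tests"] = alpha, bc, tests
        except Exception as exc:
            raise PipelineError(f"diversity: {exc}") from exc

    if any(s in stages for s in ("enterotype", "dynamics", "network")):
        try:
            jsd = et.jsd_distance(rel, pseudocount=cfg.pseudocount)
            scan = et.select_k(jsd, cfg.k_min, cfg.k_max)
            best = scan.results[scan.best_k]
            labels = pd.Series(best.labels, index=rel.columns, name="cluster")
            bundle["jsd"], bundle["optimal_k"], bundle["clusters"] = jsd, scan, labels
            _write(
                pd.DataFrame({"k": scan.k_range, "ch_index": scan.ch_scores}),
                out / "ch_curve.tsv", manifest,
            )
            assign = labels.to_frame()
            assign["is_medoid"] = assign.index.isin(best.medoids)
            _write(assign, out / "cluster_assignments.tsv", manifest,
                   index_label="sample")
            drivers = et.driver_taxa(rel, best.labels, top_n=5)
            drv = pd.concat(
                [f.assign(cluster=c) for c, f in drivers.items()], ignore_index=True
            )
            _write(drv[["cluster", "taxon", "mean_abundance"]],
                   out / "driver_taxa.tsv", manifest)
            sigs = et.signature_taxa(rel, best.labels)
            _write(sigs, out / "signature_taxa.tsv", manifest)
            bundle["drivers"], bundle["signatures"] = drivers, sigs
            logger.info("enterotype: best k = %d (CH curve in ch_curve.tsv)",
                        scan.best_k)
        except Exception as exc:
            raise PipelineError(f"enterotype: {exc}") from exc

    if "dynamics" in stages:
        try:
            labels = bundle["clusters"]
            traj = _trajectories_from_labels(meta, labels)
            prop = (
                pd.crosstab(meta["age"], labels, normalize="index")
                .rename_axis(columns="cluster")
            )
            _write(prop, out / "cluster_proportions_by_age.tsv", manifest,
                   index_label="age")
            tc = dyn.count_transitions(traj)
            model = dyn.estimate_markov(tc, smoothing=cfg.smoothing)
            if cfg.n_boot >= 100:
                model.ci = dyn.bootstrap_ci(
                    traj, n_boot=cfg.n_boot, seed=stage_seed(cfg.seed, "dynamics")
                )
            _write(model.to_edge_frame(), out / "transition_edges.tsv", manifest)
            _write(
                pd.DataFrame(tc.N,
                             index=[f"from_{i+1}" for i in range(tc.K)],
                             columns=[f"to_{j+1}" for j in range(tc.K)]),
                out / "transition_counts.tsv", manifest, index_label="state",
            )
            bundle["trajectories"], bundle["transition_model"] = traj, model
        except Exception as exc:
            raise PipelineError(f"dynamics: {exc}") from exc

    if "network" in stages:
        try:
            labels = bundle["clusters"]
            nets = nw.cluster_networks(
                rel, labels.to_numpy(), min_prevalence=cfg.net_min_prevalence,
                r_thresh=cfg.r_thresh, p_thresh=cfg.p_thresh,
            )
            seed = stage_seed(cfg.seed, "network")
            summary_rows = []
            for c, net in nets.items():
                _write(net.edges, out / f"network_edges_cluster{c}.tsv", manifest)
                curve = nw.robustness_curve(
                    net, strategy="random", n_reps=cfg.removal_reps, seed=seed
                )
                _write(curve.to_frame(), out / f"network_robustness_cluster{c}.tsv",
                       manifest)
                _, summ = nw.degree_stats(net)
                summ.update(cluster=c, robustness_auc=curve.auc,
                            natural_connectivity=nw.natural_connectivity(net))
                summary_rows.append(summ)
            if summary_rows:
                _write(pd.DataFrame(summary_rows), out / "network_summary.tsv",
                       manifest)
            bundle["networks"] = nets
        except Exception as exc:
            raise PipelineError(f"network: {exc}") from exc

    if "agemodel" in stages:
        try:
            model = am.fit_age_model(
                rel, ages, ntree=cfg.ntree, mtry=cfg.mtry,
                seed=stage_seed(cfg.seed, "agemodel"),
            )
            mae, r2 = am.evaluate(model)
            imp = am.importance(
                model, n_perm_reps=cfg.n_perm_reps,
                seed=stage_seed(cfg.seed, "agemodel") + 1,
                top_n=cfg.importance_top_n,
            )
            _write(imp, out / "age_importance.tsv", manifest)
            _write(am.predictions_frame(model), out / "age_predictions.tsv", manifest)
            _write(
                pd.DataFrame([{"oob_mae_days": mae, "oob_r_squared": r2,
                               "ntree": model.params["ntree"]}]),
                out / "age_model_metrics.tsv", manifest,
            )
            bundle["age_model"], bundle["age_metrics"] = model, (mae, r2)
            logger.info("agemodel: OOB MAE = %.2f days, R^2 = %.4f", mae, r2)
        except Exception as exc:
            raise PipelineError(f"agemodel: {exc}") from exc

    cfg.to_yaml(out / "config.yaml")
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    bundle["manifest"] = manifest
    return bundle
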