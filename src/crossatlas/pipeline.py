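"""End-to-end orchestration: simulate or ingest, filter, compare, score.

``run_pipeline`` executes the enabled stages in dependency order --
simulate/ingest -> detection -> concordance -> entropy -> paralogs ->
networks -> expression conservation -- writing each artifact with a JSON
metadata sidecar and aggregating every summary statistic into a single
machine-readable report.  Stage outputs are pure functions of (inputs,
parameters, seed), so a rerun with the same config reproduces the report.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import concordance as conc
from . import conservation as cons
from . import network as net
from . import specificity as spec
from .detection import (detect_expressed_microarray, detect_expressed_rnaseq,
                        write_detection_table, DEFAULT_BINS)
from .matrix import (ExpressionMatrix, align_common_genes, collapse_replicates,
                     read_expression_table)
from .synthetic import SyntheticConfig, write_synthetic_dataset
from .transforms import platform_transform


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is recorded."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


ALL_STAGES = ("detection", "concordance", "entropy", "paralogs",
              "network", "ec")


@dataclass
class RunConfig:
    """Single-file configuration for a full run."""

    outdir: str = "atlas_run"
    seed: int = 0
    # input tables; when absent, `synthetic` must be set
    rnaseq_path: str | None = None
    microarray_path: str | None = None
    paralog_path: str | None = None
    synthetic: dict | None = None
    # thresholds (defaults mirror the analysis conventions)
    ma_threshold: float = 200.0
    ma_strict: bool = True
    fpkm_bins: tuple = DEFAULT_BINS
    fpkm_min: float = 5.0
    ci_level: float = 0.95
    alpha: float = 0.01
    tau: float = 2.0
    boot_reps: int = 1000
    pca_k: int = 1000
    stages: dict = field(default_factory=lambda: {s: True for s in ALL_STAGES})

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})
        for k, v in cfg.stages.items():
            if k not in ALL_STAGES:
                raise ValueError(f"unknown stage {k!r}")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def enabled(self, stage: str) -> bool:
        return self.stages.get(stage, True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _sidecar(path: Path, meta: dict) -> None:
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, default=str))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and return (and write) the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "warnings": [], "stages_run": [],
                    "parameters": {
                        "ma_threshold": config.ma_threshold,
                        "fpkm_bins": list(config.fpkm_bins),
                        "fpkm_min": config.fpkm_min,
                        "ci_level": config.ci_level,
                        "alpha": config.alpha,
                        "tau": config.tau,
                        "boot_reps": config.boot_reps,
                    }}

    def fail(stage: str, exc: BaseException):
        (outdir / f"FAILED_{stage}").write_text(str(exc))
        raise StageError(stage, exc)

    # -- ingest / simulate -------------------------------------------------
    try:
        if config.synthetic is not None:
            syn = dict(config.synthetic)
            syn.setdefault("seed", config.seed)
            syn_cfg = SyntheticConfig(**{
                k: (tuple(tuple(g) for g in v) if k == "tissue_groups" else v)
                for k, v in syn.items()})
            paths = write_synthetic_dataset(syn_cfg, outdir / "inputs")
            rnaseq_path = Path(paths["rnaseq"])
            microarray_path = Path(paths["microarray"])
            paralog_path = Path(paths["paralogs"])
        else:
            if not config.rnaseq_path or not config.microarray_path:
                raise ValueError("need rnaseq_path and microarray_path, "
                                 "or a synthetic block")
            rnaseq_path = Path(config.rnaseq_path)
            microarray_path = Path(config.microarray_path)
            paralog_path = Path(config.paralog_path) if config.paralog_path else None
        rnaseq = read_expression_table(rnaseq_path, "rnaseq")
        microarray = read_expression_table(microarray_path, "microarray")
        report["inputs"] = {
            "rnaseq": {"path": str(rnaseq_path), "sha256": _sha256(rnaseq_path),
                       "n_genes": rnaseq.n_genes, "n_tissues": rnaseq.n_tissues},
            "microarray": {"path": str(microarray_path),
                           "sha256": _sha256(microarray_path),
                           "n_genes": microarray.n_genes,
                           "n_tissues": microarray.n_tissues},
        }
    except StageError:
        raise
    except Exception as exc:
        fail("ingest", exc)

    rnaseq_mean = collapse_replicates(rnaseq) if rnaseq.has_replicates else rnaseq
    ma_mean = collapse_replicates(microarray) if microarray.has_replicates \
        else microarray

    det_rna = det_ma = None
    if config.enabled("detection"):
        try:
            det_rna = detect_expressed_rnaseq(rnaseq, confidence=config.ci_level,
                                              bins=config.fpkm_bins)
            det_ma = detect_expressed_microarray(ma_mean,
                                                 threshold=config.ma_threshold,
                                                 strict=config.ma_strict,
                                                 bins=config.fpkm_bins)
            for name, det in (("rnaseq", det_rna), ("microarray", det_ma)):
                p = outdir / f"detection_{name}.tsv"
                write_detection_table(det, p)
                _sidecar(p, {"criterion": det.criterion, "seed": config.seed})
            report["detection"] = {
                "rnaseq_expressed": int(det_rna.expressed.sum()),
                "rnaseq_fraction": float(det_rna.expressed.mean()),
                "microarray_expressed": int(det_ma.expressed.sum()),
                "microarray_fraction": float(det_ma.expressed.mean()),
            }
            report["stages_run"].append("detection")
        except Exception as exc:
            fail("detection", exc)

    if config.enabled("concordance"):
        try:
            rep_qc = conc.replicate_correlations(rnaseq)
            modes = {"all_common": None}
            if det_rna is not None and det_ma is not None:
                modes["expressed_both"] = (det_rna, det_ma)
            per_mode = {}
            for mode, dets in modes.items():
                a, b = align_common_genes(rnaseq_mean, ma_mean, mode=mode,
                                          detections=dets)
                rr = conc.cross_platform_correlations(a, b)
                per_mode[mode] = {
                    "per_tissue_r": rr.per_tissue_r.round(6).to_dict(),
                    "mean_r": rr.mean_r, "sd_r": rr.sd_r,
                    "n_genes": a.n_genes,
                }
            from .transforms import transform_log2_floor
            dend = conc.cluster_tissues(transform_log2_floor(rnaseq_mean))
            (outdir / "tissue_dendrogram.nwk").write_text(dend.to_newick())
            ord_ = conc.pca_tissues(transform_log2_floor(rnaseq_mean),
                                    k=min(config.pca_k, rnaseq_mean.n_genes),
                                    seed=config.seed)
            ord_.coordinates.to_csv(outdir / "pca_tissues.tsv", sep="\t")
            top = conc.top_expressed_genes(rnaseq_mean, n=10)
            top.to_csv(outdir / "top_genes.tsv", sep="\t", index=False)
            report["concordance"] = {
                "replicate_mean_r": rep_qc.mean_r,
                "replicate_sd_r": rep_qc.sd_r,
                "replicate_fraction_above": rep_qc.fraction_above,
                "cross_platform": per_mode,
                "pca_explained_variance": [round(float(v), 6) for v in
                                           ord_.explained_variance_ratio[:5]],
            }
            report["stages_run"].append("concordance")
        except StageError:
            raise
        except Exception as exc:
            fail("concordance", exc)

    if config.enabled("entropy"):
        try:
            ent_rna = spec.expression_entropy(rnaseq_mean, detection=det_rna)
            ent_ma = spec.expression_entropy(ma_mean, detection=det_ma)
            cmp_ = spec.compare_entropy_distributions(ent_rna, ent_ma)
            report["entropy"] = {
                "rnaseq_median": cmp_.median_a, "microarray_median": cmp_.median_b,
                "mannwhitney_p": cmp_.p_value, "more_specific": cmp_.more_specific,
                "n_rnaseq": cmp_.n_a, "n_microarray": cmp_.n_b,
            }
            report["stages_run"].append("entropy")
        except Exception as exc:
            fail("entropy", exc)

    if config.enabled("paralogs") and paralog_path is not None:
        try:
            pairs = spec.read_paralog_pairs(paralog_path)
            out = {}
            for name, mat in (("rnaseq", rnaseq_mean), ("microarray", ma_mean)):
                t = platform_transform(mat)
                rep = spec.paralog_analysis(t, pairs, seed=config.seed)
                out[name] = {"n_pairs": len(rep.pair_r),
                             "fraction_high": rep.fraction_high,
                             "null_mean": rep.null_mean, "null_sd": rep.null_sd}
            report["paralogs"] = out
            report["stages_run"].append("paralogs")
        except Exception as exc:
            fail("paralogs", exc)

    tA = tB = None
    if config.enabled("network") or config.enabled("ec"):
        try:
            a, b = align_common_genes(ma_mean, rnaseq_mean)
            ta, tb = platform_transform(a), platform_transform(b)
            ta, dropped_a = net.remove_constant_genes(ta)
            tb, dropped_b = net.remove_constant_genes(tb)
            keep = [g for g in ta.gene_ids if g in set(tb.gene_ids)]
            tA, tB = ta.subset_genes(keep), tb.subset_genes(keep)
            report["network_genes"] = {"n_used": len(keep),
                                       "dropped_constant": sorted(
                                           set(dropped_a) | set(dropped_b))}
        except Exception as exc:
            fail("network", exc)

    if config.enabled("network"):
        try:
            na = net.fisher_normalize(net.build_network(tA))
            nb = net.fisher_normalize(net.build_network(tB))
            similarity = net.network_similarity(na, nb)
            boot = net.mixed_bootstrap(tA, tB, B=config.boot_reps,
                                       seed=config.seed)
            kept, removed = net.stringent_expression_filter(
                rnaseq_mean.subset_genes(list(tA.gene_ids)),
                cutoff=config.fpkm_min)
            report["network"] = {
                "similarity": similarity,
                "bootstrap_observed": boot.observed_similarity,
                "bootstrap_percentile": boot.percentile_of_observed,
                "bootstrap_null_mean": float(boot.null_similarities.mean()),
                "stringent_filter_removed": len(removed),
            }
            report["stages_run"].append("network")
        except StageError:
            raise
        except Exception as exc:
            fail("network", exc)

    if config.enabled("ec"):
        try:
            if config.boot_reps < 100 or 1.0 / (config.boot_reps + 1) > config.alpha:
                report["warnings"].append(
                    f"boot_reps={config.boot_reps}: p-value resolution "
                    f"{1 / (config.boot_reps + 1):.3g} is coarse relative to "
                    f"alpha={config.alpha}")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ec = cons.ec_significance(tA, tB, B=config.boot_reps,
                                          seed=config.seed, alpha=config.alpha,
                                          tau=config.tau)
            classes, summary = cons.classify_divergent(
                ec, expr_a=ma_mean.subset_genes(list(tA.gene_ids)),
                expr_b=rnaseq_mean.subset_genes(list(tA.gene_ids)))
            p = outdir / "ec_scores.tsv"
            ec.to_frame().to_csv(p, sep="\t")
            _sidecar(p, {"B": config.boot_reps, "seed": config.seed,
                         "alpha": config.alpha, "tau": config.tau})
            report["ec"] = {
                "n_flagged": len(ec.flagged),
                "fraction_conserved": 1.0 - len(ec.flagged) / len(ec.per_gene_ec),
                "class_counts": summary["counts"],
                "n_saturated_cluster": len(summary["saturated_cluster"]),
                "n_low_expression_cluster": len(summary["low_expression_cluster"]),
            }
            report["stages_run"].append("ec")
        except StageError:
            raise
        except Exception as exc:
            fail("ec", exc)

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
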