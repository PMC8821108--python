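"""End-to-end orchestration of the pattern-discovery analysis.

Stages, in order (each writes its outputs as TSV under the output
directory and registers them in ``manifest.json``):

1.  preprocess        expression load, optional FPKM->TPM + log2, optional
                      batch adjustment
2.  consensus         consensus clustering of samples on the regulator panel
3.  de                one-vs-rest moderated DE between the patterns
4.  degs              fold-change / adjusted-p DEG selection
5.  prognostic        univariate-Cox screen of the DEGs
6.  gene_cluster      consensus clustering of the prognostic DEGs (genes as
                      items, samples as features)
7.  hascore           PCA signature score of every sample
8.  cutpoint          maximally-selected rank-statistic dichotomization
                      (within each batch when batch labels exist, groups
                      pooled afterwards)
9.  survival          KM curves, log-rank, univariate + multivariate Cox
10. enrichment        ssGSEA scores and per-pattern Kruskal-Wallis tests,
                      plus the EMT score when marker sets are provided
11. associations      drug-AUC correlation screen and categorical clinical
                      feature tests

One master seed deterministically derives one sub-seed per stage through
``numpy.random.SeedSequence([master_seed, stage_index])``, so any stage can
be rerun in isolation; a rerun with the same config and seed is
byte-identical.  Optional inputs (gene sets, drug table) only skip their
own stage.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import kruskal

from . import __version__
from .association import categorical_association, drug_correlation
from .consensus import ConsensusClustering
from .differential import moderated_de, select_degs
from .enrichment import ssgsea_table
from .io import (batch_adjust, fpkm_to_tpm, log2_transform, read_clinical,
                 read_expression, read_gmt, write_matrix)
from .scoring import emt_score, hascore, prognostic_screen
from .simulate import DrugResponseTable
from .survival import best_cutpoint, cox_fit, km_curve, logrank_test

logger = logging.getLogger("hapattern")

__all__ = ["PipelineConfig", "run_pipeline"]

_STAGES = ("preprocess", "consensus", "de", "degs", "prognostic",
           "gene_cluster", "hascore", "cutpoint", "survival", "enrichment",
           "associations")


@dataclass
class PipelineConfig:
    """Paths and parameters for :func:`run_pipeline`.

    ``expression`` / ``clinical`` / ``panel`` are required; ``gene_sets``
    (GMT), ``emt_gene_sets`` (GMT with sets named MESENCHYMAL and
    EPITHELIAL), ``drugs`` (sample x drug AUC TSV) and ``drug_annotation``
    (drug -> pathway TSV) are optional.
    """

    expression: str
    clinical: str
    panel: str
    gene_sets: str | None = None
    emt_gene_sets: str | None = None
    drugs: str | None = None
    drug_annotation: str | None = None
    expression_scale: str = "log2tpm"   # or "fpkm" (converted + logged)
    k_min: int = 2
    k_max: int = 6
    reps: int = 1000
    subsample_frac: float = 0.8
    fc_thresh: float = 1.5
    adjp_thresh: float = 0.001
    prognostic_p: float = 0.05
    ssgsea_alpha: float = 0.25
    minprop: float = 0.1
    rs_thresh: float = 0.3
    fdr_thresh: float = 0.05
    covariates: tuple[str, ...] = ()
    gene_cluster_k_max: int = 4
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "covariates" in raw and raw["covariates"] is not None:
            raw["covariates"] = tuple(raw["covariates"])
        return cls(**raw)


def _stage_seed(master: int, stage: str) -> int:
    idx = _STAGES.index(stage)
    return int(np.random.SeedSequence([master, idx]).generate_state(1)[0] % (2**31))


def _read_panel(path) -> list[str]:
    with open(path) as fh:
        genes = [line.strip() for line in fh if line.strip()
                 and not line.startswith("#")]
    if not genes:
        raise ValueError(f"empty gene panel: {path}")
    return genes


def _write(df: pd.DataFrame, path: Path, stage: str, index_label: str,
           manifest: dict) -> None:
    write_matrix(df, path, index_label=index_label,
                 comment=f"hapattern {__version__} stage={stage}")
    manifest["stages"].setdefault(stage, []).append(path.name)


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def run_pipeline(cfg: PipelineConfig, out_dir) -> dict:
    """Run every stage; returns the manifest dictionary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": cfg.seed,
                      "config": {k: (list(v) if isinstance(v, tuple) else v)
                                 for k, v in vars(cfg).items()},
                      "stages": {}}
    stage = "preprocess"
    try:
        expr = read_expression(cfg.expression)
        if cfg.expression_scale == "fpkm":
            expr = log2_transform(fpkm_to_tpm(expr))
        elif cfg.expression_scale != "log2tpm":
            raise ValueError(f"unknown expression_scale {cfg.expression_scale!r}")
        clinical = read_clinical(cfg.clinical)
        shared = [s for s in expr.columns if s in clinical.index]
        if len(shared) < 4:
            raise ValueError("fewer than 4 samples shared between expression "
                             "and clinical tables")
        expr = expr[shared]
        clinical = clinical.loc[shared]
        if "batch" in clinical.columns:
            expr = batch_adjust(expr, clinical["batch"])
        _write(expr, out / "expression_preprocessed.tsv", stage, "gene_id",
               manifest)

        stage = "consensus"
        panel = _read_panel(cfg.panel)
        present = [g for g in panel if g in expr.index]
        if len(present) < len(panel):
            warnings.warn(f"{len(panel) - len(present)} panel gene(s) absent")
        cc = ConsensusClustering(
            k_range=range(cfg.k_min, cfg.k_max + 1), reps=cfg.reps,
            subsample_frac=cfg.subsample_frac,
            random_state=_stage_seed(cfg.seed, stage))
        cc.fit(expr.loc[present].to_numpy().T)
        res = cc.result(sample_ids=expr.columns)
        assignments = res.assignments
        _write(res.metrics_frame().set_index("k"),
               out / "consensus_metrics.tsv", stage, "k", manifest)
        _write(assignments.to_frame(), out / "assignments.tsv", stage,
               "sample_id", manifest)
        _write(res.consensus[res.chosen_k],
               out / f"consensus_k{res.chosen_k}.tsv", stage, "sample_id",
               manifest)

        stage = "de"
        de = moderated_de(expr, assignments)
        _write(de.set_index("gene"), out / "de.tsv", stage, "gene", manifest)

        stage = "degs"
        degs = select_degs(de, cfg.fc_thresh, cfg.adjp_thresh)
        if not degs:
            raise ValueError("no DEG passed the thresholds")
        _write(pd.DataFrame({"gene": degs}).set_index("gene"),
               out / "degs.tsv", stage, "gene", manifest)

        stage = "prognostic"
        prognostic = prognostic_screen(expr, clinical, degs,
                                       p_thresh=cfg.prognostic_p)
        _write(pd.DataFrame({"gene": prognostic}).set_index("gene"),
               out / "prognostic_genes.tsv", stage, "gene", manifest)

        stage = "gene_cluster"
        gk_max = max(2, min(cfg.gene_cluster_k_max, len(prognostic) // 2))
        gcc = ConsensusClustering(
            k_range=range(2, gk_max + 1), reps=cfg.reps,
            subsample_frac=cfg.subsample_frac,
            random_state=_stage_seed(cfg.seed, stage))
        gcc.fit(expr.loc[prognostic].to_numpy())  # genes as items
        gres = gcc.result(sample_ids=prognostic)
        _write(gres.assignments.to_frame(), out / "gene_clusters.tsv", stage,
               "gene", manifest)

        stage = "hascore"
        scores = hascore(expr, prognostic)
        score_tab = scores.to_frame()
        score_tab["pattern"] = assignments
        _write(score_tab, out / "hascore.tsv", stage, "sample_id", manifest)

        stage = "cutpoint"
        time = clinical["os_time"].to_numpy(dtype=float)
        event = clinical["os_event"].to_numpy()
        groups = pd.Series(index=scores.index, dtype=object)
        cut_rows = []
        if "batch" in clinical.columns and \
                clinical["batch"].value_counts().min() >= 20:
            for lab, sub in clinical.groupby("batch"):
                ids = sub.index
                c, z = best_cutpoint(scores.loc[ids],
                                     sub["os_time"], sub["os_event"],
                                     minprop=cfg.minprop)
                groups.loc[ids] = np.where(scores.loc[ids] > c, "high", "low")
                cut_rows.append({"batch": lab, "cutpoint": c, "max_stat": z})
        else:
            c, z = best_cutpoint(scores, time, event, minprop=cfg.minprop)
            groups[:] = np.where(scores > c, "high", "low")
            cut_rows.append({"batch": "all", "cutpoint": c, "max_stat": z})
        score_tab["ha_group"] = groups
        _write(pd.DataFrame(cut_rows).set_index("batch"),
               out / "cutpoint.tsv", stage, "batch", manifest)
        _write(score_tab, out / "ha_groups.tsv", stage, "sample_id", manifest)

        stage = "survival"
        km_rows = []
        for lab in ("high", "low"):
            m = (groups == lab).to_numpy()
            curve = km_curve(time[m], event[m])
            for t, s, r, d in zip(curve.event_times, curve.survival,
                                  curve.at_risk, curve.events):
                km_rows.append({"group": lab, "time": t, "survival": s,
                                "at_risk": r, "events": d})
        _write(pd.DataFrame(km_rows).set_index("group"), out / "km.tsv",
               stage, "group", manifest)
        chi2, df, p = logrank_test(time, event, groups.to_numpy())
        _write(pd.DataFrame([{"test": "logrank_high_vs_low", "chi2": chi2,
                              "df": df, "p": p}]).set_index("test"),
               out / "logrank.tsv", stage, "test", manifest)
        uni = cox_fit(time, event, scores.to_numpy(), names=("hascore",))
        covs = pd.DataFrame({"hascore": scores})
        for cname in cfg.covariates:
            if cname not in clinical.columns:
                raise ValueError(f"covariate {cname!r} not in clinical table")
            col = clinical[cname]
            if col.dtype == object or str(col.dtype) == "category":
                dummies = pd.get_dummies(col.astype(str), prefix=cname,
                                         drop_first=True)
                covs = covs.join(dummies.astype(float))
            else:
                covs[cname] = col.astype(float)
        multi = cox_fit(time, event, covs)
        _write(uni.summary().set_index("covariate"), out / "cox_uni.tsv",
               stage, "covariate", manifest)
        _write(multi.summary().set_index("covariate"), out / "cox_multi.tsv",
               stage, "covariate", manifest)

        stage = "enrichment"
        if cfg.gene_sets:
            sets = read_gmt(cfg.gene_sets)
            enr = ssgsea_table(expr, sets, alpha=cfg.ssgsea_alpha)
            _write(enr, out / "ssgsea.tsv", stage, "gene_set", manifest)
            rows = []
            for name in enr.index:
                by_pat = [enr.loc[name, assignments == g]
                          for g in sorted(assignments.unique())]
                if all(len(v) > 1 for v in by_pat):
                    stat, pval = kruskal(*[v.to_numpy() for v in by_pat])
                    rows.append({"gene_set": name, "kruskal_h": stat,
                                 "p": pval})
            if rows:
                _write(pd.DataFrame(rows).set_index("gene_set"),
                       out / "enrichment_tests.tsv", stage, "gene_set",
                       manifest)
        if cfg.emt_gene_sets:
            emt_sets = {gs.name.upper(): gs for gs in read_gmt(cfg.emt_gene_sets)}
            if {"MESENCHYMAL", "EPITHELIAL"} <= set(emt_sets):
                emt = emt_score(expr, emt_sets["MESENCHYMAL"],
                                emt_sets["EPITHELIAL"])
                _write(emt.to_frame(), out / "emt.tsv", stage, "sample_id",
                       manifest)
            else:
                raise ValueError("EMT GMT must contain sets named "
                                 "MESENCHYMAL and EPITHELIAL")
        if not cfg.gene_sets and not cfg.emt_gene_sets:
            logger.info("enrichment stage skipped (no gene sets provided)")

        stage = "associations"
        if cfg.drugs:
            auc = pd.read_csv(cfg.drugs, sep="\t", comment="#",
                              index_col="sample_id")
            pathways = {}
            if cfg.drug_annotation:
                ann = pd.read_csv(cfg.drug_annotation, sep="\t", comment="#")
                pathways = dict(zip(ann["drug"].astype(str),
                                    ann["pathway"].astype(str)))
            table = DrugResponseTable(auc=auc, pathways=pathways)
            hits = drug_correlation(scores, table, rs_thresh=cfg.rs_thresh,
                                    fdr_thresh=cfg.fdr_thresh)
            hit_tab = pd.DataFrame(
                [vars(h) for h in hits],
                columns=["drug", "rs", "p", "fdr", "direction", "pathway"])
            _write(hit_tab.set_index("drug"), out / "drug_hits.tsv", stage,
                   "drug", manifest)
        feat_rows = []
        for cname in clinical.columns:
            if cname in ("os_time", "os_event", "batch"):
                continue
            col = clinical[cname]
            if col.dtype != object and col.nunique() > 6:
                continue  # continuous covariates are not contingency material
            try:
                test, stat, p = categorical_association(groups, col)
                feat_rows.append({"feature": cname, "test": test,
                                  "statistic": stat, "p": p})
            except ValueError:
                continue
        if feat_rows:
            _write(pd.DataFrame(feat_rows).set_index("feature"),
                   out / "clinical_assoc.tsv", stage, "feature", manifest)
    except StageError:
        raise
    except Exception as err:  # noqa: BLE001 - stage attribution
        raise StageError(stage, err) from err

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
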