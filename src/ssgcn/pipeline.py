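"""End-to-end pipeline: preprocess -> networks -> localization -> survival.

A :class:`PipelineConfig` either points at existing expression/annotation/
clinical files (one expression matrix per cohort) or embeds a
:class:`~ssgcn.simulate.SimulationConfig`, in which case the two synthetic
cohorts (normal-like, cancer-like) are generated first. Stages write plain
TSV/CSV/JSON tables under the output directory and every stage can be
resumed from the previous stage's files; a manifest records the config hash,
seed and the files each stage produced.

When survival data are simulated, the high/low group labels used for the
hazard effect are the CIS-proportion median split actually computed from the
single-sample networks, so the planted hazard ratio refers to the same
stratification the analysis tests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import hotspots, hubs, io, netmetrics, simulate, survival
from .containers import EdgeList
from .lioness import all_sample_networks, mi_score, top_k_abs
from .mi import build_mi_matrix, dpi_prune, top_k_edges
from .preprocess import filter_genes, gc_length_correct, normalize, tmm_factors

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: str
    expression: dict[str, str] | None = None  # cohort name -> matrix path
    annotation: str | None = None
    clinical: str | None = None
    simulation: simulate.SimulationConfig | None = None
    reference_cohort: str = "normal"
    k_top_edges: int = 10_000
    mi_bins: int | None = None
    miller_madow: bool = False
    dpi: bool = False
    dpi_tolerance: float = 0.0
    gc_length_correct: bool = False
    top_n_hubs: int = 10
    five_year: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.k_top_edges < 1:
            raise ValueError("k_top_edges must be >= 1")
        if self.expression is None and self.simulation is None:
            raise ValueError("config needs either expression paths or a simulation")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.get("simulation")
        if sim is not None:
            sim = dict(sim)
            sim["planted_blocks"] = tuple(
                simulate.PlantedBlock(**dict(b)) if not isinstance(b, simulate.PlantedBlock) else b
                for b in sim.get("planted_blocks", ())
            )
            surv = sim.get("survival")
            if surv is not None and not isinstance(surv, simulate.SurvivalParams):
                sim["survival"] = simulate.SurvivalParams(**dict(surv))
            d["simulation"] = simulate.SimulationConfig(**sim)
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _score_fn(config: PipelineConfig):
    return mi_score(bins=config.mi_bins, miller_madow=config.miller_madow)


class _Runner:
    def __init__(self, config: PipelineConfig, resume: bool):
        self.config = config
        self.resume = resume
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "config_hash": config.digest(),
            "seed": config.seed,
            "stages": {},
            "files": {},
        }

    def _register(self, stage: str, files: dict, elapsed: float) -> None:
        self.manifest["stages"][stage] = {"seconds": round(elapsed, 3)}
        self.manifest["files"][stage] = {k: str(v) for k, v in files.items()}

    # -- stage 0: data ------------------------------------------------------
    def stage_data(self):
        cfg = self.config
        t0 = time.time()
        datadir = self.outdir / "data"
        datadir.mkdir(exist_ok=True)
        files: dict = {}
        if cfg.simulation is not None:
            ann_path = datadir / "annotation.tsv"
            cohort_paths = {
                "normal": datadir / "expression_normal.tsv",
                "cancer": datadir / "expression_cancer.tsv",
            }
            if not (self.resume and ann_path.exists() and all(p.exists() for p in cohort_paths.values())):
                annotation = simulate.generate_annotation(cfg.simulation)
                io.write_annotation(annotation, ann_path)
                for cohort, regime in (("normal", "normal_like"), ("cancer", "cancer_like")):
                    expr = simulate.generate_expression(cfg.simulation, regime, annotation)
                    io.write_expression(expr, cohort_paths[cohort])
            annotation = io.read_annotation(ann_path)
            cohorts = {c: io.read_expression(p) for c, p in cohort_paths.items()}
            files = {"annotation": ann_path, **cohort_paths}
        else:
            annotation = io.read_annotation(cfg.annotation)
            cohorts = {c: io.read_expression(p) for c, p in cfg.expression.items()}
            files = {"annotation": cfg.annotation, **cfg.expression}
        self._register("data", files, time.time() - t0)
        return annotation, cohorts

    # -- stage 1: preprocess -------------------------------------------------
    def stage_preprocess(self, cohorts, annotation):
        cfg = self.config
        t0 = time.time()
        outdir = self.outdir / "preprocess"
        outdir.mkdir(exist_ok=True)
        normalized = {}
        files = {}
        for cohort, expr in cohorts.items():
            norm_path = outdir / f"{cohort}.normalized.tsv"
            report_path = outdir / f"{cohort}.removed.csv"
            if self.resume and norm_path.exists():
                normalized[cohort] = io.read_expression(norm_path, stage="normalized")
            else:
                filtered, report = filter_genes(expr)
                factors = tmm_factors(filtered)
                norm = normalize(filtered, factors)
                if cfg.gc_length_correct:
                    norm = gc_length_correct(norm.values, annotation)
                io.write_expression(norm, norm_path)
                report.to_csv(report_path, index=False)
                normalized[cohort] = norm
            files[f"{cohort}_normalized"] = norm_path
            files[f"{cohort}_removed"] = report_path
        self._register("preprocess", files, time.time() - t0)
        return normalized

    # -- stage 2: aggregated networks ---------------------------------------
    def stage_aggnet(self, normalized):
        cfg = self.config
        t0 = time.time()
        outdir = self.outdir / "aggregated"
        outdir.mkdir(exist_ok=True)
        agg = {}
        files = {}
        for cohort, norm in normalized.items():
            path = outdir / f"{cohort}.edges.tsv"
            if self.resume and path.exists():
                agg[cohort] = io.read_edge_list(path, provenance="aggregated")
            else:
                mim = build_mi_matrix(norm, bins=cfg.mi_bins, miller_madow=cfg.miller_madow)
                if cfg.dpi:
                    mim = dpi_prune(mim, cfg.dpi_tolerance)
                agg[cohort] = top_k_edges(mim, k=cfg.k_top_edges)
                io.write_edge_list(agg[cohort], path)
            files[cohort] = path
        self._register("aggregated", files, time.time() - t0)
        return agg

    # -- stage 3: single-sample networks --------------------------------------
    def stage_ssn(self, normalized):
        cfg = self.config
        t0 = time.time()
        outdir = self.outdir / "ssn"
        outdir.mkdir(exist_ok=True)
        ssn: dict[str, dict[str, EdgeList]] = {}
        files = {}
        for cohort, norm in normalized.items():
            cdir = outdir / cohort
            cdir.mkdir(exist_ok=True)
            manifest_path = cdir / "manifest.json"
            if self.resume and manifest_path.exists():
                with open(manifest_path) as fh:
                    m = json.load(fh)
                ssn[cohort] = {
                    sid: io.read_edge_list(cdir / fname, provenance="single_sample")
                    for sid, fname in m["samples"].items()
                }
                for sid, e in ssn[cohort].items():
                    e.meta["sample_id"] = sid
            else:
                nets = all_sample_networks(norm, _score_fn(cfg))
                ssn[cohort] = {}
                sample_files = {}
                for net in nets:
                    edges = top_k_abs(net, k=cfg.k_top_edges)
                    fname = f"{net.sample_id}.edges.tsv"
                    io.write_edge_list(edges, cdir / fname)
                    ssn[cohort][net.sample_id] = edges
                    sample_files[net.sample_id] = fname
                with open(manifest_path, "w") as fh:
                    json.dump(
                        {
                            "cohort": cohort,
                            "n_cohort": norm.n_samples,
                            "k": cfg.k_top_edges,
                            "estimator": {
                                "bins": cfg.mi_bins,
                                "miller_madow": cfg.miller_madow,
                            },
                            "samples": sample_files,
                        },
                        fh,
                        indent=1,
                        sort_keys=True,
                    )
            files[cohort] = manifest_path
        self._register("ssn", files, time.time() - t0)
        return ssn

    # -- stage 4: hotspots -----------------------------------------------------
    def stage_hotspots(self, agg, ssn, normalized, annotation):
        t0 = time.time()
        outdir = self.outdir / "hotspots"
        outdir.mkdir(exist_ok=True)
        files = {}
        cis_by_cohort = {}
        for cohort in agg:
            universe = normalized[cohort].gene_ids
            summary = hotspots.cis_trans_summary(agg[cohort], annotation)
            per_sample = []
            for sid, edges in ssn[cohort].items():
                s = hotspots.cis_trans_summary(edges, annotation)
                s["sample_id"] = sid
                per_sample.append(s)
            per_sample = pd.DataFrame(per_sample)
            cis_by_cohort[cohort] = per_sample.set_index("sample_id")["cis_fraction"]
            paths = {
                f"{cohort}_summary": outdir / f"{cohort}.cis_trans.json",
                f"{cohort}_per_sample": outdir / f"{cohort}.per_sample_cis.csv",
                f"{cohort}_chromosome": outdir / f"{cohort}.chromosome_hotspots.csv",
                f"{cohort}_cytoband": outdir / f"{cohort}.cytoband_hotspots.csv",
                f"{cohort}_argmax_chromosome": outdir / f"{cohort}.argmax_chromosome.csv",
                f"{cohort}_argmax_cytoband": outdir / f"{cohort}.argmax_cytoband.csv",
            }
            with open(paths[f"{cohort}_summary"], "w") as fh:
                json.dump(summary, fh, indent=1, sort_keys=True)
            per_sample.to_csv(paths[f"{cohort}_per_sample"], index=False)
            for level in ("chromosome", "cytoband"):
                hotspots.region_hotspots(
                    agg[cohort], annotation, level=level, universe=universe
                ).to_csv(paths[f"{cohort}_{level}"], index=False)
                hotspots.per_sample_argmax_regions(
                    ssn[cohort], annotation, level=level, universe=universe
                ).to_csv(paths[f"{cohort}_argmax_{level}"], index=False)
            files.update(paths)
        self._register("hotspots", files, time.time() - t0)
        return cis_by_cohort

    # -- stage 5: metrics + jaccard -------------------------------------------
    def stage_metrics(self, agg, ssn):
        cfg = self.config
        t0 = time.time()
        outdir = self.outdir / "metrics"
        outdir.mkdir(exist_ok=True)
        files = {}
        records_by_cohort = {}
        for cohort in agg:
            records = []
            jac = []
            for sid, edges in ssn[cohort].items():
                lcc = netmetrics.largest_component(edges)
                records.append(netmetrics.compute_metrics(lcc, network_id=sid))
                jac.append({"sample_id": sid, "jaccard": netmetrics.jaccard(agg[cohort], edges)})
            records_by_cohort[cohort] = records
            mpath = outdir / f"{cohort}.metrics.csv"
            jpath = outdir / f"{cohort}.jaccard.csv"
            netmetrics.metrics_table(records).to_csv(mpath, index=False)
            (
                pd.DataFrame(jac)
                .sort_values(["jaccard", "sample_id"], ascending=[False, True])
                .to_csv(jpath, index=False)
            )
            files[f"{cohort}_metrics"] = mpath
            files[f"{cohort}_jaccard"] = jpath
        if cfg.reference_cohort in records_by_cohort and len(records_by_cohort) > 1:
            cpath = outdir / "group_comparison.csv"
            netmetrics.compare_groups(records_by_cohort, cfg.reference_cohort).to_csv(
                cpath, index=False
            )
            files["group_comparison"] = cpath
        self._register("metrics", files, time.time() - t0)
        return records_by_cohort

    # -- stage 6: hubs ----------------------------------------------------------
    def stage_hubs(self, ssn, annotation):
        cfg = self.config
        t0 = time.time()
        outdir = self.outdir / "hubs"
        outdir.mkdir(exist_ok=True)
        files = {}
        for cohort, nets in ssn.items():
            rec = hubs.hub_recurrence(nets, top_n=cfg.top_n_hubs)
            dist = hubs.hub_cytoband_distribution(rec, annotation)
            rpath = outdir / f"{cohort}.hub_recurrence.csv"
            dpath = outdir / f"{cohort}.hub_cytobands.csv"
            rec.to_csv(rpath, index=False)
            dist.to_csv(dpath, index=False)
            files[f"{cohort}_recurrence"] = rpath
            files[f"{cohort}_cytobands"] = dpath
        self._register("hubs", files, time.time() - t0)

    # -- stage 7: survival -------------------------------------------------------
    def stage_survival(self, cis_by_cohort):
        cfg = self.config
        t0 = time.time()
        outdir = self.outdir / "survival"
        outdir.mkdir(exist_ok=True)
        files = {}
        cis_all = pd.concat(cis_by_cohort.values())
        if cfg.clinical is not None:
            clinical = io.read_clinical(cfg.clinical)
        elif cfg.simulation is not None:
            # simulate outcomes with the hazard effect tied to the CIS split
            med = {c: s.median() for c, s in cis_by_cohort.items()}
            labels = pd.concat(
                [
                    pd.Series(
                        np.where(s > med[c], "high", "low"), index=s.index
                    )
                    for c, s in cis_by_cohort.items()
                ]
            )
            clinical = simulate.generate_clinical(cfg.simulation, labels)
            clinical["subtype"] = [
                c
                for c, s in cis_by_cohort.items()
                for _ in range(len(s))
            ]
            io.write_clinical(clinical, outdir / "clinical.csv")
            files["clinical"] = outdir / "clinical.csv"
        else:
            self._register("survival", {}, time.time() - t0)
            return None
        if "subtype" not in clinical.columns:
            clinical["subtype"] = "all"
        clinical = clinical.drop(columns=[c for c in ("group",) if c in clinical.columns])
        clinical = survival.split_by_cis(cis_all, clinical)
        results = {}
        tables = [("overall", clinical)]
        if cfg.five_year:
            tables.append(("five_year", survival.truncate_5year(clinical)))
        for tag, tab in tables:
            for subtype in sorted(tab["subtype"].unique()):
                sub = tab[tab["subtype"] == subtype]
                hi = sub[sub["group"] == "high"]
                lo = sub[sub["group"] == "low"]
                entry: dict = {"n_high": len(hi), "n_low": len(lo)}
                if len(hi) and len(lo):
                    chi2, p = survival.logrank_test(
                        hi["time_days"], hi["event"], lo["time_days"], lo["event"]
                    )
                    entry.update({"logrank_chi2": chi2, "logrank_p": p})
                    if sub["event"].sum() > 0 and hi["event"].sum() > 0 and lo["event"].sum() > 0:
                        entry["cox"] = survival.cox_hazard_ratio(sub)
                    for grp, frame in (("high", hi), ("low", lo)):
                        km, _ = survival.km_estimate(
                            frame["time_days"], frame["event"], label=grp
                        )
                        kpath = outdir / f"{subtype}.{tag}.{grp}.km.csv"
                        km.to_csv(kpath, index=False, float_format=io.FLOAT_FORMAT)
                        files[f"{subtype}_{tag}_{grp}_km"] = kpath
                results[f"{subtype}:{tag}"] = entry
        rpath = outdir / "survival_results.json"
        with open(rpath, "w") as fh:
            json.dump(results, fh, indent=1, sort_keys=True)
        files["results"] = rpath
        self._register("survival", files, time.time() - t0)
        return results


def run_pipeline(config: PipelineConfig, resume: bool = False) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    runner = _Runner(config, resume)
    try:
        annotation, cohorts = runner.stage_data()
        normalized = runner.stage_preprocess(cohorts, annotation)
        agg = runner.stage_aggnet(normalized)
        ssn = runner.stage_ssn(normalized)
        cis = runner.stage_hotspots(agg, ssn, normalized, annotation)
        runner.stage_metrics(agg, ssn)
        runner.stage_hubs(ssn, annotation)
        runner.stage_survival(cis)
    except Exception as exc:
        raise RuntimeError(
            f"pipeline aborted (config {config.digest()}): {exc}"
        ) from exc
    manifest_path = runner.outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(runner.manifest, fh, indent=1, sort_keys=True)
    config.to_yaml(runner.outdir / "config.yaml")
    return runner.manifest
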