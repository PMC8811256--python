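"""End-to-end orchestration of the two-tier screen and QTL analysis.

A :class:`PipelineConfig` collects every constant of the analysis (class
thresholds, slope-test alpha, scan step, cofactor count and window,
permutation count and alpha, support-interval drop, candidate keywords,
seed) with the study defaults.  :func:`run_pipeline` executes whatever
stages its inputs allow — tier-1 indices/summaries/heritability from a
weighing CSV, tier-2 breakpoint fits from a VPD CSV, SIM + CIM scans,
permutation thresholds and the additive QTL model from a genotype matrix,
and candidate genes from an annotation — writing one table per stage plus
a machine-readable run manifest.
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

from . import candidate_genes as cg
from . import phenotypes as ph
from . import quantgen as qg
from . import vpd_response as vr
from .errors import InvalidInputError, StageError

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("trlim")


@dataclass
class PipelineConfig:
    """Structured configuration; unknown keys are rejected."""

    weighing_csv: str | None = None
    vpd_csv: str | None = None
    genotype_csv: str | None = None
    map_tsv: str | None = None
    annotation: str | None = None  # GFF3 (.gff/.gff3) or flat TSV
    out_dir: str = "trlim_out"

    reference_parent_1: str = "Jackson"
    reference_parent_2: str = "KS4895"
    classify_on: str = "rdtr_k"
    slow_max: float = 0.50
    moderate_max: float = 1.00

    slope_alpha: float = 0.05
    scan_step: float = 1.0
    n_cofactors: int = 3
    cim_window: float = 10.0
    n_perm: int = 1000
    qtl_alpha: float = 0.05
    support_drop: float = 1.5
    scan_traits: tuple = ("tr_h2o", "tr_agno3", "dtr")

    keywords: tuple = cg.DEFAULT_KEYWORDS
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
        for key in ("keywords", "scan_traits"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _stage(name: str, manifest: dict):
    """Context decorator: time a stage, record it, convert failures."""

    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                manifest["stages"][name] = {"status": "ok", "seconds": round(dt, 3)}
                log.info("stage %s: done in %.2fs", name, dt)
                return False
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            log.error("stage %s: FAILED (%s)", name, exc)
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage the configured inputs allow; return the manifest.

    Stage outputs land in ``config.out_dir``; stages whose inputs are
    missing are skipped with a notice, and a failing stage aborts with the
    stage named while earlier outputs are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "stages": {},
        "outputs": [],
    }

    def save(df: pd.DataFrame, name: str, **kwargs) -> None:
        path = out / name
        df.to_csv(path, sep="\t" if name.endswith(".tsv") else ",", **kwargs)
        manifest["outputs"].append(name)

    index_table = None
    if config.weighing_csv:
        with _stage("indices", manifest):
            weighing = ph.read_weighing_csv(config.weighing_csv)
            index_table = ph.compute_index_table(
                weighing,
                parent_jackson=config.reference_parent_1,
                parent_ks4895=config.reference_parent_2,
                classify_on=config.classify_on,
            )
            save(index_table, "index_table.csv", index=True)
        with _stage("summaries", manifest):
            save(ph.summary_report(index_table), "trait_summary.tsv", index=True)
        with _stage("correlations", manifest):
            numeric = index_table.drop(columns=["wilting_class"])
            r, p = ph.correlation_matrix(numeric)
            save(r, "correlation_r.tsv", index=True)
            save(p, "correlation_p.tsv", index=True)
        with _stage("heritability", manifest):
            rates = ph._rates_long(weighing, drop_negative=True)
            h2_rows = []
            n_env = rates["set"].nunique()
            n_rep = int(rates.groupby(["genotype", "set", "phase"]).size().median())
            for phase, trait in [("water", "tr_h2o"), ("agno3", "tr_agno3")]:
                sub = rates[rates["phase"] == phase]
                vc = ph.variance_components(sub, "rate")
                est = ph.heritability(vc, n_env, n_rep)
                h2_rows.append(
                    {
                        "trait": trait,
                        "h2": est.h2,
                        "sigma_g2": est.sigma_g2,
                        "sigma_ge2": est.sigma_ge2,
                        "sigma_e2": est.sigma_e2,
                        "n_env": n_env,
                        "n_rep": n_rep,
                    }
                )
            save(pd.DataFrame(h2_rows), "heritability.tsv", index=False)
    else:
        log.info("no weighing CSV: tier-1 stages skipped")

    if config.vpd_csv:
        with _stage("breakpoints", manifest):
            points = vr.read_vpd_csv(config.vpd_csv)
            report = vr.fit_report(points, alpha=config.slope_alpha)
            if index_table is not None:
                report = report.merge(
                    index_table["wilting_class"].astype(str).rename("wilting_class"),
                    left_on="genotype",
                    right_index=True,
                    how="left",
                )
            save(report, "breakpoint_fits.tsv", index=False)
            if "wilting_class" in report.columns and report["wilting_class"].notna().any():
                counts = vr.trlim_count_table(
                    report.rename(columns={"bp": "bp"})[
                        ["wilting_class", "temperature_c", "bp"]
                    ]
                )
                save(counts, "trlim_counts.tsv", index=False)
    else:
        log.info("no VPD CSV: tier-2 stage skipped")

    if config.genotype_csv and config.map_tsv:
        with _stage("qtl", manifest):
            pop = qg.RILPopulation.from_abh_csv(config.genotype_csv, config.map_tsv)
            if index_table is None:
                raise InvalidInputError("QTL stage needs the tier-1 index table")
            grid = qg.genotype_prob_grid(pop, config.scan_step)
            qtl_rows = []
            for trait in config.scan_traits:
                if trait not in index_table.columns:
                    continue
                phen = (
                    index_table[trait].reindex(pop.line_ids).to_numpy(dtype=float)
                )
                sim = qg.hk_scan(pop, phen, config.scan_step, _grid=grid)
                cim = qg.cim_scan(
                    pop,
                    phen,
                    config.scan_step,
                    config.n_cofactors,
                    config.cim_window,
                    _grid=grid,
                )
                thr = qg.permutation_threshold(
                    pop,
                    phen,
                    n_perm=config.n_perm,
                    alpha=config.qtl_alpha,
                    seed=config.seed,
                    _grid=grid,
                )
                sim.threshold = cim.threshold = thr
                save(
                    sim.positions.assign(lod_sim=sim.lod, lod_cim=cim.lod),
                    f"scan_{trait}.tsv",
                    index=False,
                )
                peaks = cim.chrom_peaks(thr)
                if len(peaks):
                    fits = qg.fit_qtl_model(
                        pop,
                        phen,
                        [
                            (r["chromosome"], r["pos_cm"])
                            for _, r in peaks.iterrows()
                        ],
                        step=config.scan_step,
                        drop=config.support_drop,
                        name_prefix=f"q{trait}",
                    )
                    rep = qg.qtl_report(fits).assign(trait=trait, threshold=thr)
                    qtl_rows.append(rep)
            if qtl_rows:
                save(pd.concat(qtl_rows, ignore_index=True), "qtl_report.tsv", index=False)
            manifest["qtl_traits"] = list(config.scan_traits)
    else:
        log.info("no genotype matrix + map: QTL stage skipped")

    if config.annotation:
        with _stage("candidates", manifest):
            path = str(config.annotation)
            if path.endswith((".gff", ".gff3")):
                genes = cg.read_annotation_gff3(path)
            else:
                genes = cg.read_annotation_tsv(path)
            qtl_path = out / "qtl_report.tsv"
            calls_frames = []
            if qtl_path.exists():
                report = pd.read_csv(qtl_path, sep="\t")
                for _, row in report.iterrows():
                    hits = cg.genes_in_interval(
                        genes, str(row["chromosome"]), 1, 10**9
                    )
                    calls = cg.filter_candidates(hits, tuple(config.keywords))
                    frame = cg.candidate_report(calls)
                    frame["qtl"] = row["qtl"]
                    calls_frames.append(frame)
            else:
                calls = cg.filter_candidates(genes, tuple(config.keywords))
                calls_frames.append(cg.candidate_report(calls))
            save(
                pd.concat(calls_frames, ignore_index=True)
                if calls_frames
                else pd.DataFrame(),
                "candidate_genes.tsv",
                index=False,
            )
    else:
        log.info("no annotation: candidate-gene stage skipped")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
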