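"""End-to-end orchestration: simulate (or load) -> QC -> scan -> candidates
-> co-expression network -> tumor statistics, under one config and one seed.

The global seed is expanded into per-stage seeds through a fixed counter
scheme (``SeedSequence([global_seed, stage_counter])``), so each stage is
independently reproducible and the full run is byte-identical under a
fixed config + seed.  Outputs land in one directory with a manifest
(parameters, per-stage seeds, SHA-256 checksums of every written file).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import candidates as cand
from . import coexpnet, qtlscan, simdata, tumorstats
from .genotypes import MISSING, QCThresholds, X_CHROM, qc_filter_individuals, \
    qc_filter_markers
from .simdata import (Cohort, EQTLEffect, ModuleSpec, QTLEffect, SimConfig,
                      nearest_marker, simulate_cohort)

log = logging.getLogger("bxlink")

# Stage counters for seed derivation (documented scheme, never reordered).
STAGE_SEEDS = {"simulate": 0, "qc": 1, "scan": 2, "candidates": 3,
               "network": 4, "tumorstats": 5}


def stage_seed(global_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([int(global_seed), STAGE_SEEDS[stage]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def config_to_simconfig(block: dict, seed: int) -> SimConfig:
    """Build a SimConfig from the ``simulate`` block of a pipeline config."""
    qtl = [QTLEffect(**e) for e in block.get("qtl_effects", [])]
    eqtl = [EQTLEffect(**e) for e in block.get("eqtl_effects", [])]
    mod = block.get("module")
    kwargs = {k: v for k, v in block.items()
              if k in ("n_individuals", "sex_ratio", "n_genes",
                       "genotype_error_rate")}
    if mod:
        module = ModuleSpec(**mod)
    else:
        # default module only when the configured gene count can hold it
        module = ModuleSpec()
        if kwargs.get("n_genes", 2000) < module.size + len(eqtl):
            module = None
    return SimConfig(qtl_effects=qtl, eqtl_effects=eqtl, module_spec=module,
                     rng_seed=seed, **kwargs)


def run_full(config: dict | str | Path, outdir, seed: int | None = None
             ) -> dict:
    """Execute all configured stages; returns the combined report dict.

    ``config`` is a dict or a YAML path.  Stages with no config block are
    skipped with a notice (partial pipelines are valid: a scan-only config
    still runs).  A stage failure raises with the stage name attached.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    report: dict = {"seed": seed, "stages": [], "skipped": []}
    written: list[Path] = []

    def run_stage(name, fn):
        log.info("stage %s starting", name)
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        report["stages"].append(name)
        log.info("stage %s done", name)

    cohort_holder: dict = {}

    def _simulate():
        cfg = config_to_simconfig(config.get("simulate", {}),
                                  stage_seed(seed, "simulate"))
        cohort = simulate_cohort(
            cfg, driver_coupling=config.get("simulate", {})
            .get("driver_coupling", 0.0))
        cohort_holder["cohort"] = cohort
        simdata.write_cohort(cohort, out / "data")
        written.extend(sorted((out / "data").glob("*")))

    run_stage("simulate", _simulate)
    cohort: Cohort = cohort_holder["cohort"]

    def _qc():
        th = QCThresholds(**config.get("qc", {}).get("thresholds", {})) \
            if config.get("qc", {}).get("thresholds") else QCThresholds()
        gm, rep_i = qc_filter_individuals(cohort.genotypes, th)
        gm, rep_m = qc_filter_markers(gm, th)
        keep = pd.Index(gm.individuals)
        cohort.phenotypes = cohort.phenotypes[
            cohort.phenotypes["id"].isin(keep)].reset_index(drop=True)
        cohort.expression = cohort.expression[list(gm.individuals)]
        cohort.genotypes = gm
        report["qc"] = {"individuals": rep_i, "markers": rep_m}
        _write_json(out / "qc.json", report["qc"])
        written.append(out / "qc.json")

    if "qc" in config:
        run_stage("qc", _qc)
    else:
        report["skipped"].append("qc")

    probs_holder: dict = {}
    peaks: list[qtlscan.QTLPeak] = []

    def _scan():
        sc = config.get("scan", {})
        step = float(sc.get("step_cm", 2.0))
        err = float(sc.get("error_rate", 1e-4))
        probs = qtlscan.calc_genoprob(cohort.genotypes, step, err)
        probs_holder["probs"] = probs
        pheno_rows = []
        scan_frames = []
        for pconf in sc.get("phenotypes", [{"name": "bmi"}]):
            name = pconf["name"]
            y = tumorstats.mean_center_by_sex(
                cohort.phenotypes[name].to_numpy(float),
                cohort.phenotypes["sex"].to_numpy())
            intcov = ((cohort.genotypes.sex == "M").astype(float)
                      if pconf.get("sex_interactive") else None)
            scan = qtlscan.scanone_hk(probs, y, intcovar=intcov)
            scan_frames.append(scan.df.assign(phenotype=name))
            thr = qtlscan.permutation_thresholds(
                probs, y, intcovar=intcov, alpha=float(sc.get("alpha", 0.05)),
                n_perm_auto=int(sc.get("perms", 1000)),
                n_perm_x=int(sc.get("xperms", 1000)),
                seed=stage_seed(seed, "scan"))
            for chrom in probs.chrom_names:
                lim = thr.x_threshold if chrom == X_CHROM else \
                    thr.auto_threshold
                if scan.max_lod([chrom]) >= lim:
                    peak = qtlscan.locate_peak(scan, probs, chrom, y,
                                               name.upper(), name)
                    peaks.append(peak)
                    pheno_rows.append(dataclasses.asdict(peak))
            report.setdefault("thresholds", {})[name] = {
                "autosome": thr.auto_threshold, "x": thr.x_threshold,
                "alpha_auto": thr.alpha_auto, "alpha_x": thr.alpha_x}
        pd.concat(scan_frames).to_csv(out / "scan.tsv", sep="\t",
                                      index=False, float_format="%.6g")
        pd.DataFrame(pheno_rows).to_csv(out / "peaks.tsv", sep="\t",
                                        index=False, float_format="%.6g")
        _write_json(out / "thresholds.json", report["thresholds"])
        written.extend([out / "scan.tsv", out / "peaks.tsv",
                        out / "thresholds.json"])
        report["peaks"] = pheno_rows

    if "scan" in config:
        run_stage("scan", _scan)
    else:
        report["skipped"].append("scan")

    def _candidates():
        if cohort.expression is None or "scan" not in report["stages"]:
            report["skipped"].append("candidates")
            log.info("candidates stage skipped: no expression/scan inputs")
            return
        cc = config.get("candidates", {})
        alpha = float(cc.get("alpha", 0.05))
        lod_min = float(cc.get("lod_min", 3.0))
        probs = probs_holder["probs"]
        all_tables = []
        for peak in peaks:
            pheno = tumorstats.mean_center_by_sex(
                cohort.phenotypes[peak.phenotype].to_numpy(float),
                cohort.phenotypes["sex"].to_numpy())
            mk = nearest_marker(cohort.genotypes.map, peak.chrom, peak.pos_cm)
            g = cohort.genotypes.genotype_at(mk)
            snp_set = cand.snp_route(cohort.variants, peak, cohort.gene_info)
            de = cand.de_vs_marker(
                cohort.expression, g, cohort.genotypes.sex,
                x_chrom=peak.chrom == X_CHROM,
                n_perm=int(cc.get("de_perms", 50)), alpha=alpha,
                seed=stage_seed(seed, "candidates"))
            eqtl_res = []
            for gene in de.loc[de["flagged"], "gene"]:
                expr = cohort.expression.loc[gene].to_numpy(float)
                eqtl_res.append(cand.eqtl_route(expr, probs, peak,
                                                gene=gene, lod_min=lod_min))
            union = sorted(set(snp_set)
                           | {r.gene for r in eqtl_res if r.is_candidate})
            if not union:
                continue
            assoc = cand.phenotype_association(
                cohort.expression.loc[union], pheno, g, alpha=alpha)
            table = cand.assemble_candidates(
                snp_set, eqtl_res, assoc, cohort.gene_info,
                peak.direction, de_stats=de)
            table.insert(0, "qtl", peak.name)
            all_tables.append(table)
        result = (pd.concat(all_tables, ignore_index=True) if all_tables
                  else pd.DataFrame())
        result.to_csv(out / "candidates.tsv", sep="\t", index=False,
                      float_format="%.6g")
        written.append(out / "candidates.tsv")
        report["candidates"] = result.to_dict("records")

    if "candidates" in config:
        run_stage("candidates", _candidates)
    else:
        report["skipped"].append("candidates")

    def _network():
        nc = config.get("network", {})
        seed_gene = nc.get("seed_gene")
        if seed_gene is None and cohort.truth.module_genes:
            seed_gene = cohort.truth.module_genes[0]
        expr = cohort.expression
        stratum = nc.get("stratum", "all")
        if stratum in ("M", "F"):
            expr = expr.loc[:, cohort.genotypes.sex == stratum]
        thr = coexpnet.gwer_threshold(
            expr, n_perm=int(nc.get("perms", 1000)),
            alpha=float(nc.get("alpha", 0.05)),
            seed=stage_seed(seed, "network"))
        corr = coexpnet.spearman_matrix(expr)
        nbhd = coexpnet.build_neighborhood(corr, seed_gene, thr)
        enr = coexpnet.go_enrichment(nbhd.nodes, cohort.go)
        coexpnet.export_network(nbhd, out / "network")
        enr.to_csv(out / "network" / "enrichment.tsv", sep="\t",
                   index=False, float_format="%.6g")
        written.extend(sorted((out / "network").glob("*")))
        report["network"] = {
            "seed_gene": seed_gene, "threshold": thr,
            "n_first": len(nbhd.first_degree),
            "n_second": len(nbhd.second_degree),
            "n_edges": len(nbhd.edges),
            "top_term": enr.iloc[0].to_dict() if len(enr) else None}

    if "network" in config:
        run_stage("network", _network)
    else:
        report["skipped"].append("network")

    def _tumorstats():
        ph = cohort.phenotypes
        count_cols = [c for c in ph.columns if c.startswith("pap")]
        corr = tumorstats.phenotype_tumor_correlations(
            ph, ["bmi", "weight", "length"], count_cols)
        corr.to_csv(out / "correlations.tsv", sep="\t", index=False,
                    float_format="%.6g")
        sexv = ph["sex"].to_numpy()
        bmi_c = tumorstats.mean_center_by_sex(ph["bmi"].to_numpy(float), sexv)
        qc_res = tumorstats.quartile_contrast(
            ph["bmi"].to_numpy(float), ph[count_cols[-1]].to_numpy(float),
            sexv)
        p_int, _ = tumorstats.interaction_model(
            ph[count_cols[-1]].to_numpy(float), bmi_c, sexv)
        stats_rep = {
            "quartile_contrast": {s: dataclasses.asdict(r)
                                  for s, r in qc_res.items()},
            "interaction_p": p_int,
        }
        if "carcinoma_time" in ph.columns:
            surv = {}
            for s in ("M", "F"):
                m = sexv == s
                top, bottom = tumorstats.quartile_groups(bmi_c[m])
                grp = m.copy()
                sel = np.flatnonzero(m)[top | bottom]
                gx = np.zeros(len(sel))
                gx[top[top | bottom]] = 1.0
                res = tumorstats.carcinoma_survival(
                    ph["carcinoma_time"].to_numpy(float)[sel],
                    ph["carcinoma_event"].to_numpy(int)[sel], gx)
                surv[s] = {"hr": res.hr, "ci": res.ci,
                           "p_logrank": res.p_logrank}
            stats_rep["carcinoma_survival"] = surv
        _write_json(out / "tumorstats.json", stats_rep)
        written.extend([out / "correlations.tsv", out / "tumorstats.json"])
        report["tumorstats"] = stats_rep

    if "tumorstats" in config:
        run_stage("tumorstats", _tumorstats)
    else:
        report["skipped"].append("tumorstats")

    manifest = {
        "seed": seed,
        "stage_seeds": {k: stage_seed(seed, k) for k in STAGE_SEEDS},
        "config": config,
        "stages_run": report["stages"],
        "stages_skipped": report["skipped"],
        "checksums": {str(p.relative_to(out)): _sha256(p)
                      for p in sorted(set(written)) if p.is_file()},
    }
    _write_json(out / "manifest.json", manifest)
    _write_json(out / "report.json", report)
    return report


def _write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    return str(o)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Recovery benchmark
# ---------------------------------------------------------------------------

def recovery_benchmark(effect_grid, n_grid, seeds, chrom: str = "4",
                       pos_cm: float = 60.0, alpha: float = 0.05,
                       n_perm: int = 100) -> pd.DataFrame:
    """Localization and detection rates over an effect x n x seed grid.

    For each cell a cohort with one planted additive BMI QTL (effect in
    phenotype SD) is simulated, scanned, and scored: was the genome-max
    peak above its permutation threshold, and did the planted position
    fall inside the 95% Bayes interval.  Zero-effect cells measure the
    false-positive rate instead of recall.
    """
    rows = []
    for effect in effect_grid:
        for n in n_grid:
            detected, localized = [], []
            for s in seeds:
                cfg = SimConfig(
                    n_individuals=n,
                    qtl_effects=[QTLEffect(chrom, pos_cm, "bmi", effect)]
                    if effect else [],
                    module_spec=None, n_genes=0, rng_seed=int(s))
                gmap = simdata.simulate_map(cfg.map_spec)
                ss = np.random.SeedSequence(cfg.rng_seed)
                rngs = [np.random.default_rng(c) for c in ss.spawn(3)]
                sex = simdata.simulate_sexes(n, 0.5, rngs[0])
                gm = simdata.simulate_genotypes(gmap, n, sex, rng=rngs[1])
                ph = simdata.simulate_phenotypes(
                    gm, cfg.qtl_effects, rng=rngs[2])
                y = tumorstats.mean_center_by_sex(
                    ph["bmi"].to_numpy(float), sex)
                probs = qtlscan.calc_genoprob(gm, step_cm=0, error_rate=0)
                scan = qtlscan.scanone_hk(probs, y)
                thr = qtlscan.permutation_thresholds(
                    probs, y, alpha=alpha, n_perm_auto=n_perm,
                    n_perm_x=n_perm, seed=int(s))
                hit = scan.max_lod(probs.autosomes()) >= thr.auto_threshold
                detected.append(hit)
                if effect:
                    l, p, r, *_ = qtlscan.bayes_interval(scan, chrom)
                    localized.append(l <= pos_cm <= r)
            rows.append({
                "effect": effect, "n": n, "n_seeds": len(seeds),
                "detection_rate": float(np.mean(detected)),
                "localization_rate": (float(np.mean(localized))
                                      if effect else np.nan)})
    df = pd.DataFrame(rows)
    return df
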