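"""End-to-end orchestration of the QC / normalization / SVA / concordance
pipeline, with a consolidated JSON-serialisable report.

Stage order mirrors the analysis protocol: per-tissue sample QC (drop
failing arrays), background + dye-bias correction, functional
normalization (replicate concordance tested before/after), sequential
probe filters (McNemar comparison of per-probe outcomes between tissues),
reference-based deconvolution in blood (flagging composition outliers),
SVA + permuted-trait null EWAS per sample set (genomic inflation with and
without surrogate variables), and blood-vs-CSF correlation per CSF target
day, stratified by region and orientation.

A single pipeline seed fans out to per-stage sub-seeds through a fixed
derivation so each stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib

import numpy as np
import pandas as pd

from . import cellcomp, normalize, probe_qc, sample_qc, sva_ewas, tissue_corr
from .data_model import MethylationDataset, m_from_beta
from .synthgen import SimConfig, TruthRecord, simulate_dataset

log = logging.getLogger("methylqc")

_STAGE_SEEDS = {"simulate": 1, "permute": 2, "num_sv": 3}


def _stage_seed(seed: int, stage: str) -> int:
    return (seed * 1000003 + _STAGE_SEEDS[stage]) % (2**31)


@dataclasses.dataclass
class PipelineConfig:
    """Pipeline settings; unknown keys in a config file are rejected."""

    seed: int = 0
    simulate: bool = True
    input_dir: str | None = None
    out_dir: str | None = None
    sim: dict = dataclasses.field(default_factory=dict)   # SimConfig overrides

    # stage toggles
    do_normalize: bool = True
    do_sva: bool = True
    do_correlation: bool = True

    # thresholds
    detection_p_thresh: float = 0.01
    bead_thresh: int = 3
    sample_frac_thresh: float = 0.01
    bisulfite_sd_mult: float = 3.0
    funnorm_k: int = 2
    n_quantiles: int = 500
    n_discriminating: int = 100
    extreme_lo: float = 0.10
    extreme_hi: float = 0.90
    max_sv: int = 6

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def analysis_samples(sheet: pd.DataFrame) -> pd.Series:
    """Sample ids for analysis: biological samples only, one assay per
    technical-replicate group (the original, not the re-assay)."""
    bio = sheet[~sheet["is_control_sample"].astype(bool)]
    first = ~bio.duplicated(subset=["subject_id", "tissue", "collection_day"])
    return bio.loc[first, "sample_id"]


def _covariates_for(sheet: pd.DataFrame, ids) -> pd.DataFrame:
    sub = sheet.set_index("sample_id").loc[list(ids)]
    return pd.DataFrame({"age": sub["age"].astype(float), "sex": sub["sex"]})


def run_pipeline(config: PipelineConfig | None = None):
    """Run every stage on (by default) simulated data; returns the report
    dict and a bundle of intermediate objects for programmatic use."""
    cfg = config or PipelineConfig()
    report: dict = {"config": cfg.to_dict(), "seed": cfg.seed}
    bundle: dict = {}

    # ------------------------------------------------------------------ data
    if cfg.simulate:
        sim_cfg = SimConfig(**cfg.sim)
        dataset, truth, annotation = simulate_dataset(
            sim_cfg, seed=_stage_seed(cfg.seed, "simulate"))
        bundle["truth"] = truth
    else:
        from .data_model import read_annotation, read_dataset
        if cfg.input_dir is None:
            raise ValueError("input_dir required when simulate is false")
        dataset = read_dataset(cfg.input_dir)
        annotation = read_annotation(pathlib.Path(cfg.input_dir) / "annotation.tsv")
        truth = None
    bundle["dataset"] = dataset
    bundle["annotation"] = annotation
    log.info("data: %d probes x %d samples", len(dataset.probes), len(dataset.sample_ids))

    # ------------------------------------------------------- per-tissue QC
    tissue_data: dict = {}
    qc_counts = {}
    for tissue in ("blood", "csf"):
        mask = (dataset.samples.tissue == tissue) \
            & ~dataset.samples.is_control_sample.astype(bool)
        ids = dataset.samples.loc[mask, "sample_id"]
        if not len(ids):
            continue
        sub = dataset.subset_samples(ids)
        detp = sample_qc.detection_pvalues(sub, annotation)
        qc = sample_qc.flag_low_quality_samples(
            sub, detp, annotation,
            p_thresh=cfg.detection_p_thresh, bead_thresh=cfg.bead_thresh,
            frac_thresh=cfg.sample_frac_thresh, sd_mult=cfg.bisulfite_sd_mult)
        passed = sub.subset_samples(qc.passed)
        tissue_data[tissue] = {
            "qc": qc,
            "dataset": passed,
            "detp": detp[qc.passed],
        }
        qc_counts[tissue] = {"n_total": len(ids), "n_fail": len(qc.failed),
                             "failed_ids": qc.failed}
        log.info("sample QC %s: %d/%d failed", tissue, len(qc.failed), len(ids))
    if {"blood", "csf"} <= set(qc_counts):
        p, odds = sample_qc.tissue_failure_test(
            qc_counts["csf"]["n_fail"], qc_counts["csf"]["n_total"],
            qc_counts["blood"]["n_fail"], qc_counts["blood"]["n_total"])
        qc_counts["fisher_p"] = p
        qc_counts["odds_ratio"] = odds
    report["sample_qc"] = qc_counts

    # --------------------------------------------------------- normalization
    norm_report = {}
    for tissue, td in tissue_data.items():
        ds = td["dataset"]
        M_before = m_from_beta(ds.beta())
        if cfg.do_normalize:
            ds = normalize.background_correct(ds, annotation)
            ds = normalize.dye_bias_correct(ds, annotation)
            ds, mvals = normalize.functional_normalize(
                ds, annotation, k=cfg.funnorm_k, n_quantiles=cfg.n_quantiles)
            td["dataset_norm"] = ds
            td["M"] = mvals.values
            td["provenance"] = "funnorm"
        else:
            td["dataset_norm"] = ds
            td["M"] = M_before
            td["provenance"] = "raw"
        groups = normalize.replicate_groups_from_sheet(ds.samples)
        if len(normalize._replicate_pairs(groups)) >= 2:
            conc = normalize.replicate_concordance_test(M_before, td["M"], groups)
            norm_report[tissue] = {
                "n_replicate_pairs": len(conc.pairs),
                "mean_d_before": float(conc.pairs["d_before"].mean()),
                "mean_d_after": float(conc.pairs["d_after"].mean()),
                "t": conc.t_statistic, "p_one_sided": conc.p_value,
            }
    report["normalization"] = norm_report

    # ------------------------------------------------------------ probe QC
    probe_reports = {}
    for tissue, td in tissue_data.items():
        ds = td["dataset_norm"]
        rep = probe_qc.filter_probes(
            ds.beta(), td["detp"][ds.sample_ids], ds.beads, annotation,
            p_thresh=cfg.detection_p_thresh, bead_thresh=cfg.bead_thresh,
            sample_frac=cfg.sample_frac_thresh)
        td["probe_report"] = rep
        probe_reports[tissue] = {
            "steps": rep.steps.to_dict(orient="records"),
            "n_retained": len(rep.retained),
        }
        log.info("probe QC %s: %d retained", tissue, len(rep.retained))
    if {"blood", "csf"} <= set(tissue_data):
        chi2, p = probe_qc.mcnemar_filter_test(
            tissue_data["blood"]["probe_report"].probe_status["pass"],
            tissue_data["csf"]["probe_report"].probe_status["pass"])
        probe_reports["mcnemar_chi2"] = chi2
        probe_reports["mcnemar_p"] = p
    report["probe_qc"] = probe_reports

    # ------------------------------------------------- blood deconvolution
    if "blood" in tissue_data and truth is not None and truth.references:
        td = tissue_data["blood"]
        ds = td["dataset_norm"]
        bio = ds.samples.loc[~ds.samples.is_control_sample.astype(bool), "sample_id"]
        props = cellcomp.estimate_cell_proportions(
            ds.beta()[list(bio)], truth.references["blood"],
            n_discriminating=cfg.n_discriminating, reference_id="synthetic-blood")
        bundle["cell_proportions"] = props
        try:
            flags = cellcomp.flag_composition_outliers(props, "B_cell")
            outliers = list(flags.index[flags])
        except ValueError:
            outliers = []
        report["cell_composition"] = {
            "mean_fractions": props.fractions.mean().round(4).to_dict(),
            "b_cell_outliers": outliers,
        }

    # ------------------------------------------------------- SVA/null EWAS
    if cfg.do_sva:
        sva_report = {}
        sets = {}
        if "blood" in tissue_data:
            sheet = tissue_data["blood"]["dataset_norm"].samples
            sets["blood"] = list(analysis_samples(sheet))
        if "csf" in tissue_data:
            sheet = tissue_data["csf"]["dataset_norm"].samples
            day_sets = sva_ewas.csf_day_subsets(sheet)
            for day, ids in day_sets.items():
                if len(ids) >= 16:
                    sets[f"csf_day{day}"] = ids
        bundle["svs"] = {}
        for name, ids in sets.items():
            tissue = "blood" if name == "blood" else "csf"
            td = tissue_data[tissue]
            retained = td["probe_report"].retained
            M = td["M"].loc[retained, ids]
            sheet = td["dataset_norm"].samples.set_index("sample_id").loc[ids]
            trait = sheet["trait"].astype(float).to_numpy()
            if len(np.unique(trait[~np.isnan(trait)])) < 2:
                continue
            covars = _covariates_for(td["dataset_norm"].samples, ids)
            perm = sva_ewas.permute_trait(trait, seed=_stage_seed(cfg.seed, "permute"))
            n_sv = sva_ewas.estimate_num_sv(M, covars,
                                            seed=_stage_seed(cfg.seed, "num_sv"))
            n_sv = max(1, min(n_sv, cfg.max_sv))
            svs = sva_ewas.compute_surrogate_variables(M, perm, n_sv, covars)
            bundle["svs"][name] = svs
            ewas_raw = sva_ewas.run_ewas(M, perm, covars, svs=None)
            ewas_adj = sva_ewas.run_ewas(M, perm, covars, svs=svs)
            sva_report[name] = {
                "n_samples": len(ids), "n_sv": n_sv,
                "lambda_unadjusted": ewas_raw.inflation,
                "lambda_adjusted": ewas_adj.inflation,
            }
            log.info("null EWAS %s: lambda %0.3f -> %0.3f (n_sv=%d)",
                     name, ewas_raw.inflation, ewas_adj.inflation, n_sv)
        report["sva_ewas"] = sva_report

    # ------------------------------------------------------- tissue corr
    if cfg.do_correlation and {"blood", "csf"} <= set(tissue_data):
        corr_report = {}
        td_b, td_c = tissue_data["blood"], tissue_data["csf"]
        sheet_b = td_b["dataset_norm"].samples
        blood_ids = set(analysis_samples(sheet_b))
        blood_bio = sheet_b[sheet_b.sample_id.isin(blood_ids)]
        blood_by_subject = blood_bio.set_index("subject_id")["sample_id"].to_dict()
        day_sets = sva_ewas.csf_day_subsets(td_c["dataset_norm"].samples)
        retained = [p for p in td_b["probe_report"].retained
                    if p in set(td_c["probe_report"].retained)]
        csf_sheet = td_c["dataset_norm"].samples.set_index("sample_id")
        bundle["correlations"] = {}
        for day, csf_ids in day_sets.items():
            pairs = []
            for sid in csf_ids:
                subj = csf_sheet.loc[sid, "subject_id"]
                if subj in blood_by_subject:
                    pairs.append({"subject_id": subj,
                                  "blood_sample": blood_by_subject[subj],
                                  "csf_sample": sid})
            if len(pairs) < 5:
                continue
            pairs = pd.DataFrame(pairs)
            svs_b = bundle.get("svs", {}).get("blood")
            svs_c = bundle.get("svs", {}).get(f"csf_day{day}")

            def _sv_cols(svs, ids):
                if svs is None:
                    return None
                v = svs.values.reindex(ids)
                return None if v.isna().any().any() else v

            res = tissue_corr.compare_tissues(
                td_b["dataset_norm"].beta().loc[retained],
                td_b["M"].loc[retained],
                td_c["dataset_norm"].beta().loc[retained],
                td_c["M"].loc[retained],
                pairs,
                _covariates_for(sheet_b, pairs["blood_sample"]),
                _covariates_for(td_c["dataset_norm"].samples, pairs["csf_sample"]),
                annotation,
                svs_blood=_sv_cols(svs_b, list(pairs["blood_sample"])),
                svs_csf=_sv_cols(svs_c, list(pairs["csf_sample"])),
                lo=cfg.extreme_lo, hi=cfg.extreme_hi)
            bundle["correlations"][day] = res
            entry = res.summary()
            try:
                strata = tissue_corr.stratified_comparison(
                    res.per_cpg["r"], annotation, "region")
                entry["region_mean_r"] = strata.per_stratum["mean"].round(4).to_dict()
                entry["region_omnibus_p"] = strata.omnibus_p
            except ValueError:
                pass
            corr_report[f"day{day}"] = entry
        report["tissue_correlation"] = corr_report

    # ------------------------------------------------------------- persist
    if cfg.out_dir:
        out = pathlib.Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True, default=str)
    return report, bundle
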