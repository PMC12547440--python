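"""End-to-end pipeline: preprocess -> clean -> (enhance) -> evaluate -> rank.

This module provides the programmatic orchestration behind the ``esg`` command
line: a dispatcher over the five cleaning methods, the automatic
component-count selection loop (metric curves over k = 1..20 fed into the
weighted elbow rule), per-condition metric evaluation, and the overall method
ranking.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import enhance as enh
from . import ica as ica_mod
from . import metrics as met
from . import pca_obs
from . import subspace as sub
from .recording import Recording, epoch

logger = logging.getLogger(__name__)

CLEANING_METHODS = ("pca_obs", "ica", "ssp", "cca", "dss")
SSP_EPOCH_WINDOW = (-0.2, 0.4)
CCA_EPOCH_WINDOW = (-0.4, 0.6)
SEP_EPOCH_WINDOW = (-0.2, 0.7)
K_GRID_MAX = 20


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    methods: tuple = CLEANING_METHODS
    conditions: tuple = ("median", "tibial")
    n_pcs: int = 4
    taper: str = "none"
    k: int | str = "auto"        # components/projectors to remove, or 'auto'
    ctps_threshold: float = ica_mod.CTPS_THRESHOLD
    seed: int = 0
    enhance_methods: tuple = ("cca_sep", "dss_sep")
    notch_stage: str = "pre"
    sim: dict = field(default_factory=dict)
    input_path: str | None = None
    output_dir: str = "esg_out"


def _component_filters(uncleaned: Recording, method: str) -> sub.SpatialFilterSet:
    if method == "ssp":
        ep = epoch(uncleaned, "r_peak", *SSP_EPOCH_WINDOW,
                   picks=uncleaned.esg_picks)
        n_max = min(K_GRID_MAX, ep.data.shape[1] - 1)
        return sub.compute_ssp(ep, n_proj=n_max)
    if method == "cca":
        return sub.beat_cca(uncleaned, *CCA_EPOCH_WINDOW)
    if method == "dss":
        ep = epoch(uncleaned, "r_peak", *CCA_EPOCH_WINDOW,
                   picks=uncleaned.esg_picks)
        return sub.dss(uncleaned, ep)
    raise ValueError(f"no component filters for method {method!r}")


def _apply_k(uncleaned: Recording, method: str,
             filters: sub.SpatialFilterSet, k: int) -> Recording:
    if method == "ssp":
        return sub.apply_projection(uncleaned, filters, k)
    return sub.remove_components(uncleaned, filters, k)


def component_count_curves(uncleaned: Recording, method: str, condition: str,
                           filters: sub.SpatialFilterSet | None = None,
                           k_max: int = K_GRID_MAX) -> pd.DataFrame:
    """RI(k), INPSR(k) and SNR(k) for k = 1..k_max for one subspace method.

    The metrics only involve the three channels of interest, so the cleaned
    data are reconstructed incrementally on those channels (a rank-1 update
    per k) instead of back-projecting the full montage at every k.
    """
    if filters is None:
        filters = _component_filters(uncleaned, method)
    coi = uncleaned.channels_of_interest(condition)
    k_max = min(k_max, filters.n_components)
    idx_all = uncleaned.picks(labels=filters.channels)
    X = uncleaned.data[idx_all]
    # rows of the filter channel list corresponding to the channels of interest
    coi_rows = [filters.channels.index(c) for c in coi]
    if method == "ssp":
        U, _ = np.linalg.qr(filters.filters[:k_max].T)
        comps = U.T @ X
        mix_rows = U[coi_rows]
    else:
        comps = filters.filters @ X
        mix_rows = filters.patterns[coi_rows][:, :k_max]

    unc_coi = Recording(X[coi_rows], uncleaned.srate, list(coi),
                        ["esg_cervical"] * len(coi),
                        uncleaned.events)
    cleaned_coi = unc_coi.data.copy()
    rows = []
    for k in range(1, k_max + 1):
        cleaned_coi = cleaned_coi - np.outer(mix_rows[:, k - 1], comps[k - 1])
        cl = Recording(cleaned_coi, uncleaned.srate, list(coi),
                       ["esg_cervical"] * len(coi), uncleaned.events)
        ep = epoch(cl, "stimulus", *SEP_EPOCH_WINDOW,
                   baseline=met.SNR_BASELINE, condition=condition)
        rows.append({"k": k,
                     "ri": met.residual_intensity(cl, unc_coi, coi),
                     "inpsr": met.inpsr(cl, unc_coi, coi),
                     "snr": met.sep_snr(ep, condition, channels=coi)})
    return pd.DataFrame(rows)


def auto_component_count(uncleaned: Recording, method: str, condition: str,
                         filters: sub.SpatialFilterSet | None = None,
                         k_max: int = K_GRID_MAX) -> sub.CountSelection:
    curves = component_count_curves(uncleaned, method, condition, filters, k_max)
    return sub.select_component_count(curves["k"], curves["ri"],
                                      curves["inpsr"], curves["snr"])


def clean(uncleaned: Recording, method: str, config: RunConfig | None = None,
          condition: str = "median") -> Recording:
    """Dispatch one cardiac-cleaning method on Uncleaned data."""
    cfg = config or RunConfig()
    if method == "pca_obs":
        return pca_obs.clean_recording(uncleaned, n_pcs=cfg.n_pcs,
                                       taper=cfg.taper)
    if method == "ica":
        cleaned, _, _ = ica_mod.clean_recording(uncleaned, seed=cfg.seed,
                                                threshold=cfg.ctps_threshold)
        return cleaned
    if method in ("ssp", "cca", "dss"):
        filters = _component_filters(uncleaned, method)
        if cfg.k == "auto":
            sel = auto_component_count(uncleaned, method, condition, filters)
            k = sel.chosen
            logger.info("%s/%s: auto-selected k=%d (RI %d, INPSR %d, SNR %d)",
                        method, condition, k, sel.idx_ri, sel.idx_inpsr,
                        sel.idx_snr)
        else:
            k = int(cfg.k)
        return _apply_k(uncleaned, method, filters, k)
    raise ValueError(f"unknown cleaning method {method!r}")


def evaluate(cleaned: Recording, uncleaned: Recording, method: str,
             condition: str) -> met.MetricReport:
    """RI, INPSR and SEP SNR of one cleaned recording for one condition."""
    coi = uncleaned.channels_of_interest(condition)
    ep = epoch(cleaned, "stimulus", *SEP_EPOCH_WINDOW,
               baseline=met.SNR_BASELINE, condition=condition)
    return met.MetricReport(
        method=method, condition=condition,
        ri=met.residual_intensity(cleaned, uncleaned, coi),
        inpsr_log=met.inpsr(cleaned, uncleaned, coi),
        snr=met.sep_snr(ep, condition, channels=coi),
        channels_used=coi)


def enhance_recording(rec: Recording, method: str, condition: str
                      ) -> enh.EnhancedSep:
    """Run CCA-SEP or DSS-SEP on one condition of a (possibly cleaned) recording."""
    ep = epoch(rec, "stimulus", *SEP_EPOCH_WINDOW, baseline=met.SNR_BASELINE,
               condition=condition, picks=rec.patch_picks(condition))
    if method == "cca_sep":
        return enh.cca_sep(ep, condition)
    if method == "dss_sep":
        return enh.dss_sep(ep, rec, condition)
    raise ValueError(f"unknown enhancement method {method!r}")


def run_pipeline(uncleaned: Recording, config: RunConfig | None = None
                 ) -> dict:
    """Full run: clean with every method, evaluate, rank, optionally enhance.

    Returns a dict with per-condition MetricReports, RankTables, enhancement
    metrics (SNR/CoV before and after), and a reproducibility manifest.
    """
    cfg = config or RunConfig()
    results: dict = {"reports": {}, "ranks": {}, "enhanced": {},
                     "manifest": {"seed": cfg.seed, "methods": list(cfg.methods),
                                  "k": cfg.k, "n_pcs": cfg.n_pcs,
                                  "taper": cfg.taper,
                                  "ctps_threshold": cfg.ctps_threshold}}
    uncleaned_snr = {}
    for cond in cfg.conditions:
        coi = uncleaned.channels_of_interest(cond)
        ep_u = epoch(uncleaned, "stimulus", *SEP_EPOCH_WINDOW,
                     baseline=met.SNR_BASELINE, condition=cond)
        uncleaned_snr[cond] = met.sep_snr(ep_u, cond, channels=coi)
    results["uncleaned_snr"] = uncleaned_snr

    cleaned_cache: dict = {}
    for cond in cfg.conditions:
        reports = []
        for method in cfg.methods:
            key = (method, cond if method in ("ssp", "cca", "dss")
                   and cfg.k == "auto" else "shared")
            if key not in cleaned_cache:
                cleaned_cache[key] = clean(uncleaned, method, cfg, condition=cond)
            reports.append(evaluate(cleaned_cache[key], uncleaned, method, cond))
        results["reports"][cond] = reports
        results["ranks"][cond] = met.rank_methods(reports)

    for cond in cfg.conditions:
        for emethod in cfg.enhance_methods:
            es = enhance_recording(uncleaned, emethod, cond)
            ep_u = epoch(uncleaned, "stimulus", *SEP_EPOCH_WINDOW,
                         baseline=met.SNR_BASELINE, condition=cond,
                         picks=uncleaned.patch_picks(cond))
            centre = uncleaned.channels_of_interest(cond)[1]
            results["enhanced"][(cond, emethod)] = {
                "snr_before": uncleaned_snr[cond],
                "snr_after": met.sep_snr(es, cond),
                "cov_before": met.single_trial_cov(ep_u, cond, channel=centre),
                "cov_after": met.single_trial_cov(es, cond),
                "polarity_inverted": es.polarity_inverted,
                "score": es.score}
    return results


def report_frame(results: dict) -> pd.DataFrame:
    """Flatten pipeline results into the report table written by the CLI."""
    rows = []
    for cond, reports in results["reports"].items():
        rank = results["ranks"][cond].table
        for r in reports:
            rows.append({"method": r.method, "condition": cond, "ri": r.ri,
                         "inpsr_log": r.inpsr_log, "snr": r.snr,
                         "rank_ri": rank.loc[r.method, "rank_ri"],
                         "rank_inpsr": rank.loc[r.method, "rank_inpsr"],
                         "rank_snr": rank.loc[r.method, "rank_snr"],
                         "overall": rank.loc[r.method, "overall"]})
    return pd.DataFrame(rows)


def write_outputs(results: dict, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report_frame(results).to_csv(out / "report.tsv", sep="\t", index=False)
    enh_rows = [{"condition": c, "method": m, **{k: v for k, v in d.items()}}
                for (c, m), d in results["enhanced"].items()]
    if enh_rows:
        pd.DataFrame(enh_rows).to_csv(out / "enhancement.tsv", sep="\t",
                                      index=False)
    with open(out / "manifest.json", "w") as f:
        json.dump(results["manifest"], f, indent=2)
    return out
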