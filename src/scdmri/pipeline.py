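"""End-to-end experiment orchestration and report tables.

``run_experiment`` simulates (or consumes) a cohort, runs the
appropriate estimator per protocol (tensor route for full-rank schemes,
two-direction route otherwise), computes every ROI statistic, and emits
tidy tables: per-ROI mean metrics, inter-/intra-subject CV,
best-protocol-per-cell, effect-size/p comparison tables, and SNR/CNR.
All outputs are deterministic for a fixed configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import phantom as ph
from . import stats as st
from .dwi_io import RoiSet, ROI_NAMES, DWIStudy
from .estimators import (fit_tensor, tensor_metrics, fit_adc_per_direction,
                         two_direction_metrics, angular_deviation)
from .phantom import PhantomSpec, TissueParams, make_cohort, Cohort
from .schemes import (AcquisitionProtocol, builtin_protocol,
                      protocol_from_config, is_tensor_estimable)

__all__ = [
    "ExperimentConfig", "ReportBundle",
    "run_experiment", "compute_subject_table", "metric_maps",
    "best_protocol_table", "comparison_tables", "write_report",
    "config_from_yaml",
]

log = logging.getLogger("scdmri")

METRICS = ("FA", "MD", "AD", "RD")


@dataclass
class ExperimentConfig:
    """Validated experiment description (see ``config_from_yaml``)."""

    protocols: list = field(default_factory=lambda: ["A", "B", "C"])
    n_per_group: int = 7
    groups: tuple = ph.GROUPS
    timepoints: tuple = ph.TIMEPOINTS
    seed: int = 0
    fit_method: str = "wls"
    phantom: dict = field(default_factory=dict)

    def __post_init__(self):
        self.groups = tuple(self.groups)
        self.timepoints = tuple(self.timepoints)
        if self.fit_method not in ("ols", "wls"):
            raise ValueError("fit_method must be 'ols' or 'wls'")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not self.protocols:
            raise ValueError("at least one protocol is required")
        for tp in self.timepoints:
            if tp not in ph.TIMEPOINTS:
                raise ValueError(f"unknown timepoint {tp!r}")
        for g in self.groups:
            if g not in ph.GROUPS:
                raise ValueError(f"unknown group {g!r}")
        self.phantom_spec()      # validate eagerly
        self.protocol_objects()

    def phantom_spec(self) -> PhantomSpec:
        cfg = dict(self.phantom)
        if "grid" in cfg:
            cfg["grid"] = tuple(cfg["grid"])
        if "voxel_size" in cfg:
            cfg["voxel_size"] = tuple(cfg["voxel_size"])
        tissue = cfg.pop("tissue_params", None)
        if tissue is not None:
            base = ph.default_tissue_params()
            for roi, params in tissue.items():
                base[roi] = TissueParams(**{**asdict(base[roi]), **params})
            cfg["tissue_params"] = base
        return PhantomSpec(**cfg)

    def protocol_objects(self) -> list:
        objs = []
        for p in self.protocols:
            if isinstance(p, AcquisitionProtocol):
                objs.append(p)
            elif isinstance(p, dict):
                objs.append(protocol_from_config(p))
            else:
                objs.append(builtin_protocol(str(p), seed=self.seed + 2016))
        return objs

    def to_dict(self) -> dict:
        d = {
            "protocols": [p.name if isinstance(p, AcquisitionProtocol) else p
                          for p in self.protocols],
            "n_per_group": self.n_per_group,
            "groups": list(self.groups),
            "timepoints": list(self.timepoints),
            "seed": self.seed,
            "fit_method": self.fit_method,
            "phantom": self.phantom,
        }
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def config_from_yaml(path) -> ExperimentConfig:
    """Load and validate an experiment config from a YAML document."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return ExperimentConfig(**raw)


def metric_maps(study: DWIStudy, rois: RoiSet, method: str = "wls") -> dict:
    """Metric maps for one study; route chosen by scheme rank.

    Tensor-estimable schemes yield FA/MD/AD/RD plus the angular
    deviation ``theta``; two-direction schemes yield the four metrics
    from the slice/read ADC formulas (no ``theta``).
    """
    mask = rois.cord_mask()
    if is_tensor_estimable(study.scheme):
        fitted = fit_tensor(study, mask=mask, method=method)
        tm = tensor_metrics(fitted)
        return {"FA": tm.fa, "MD": tm.md, "AD": tm.ad, "RD": tm.rd,
                "theta": angular_deviation(tm.v1)}
    adc_s = fit_adc_per_direction(study, "slice", mask=mask)
    adc_r = fit_adc_per_direction(study, "read", mask=mask)
    est = two_direction_metrics(adc_s, adc_r)
    return {"FA": est.fa, "MD": est.md, "AD": est.ad, "RD": est.rd}


def compute_subject_table(cohort: Cohort, method: str = "wls") -> pd.DataFrame:
    """Per-(protocol, subject, timepoint, roi, metric) ROI summaries."""
    rows = []
    for study in cohort.studies:
        t0 = time.perf_counter()
        maps = metric_maps(study, cohort.rois, method=method)
        meta = study.meta
        for metric, volume in maps.items():
            for roi in ROI_NAMES:
                values = volume[cohort.rois.mask(roi)]
                values = values[np.isfinite(values)]
                if values.size == 0:
                    continue
                rows.append(dict(
                    protocol=meta.get("protocol"),
                    subject=meta.get("subject"),
                    group=meta.get("group"),
                    timepoint=meta.get("timepoint"),
                    roi=roi, metric=metric,
                    mean=float(values.mean()),
                    sd=float(np.std(values, ddof=1)) if values.size > 1
                    else 0.0,
                    n_voxels=int(values.size),
                ))
        log.debug("fitted %s/%s/%s in %.2fs", meta.get("subject"),
                  meta.get("timepoint"), meta.get("protocol"),
                  time.perf_counter() - t0)
    return pd.DataFrame(rows)


def snr_cnr_table(cohort: Cohort, method: str = "wls") -> pd.DataFrame:
    """Raw-image SNR and metric-map CNR, averaged over WT subjects."""
    rois = cohort.rois
    wm = rois.mask("wholeWM")
    gm = rois.mask("wholeGM")
    bg = rois.label_map == 0
    rows = []
    for study in cohort.studies:
        if study.meta.get("group") != "WT":
            continue
        entry = dict(protocol=study.meta.get("protocol"),
                     subject=study.meta.get("subject"),
                     timepoint=study.meta.get("timepoint"))
        b0 = study.b0_volumes().mean(axis=3)
        dwi = study.weighted_volumes().mean(axis=3)
        for quantity, vol, tissue in (("snr_wm_b0", b0, wm),
                                      ("snr_gm_b0", b0, gm),
                                      ("snr_wm_dwi", dwi, wm),
                                      ("snr_gm_dwi", dwi, gm)):
            try:
                value = st.snr(vol, tissue, bg)
            except ValueError:
                value = np.nan
            rows.append(dict(entry, quantity=quantity, value=value))
        maps = metric_maps(study, rois, method=method)
        for metric in METRICS:
            try:
                value = st.cnr(maps[metric], wm, gm)
            except ValueError:
                value = np.nan
            rows.append(dict(entry, quantity=f"cnr_{metric.lower()}",
                             value=value))
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    return (df.groupby(["protocol", "quantity"], as_index=False)["value"]
            .mean())


def cv_tables(subject_table: pd.DataFrame) -> pd.DataFrame:
    """Inter- and intra-subject CV per (protocol, metric, roi, group,
    timepoint); tidy with a ``cv_kind`` column."""
    rows = []
    keys = ["protocol", "metric", "roi", "group", "timepoint"]
    for key, grp in subject_table.groupby(keys, sort=True):
        if len(grp) < 2 or grp["metric"].iloc[0] == "theta":
            continue
        entry = dict(zip(keys, key))
        rows.append(dict(entry, cv_kind="inter",
                         cv=st.cv_inter(grp["mean"].to_numpy()),
                         n_subjects=len(grp)))
        per_subject = (grp["sd"] / grp["mean"].abs()).to_numpy()
        rows.append(dict(entry, cv_kind="intra",
                         cv=float(np.mean(per_subject)),
                         n_subjects=len(grp)))
    return pd.DataFrame(rows)


def mean_metrics_table(subject_table: pd.DataFrame) -> pd.DataFrame:
    keys = ["protocol", "metric", "roi", "group", "timepoint"]
    agg = (subject_table.groupby(keys, sort=True)
           .agg(n_subjects=("subject", "nunique"),
                mean=("mean", "mean"),
                sd=("mean", lambda v: float(np.std(v, ddof=1))))
           .reset_index())
    return agg


def best_protocol_table(cv_table: pd.DataFrame, ndir_map: dict,
                        group: str = "WT") -> pd.DataFrame:
    """Per (cv_kind, metric, roi, timepoint): the protocol with minimum
    CV in the reference group.  Exact ties are broken toward fewer
    diffusion directions and reported in the ``tie`` column."""
    sub = cv_table[cv_table["group"] == group]
    rows = []
    keys = ["cv_kind", "metric", "roi", "timepoint"]
    for key, grp in sub.groupby(keys, sort=True):
        if grp["protocol"].nunique() < 2:
            raise ValueError(
                f"cell {dict(zip(keys, key))} has fewer than 2 protocols")
        best_cv = grp["cv"].min()
        winners = grp.loc[grp["cv"] == best_cv, "protocol"].tolist()
        tie = len(winners) > 1
        winner = min(winners, key=lambda p: ndir_map.get(p, np.inf))
        rows.append(dict(zip(keys, key), best=winner, cv=float(best_cv),
                         tie=tie))
    return pd.DataFrame(rows)


def comparison_tables(subject_table: pd.DataFrame,
                      timepoints=ph.TIMEPOINTS,
                      groups=ph.GROUPS) -> pd.DataFrame:
    """Effect-size + Mann-Whitney tables for the standard contrasts:
    case group vs control at each timepoint, and late vs early timepoint
    within each group (reference: control group / early timepoint)."""
    contrasts = []
    if len(groups) == 2:
        case_g, ctrl_g = groups[1], groups[0]
        if groups[0] == "G93A":
            case_g, ctrl_g = groups[0], groups[1]
        for tp in timepoints:
            contrasts.append((f"{case_g}_vs_{ctrl_g}_{tp}",
                              dict(group=case_g, timepoint=tp),
                              dict(group=ctrl_g, timepoint=tp)))
    if len(timepoints) == 2:
        early, late = timepoints
        for g in groups:
            contrasts.append((f"{g}_{late}_vs_{early}",
                              dict(group=g, timepoint=late),
                              dict(group=g, timepoint=early)))

    sub = subject_table[subject_table["metric"].isin(METRICS)]
    rows = []
    for name, case_sel, ctrl_sel in contrasts:
        for (protocol, metric, roi), grp in sub.groupby(
                ["protocol", "metric", "roi"], sort=True):
            case = grp
            for k, v in case_sel.items():
                case = case[case[k] == v]
            ctrl = grp
            for k, v in ctrl_sel.items():
                ctrl = ctrl[ctrl[k] == v]
            if case.empty or ctrl.empty:
                log.warning("contrast %s: missing group for %s/%s/%s — "
                            "skipped", name, protocol, metric, roi)
                continue
            x = case["mean"].to_numpy()
            y = ctrl["mean"].to_numpy()
            try:
                es = st.effect_size(x, y)
            except ValueError as exc:
                raise ValueError(
                    f"effect size failed in cell (contrast={name}, "
                    f"protocol={protocol}, metric={metric}, roi={roi}): {exc}"
                ) from exc
            _, p = st.mann_whitney(x, y)
            rows.append(dict(contrast=name, protocol=protocol, metric=metric,
                             roi=roi, es=es, p=p, significant=p < 0.05))
    return pd.DataFrame(rows)


@dataclass
class ReportBundle:
    """All report tables produced by one experiment run."""

    mean_metrics: pd.DataFrame
    cv: pd.DataFrame
    best_protocol: pd.DataFrame
    comparisons: pd.DataFrame
    snr_cnr: pd.DataFrame
    subject_table: pd.DataFrame
    config_hash: str = ""
    seed: int = 0

    def tables(self) -> dict:
        return {"mean_metrics": self.mean_metrics, "cv": self.cv,
                "best_protocol": self.best_protocol,
                "comparisons": self.comparisons, "snr_cnr": self.snr_cnr,
                "subject_table": self.subject_table}


def run_experiment(config: ExperimentConfig,
                   cohort: Cohort | None = None) -> ReportBundle:
    """Run the full experiment: simulate, fit, analyze, tabulate.

    An existing cohort may be supplied to skip simulation.
    """
    spec = config.phantom_spec()
    protocols = config.protocol_objects()
    t0 = time.perf_counter()
    if cohort is None:
        cohort = make_cohort(spec, config.n_per_group,
                             timepoints=config.timepoints,
                             protocols=protocols, seed=config.seed,
                             groups=config.groups)
        log.info("simulated %d studies in %.1fs", len(cohort.studies),
                 time.perf_counter() - t0)
    t1 = time.perf_counter()
    subject_table = compute_subject_table(cohort, method=config.fit_method)
    log.info("fitted cohort in %.1fs", time.perf_counter() - t1)

    cv = cv_tables(subject_table)
    ndir_map = {p.name: p.scheme.n_weighted for p in protocols}
    if len(protocols) >= 2 and "WT" in config.groups:
        best = best_protocol_table(cv, ndir_map)
    else:
        best = pd.DataFrame()
    comparisons = comparison_tables(subject_table,
                                    timepoints=config.timepoints,
                                    groups=config.groups)
    snr_cnr = snr_cnr_table(cohort, method=config.fit_method)
    return ReportBundle(mean_metrics=mean_metrics_table(subject_table),
                        cv=cv, best_protocol=best, comparisons=comparisons,
                        snr_cnr=snr_cnr, subject_table=subject_table,
                        config_hash=config.hash(), seed=config.seed)


def write_report(bundle: ReportBundle, out_dir) -> dict:
    """Write every table as TSV with a provenance comment header."""
    import os
    os.makedirs(out_dir, exist_ok=True)
    header = (f"# scdmri report\n# config_hash: {bundle.config_hash}\n"
              f"# seed: {bundle.seed}\n")
    paths = {}
    for name, df in bundle.tables().items():
        path = os.path.join(out_dir, f"{name}.tsv")
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False, float_format="%.10g")
        paths[name] = path
    return paths
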