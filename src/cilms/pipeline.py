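"""End-to-end orchestration: simulate/load -> calibrate -> pair-pick ->
align -> filter -> normalize -> identify -> statistics -> cascade.

Each stage reads and writes the plain-text interchange formats, so any
stage can be re-run in isolation from its serialized inputs.  A run
manifest (config hash, seed, stage outputs) makes reruns verifiable:
the same config and seed reproduce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import chem, classify, stats
from . import pairpick as pp
from . import synthetic as syn
from .align import (FeatureTable, align as align_pairs, presence_filter,
                    normalize_ratios, identify, read_library)
from .meta import read_metadata, TIME_WINDOWS

log = logging.getLogger("cilms")


@dataclass
class PipelineConfig:
    workdir: str = "cohort"
    outdir: str = "results"
    biofluid: str = "CSF"
    simulate: bool = True
    seed: int = 0
    # pair picking
    pair_ppm_tol: float = 5.0
    pair_rt_tol: float = 6.0
    calib_match_ppm: float = 20.0
    min_intensity: float = 0.0
    # alignment / identification
    align_ppm_tol: float = 5.0
    align_rt_tol: float = 20.0
    presence_min_frac: float = 0.5
    normalize: str = "sample_median"
    id_ppm_tol: float = 5.0
    id_rt_tol: float = 30.0
    # statistics
    fc_threshold: float = 1.5
    p_threshold: float = 0.05
    vip_threshold: float = 1.5
    n_permutations: int = 20
    pattern_epsilon: float = 0.1
    # classification
    max_panel: int = 6
    synthetic: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("pair_ppm_tol", "pair_rt_tol", "align_ppm_tol",
                     "align_rt_tol", "presence_min_frac", "fc_threshold",
                     "p_threshold", "vip_threshold", "pattern_epsilon"):
            if getattr(self, name) <= 0 and name != "pattern_epsilon":
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def qc_monitor(table: FeatureTable, warn_tol: float = 0.2) -> pd.DataFrame:
    """Per-QC-run drift summary: median ratio, deviation from the
    nominal 1:1 mix, and a warning flag when |median - 1| exceeds
    ``warn_tol``."""
    qc_ids = [s.sample_id for s in table.samples if s.is_qc]
    if not qc_ids:
        raise ValueError("no QC samples in table")
    rows = []
    for sid in qc_ids:
        med = float(table.values[sid].median(skipna=True))
        rows.append((sid, med, med - 1.0, abs(med - 1.0) > warn_tol))
    return pd.DataFrame(rows, columns=["sample_id", "median_ratio",
                                       "deviation", "warning"])


def concat_biofluids(table_csf: FeatureTable, table_serum: FeatureTable
                     ) -> FeatureTable:
    """Concatenate CSF and serum feature tables by patient and time
    window for combined-panel classification.

    Only patient-time combinations present in both fluids are kept;
    feature ids are prefixed with the biofluid to stay unique.  The
    merged table reuses the CSF arm's sample identities.
    """
    key = {}
    for t, fluid in ((table_csf, "CSF"), (table_serum, "serum")):
        for s in t.samples:
            if not s.is_qc:
                key.setdefault((s.patient_id, s.time_window), {})[fluid] = s
    shared = sorted(k for k, v in key.items() if len(v) == 2)
    if not shared:
        raise ValueError("no patient-time overlap between biofluids")
    metas = [key[k]["CSF"] for k in shared]
    cols_csf = [key[k]["CSF"].sample_id for k in shared]
    cols_ser = [key[k]["serum"].sample_id for k in shared]
    vals_ser = table_serum.values[cols_ser].copy()
    vals_ser.columns = cols_csf
    values = pd.concat([table_csf.values[cols_csf], vals_ser],
                       ignore_index=True)
    feats = []
    for t, fluid in ((table_csf, "CSF"), (table_serum, "serum")):
        f = t.features.copy()
        f["feature_id"] = fluid + ":" + f["feature_id"].astype(str)
        f["identity"] = [None if i is None or pd.isna(i) else f"{fluid}:{i}"
                         for i in f["identity"]]
        feats.append(f)
    features = pd.concat(feats, ignore_index=True)
    return FeatureTable(values, features, metas)


def build_feature_table(config: PipelineConfig):
    """Stages simulate..identify for one biofluid; returns the
    normalized, identified feature table plus intermediates."""
    if config.simulate:
        try:
            syn_cfg = syn.CohortConfig(seed=config.seed, **config.synthetic)
            cohort = syn.generate_cohort(syn_cfg)
            syn.write_cohort(cohort, config.workdir)
        except Exception as exc:
            raise StageError("simulate", exc) from exc
    try:
        samples = read_metadata(os.path.join(config.workdir, "metadata.csv"))
    except Exception as exc:
        raise StageError("load-metadata", exc) from exc
    samples = [s for s in samples if s.biofluid == config.biofluid]
    anchors = chem.default_calibrant_mzs()
    pair_lists = {}
    for s in samples:
        path = os.path.join(config.workdir, f"{s.sample_id}.tsv")
        try:
            flist = pp.FeatureList.read_tsv(path, s.sample_id)
            model = pp.calibrate(flist, anchors, config.calib_match_ppm)
            flist = pp.apply_calibration(flist, model)
            pairs = pp.detect_pairs(flist, config.pair_ppm_tol,
                                    config.pair_rt_tol)
            pair_lists[s.sample_id] = pp.pair_level_filter(
                pairs, config.min_intensity)
        except Exception as exc:
            raise StageError(f"pairpick:{s.sample_id}", exc) from exc
        log.info("run %s: %d pairs", s.sample_id, len(pair_lists[s.sample_id]))
    try:
        table = align_pairs(pair_lists, config.align_rt_tol,
                         config.align_ppm_tol, samples=samples)
        table = presence_filter(table, config.presence_min_frac)
        table = normalize_ratios(table, config.normalize)
        library = read_library(os.path.join(config.workdir, "library.csv"))
        table = identify(table, library, config.id_ppm_tol, config.id_rt_tol)
    except Exception as exc:
        raise StageError("align-identify", exc) from exc
    return table, pair_lists


def run_stats(table: FeatureTable, config: PipelineConfig) -> dict:
    """Venn selection, temporal-pattern calls and time-resolved PLS-DA."""
    comparisons = {g: stats.grade_vs_control(table, g, "t1")
                   for g in ("A", "B", "C")}
    venn = stats.venn_select(comparisons, config.fc_threshold,
                             config.p_threshold)
    names = stats._feature_names(table)
    log_vals = np.log2(table.values)
    ids_n = [s.sample_id for s in table.samples if s.grade == "N" and not s.is_qc]
    patterns = []
    for i, name in enumerate(names):
        ctrl = float(np.nanmean(log_vals[ids_n].iloc[i]))
        t_means = []
        for tw in TIME_WINDOWS:
            ids_t = [s.sample_id for s in table.samples
                     if s.time_window == tw and not s.is_qc]
            t_means.append(float(np.nanmean(log_vals[ids_t].iloc[i])))
        patterns.append(stats.classify_temporal_pattern(
            name, ctrl, tuple(t_means), config.pattern_epsilon))
    # PLS-DA over time windows on injured samples
    ids_inj = [s.sample_id for s in table.samples
               if s.grade in "ABC" and not s.is_qc]
    tw_labels = {s.sample_id: s.time_window for s in table.samples}
    X = stats.impute_half_min(table.values[ids_inj]).to_numpy().T
    X = stats.autoscale(np.log2(X))
    y = [tw_labels[i] for i in ids_inj]
    model = stats.plsda_fit(X, y, n_components=2, seed=config.seed)
    valid, perm_r2, perm_q2 = stats.permutation_validate(
        X, y, n_components=2, n_perm=config.n_permutations, seed=config.seed)
    return {"comparisons": comparisons, "venn": venn, "patterns": patterns,
            "plsda": model, "plsda_valid": valid,
            "perm_r2": perm_r2, "perm_q2": perm_q2}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle + manifest."""
    os.makedirs(config.outdir, exist_ok=True)
    table, pair_lists = build_feature_table(config)
    table_path = os.path.join(config.outdir,
                              f"feature_table_{config.biofluid}.csv")
    table.to_csv(table_path)
    qc = qc_monitor(table)
    qc.to_csv(os.path.join(config.outdir, "qc_monitor.csv"), index=False)
    try:
        st = run_stats(table, config)
    except Exception as exc:
        raise StageError("stats", exc) from exc
    try:
        cascade = classify.cascade_loocv(table, max_features=config.max_panel)
    except Exception as exc:
        raise StageError("classify", exc) from exc
    report = {
        "biofluid": config.biofluid,
        "n_features": table.n_features,
        "n_samples": table.n_samples,
        "n_venn_selected": sum(len(v) for v in st["venn"].values()),
        "plsda_r2": st["plsda"].r2,
        "plsda_q2": st["plsda"].q2,
        "plsda_valid": st["plsda_valid"],
        "n_pattern1": sum(p.pattern == "pattern1" for p in st["patterns"]),
        "n_pattern2": sum(p.pattern == "pattern2" for p in st["patterns"]),
        "cascade": {
            "step1_features": list(cascade.step1_features),
            "step2_features": list(cascade.step2_features),
            "confusion": cascade.confusion.to_dict(),
            "step1_accuracy": cascade.step1_accuracy,
            "step2_accuracy": cascade.step2_accuracy,
            "overall_accuracy": cascade.overall_accuracy,
        },
        "qc_warnings": int(qc["warning"].sum()),
    }
    with open(os.path.join(config.outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1)
    cascade.predictions.to_csv(
        os.path.join(config.outdir, "loocv_predictions.tsv"),
        sep="\t", index=False)
    manifest = {
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(dataclasses.asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "feature_table_hash": _hash_file(table_path),
    }
    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    report["manifest"] = manifest
    return report
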