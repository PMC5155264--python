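"""Ground-truthed synthetic cohorts for the differential-labeling pipeline.

Emulates the clinical study design end to end: 30 injured patients
(10 AIS A, 12 B, 8 C) sampled in three post-injury windows plus
non-injured controls and interleaved QC runs, in two biofluids.  Every
labeled metabolite appears in each run as a co-eluting 12C/13C peak
pair; the heavy channel carries the pooled-reference level, the light
channel the sample's true level, so the pair ratio encodes the injected
group structure (severity-ordered markers, temporal patterns 1 and 2).
Mass error is ppm-scale with a per-run calibration offset recoverable
from spiked calibrant ions; intensities carry log-normal noise; runs
contain unpaired background peaks and randomly missing features.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np

from . import chem
from .align import LibraryEntry, write_library
from .meta import SampleMeta, TIME_WINDOWS, write_metadata
from .pairpick import FeatureList

PATTERNS = ("pattern1_up", "pattern1_down", "pattern2", "flat")

#: log2-effect time course per pattern, as a fraction of the full effect
#: at (t1, t2, t3).  Pattern 1 drifts monotonically away from the
#: non-injured level; pattern 2 peaks acutely at t1 and restores.
PATTERN_PROFILE = {
    "pattern1_up": (1 / 3, 2 / 3, 1.0),
    "pattern1_down": (1 / 3, 2 / 3, 1.0),
    "pattern2": (1.0, 0.45, 0.1),
    "flat": (0.0, 0.0, 0.0),
}

#: full |log2 FC| of severity markers per grade (A > B > C)
SEVERITY_EFFECTS = {"A": 1.6, "B": 1.0, "C": 0.5}


@dataclass(frozen=True)
class GroundTruthMetabolite:
    name: str
    base_mass_labeled_1tag_z1: float  # m/z of the 1-tag, z=1 light ion (Th)
    n_tags: int
    charge: int
    reference_rt: float               # seconds
    control_level: float              # arbitrary concentration units
    group_fold_changes: dict          # (grade, time_window) -> linear FC
    temporal_pattern: str
    severity_marker: bool

    def fold_change(self, grade: str, time_window: str) -> float:
        if grade == "N" or time_window == "none":
            return 1.0
        return self.group_fold_changes[(grade, time_window)]


@dataclass
class CohortConfig:
    """Study-design and noise parameters of the synthetic cohort."""
    n_patients_per_grade: dict = field(
        default_factory=lambda: {"A": 10, "B": 12, "C": 8})
    n_controls: int = 8
    n_metabolites: int = 60
    n_severity_markers: int = 6
    pattern_proportions: dict = field(
        default_factory=lambda: {"pattern1_up": 0.15, "pattern1_down": 0.15,
                                 "pattern2": 0.40, "flat": 0.30})
    effect_log2_range: tuple = (0.8, 2.0)   # |log2 FC| of non-marker effects
    ppm_noise_sd: float = 2.0               # marginal m/z error per peak (ppm)
    run_offset_ppm: float = 8.0             # per-run calibration offset bound
    rt_jitter_sd: float = 4.0               # between-run RT jitter (s)
    coelution_rt_sd: float = 0.5            # light/heavy RT offset (s)
    intensity_cv: float = 0.15              # log-normal CV per channel
    missing_rate: float = 0.05
    n_background_peaks: int = 200
    qc_interval: int = 20                   # QC run after every N samples
    biofluids: tuple = ("CSF", "serum")
    mz_range: tuple = (280.0, 780.0)        # 1-tag z=1 light m/z draw window
    rt_range: tuple = (100.0, 1500.0)       # gradient elution window (s)
    seed: int = 0

    def __post_init__(self):
        for name in ("missing_rate",):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        if abs(sum(self.pattern_proportions.values()) - 1) > 1e-9:
            raise ValueError("pattern proportions must sum to 1")


@dataclass
class Cohort:
    feature_lists: dict                     # sample_id -> FeatureList
    samples: list                           # SampleMeta, acquisition order
    library: list                           # LibraryEntry per metabolite
    truths: list                            # GroundTruthMetabolite
    truth_record: dict                      # JSON-serializable ground truth


def _rng(config: CohortConfig, stage: int, *extra) -> np.random.Generator:
    """Independent deterministic stream per stage (and optional key)."""
    return np.random.default_rng([config.seed & 0x7FFFFFFF, stage, *extra])


def generate_truth(config: CohortConfig, n_metabolites: int | None = None
                   ) -> list[GroundTruthMetabolite]:
    """Draw the ground-truth metabolite panel.

    The first ``n_severity_markers`` metabolites are severity markers:
    pattern-2 trajectories whose t1 effect magnitudes are ordered
    A > B > C.  Remaining metabolites receive a pattern from the
    configured proportions with one shared effect size across grades.
    """
    n = config.n_metabolites if n_metabolites is None else n_metabolites
    if n < 1:
        raise ValueError("n_metabolites must be >= 1")
    rng = _rng(config, 1)
    lo, hi = config.mz_range
    masses = np.sort(rng.uniform(lo, hi, n))
    # keep draws resolvable: enforce 0.2 Th spacing by redrawing collisions
    for _ in range(100):
        close = np.where(np.diff(masses) < 0.2)[0]
        if close.size == 0:
            break
        masses[close + 1] = rng.uniform(lo, hi, close.size)
        masses = np.sort(masses)
    tags = rng.choice([1, 2], size=n, p=[0.75, 0.25])
    charges = rng.choice([1, 2], size=n, p=[0.9, 0.1])
    rts = rng.uniform(*config.rt_range, size=n)
    levels = 10 ** rng.uniform(2.5, 5.0, size=n)
    pat_names = list(config.pattern_proportions)
    pat_probs = [config.pattern_proportions[k] for k in pat_names]
    truths = []
    for i in range(n):
        marker = i < config.n_severity_markers
        if marker:
            pattern = "pattern2"
            scale = rng.uniform(0.9, 1.1)
            mags = {g: SEVERITY_EFFECTS[g] * scale for g in "ABC"}
            sign = 1.0
        else:
            pattern = rng.choice(pat_names, p=pat_probs)
            mag = rng.uniform(*config.effect_log2_range) \
                if pattern != "flat" else 0.0
            sign = -1.0 if pattern == "pattern1_down" else \
                (1.0 if pattern != "pattern2" else rng.choice([-1.0, 1.0]))
            mags = {g: mag for g in "ABC"}
        profile = PATTERN_PROFILE[pattern]
        fcs = {(g, tw): float(2 ** (sign * mags[g] * profile[k]))
               for g in "ABC" for k, tw in enumerate(TIME_WINDOWS)}
        truths.append(GroundTruthMetabolite(
            name=f"M{i:03d}",
            base_mass_labeled_1tag_z1=float(masses[i]),
            n_tags=int(tags[i]), charge=int(charges[i]),
            reference_rt=float(rts[i]), control_level=float(levels[i]),
            group_fold_changes=fcs, temporal_pattern=str(pattern),
            severity_marker=marker))
    return truths


def design_samples(config: CohortConfig) -> list[SampleMeta]:
    """Acquisition list for one cohort: per biofluid, every patient at
    every time window, then controls, with a QC run interleaved after
    every ``qc_interval`` analytical runs."""
    samples = []
    for fluid in config.biofluids:
        run_count = 0
        qc_count = 0

        def push(s, analytical=True):
            nonlocal run_count, qc_count
            samples.append(s)
            if analytical:
                run_count += 1
                if config.qc_interval and run_count % config.qc_interval == 0:
                    qc_count += 1
                    samples.append(SampleMeta(
                        f"{fluid}_QC{qc_count:02d}", f"QC{qc_count:02d}",
                        "N", "none", fluid, is_qc=True))

        for grade, n_pat in config.n_patients_per_grade.items():
            for p in range(1, n_pat + 1):
                pid = f"{grade}{p:02d}"
                for tw in TIME_WINDOWS:
                    push(SampleMeta(f"{fluid}_{pid}_{tw}", pid, grade, tw, fluid))
        for c in range(1, config.n_controls + 1):
            pid = f"N{c:02d}"
            push(SampleMeta(f"{fluid}_{pid}", pid, "N", "none", fluid))
    return samples


def pooled_levels(truths, config: CohortConfig) -> np.ndarray:
    """Expected level of each metabolite in the pooled (UMS) sample: the
    mean over every individual patient-time and control sample."""
    out = np.empty(len(truths))
    n_pat = sum(config.n_patients_per_grade.values())
    total = n_pat * len(TIME_WINDOWS) + config.n_controls
    for i, t in enumerate(truths):
        s = config.n_controls * 1.0
        for g, n in config.n_patients_per_grade.items():
            for tw in TIME_WINDOWS:
                s += n * t.fold_change(g, tw)
        out[i] = t.control_level * s / total
    return out


def simulate_run(truths, meta: SampleMeta, config: CohortConfig) -> FeatureList:
    """Simulate the centroided feature list of one LC-MS run."""
    flist, _ = _simulate_run(truths, meta, config)
    return flist


def _simulate_run(truths, meta, config):
    if not truths:
        raise ValueError("truths must be non-empty")
    rng = _rng(config, 2, zlib.crc32(meta.sample_id.encode()))
    pooled = pooled_levels(truths, config)
    sigma = float(np.sqrt(np.log1p(config.intensity_cv ** 2)))
    run_offset = rng.uniform(-config.run_offset_ppm, config.run_offset_ppm)
    # split the marginal ppm error into a component shared by both peaks
    # of a pair (same scan, same calibration) and a small independent part
    shared_sd = 0.9 * config.ppm_noise_sd
    indep_sd = float(np.sqrt(max(config.ppm_noise_sd ** 2 - shared_sd ** 2, 0.0)))
    mzs, rts, ints = [], [], []
    emitted = []
    for i, t in enumerate(truths):
        if rng.random() < config.missing_rate:
            continue
        if meta.is_qc:
            level = pooled[i]
        else:
            level = t.control_level * t.fold_change(meta.grade, meta.time_window)
        light_i = level * np.exp(rng.normal(0, sigma) - sigma ** 2 / 2)
        heavy_i = pooled[i] * np.exp(rng.normal(0, sigma) - sigma ** 2 / 2)
        mz_l = chem.light_mz(t.base_mass_labeled_1tag_z1, t.n_tags, t.charge)
        mz_h = chem.heavy_mz(mz_l, t.n_tags, t.charge)
        e_shared = rng.normal(0, shared_sd) + run_offset
        for mz, inten in ((mz_l, light_i), (mz_h, heavy_i)):
            ppm = e_shared + rng.normal(0, indep_sd)
            mzs.append(mz * (1 + ppm * 1e-6))
            ints.append(inten)
        rt = t.reference_rt + rng.normal(0, config.rt_jitter_sd)
        rts.extend([rt, rt + rng.normal(0, config.coelution_rt_sd)])
        emitted.append(t.name)
    # spiked calibrant ions, carrying the run offset (tight ppm error)
    for theo in chem.default_calibrant_mzs():
        mzs.append(theo * (1 + (run_offset + rng.normal(0, 0.2)) * 1e-6))
        rts.append(rng.uniform(*config.rt_range))
        ints.append(10 ** rng.uniform(5, 6))
    # unpaired background singlets
    nb = config.n_background_peaks
    mzs.extend(rng.uniform(150.0, 1000.0, nb))
    rts.extend(rng.uniform(config.rt_range[0] - 50, config.rt_range[1] + 50, nb))
    ints.extend(10 ** rng.uniform(2.0, 4.5, nb))
    flist = FeatureList(meta.sample_id, np.array(mzs), np.array(rts),
                        np.array(ints))
    return flist, emitted


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full cohort: feature lists, metadata, dansyl library
    and the ground-truth record used for scoring."""
    truths = generate_truth(config)
    samples = design_samples(config)
    lists = {}
    emitted = {}
    for s in samples:
        flist, names = _simulate_run(truths, s, config)
        lists[s.sample_id] = flist
        emitted[s.sample_id] = names
    library = [LibraryEntry(t.name, t.base_mass_labeled_1tag_z1,
                            t.reference_rt) for t in truths]
    record = {
        "config": {**asdict(config),
                   "n_patients_per_grade": dict(config.n_patients_per_grade)},
        "metabolites": [
            {"name": t.name,
             "mz_light": chem.light_mz(t.base_mass_labeled_1tag_z1,
                                       t.n_tags, t.charge),
             "mz_heavy": chem.heavy_mz(
                 chem.light_mz(t.base_mass_labeled_1tag_z1, t.n_tags, t.charge),
                 t.n_tags, t.charge),
             "n_tags": t.n_tags, "charge": t.charge,
             "rt": t.reference_rt, "control_level": t.control_level,
             "pattern": t.temporal_pattern,
             "severity_marker": t.severity_marker,
             "log2_fc": {f"{g}:{tw}": float(np.log2(t.fold_change(g, tw)))
                         for g in "ABC" for tw in TIME_WINDOWS}}
            for t in truths],
        "emitted": emitted,
    }
    return Cohort(lists, samples, library, truths, record)


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write the cohort in the plain-text interchange formats: one TSV
    feature list per run, metadata CSV, library CSV and truth JSON."""
    import os
    os.makedirs(outdir, exist_ok=True)
    try:
        for sid, flist in cohort.feature_lists.items():
            flist.write_tsv(os.path.join(outdir, f"{sid}.tsv"))
        write_metadata(cohort.samples, os.path.join(outdir, "metadata.csv"))
        write_library(cohort.library, os.path.join(outdir, "library.csv"))
        with open(os.path.join(outdir, "truth.json"), "w") as fh:
            json.dump(cohort.truth_record, fh, indent=1)
    except OSError as exc:
        raise OSError(f"failed writing cohort to {outdir}: {exc}") from exc


def score_pair_recovery(pairs_by_run: dict, cohort: Cohort,
                        ppm_tol: float = 10.0, rt_tol: float = 20.0
                        ) -> dict:
    """Score detected peak pairs against the ground truth.

    Recovery is the fraction of emitted (metabolite, run) pairs matched
    by a detected pair within ``ppm_tol`` of the true light m/z and
    ``rt_tol`` seconds; the false rate is the fraction of detected pairs
    that match no emitted metabolite.
    """
    truth_by_name = {m["name"]: m for m in cohort.truth_record["metabolites"]}
    n_truth = n_found = n_pairs = n_false = 0
    for sid, pairs in pairs_by_run.items():
        names = cohort.truth_record["emitted"].get(sid, [])
        n_truth += len(names)
        n_pairs += len(pairs)
        matched = set()
        for p in pairs:
            hit = None
            for name in names:
                m = truth_by_name[name]
                if (abs(p.mz_light - m["mz_light"]) <= m["mz_light"] * ppm_tol * 1e-6
                        and abs(p.rt - m["rt"]) <= rt_tol):
                    hit = name
                    break
            if hit is None:
                n_false += 1
            else:
                matched.add(hit)
        n_found += len(matched)
    return {"recovery": n_found / n_truth if n_truth else float("nan"),
            "false_rate": n_false / n_pairs if n_pairs else 0.0,
            "n_truth": n_truth, "n_detected": n_pairs}
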