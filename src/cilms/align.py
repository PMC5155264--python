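"""Cross-run alignment of peak pairs into a feature table, presence
filtering, ratio normalization and dansyl-library identification.

Pairs from multiple runs are clustered on (m/z, RT) within instrument
tolerances; the resulting features-by-samples matrix of light/heavy
ratios is the quantitative object every downstream statistic consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import to_1tag_z1
from .meta import SampleMeta, metadata_frame
from .pairpick import PeakPair

FEATURE_META_COLUMNS = ["feature_id", "consensus_mz", "rt_sec",
                        "n_tags", "charge", "identity"]


@dataclass(frozen=True)
class LibraryEntry:
    """A dansyl-standard library record: metabolite identity anchored to
    the accurate mass of its 1-tag, z=1 labeled ion and a reference RT."""
    name: str
    labeled_mz_1tag_z1: float
    rt_ref: float

    def __post_init__(self):
        if self.labeled_mz_1tag_z1 <= 0:
            raise ValueError("library mass must be positive")


def read_library(path) -> list[LibraryEntry]:
    df = pd.read_csv(path)
    entries = [LibraryEntry(str(r.name), float(r.labeled_mz_1tag_z1),
                            float(r.rt_sec))
               for r in df.itertuples(index=False)]
    names = [e.name for e in entries]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate library names: {dup}")
    return entries


def write_library(entries, path) -> None:
    pd.DataFrame([(e.name, e.labeled_mz_1tag_z1, e.rt_ref) for e in entries],
                 columns=["name", "labeled_mz_1tag_z1", "rt_sec"]
                 ).to_csv(path, index=False)


@dataclass
class FeatureTable:
    """Aligned pair-ratio matrix.

    ``values`` is a features-by-samples DataFrame of light/heavy ratios
    (NaN = feature not observed in that run); ``features`` holds the
    consensus m/z, RT, ion form and (after :func:`identify`) the library
    identity of each row; ``samples`` is the sample metadata in column
    order.
    """
    values: pd.DataFrame
    features: pd.DataFrame
    samples: list[SampleMeta] = field(default_factory=list)

    def __post_init__(self):
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids in feature table")
        if self.samples and list(self.values.columns) != [s.sample_id for s in self.samples]:
            raise ValueError("sample metadata order must match value columns")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, keep) -> "FeatureTable":
        keep = list(keep)
        ids = [s.sample_id for s in self.samples if s.sample_id in set(keep)]
        metas = [s for s in self.samples if s.sample_id in set(keep)]
        return FeatureTable(self.values[ids].copy(), self.features.copy(), metas)

    def to_csv(self, path) -> None:
        out = pd.concat([self.features.reset_index(drop=True),
                         self.values.reset_index(drop=True)], axis=1)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, samples=None) -> "FeatureTable":
        df = pd.read_csv(path)
        feats = df[FEATURE_META_COLUMNS].copy()
        vals = df.drop(columns=FEATURE_META_COLUMNS)
        vals.columns = [str(c) for c in vals.columns]
        return cls(vals, feats, list(samples) if samples else [])


def _new_table(clusters, sample_ids, samples) -> FeatureTable:
    feats = pd.DataFrame(
        [(f"F{i:05d}", c["mz"], c["rt"], c["n_tags"], c["charge"], None)
         for i, c in enumerate(clusters)], columns=FEATURE_META_COLUMNS)
    mat = np.full((len(clusters), len(sample_ids)), np.nan)
    col = {sid: j for j, sid in enumerate(sample_ids)}
    for i, c in enumerate(clusters):
        for sid, ratio in c["obs"].items():
            mat[i, col[sid]] = ratio
    values = pd.DataFrame(mat, columns=sample_ids)
    return FeatureTable(values, feats, list(samples) if samples else [])


def align(pair_lists: dict[str, list[PeakPair]], rt_tol: float = 20.0,
          ppm_tol: float = 5.0, samples=None) -> FeatureTable:
    """Greedy centroid clustering of per-run peak pairs.

    Runs are processed in descending pair count.  Each pair joins the
    existing cluster with the same ion form (n_tags, charge) whose
    running centroid lies within ``ppm_tol`` and ``rt_tol`` (closest ppm
    wins); otherwise it founds a new cluster.  A run contributes at most
    one observation per cluster.
    """
    order_ids = ([s.sample_id for s in samples] if samples is not None
                 else list(pair_lists))
    clusters: list[dict] = []
    run_order = sorted(pair_lists, key=lambda sid: -len(pair_lists[sid]))
    for sid in run_order:
        taken: set[int] = set()
        for p in sorted(pair_lists[sid], key=lambda q: q.mz_light):
            best = None
            for ci, c in enumerate(clusters):
                if ci in taken or c["n_tags"] != p.n_tags or c["charge"] != p.charge:
                    continue
                ppm = abs(p.mz_light - c["mz"]) / c["mz"] * 1e6
                if ppm <= ppm_tol and abs(p.rt - c["rt"]) <= rt_tol:
                    if best is None or ppm < best[0]:
                        best = (ppm, ci)
            if best is None:
                clusters.append({"mz": p.mz_light, "rt": p.rt,
                                 "n_tags": p.n_tags, "charge": p.charge,
                                 "n": 1, "obs": {sid: p.ratio}})
                taken.add(len(clusters) - 1)
            else:
                c = clusters[best[1]]
                c["n"] += 1
                c["mz"] += (p.mz_light - c["mz"]) / c["n"]
                c["rt"] += (p.rt - c["rt"]) / c["n"]
                c["obs"][sid] = p.ratio
                taken.add(best[1])
    clusters.sort(key=lambda c: (c["mz"], c["rt"]))
    ids = [sid for sid in order_ids if sid in pair_lists] if samples is not None \
        else sorted(pair_lists)
    metas = [s for s in (samples or []) if s.sample_id in pair_lists]
    return _new_table(clusters, ids, metas)


def presence_filter(table: FeatureTable, min_frac: float = 0.5) -> FeatureTable:
    """Keep features observed in strictly more than ``min_frac`` of samples."""
    if not 0 < min_frac < 1:
        raise ValueError("min_frac must be in (0, 1)")
    frac = table.values.notna().mean(axis=1)
    keep = frac > min_frac
    return FeatureTable(table.values[keep.values].reset_index(drop=True),
                        table.features[keep.values].reset_index(drop=True),
                        list(table.samples))


def normalize_ratios(table: FeatureTable, method: str = "sample_median") -> FeatureTable:
    """Per-sample ratio normalization.

    ``sample_median`` divides each sample's ratios by that sample's
    median observed ratio, removing run-level mixing/injection bias;
    ``none`` returns the table unchanged.
    """
    if method == "none":
        return table
    if method != "sample_median":
        raise ValueError(f"unknown normalization method {method!r}")
    medians = table.values.median(axis=0, skipna=True)
    bad = medians.index[medians.isna()].tolist()
    if bad:
        raise ValueError(f"sample(s) with no observed ratios: {bad}")
    return FeatureTable(table.values.div(medians, axis=1),
                        table.features.copy(), list(table.samples))


def identify(table: FeatureTable, library, ppm_tol: float = 5.0,
             rt_tol: float = 30.0) -> FeatureTable:
    """Annotate features by accurate-mass + RT search against the dansyl
    library.

    Each feature's light m/z is reduced to its 1-tag, z=1 equivalent
    before matching; the entry with the smallest ppm error inside both
    the ``ppm_tol`` and ``rt_tol`` windows wins; unmatched features keep
    ``identity`` empty.
    """
    names = [e.name for e in library]
    if len(set(names)) != len(names):
        raise ValueError("duplicate names in library")
    feats = table.features.copy()
    idents = []
    for r in feats.itertuples(index=False):
        equiv = to_1tag_z1(r.consensus_mz, int(r.n_tags), int(r.charge))
        best = None
        for e in library:
            ppm = abs(equiv - e.labeled_mz_1tag_z1) / e.labeled_mz_1tag_z1 * 1e6
            if ppm < ppm_tol and abs(r.rt_sec - e.rt_ref) < rt_tol:
                if best is None or ppm < best[0]:
                    best = (ppm, e.name)
        idents.append(best[1] if best else None)
    feats["identity"] = idents
    return FeatureTable(table.values.copy(), feats, list(table.samples))


def fluid_overlap(table_a: FeatureTable, table_b: FeatureTable) -> tuple[int, int, int]:
    """Identified-metabolite overlap between two biofluids:
    (common, only in first, only in second)."""
    ids_a = set(table_a.features["identity"].dropna())
    ids_b = set(table_b.features["identity"].dropna())
    return (len(ids_a & ids_b), len(ids_a - ids_b), len(ids_b - ids_a))
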