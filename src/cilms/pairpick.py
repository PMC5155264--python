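"""Mass calibration and 12C/13C dansyl peak-pair detection.

A differential-labeling run contains, for every labeled metabolite, a
*light* peak (12C-tagged individual sample) and a co-eluting *heavy* peak
(13C-tagged pooled reference) separated by ``n_tags * DELTA_TAG / z`` in
m/z.  The light/heavy intensity ratio is the relative concentration of
the metabolite in the individual sample versus the pooled standard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem import DELTA_TAG, PROTON

FEATURE_COLUMNS = ["mz", "rt_sec", "intensity"]

PAIR_COLUMNS = [
    "mz_light", "mz_heavy", "rt_sec", "n_tags", "charge",
    "intensity_light", "intensity_heavy", "ratio", "ppm_error",
]


class CalibrationError(RuntimeError):
    """No calibrant anchor could be matched in a run."""


@dataclass(frozen=True)
class CalibrationModel:
    """Single global multiplicative ppm correction for one run."""
    ppm_offset: float
    n_anchors_used: int


@dataclass(frozen=True)
class PeakPair:
    mz_light: float
    mz_heavy: float
    rt: float
    n_tags: int
    charge: int
    intensity_light: float
    intensity_heavy: float
    ratio: float
    ppm_error: float

    def __post_init__(self):
        if self.mz_heavy <= self.mz_light:
            raise ValueError("heavy m/z must exceed light m/z")


@dataclass
class FeatureList:
    """Centroided features of one LC-MS run, sorted by m/z."""
    sample_id: str
    mz: np.ndarray
    rt: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if not (len(self.mz) == len(self.rt) == len(self.intensity)):
            raise ValueError("mz/rt/intensity lengths differ")
        if np.any(self.mz <= 0) or np.any(self.rt < 0):
            raise ValueError("m/z must be positive and RT non-negative")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.rt = self.rt[order]
        self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return len(self.mz)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mz": self.mz, "rt_sec": self.rt, "intensity": self.intensity})

    @classmethod
    def from_frame(cls, sample_id: str, df: pd.DataFrame) -> "FeatureList":
        missing = set(FEATURE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"feature list missing columns {sorted(missing)}")
        return cls(sample_id, df["mz"].to_numpy(),
                   df["rt_sec"].to_numpy(), df["intensity"].to_numpy())

    @classmethod
    def read_tsv(cls, path, sample_id: str | None = None) -> "FeatureList":
        df = pd.read_csv(path, sep="\t")
        sid = sample_id if sample_id is not None else _stem(path)
        return cls.from_frame(sid, df)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _stem(path) -> str:
    import os
    return os.path.splitext(os.path.basename(str(path)))[0]


def calibrate(flist: FeatureList, anchor_mzs, match_ppm: float = 20.0,
              max_offset_ppm: float = 50.0) -> CalibrationModel:
    """Estimate a global ppm offset from calibrant anchor ions.

    Each anchor is matched to the closest observed feature within
    ``match_ppm``; the offset is the mean signed ppm deviation
    (observed - theoretical).  Raises :class:`CalibrationError` when no
    anchor is found.
    """
    deviations = []
    for theo in anchor_mzs:
        tol = theo * match_ppm * 1e-6
        lo = np.searchsorted(flist.mz, theo - tol)
        hi = np.searchsorted(flist.mz, theo + tol)
        if hi > lo:
            cands = flist.mz[lo:hi]
            best = cands[np.argmin(np.abs(cands - theo))]
            deviations.append((best - theo) / theo * 1e6)
    if not deviations:
        raise CalibrationError(
            f"run {flist.sample_id!r}: no calibrant anchor matched "
            f"within {match_ppm} ppm")
    offset = float(np.mean(deviations))
    if abs(offset) > max_offset_ppm:
        raise CalibrationError(
            f"run {flist.sample_id!r}: fitted offset {offset:.1f} ppm "
            f"exceeds {max_offset_ppm} ppm")
    return CalibrationModel(ppm_offset=offset, n_anchors_used=len(deviations))


def apply_calibration(flist: FeatureList, model: CalibrationModel) -> FeatureList:
    """Rescale every m/z by ``(1 - ppm_offset * 1e-6)``."""
    return FeatureList(flist.sample_id,
                       flist.mz * (1.0 - model.ppm_offset * 1e-6),
                       flist.rt.copy(), flist.intensity.copy())


def _tag_charge_forms(tag_range=(1, 3), charge_range=(1, 2)):
    """Candidate (n_tags, charge) forms ordered by mass spacing, with
    degenerate spacings (e.g. 1 tag z=1 vs 2 tags z=2) collapsed onto the
    simplest form (fewest tags, then lowest charge)."""
    forms = []
    seen = []
    for t in range(tag_range[0], tag_range[1] + 1):
        for z in range(charge_range[0], charge_range[1] + 1):
            dm = t * DELTA_TAG / z
            if any(abs(dm - s) < 1e-6 for s in seen):
                continue
            seen.append(dm)
            forms.append((t, z, dm))
    forms.sort(key=lambda f: f[2])
    return forms


def detect_pairs(flist: FeatureList, ppm_tol: float = 5.0, rt_tol: float = 6.0,
                 tag_range=(1, 3), charge_range=(1, 2)) -> list[PeakPair]:
    """Detect light/heavy peak pairs in a calibrated feature list.

    For each feature, taken in ascending m/z as the light candidate, a
    heavier partner is searched at every supported tag/charge spacing
    within ``ppm_tol`` (evaluated on the heavy m/z) and ``rt_tol``
    seconds.  Ambiguities are resolved by smallest absolute ppm error,
    then largest heavy intensity; each feature joins at most one pair.
    """
    n = len(flist)
    used = np.zeros(n, dtype=bool)
    forms = _tag_charge_forms(tag_range, charge_range)
    pairs: list[PeakPair] = []
    for i in range(n):
        if used[i]:
            continue
        best = None  # (|ppm|, -intensity, j, t, z, ppm)
        for t, z, dm in forms:
            expected = flist.mz[i] + dm
            tol = expected * ppm_tol * 1e-6
            lo = np.searchsorted(flist.mz, expected - tol)
            hi = np.searchsorted(flist.mz, expected + tol)
            for j in range(lo, hi):
                if used[j] or j == i:
                    continue
                if abs(flist.rt[j] - flist.rt[i]) > rt_tol:
                    continue
                ppm = (flist.mz[j] - expected) / expected * 1e6
                key = (abs(ppm), -flist.intensity[j])
                if best is None or key < best[0]:
                    best = (key, j, t, z, ppm)
        if best is None:
            continue
        _, j, t, z, ppm = best
        used[i] = used[j] = True
        ih = flist.intensity[j]
        il = flist.intensity[i]
        pairs.append(PeakPair(
            mz_light=float(flist.mz[i]), mz_heavy=float(flist.mz[j]),
            rt=float(flist.rt[i]), n_tags=t, charge=z,
            intensity_light=float(il), intensity_heavy=float(ih),
            ratio=float(il / ih) if ih > 0 else float("inf"),
            ppm_error=float(ppm)))
    pairs.sort(key=lambda p: p.mz_light)
    return pairs


def pair_level_filter(pairs, min_intensity: float = 0.0,
                      mass_ppm: float = 10.0, rt_tol: float = 10.0) -> list[PeakPair]:
    """Retain quantifiable pairs and collapse redundant ion forms.

    Drops pairs whose heavy channel is zero (ratio undefined) or whose
    channels fall below ``min_intensity``.  When several tag/charge forms
    of the same metabolite survive — same light neutral tagged mass
    within ``mass_ppm`` and RT within ``rt_tol`` — only the form with the
    highest summed intensity is kept.
    """
    kept = [p for p in pairs
            if p.intensity_heavy > 0
            and p.intensity_light >= min_intensity
            and p.intensity_heavy >= min_intensity]
    # group by light neutral tagged mass + RT
    def neutral(p: PeakPair) -> float:
        return p.mz_light * p.charge - p.charge * PROTON

    kept.sort(key=neutral)
    out: list[PeakPair] = []
    group: list[PeakPair] = []

    def flush():
        if group:
            out.append(max(group, key=lambda p: p.intensity_light + p.intensity_heavy))

    for p in kept:
        if group:
            ref = group[0]
            if (abs(neutral(p) - neutral(ref)) <= neutral(ref) * mass_ppm * 1e-6
                    and abs(p.rt - ref.rt) <= rt_tol):
                group.append(p)
                continue
            flush()
        group = [p]
    flush()
    out.sort(key=lambda p: p.mz_light)
    return out


def pairs_to_frame(pairs) -> pd.DataFrame:
    rows = [(p.mz_light, p.mz_heavy, p.rt, p.n_tags, p.charge,
             p.intensity_light, p.intensity_heavy, p.ratio, p.ppm_error)
            for p in pairs]
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def frame_to_pairs(df: pd.DataFrame) -> list[PeakPair]:
    return [PeakPair(r.mz_light, r.mz_heavy, r.rt_sec, int(r.n_tags),
                     int(r.charge), r.intensity_light, r.intensity_heavy,
                     r.ratio, r.ppm_error)
            for r in df.itertuples(index=False)]


def write_pairs_tsv(pairs, path) -> None:
    pairs_to_frame(pairs).to_csv(path, sep="\t", index=False)


def read_pairs_tsv(path) -> list[PeakPair]:
    return frame_to_pairs(pd.read_csv(path, sep="\t"))
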