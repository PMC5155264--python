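"""Sample metadata: patients, AIS grades, time windows, biofluids, QC runs."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

GRADES = ("A", "B", "C", "N")
#: sampling windows in hours post-injury
TIME_WINDOWS = {"t1": (16, 32), "t2": (40, 56), "t3": (64, 80)}
BIOFLUIDS = ("CSF", "serum")

META_COLUMNS = ["sample_id", "patient_id", "grade", "time_window",
                "biofluid", "is_qc"]


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    patient_id: str
    grade: str          # AIS grade A/B/C, or N for non-injured control
    time_window: str    # t1/t2/t3, or "none" for controls and QC
    biofluid: str
    is_qc: bool = False

    def __post_init__(self):
        if self.grade not in GRADES:
            raise ValueError(f"unknown grade {self.grade!r}")
        if self.time_window not in (*TIME_WINDOWS, "none"):
            raise ValueError(f"unknown time window {self.time_window!r}")
        if self.biofluid not in BIOFLUIDS:
            raise ValueError(f"unknown biofluid {self.biofluid!r}")
        if (self.grade == "N" or self.is_qc) and self.time_window != "none":
            raise ValueError("controls and QC runs carry no time window")


def metadata_frame(samples) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.sample_id, s.patient_id, s.grade, s.time_window, s.biofluid, s.is_qc)
         for s in samples], columns=META_COLUMNS)


def read_metadata(path) -> list[SampleMeta]:
    df = pd.read_csv(path, dtype={"is_qc": bool})
    return [SampleMeta(str(r.sample_id), str(r.patient_id), r.grade,
                       r.time_window, r.biofluid, bool(r.is_qc))
            for r in df.itertuples(index=False)]


def write_metadata(samples, path) -> None:
    metadata_frame(samples).to_csv(path, index=False)
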