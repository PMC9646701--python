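"""EBC-CSV: plain-text formats for eyeblink trial data.

Two dialects carry the same information:

* wide — one row per trial: metadata columns followed by the fixed-length
  sample vector (``v0 .. v{n-1}``). Compact and fast.
* long — one row per (trial, sample): metadata columns plus ``sample_index``
  and ``value``. Convenient for plotting tools.

``read_ebc(write_ebc(x))`` round-trips bit-exactly for sample values (CSV
floats are written with shortest-round-trip precision) and exactly for
metadata. Schema violations raise ``SchemaError`` naming the offending
column or key.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import TrialRecord

SCHEMA_VERSION = "ebc-csv-1"
META_COLS = ["schema_version", "mouse_id", "genotype", "day", "phase", "block",
             "trial", "trial_type", "isi_ms", "fps", "cs_onset_index",
             "us_onset_index"]


class SchemaError(ValueError):
    pass


@dataclass
class EBCDataset:
    trials: list[TrialRecord]
    schema_version: str = SCHEMA_VERSION

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        seen = set()
        n_expected = None
        for t in self.trials:
            key = (t.mouse_id, t.day, t.trial)
            if key in seen:
                raise SchemaError(f"duplicate trial key {key}")
            seen.add(key)
            if n_expected is None:
                n_expected = len(t.samples)
            elif len(t.samples) != n_expected:
                raise SchemaError(
                    f"inconsistent sample count for {key}: "
                    f"{len(t.samples)} != {n_expected}")

    def __eq__(self, other):
        if not isinstance(other, EBCDataset) or len(self.trials) != len(other.trials):
            return False
        for a, b in zip(self.trials, other.trials):
            for f in ("mouse_id", "genotype", "day", "phase", "block", "trial",
                      "trial_type", "isi_ms", "fps", "cs_onset_index",
                      "us_onset_index"):
                if getattr(a, f) != getattr(b, f):
                    return False
            if not np.array_equal(a.samples, b.samples):
                return False
        return True


def _meta_row(t: TrialRecord) -> dict:
    return dict(schema_version=SCHEMA_VERSION, mouse_id=t.mouse_id,
                genotype=t.genotype, day=t.day, phase=t.phase, block=t.block,
                trial=t.trial, trial_type=t.trial_type, isi_ms=t.isi_ms,
                fps=t.fps, cs_onset_index=t.cs_onset_index,
                us_onset_index=-1 if t.us_onset_index is None else t.us_onset_index)


def write_ebc(ds: EBCDataset, path, dialect: str = "wide") -> None:
    if dialect not in ("wide", "long"):
        raise ValueError("dialect must be 'wide' or 'long'")
    rows = []
    for t in ds.trials:
        meta = _meta_row(t)
        if dialect == "wide":
            row = dict(meta)
            row.update({f"v{i}": v for i, v in enumerate(t.samples)})
            rows.append(row)
        else:
            for i, v in enumerate(t.samples):
                row = dict(meta)
                row.update(sample_index=i, value=v)
                rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_ebc(path, dialect: str | None = None) -> EBCDataset:
    # round_trip parsing keeps read(write(x)) bit-exact for sample values
    df = pd.read_csv(path, float_precision="round_trip")
    if dialect is None:
        dialect = "long" if "sample_index" in df.columns else "wide"
    for col in META_COLS:
        if col not in df.columns:
            raise SchemaError(f"missing required column '{col}'")
    trials = []
    if dialect == "wide":
        vcols = sorted((c for c in df.columns if c.startswith("v")
                        and c[1:].isdigit()), key=lambda c: int(c[1:]))
        if not vcols:
            raise SchemaError("wide dialect requires sample columns v0..vN")
        for _, r in df.iterrows():
            trials.append(_record_from_meta(r, r[vcols].to_numpy(dtype=float)))
    else:
        keys = ["mouse_id", "day", "trial"]
        for key, grp in df.groupby(keys, sort=False):
            grp = grp.sort_values("sample_index")
            idx = grp["sample_index"].to_numpy()
            if not np.array_equal(idx, np.arange(len(idx))):
                raise SchemaError(f"non-contiguous sample_index for trial {key}")
            trials.append(_record_from_meta(grp.iloc[0],
                                            grp["value"].to_numpy(dtype=float)))
    return EBCDataset(trials=trials,
                      schema_version=str(df["schema_version"].iloc[0]))


def _record_from_meta(r, samples: np.ndarray) -> TrialRecord:
    us = int(r["us_onset_index"])
    return TrialRecord(
        mouse_id=str(r["mouse_id"]), genotype=str(r["genotype"]),
        day=int(r["day"]), phase=str(r["phase"]), block=int(r["block"]),
        trial=int(r["trial"]), trial_type=str(r["trial_type"]),
        isi_ms=float(r["isi_ms"]), fps=float(r["fps"]),
        cs_onset_index=int(r["cs_onset_index"]),
        us_onset_index=None if us < 0 else us, samples=samples)
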