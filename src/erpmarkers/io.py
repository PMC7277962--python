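"""File formats: EDF and npz-container recordings, clinical tables, JSON.

Raw recordings round-trip through either European Data Format (EDF, 16-bit
quantized) or the package's own container (a ``.npz`` array file with a
JSON sidecar holding labels, events and provenance — lossless). EDF files
are read with mne; the writer here produces plain EDF with a JSON sidecar
carrying the event markers.

Clinical and feature tables are delimited text (CSV/TSV) with documented
column names.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .clinstats import ClinicalRecord, MEDICATION_LEVELS, SEX_LEVELS
from .sigproc import Recording

__all__ = ["read_recording", "write_recording", "read_clinical_table",
           "write_clinical_table", "clinical_to_frame", "write_ground_truth",
           "CLINICAL_COLUMNS", "FEATURE_COLUMNS"]

CLINICAL_COLUMNS = ("subject_id", "age", "sex", "medication",
                    "hamd_w0", "hamd_w2", "hamd_w4", "hamd_w8",
                    "hama_baseline", "hama_week8", "core")
FEATURE_COLUMNS = ("subject_id", "faa_f5f6_low", "faa_f7f8_low", "ldaep", "mmn")

_EVENT_PARADIGMS = {"ldaep", "mmn"}


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _write_sidecar(rec: Recording, path: Path, n_samples: int):
    meta = {
        "subject_id": rec.subject_id,
        "paradigm": rec.paradigm,
        "channel_labels": list(rec.channel_labels),
        "sampling_rate": rec.sampling_rate,
        "n_samples": int(n_samples),
        "events": [[int(s), str(c)] for s, c in rec.events],
        "meta": rec.meta,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, default=str))


def _fixed(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(rec: Recording, path: Path):
    """Minimal EDF writer: 1-s data records, 16-bit, physical unit μV.

    The signal is zero-padded to a whole number of records; the true
    sample count is stored in the JSON sidecar and restored on read.
    """
    fs = rec.sampling_rate
    spr = int(round(fs))  # samples per 1-s record, per channel
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    n_ch, n_samples = rec.data.shape
    n_rec = int(np.ceil(n_samples / spr))
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_samples] = rec.data

    pmin = np.floor(padded.min(axis=1) - 1.0)
    pmax = np.ceil(padded.max(axis=1) + 1.0)
    dmin, dmax = -32768, 32767
    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.round((padded - pmin[:, None]) / scale[:, None] + dmin).astype("<i2")

    now = datetime.datetime(2000, 1, 1)
    header = b"".join([
        _fixed("0", 8),
        _fixed(rec.subject_id, 80),
        _fixed(f"Startdate 01-JAN-2000 {rec.paradigm}", 80),
        _fixed(now.strftime("%d.%m.%y"), 8),
        _fixed(now.strftime("%H.%M.%S"), 8),
        _fixed(256 + 256 * n_ch, 8),
        _fixed("", 44),
        _fixed(n_rec, 8),
        _fixed(1, 8),  # record duration, seconds
        _fixed(n_ch, 4),
    ])
    sig = b"".join([
        b"".join(_fixed(lab, 16) for lab in rec.channel_labels),
        b"".join(_fixed("AgAgCl electrode", 80) for _ in range(n_ch)),
        b"".join(_fixed("uV", 8) for _ in range(n_ch)),
        b"".join(_fixed(f"{v:.1f}", 8) for v in pmin),
        b"".join(_fixed(f"{v:.1f}", 8) for v in pmax),
        b"".join(_fixed(dmin, 8) for _ in range(n_ch)),
        b"".join(_fixed(dmax, 8) for _ in range(n_ch)),
        b"".join(_fixed("", 80) for _ in range(n_ch)),
        b"".join(_fixed(spr, 8) for _ in range(n_ch)),
        b"".join(_fixed("", 32) for _ in range(n_ch)),
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        # record-interleaved: all samples of ch1 for record r, then ch2, ...
        for r in range(n_rec):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes())


def write_recording(rec: Recording, path) -> Path:
    """Write a recording to ``.edf`` (16-bit) or ``.npz`` (lossless).

    Both formats get a ``<name>.<ext>.json`` sidecar with labels, events
    and provenance; the container keeps only the sample array in the npz.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        _write_edf(rec, path)
    elif path.suffix.lower() == ".npz":
        np.savez_compressed(path, data=rec.data)
    else:
        raise ValueError(f"unsupported recording format {path.suffix!r}")
    _write_sidecar(rec, path, rec.data.shape[1])
    return path


def _read_edf(path: Path, sidecar: dict = None) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts regardless of EDF unit
    labels = list(raw.ch_names)
    fs = float(raw.info["sfreq"])
    if sidecar is not None:
        n = sidecar.get("n_samples", data.shape[1])
        data = data[:, :n]
        return Recording(subject_id=sidecar["subject_id"],
                         paradigm=sidecar["paradigm"],
                         channel_labels=sidecar.get("channel_labels", labels),
                         sampling_rate=sidecar.get("sampling_rate", fs),
                         data=data,
                         events=[(int(s), str(c)) for s, c in sidecar["events"]],
                         meta=sidecar.get("meta", {}))
    # bare EDF: events (if any) from EDF+ annotations
    events = []
    for onset, _dur, desc in zip(raw.annotations.onset, raw.annotations.duration,
                                 raw.annotations.description):
        events.append((int(round(onset * fs)), str(desc)))
    return Recording(subject_id=Path(path).stem, paradigm="resting",
                     channel_labels=labels, sampling_rate=fs, data=data,
                     events=events)


def read_recording(path, paradigm: str = None) -> Recording:
    """Read an ``.edf`` or ``.npz`` recording (values in μV).

    If ``paradigm`` names an event-related protocol, the file must carry
    event markers (sidecar or EDF+ annotations); a recording without them
    raises an error naming the paradigm.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sc_path = _sidecar_path(path)
    sidecar = json.loads(sc_path.read_text()) if sc_path.exists() else None

    if path.suffix.lower() == ".edf":
        rec = _read_edf(path, sidecar)
    elif path.suffix.lower() == ".npz":
        if sidecar is None:
            raise ValueError(f"container file {path} lacks its JSON sidecar")
        with np.load(path) as npz:
            data = npz["data"]
        rec = Recording(subject_id=sidecar["subject_id"],
                        paradigm=sidecar["paradigm"],
                        channel_labels=sidecar["channel_labels"],
                        sampling_rate=sidecar["sampling_rate"], data=data,
                        events=[(int(s), str(c)) for s, c in sidecar["events"]],
                        meta=sidecar.get("meta", {}))
    else:
        raise ValueError(f"unsupported recording format {path.suffix!r}")

    if paradigm is not None and rec.paradigm != paradigm:
        raise ValueError(f"expected a {paradigm} recording, file says {rec.paradigm}")
    if rec.paradigm in _EVENT_PARADIGMS and not rec.events:
        raise ValueError(
            f"recording {path} has no event markers, required for the "
            f"{rec.paradigm} paradigm")
    return rec


def clinical_to_frame(records) -> pd.DataFrame:
    """Clinical records -> one-row-per-subject DataFrame (documented columns)."""
    rows = []
    for r in records:
        rows.append({
            "subject_id": r.subject_id, "age": r.age, "sex": r.sex,
            "medication": r.medication,
            "hamd_w0": r.hamd.get(0), "hamd_w2": r.hamd.get(2),
            "hamd_w4": r.hamd.get(4), "hamd_w8": r.hamd.get(8),
            "hama_baseline": r.hama_baseline, "hama_week8": r.hama_week8,
            "core": r.core,
        })
    return pd.DataFrame(rows, columns=list(CLINICAL_COLUMNS))


def write_clinical_table(records, path, sep: str = ",") -> Path:
    path = Path(path)
    clinical_to_frame(records).to_csv(path, sep=sep, index=False)
    return path


def read_clinical_table(path, sep: str = None) -> list:
    """Read and validate a delimited clinical table into ClinicalRecords.

    Rows with a blank HAM-D entry are loaded with that week missing (the
    record is flagged incomplete and excluded from complete-case
    statistics downstream). Range violations and duplicate subject ids
    raise errors naming the offending row.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    missing = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"clinical table lacks columns {sorted(missing)}")
    dupes = df["subject_id"][df["subject_id"].duplicated()]
    if len(dupes):
        raise ValueError(f"duplicated subject_id values: {sorted(set(dupes))}")

    records = []
    for i, row in df.iterrows():
        rownum = i + 2  # header is line 1
        hamd = {}
        for w in (0, 2, 4, 8):
            v = row[f"hamd_w{w}"]
            if pd.isna(v):
                hamd[w] = None
                continue
            if v < 0:
                raise ValueError(f"row {rownum}: negative HAM-D at week {w}")
            hamd[w] = int(v)
        if row["medication"] not in MEDICATION_LEVELS:
            raise ValueError(
                f"row {rownum}: unknown medication {row['medication']!r} "
                f"(expected one of {MEDICATION_LEVELS})")
        if row["sex"] not in SEX_LEVELS:
            raise ValueError(f"row {rownum}: unknown sex {row['sex']!r}")
        records.append(ClinicalRecord(
            subject_id=str(row["subject_id"]), age=float(row["age"]),
            sex=str(row["sex"]), medication=str(row["medication"]), hamd=hamd,
            hama_baseline=None if pd.isna(row["hama_baseline"]) else int(row["hama_baseline"]),
            hama_week8=None if pd.isna(row["hama_week8"]) else int(row["hama_week8"]),
            core=None if pd.isna(row["core"]) else int(row["core"])))
    return records


def write_ground_truth(truth, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(truth.to_dict(), indent=1))
    return path
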