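"""Signal and table I/O plus the recording-reference convention.

Signals travel as 16-bit EDF (one file per patient, physical dimension uV,
1-second data records); channel metadata as TSV; clinical tables as CSV.  The
EDF codec here implements the plain EDF subset the pipeline needs: equal
sampling rate on all channels and integral-second epochs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "IEEGEpoch",
    "read_epoch",
    "write_epoch",
    "apply_common_average",
    "read_channel_table",
    "read_clinical_table",
    "edf_quantization_step",
]

CHANNEL_COLUMNS = ["channel", "x_mm", "y_mm", "z_mm", "artifact", "soz", "lesion", "spiking", "resected"]
CLINICAL_COLUMNS = [
    "age",
    "male",
    "daily_seizures",
    "n_aeds",
    "left_hemisphere",
    "mri_lesion",
    "habitual_sz_captured",
    "soz_fully_resected",
    "extratemporal_resection",
    "resection_size_pct",
    "ilae_class",
]


@dataclass
class IEEGEpoch:
    """A fixed-rate multichannel signal segment in microvolts."""

    samples: np.ndarray  # channels x time
    fs: float
    channel_ids: list[str]
    reference: str = "as_recorded"  # or "common_average"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be channels x time")
        if len(self.channel_ids) != self.samples.shape[0]:
            raise ValueError("one channel id per row required")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def epoch_duration_s(self) -> float:
        return self.samples.shape[1] / self.fs

    def channel(self, channel_id: str) -> np.ndarray:
        return self.samples[self.channel_ids.index(channel_id)]


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def _fmt_num(v: float, width: int = 8) -> str:
    for p in (7, 6, 5, 4, 3, 2, 1, 0):
        s = f"{v:.{p}g}"
        if len(s) <= width:
            return s
    return s[:width]


def write_epoch(path: str | Path, epoch: IEEGEpoch) -> None:
    """Write the epoch as 16-bit EDF with per-channel physical scaling."""
    n_ch, n = epoch.samples.shape
    fs = int(round(epoch.fs))
    if abs(epoch.fs - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    if n % fs != 0:
        raise ValueError("EDF writer requires an integral number of seconds")
    n_rec = n // fs

    pmaxs = np.maximum(np.abs(epoch.samples).max(axis=1), 1e-6)
    dig = np.empty((n_ch, n), dtype="<i2")
    pmins = -pmaxs
    for c in range(n_ch):
        # round-trip uses the header-printed bounds, so quantize against those
        pmax = float(_fmt_num(pmaxs[c] * 1.0001))
        pmaxs[c], pmins[c] = pmax, -pmax
        scale = (pmax - (-pmax)) / (32767 - (-32768))
        dig[c] = np.clip(np.round((epoch.samples[c] - (-pmax)) / scale) - 32768, -32768, 32767)

    header = b""
    header += _pad("0", 8)
    header += _pad("synthetic iEEG", 80)
    header += _pad(f"reference:{epoch.reference}", 80)
    header += _pad("01.01.00", 8) + _pad("00.00.00", 8)
    header += _pad(str(256 * (1 + n_ch)), 8)
    header += _pad("", 44)
    header += _pad(str(n_rec), 8)
    header += _pad("1", 8)
    header += _pad(str(n_ch), 4)
    for c in range(n_ch):
        header += _pad(epoch.channel_ids[c], 16)
    header += b"".join(_pad("", 80) for _ in range(n_ch))
    header += b"".join(_pad("uV", 8) for _ in range(n_ch))
    header += b"".join(_pad(_fmt_num(pmins[c]), 8) for c in range(n_ch))
    header += b"".join(_pad(_fmt_num(pmaxs[c]), 8) for c in range(n_ch))
    header += b"".join(_pad("-32768", 8) for _ in range(n_ch))
    header += b"".join(_pad("32767", 8) for _ in range(n_ch))
    header += b"".join(_pad("", 80) for _ in range(n_ch))
    header += b"".join(_pad(str(fs), 8) for _ in range(n_ch))
    header += b"".join(_pad("", 32) for _ in range(n_ch))

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            for c in range(n_ch):
                fh.write(dig[c, r * fs : (r + 1) * fs].tobytes())


def read_epoch(path: str | Path, expected_fs: float | None = 1000.0) -> IEEGEpoch:
    """Read an EDF file into an IEEGEpoch (samples in uV).

    Raises if the file's sampling rate differs from ``expected_fs`` — the
    analysis assumes a fixed rate throughout.
    """
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise IOError(f"{path}: truncated EDF header")
        n_rec = int(head[236:244].decode("ascii").strip())
        rec_dur = float(head[244:252].decode("ascii").strip())
        n_ch = int(head[252:256].decode("ascii").strip())
        sig = fh.read(256 * n_ch)

        def fld(off: int, width: int) -> list[str]:
            base = off * n_ch
            return [
                sig[base + i * width : base + (i + 1) * width].decode("ascii").strip()
                for i in range(n_ch)
            ]

        labels = fld(0, 16)
        # field offsets: label 16, transducer 80, dim 8, pmin 8, pmax 8, dmin 8, dmax 8
        off = 16 * n_ch + 80 * n_ch + 8 * n_ch
        pmin = np.array([float(sig[off + i * 8 : off + (i + 1) * 8].decode().strip()) for i in range(n_ch)])
        off += 8 * n_ch
        pmax = np.array([float(sig[off + i * 8 : off + (i + 1) * 8].decode().strip()) for i in range(n_ch)])
        off += 8 * n_ch
        dmin = np.array([float(sig[off + i * 8 : off + (i + 1) * 8].decode().strip()) for i in range(n_ch)])
        off += 8 * n_ch
        dmax = np.array([float(sig[off + i * 8 : off + (i + 1) * 8].decode().strip()) for i in range(n_ch)])
        off += 8 * n_ch + 80 * n_ch
        spr = [int(sig[off + i * 8 : off + (i + 1) * 8].decode().strip()) for i in range(n_ch)]

        if len(set(spr)) != 1:
            raise IOError("mixed per-channel sampling rates are not supported")
        fs = spr[0] / rec_dur
        if expected_fs is not None and abs(fs - expected_fs) > 1e-6:
            raise ValueError(f"{path}: sampling rate {fs} Hz, expected {expected_fs}")

        raw = np.frombuffer(fh.read(), dtype="<i2")

    per_rec = sum(spr)
    raw = raw[: n_rec * per_rec].reshape(n_rec, n_ch, spr[0])
    scale = (pmax - pmin) / (dmax - dmin)
    samples = np.transpose(raw, (1, 0, 2)).reshape(n_ch, -1).astype(float)
    samples = (samples - dmin[:, None]) * scale[:, None] + pmin[:, None]

    reference = "as_recorded"
    rec_id = head[88:168].decode("ascii")
    if "common_average" in rec_id:
        reference = "common_average"
    return IEEGEpoch(samples=samples, fs=fs, channel_ids=labels, reference=reference)


def edf_quantization_step(values: np.ndarray) -> float:
    """Worst-case quantization step of the 16-bit codec for this value range."""
    pmax = float(_fmt_num(max(np.abs(values).max(), 1e-6) * 1.0001))
    return 2 * pmax / 65535


def apply_common_average(epoch: IEEGEpoch, exclude: set[str] | None = None) -> IEEGEpoch:
    """Subtract the sample-wise mean of included channels from each of them.

    Excluded (artifact) channels do not enter the average and are returned
    unchanged.  Idempotent: re-applying the reference changes nothing.
    """
    exclude = exclude or set()
    keep = [i for i, c in enumerate(epoch.channel_ids) if c not in exclude]
    if len(keep) < 2:
        raise ValueError("common average needs at least 2 included channels")
    out = epoch.samples.copy()
    avg = out[keep].mean(axis=0)
    out[keep] -= avg
    return IEEGEpoch(
        samples=out,
        fs=epoch.fs,
        channel_ids=list(epoch.channel_ids),
        reference="common_average",
    )


def read_channel_table(path: str | Path) -> pd.DataFrame:
    """Read and validate the TSV channel-metadata table.

    Adds the derived ``non_epileptic`` column: a site is non-epileptic iff it
    lies outside the seizure-onset, lesional and spiking zones.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CHANNEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"channel table missing columns: {missing}")
    if df["channel"].duplicated().any():
        dup = df.loc[df["channel"].duplicated(), "channel"].iloc[0]
        raise ValueError(f"duplicate channel label {dup!r}")
    for c in ["artifact", "soz", "lesion", "spiking", "resected"]:
        df[c] = df[c].astype(bool)
    df["non_epileptic"] = ~(df["soz"] | df["lesion"] | df["spiking"])
    return df


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read and validate the CSV clinical table; derives the success indicator."""
    df = pd.read_csv(path)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    ilae = df["ilae_class"].astype(int)
    if not ilae.isin(range(1, 7)).all():
        bad = ilae[~ilae.isin(range(1, 7))].iloc[0]
        raise ValueError(f"ILAE class must lie in 1..6, got {bad}")
    df["ilae_class"] = ilae
    df["success"] = (ilae == 1).astype(int)
    return df
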