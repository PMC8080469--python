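"""BrainVision I/O and the 64-channel montage.

A recording session lives in three files: a text header (``.vhdr``), a text
marker list (``.vmrk``) and raw binary samples (``.eeg``).  The reader wraps
MNE-Python's BrainVision parser and converts everything to a plain
:class:`Recording` with data in microvolts; the writer is self-contained and
emits files that MNE (and any other standard-conforming reader) accepts.

Sample indices are 0-based everywhere in this package; the 1-based positions
mandated by the ``.vmrk`` format are converted at the file boundary.
"""

from __future__ import annotations

import configparser
import os
import re
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ChannelMismatchError, DataRangeError, FileFormatError

__all__ = [
    "Recording",
    "BrainVisionDialect",
    "read_brainvision",
    "write_brainvision",
    "standard_montage_64",
    "OCCIPITAL_SET",
]

#: Occipital electrodes averaged into the virtual SSVEP channel.
OCCIPITAL_SET = ("O1", "Oz", "O2", "PO3", "POz", "PO4", "PO7", "PO8")

#: 64-channel 10-10 cap layout (extended 10-20 nomenclature).
MONTAGE_64_LABELS = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8", "PO9", "O1", "Oz", "O2", "PO10",
    "AF7", "AF3", "AF4", "AF8", "F5", "F1", "F2", "F6",
    "FT9", "FT7", "FC3", "FC4", "FT8", "FT10",
    "C5", "C1", "C2", "C6", "TP7", "CP3", "CPz", "CP4", "TP8",
    "P5", "P1", "P2", "P6", "PO7", "PO3", "POz", "PO4", "PO8",
)


def _infer_type(label: str) -> str:
    low = label.lower()
    if low in ("ecg", "ekg"):
        return "ecg"
    if label in MONTAGE_64_LABELS or re.fullmatch(
        r"(Fp|AF|F|FT|FC|T|C|TP|CP|P|PO|O|I)z?\d{0,2}h?", label
    ):
        return "eeg" if low not in ("audio",) else "misc"
    return "misc"


@dataclass
class Recording:
    """A continuous multichannel recording with channel metadata.

    ``data`` is channels x samples, EEG rows in microvolts (auxiliary rows in
    their native units).  ``events`` is a list of ``(sample, label)`` pairs
    with 0-based sample indices.
    """

    channel_labels: list
    channel_types: list
    fs: float
    data: np.ndarray
    montage: dict = field(default_factory=dict)
    events: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_labels):
            raise ChannelMismatchError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.channel_labels)} labels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ChannelMismatchError("channel labels must be unique")
        if len(self.channel_types) != len(self.channel_labels):
            raise ChannelMismatchError("one channel type per label required")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if not self.montage:
            std = standard_montage_64()
            self.montage = {
                lab: std[lab]
                for lab, typ in zip(self.channel_labels, self.channel_types)
                if typ == "eeg" and lab in std
            }
        missing = [
            lab
            for lab, typ in zip(self.channel_labels, self.channel_types)
            if typ == "eeg" and lab not in self.montage
        ]
        if missing:
            raise ChannelMismatchError(f"eeg channels missing from montage: {missing}")

    # -- convenience accessors -------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def eeg_labels(self) -> list:
        return [l for l, t in zip(self.channel_labels, self.channel_types) if t == "eeg"]

    def indices(self, kind: str) -> np.ndarray:
        return np.array(
            [i for i, t in enumerate(self.channel_types) if t == kind], dtype=int
        )

    def eeg_data(self) -> np.ndarray:
        return self.data[self.indices("eeg")]

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_labels.index(label)]

    def audio(self) -> np.ndarray:
        for cand in ("audio", "Audio", "AUDIO"):
            if cand in self.channel_labels:
                return self.channel(cand)
        raise ChannelMismatchError("no 'audio' channel in recording")

    def ecg(self) -> np.ndarray:
        idx = self.indices("ecg")
        if idx.size == 0:
            raise ChannelMismatchError("no ECG channel in recording")
        return self.data[idx[0]]


@dataclass
class BrainVisionDialect:
    """On-disk encoding of the ``.eeg`` binary file."""

    binary_format: str = "float32"  # "float32" or "int16"
    orientation: str = "multiplexed"  # "multiplexed" or "vectorized"
    resolution: float = 0.1  # uV/bit, used for int16 only

    def __post_init__(self):
        if self.binary_format not in ("float32", "int16"):
            raise FileFormatError(
                f"unsupported binary format {self.binary_format!r}",
                keyword=self.binary_format,
            )
        if self.orientation not in ("multiplexed", "vectorized"):
            raise FileFormatError(
                f"unsupported orientation {self.orientation!r}",
                keyword=self.orientation,
            )
        if self.binary_format == "int16" and not self.resolution > 0:
            raise FileFormatError("int16 resolution must be positive")


_BV_FORMATS = {"INT_16": "int16", "IEEE_FLOAT_32": "float32"}
_BV_ORIENTATIONS = {"MULTIPLEXED": "multiplexed", "VECTORIZED": "vectorized"}


def _read_ini(path: str) -> configparser.ConfigParser:
    parser = configparser.ConfigParser(strict=False, interpolation=None)
    parser.optionxform = str
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        text = fh.read()
    # first line is a magic comment, not INI
    body = "\n".join(
        line for line in text.splitlines() if not line.startswith(("Brain Vision", ";"))
    )
    parser.read_string(body)
    return parser


def read_brainvision(vhdr_path) -> Recording:
    """Read a BrainVision triple into a :class:`Recording` (data in uV).

    Supports INT_16 (with per-channel resolution) and IEEE_FLOAT_32 binary
    formats, multiplexed or vectorized.  Marker positions are converted to
    0-based sample indices.
    """
    vhdr_path = os.fspath(vhdr_path)
    if not os.path.exists(vhdr_path):
        raise FileFormatError(f"header file not found: {vhdr_path}", path=vhdr_path)
    hdr = _read_ini(vhdr_path)
    common = hdr["Common Infos"] if hdr.has_section("Common Infos") else {}
    base_dir = os.path.dirname(os.path.abspath(vhdr_path))
    for key in ("DataFile", "MarkerFile"):
        name = common.get(key)
        if name is None:
            raise FileFormatError(f"header lacks {key}", path=vhdr_path)
        target = os.path.join(base_dir, name)
        if not os.path.exists(target):
            raise FileFormatError(
                f"companion file referenced by {key} not found: {target}", path=target
            )
    fmt = hdr.get("Binary Infos", "BinaryFormat", fallback="IEEE_FLOAT_32").strip()
    if fmt not in _BV_FORMATS:
        raise FileFormatError(
            f"unsupported BinaryFormat keyword {fmt!r}", keyword=fmt, path=vhdr_path
        )
    orient = common.get("DataOrientation", "MULTIPLEXED").strip()
    if orient not in _BV_ORIENTATIONS:
        raise FileFormatError(
            f"unsupported DataOrientation keyword {orient!r}",
            keyword=orient,
            path=vhdr_path,
        )

    import mne

    raw = mne.io.read_raw_brainvision(vhdr_path, preload=True, verbose="error")
    labels = list(raw.ch_names)
    data = raw.get_data() * 1e6  # MNE stores volts for uV-unit channels
    types = [_infer_type(lab) for lab in labels]
    events = _read_vmrk(os.path.join(base_dir, common["MarkerFile"]))
    return Recording(
        channel_labels=labels,
        channel_types=types,
        fs=float(raw.info["sfreq"]),
        data=data,
        events=events,
    )


_MK_RE = re.compile(r"^Mk\d+=([^,]*),([^,]*),(\d+)")


def _read_vmrk(vmrk_path: str) -> list:
    events = []
    with open(vmrk_path, "r", encoding="utf-8", errors="replace") as fh:
        for line in fh:
            m = _MK_RE.match(line.strip())
            if not m:
                continue
            mtype, desc, pos = m.group(1), m.group(2), int(m.group(3))
            if mtype == "New Segment":
                continue
            label = f"{mtype}/{desc}" if desc else mtype
            events.append((pos - 1, label))
    return events


def write_brainvision(rec: Recording, base_path, dialect: BrainVisionDialect = None):
    """Write ``rec`` as a BrainVision triple ``base_path`` + .vhdr/.vmrk/.eeg.

    Returns the three paths.  The default dialect is multiplexed IEEE
    float32, which is lossless for float32-representable data.
    """
    if dialect is None:
        dialect = BrainVisionDialect()
    base_path = os.fspath(base_path)
    stem = os.path.basename(base_path)
    vhdr, vmrk, eeg = (base_path + ext for ext in (".vhdr", ".vmrk", ".eeg"))
    n_ch, n_samp = rec.data.shape

    if dialect.binary_format == "int16":
        scaled = rec.data / dialect.resolution
        if not np.all(np.abs(scaled) <= 32767):
            worst = int(np.argmax(np.max(np.abs(scaled), axis=1)))
            raise DataRangeError(
                f"channel {rec.channel_labels[worst]!r} exceeds the int16 range at "
                f"resolution {dialect.resolution} uV/bit"
            )
        payload = np.round(scaled).astype("<i2")
        fmt_kw, res = "INT_16", dialect.resolution
    else:
        payload = rec.data.astype("<f4")
        fmt_kw, res = "IEEE_FLOAT_32", 1.0

    order = payload.T if dialect.orientation == "multiplexed" else payload
    with open(eeg, "wb") as fh:
        fh.write(np.ascontiguousarray(order).tobytes())

    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "; Written by sasskit",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        f"MarkerFile={stem}.vmrk",
        "DataFormat=BINARY",
        f"DataOrientation={'MULTIPLEXED' if dialect.orientation == 'multiplexed' else 'VECTORIZED'}",
        f"NumberOfChannels={n_ch}",
        f"DataPoints={n_samp}",
        f"SamplingInterval={1e6 / rec.fs:g}",
        "",
        "[Binary Infos]",
        f"BinaryFormat={fmt_kw}",
        "",
        "[Channel Infos]",
    ]
    for i, lab in enumerate(rec.channel_labels):
        lines.append(f"Ch{i + 1}={lab},,{res:g},µV")
    with open(vhdr, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    for j, (sample, label) in enumerate(rec.events, start=2):
        if "/" in label:
            mtype, desc = label.split("/", 1)
        else:
            mtype, desc = "Stimulus", label
        mlines.append(f"Mk{j}={mtype},{desc},{int(sample) + 1},1,0")
    with open(vmrk, "w", encoding="utf-8") as fh:
        fh.write("\n".join(mlines) + "\n")
    return vhdr, vmrk, eeg


_MONTAGE_CACHE = {}


def standard_montage_64() -> dict:
    """2-D electrode positions for the 64-channel 10-10 cap.

    Idealized spherical 10-10 coordinates are projected with an
    azimuthal-equidistant map about the vertex, scaled to the unit disc, so
    that angular distance from Cz on the sphere maps to radial distance on
    the plot.  Midline electrodes land on x = 0; left/right pairs mirror.
    """
    if _MONTAGE_CACHE:
        return dict(_MONTAGE_CACHE)

    import mne

    std = mne.channels.make_standard_montage("easycap-M1")
    pos3d = std.get_positions()["ch_pos"]
    out = {}
    for lab in MONTAGE_64_LABELS:
        p = np.asarray(pos3d[lab], dtype=float)
        u = p / np.linalg.norm(p)
        theta = np.arccos(np.clip(u[2], -1.0, 1.0))  # polar angle from vertex
        hyp = np.hypot(u[0], u[1])
        if hyp < 1e-12:
            out[lab] = np.zeros(2)
        else:
            out[lab] = theta * np.array([u[0], u[1]]) / hyp
    rmax = max(np.linalg.norm(v) for v in out.values())
    out = {k: v / rmax for k, v in out.items()}
    # enforce exact midline / mirror symmetry of the idealized layout
    for lab, v in out.items():
        if lab.endswith("z") and abs(v[0]) < 1e-6:
            v[0] = 0.0
    _MONTAGE_CACHE.update(out)
    return dict(out)
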