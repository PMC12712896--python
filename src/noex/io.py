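"""Readers and writers for the on-disk formats the pipeline exchanges.

Keypoint tracks use the DeepLabCut CSV dialect (three header rows: scorer /
bodyparts / coords, with x, y, likelihood columns per part).  Syllable
sequences are two-column CSV (frame, label).  Photometry is HDF5 with
``signal``, ``sync`` datasets and an ``fs`` attribute, with a plain-CSV
fallback.  Bout and transient ground-truth logs are plain CSV tables.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import h5py
import numpy as np
import pandas as pd

from .keypoints import PARTS, KeypointTrack
from .photometry import DEFAULT_CARRIERS, RawPhotometry
from .syllables import SyllableSequence

__all__ = [
    "write_dlc_csv", "read_dlc_csv",
    "write_syllable_csv", "read_syllable_csv",
    "write_photometry_h5", "read_photometry_h5",
    "write_photometry_csv", "read_photometry_csv",
]

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# DeepLabCut-dialect keypoints
# ---------------------------------------------------------------------------

def write_dlc_csv(track: KeypointTrack, path: PathLike,
                  scorer: str = "noex") -> None:
    cols = pd.MultiIndex.from_tuples(
        [(scorer, part, coord) for part in track.xy
         for coord in ("x", "y", "likelihood")],
        names=["scorer", "bodyparts", "coords"])
    data = np.column_stack(
        [np.column_stack([track.xy[p], track.likelihood[p]]) for p in track.xy])
    pd.DataFrame(data, columns=cols).to_csv(path, index_label="frame")


def read_dlc_csv(path: PathLike, fps: float) -> KeypointTrack:
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    scorer = df.columns.get_level_values(0)[0]
    xy, lik = {}, {}
    for part in df.columns.get_level_values(1).unique():
        sub = df[scorer][part]
        xy[part] = sub[["x", "y"]].to_numpy(dtype=float)
        lik[part] = sub["likelihood"].to_numpy(dtype=float)
    return KeypointTrack(xy=xy, likelihood=lik, fps=fps)


# ---------------------------------------------------------------------------
# syllables
# ---------------------------------------------------------------------------

def write_syllable_csv(seq: SyllableSequence, path: PathLike) -> None:
    pd.DataFrame({"frame": np.arange(len(seq)),
                  "label": seq.labels}).to_csv(path, index=False)


def read_syllable_csv(path: PathLike, **metadata) -> SyllableSequence:
    df = pd.read_csv(path)
    df = df.sort_values("frame")
    return SyllableSequence(labels=df["label"].to_numpy(dtype=int), **metadata)


# ---------------------------------------------------------------------------
# photometry
# ---------------------------------------------------------------------------

def write_photometry_h5(raw: RawPhotometry, path: PathLike) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=raw.signal)
        f.create_dataset("sync", data=raw.sync)
        f.attrs["fs"] = raw.fs
        for name, fc in raw.carriers.items():
            f.attrs[f"carrier_{name}"] = fc


def read_photometry_h5(path: PathLike) -> RawPhotometry:
    with h5py.File(path, "r") as f:
        carriers = {k[len("carrier_"):]: float(v)
                    for k, v in f.attrs.items() if k.startswith("carrier_")}
        return RawPhotometry(signal=f["signal"][:], sync=f["sync"][:],
                             fs=float(f.attrs["fs"]), carriers=carriers)


def write_photometry_csv(raw: RawPhotometry, path: PathLike) -> None:
    """CSV fallback; fs and carriers ride in '#'-prefixed header lines."""
    with open(path, "w") as fh:
        fh.write(f"# fs={raw.fs}\n")
        for name, fc in raw.carriers.items():
            fh.write(f"# carrier_{name}={fc}\n")
        pd.DataFrame({"signal": raw.signal, "sync": raw.sync}).to_csv(
            fh, index=False)


def read_photometry_csv(path: PathLike) -> RawPhotometry:
    fs = None
    carriers = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            key, value = line[1:].strip().split("=")
            if key.strip() == "fs":
                fs = float(value)
            elif key.strip().startswith("carrier_"):
                carriers[key.strip()[len("carrier_"):]] = float(value)
    if fs is None:
        raise ValueError("missing '# fs=' header line")
    df = pd.read_csv(path, skiprows=skip)
    return RawPhotometry(signal=df["signal"].to_numpy(),
                         sync=df["sync"].to_numpy(), fs=fs,
                         carriers=carriers or dict(DEFAULT_CARRIERS))
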