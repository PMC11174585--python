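"""Sequence exchange formats: an array archive and a per-frame CSV dialect.

The archive is a numpy ``.npz`` container whose first member is a JSON
header (format version, layout name, fps, tensor shape, class map); each
sequence is stored as its own float64 array, so a round trip is bitwise
exact.  The CSV dialect (columns ``frame, joint, x, y[, z]``) is the
human-readable interchange path for converting third-party exports; it
round-trips to the declared decimal precision.  One archive holds one
layout and one frame rate.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .synthetic import SkeletonSequence

__all__ = ["write_sequences", "read_sequences", "write_csv", "read_csv", "ArchiveError"]

FORMAT_VERSION = 1


class ArchiveError(ValueError):
    """Version, shape or truncation problem in a sequence archive."""


def write_sequences(path, sequences: list[SkeletonSequence]) -> None:
    """Write a homogeneous sequence list to an ``.npz`` archive."""
    if not sequences:
        raise ArchiveError("refusing to write an empty archive")
    c, t, v = sequences[0].shape
    fps = sequences[0].fps
    layouts = {s.provenance.get("layout", "unknown") for s in sequences}
    if len(layouts) > 1:
        raise ArchiveError(f"mixed layouts in one archive: {sorted(layouts)}")
    for s in sequences:
        if s.shape != (c, t, v):
            raise ArchiveError(f"shape {s.shape} != archive shape {(c, t, v)}")
        if s.fps != fps:
            raise ArchiveError("mixed frame rates in one archive")
    header = {
        "format_version": FORMAT_VERSION,
        "layout": layouts.pop(),
        "fps": fps,
        "channels": c,
        "frames": t,
        "joints": v,
        "n_sequences": len(sequences),
        "labels": [int(s.label) for s in sequences],
        "subject_ids": [s.subject_id for s in sequences],
        "provenance": [s.provenance for s in sequences],
    }
    arrays = {f"seq_{i:06d}": s.values for i, s in enumerate(sequences)}
    np.savez(
        path,
        __header__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
        **arrays,
    )


def read_sequences(path) -> list[SkeletonSequence]:
    """Read an archive written by :func:`write_sequences` (bitwise round trip)."""
    try:
        data = np.load(path)
    except Exception as exc:  # truncated / not an npz
        raise ArchiveError(f"cannot read archive {path}: {exc}") from exc
    with data:
        if "__header__" not in data.files:
            raise ArchiveError("missing archive header")
        header = json.loads(bytes(data["__header__"]).decode())
        version = header.get("format_version")
        if version != FORMAT_VERSION:
            raise ArchiveError(f"unrecognized format version {version!r}")
        n = header["n_sequences"]
        shape = (header["channels"], header["frames"], header["joints"])
        out = []
        for i in range(n):
            key = f"seq_{i:06d}"
            if key not in data.files:
                raise ArchiveError(f"archive truncated: missing {key}")
            values = data[key]
            if values.shape != shape:
                raise ArchiveError(
                    f"sequence {i} shape {values.shape} != header shape {shape}"
                )
            out.append(
                SkeletonSequence(
                    values=values,
                    fps=header["fps"],
                    label=header["labels"][i],
                    subject_id=header["subject_ids"][i],
                    provenance=header["provenance"][i],
                )
            )
    return out


def write_csv(path, seq: SkeletonSequence, precision: int = 9) -> None:
    """One sequence as per-frame rows ``frame, joint, x, y[, z]``.

    Metadata (fps, label, layout) goes into ``#``-prefixed comment lines.
    """
    c, t, v = seq.shape
    cols = ["x", "y", "z"][:c]
    frames = np.repeat(np.arange(t), v)
    joints = np.tile(np.arange(v), t)
    table = pd.DataFrame({"frame": frames, "joint": joints})
    # stored values are (C, T, V); CSV rows are frame-major
    for k, col in enumerate(cols):
        table[col] = seq.values[k].reshape(-1)
    with open(path, "w") as fh:
        fh.write(f"# fps={seq.fps}\n# label={seq.label}\n")
        fh.write(f"# layout={seq.provenance.get('layout', 'unknown')}\n")
        table.to_csv(fh, index=False, float_format=f"%.{precision}g")


def read_csv(path) -> SkeletonSequence:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
        table = pd.read_csv(fh)
    required = {"frame", "joint", "x", "y"}
    if not required.issubset(table.columns):
        raise ArchiveError(f"CSV missing columns {sorted(required - set(table.columns))}")
    cols = [c for c in ("x", "y", "z") if c in table.columns]
    t = int(table["frame"].max()) + 1
    v = int(table["joint"].max()) + 1
    if len(table) != t * v:
        raise ArchiveError(f"expected {t * v} rows for T={t}, V={v}, got {len(table)}")
    table = table.sort_values(["frame", "joint"])
    values = np.stack(
        [table[c].to_numpy(dtype=np.float64).reshape(t, v) for c in cols], axis=0
    )
    return SkeletonSequence(
        values=values,
        fps=float(meta.get("fps", 30.0)),
        label=int(meta.get("label", -1)),
        provenance={"layout": meta.get("layout", "unknown"), "source": "csv"},
    )
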