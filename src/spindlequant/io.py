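"""CSV/TIFF/YAML input and output for traces and spindle images.

Traces travel as long-format CSV with columns ``time_s, intensity,
is_prebleach, trace_id, role`` (role is ``sample`` or ``control``); images
as channel-major multi-page TIFF with a YAML sidecar (``<path>.yaml``)
holding the pixel size, pole coordinates, channel names and optional z
depth.  Round trips are lossless for the values stored.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .frap import FrapTrace
from .profile import SpindleImage, max_project

__all__ = [
    "TRACE_COLUMNS",
    "read_traces",
    "write_traces",
    "pair_traces",
    "read_image",
    "write_image",
]

TRACE_COLUMNS = ("time_s", "intensity", "is_prebleach", "trace_id", "role")
_ROLES = ("sample", "control")


def write_traces(pairs, path) -> None:
    """Write (sample, control) pairs — or bare traces — to CSV."""
    rows = []
    flat: list[tuple[str, str, FrapTrace]] = []
    for i, item in enumerate(pairs):
        if isinstance(item, FrapTrace):
            flat.append((f"t{i:03d}", "sample", item))
        else:
            sample, control = item
            flat.append((f"t{i:03d}", "sample", sample))
            flat.append((f"t{i:03d}", "control", control))
    for trace_id, role, tr in flat:
        for k, (t, v) in enumerate(zip(tr.times, tr.intensities)):
            rows.append(
                {
                    "time_s": t,
                    "intensity": v,
                    "is_prebleach": k < tr.n_pre,
                    "trace_id": trace_id,
                    "role": role,
                }
            )
    pd.DataFrame(rows, columns=list(TRACE_COLUMNS)).to_csv(path, index=False)


def read_traces(path) -> list[FrapTrace]:
    """Read all traces from a CSV written by :func:`write_traces`.

    Returns one :class:`FrapTrace` per (trace_id, role) pair, labelled
    ``"{trace_id}/{role}"``, in file order.  Schema violations are
    reported with the offending column or row.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace CSV is missing column(s): {', '.join(missing)}")
    bad_role = df[~df["role"].isin(_ROLES)]
    if not bad_role.empty:
        raise ValueError(
            f"invalid role {bad_role['role'].iloc[0]!r} at row "
            f"{int(bad_role.index[0]) + 2}"  # +2: header + 1-based
        )
    traces = []
    for (trace_id, role), grp in df.groupby(["trace_id", "role"], sort=False):
        grp = grp.sort_values("time_s")
        n_pre = int(grp["is_prebleach"].sum())
        if not grp["is_prebleach"].iloc[:n_pre].all():
            raise ValueError(
                f"trace {trace_id}/{role}: pre-bleach frames must precede "
                "post-bleach frames"
            )
        traces.append(
            FrapTrace(
                times=grp["time_s"].to_numpy(float),
                intensities=grp["intensity"].to_numpy(float),
                n_pre=n_pre,
                label=f"{trace_id}/{role}",
            )
        )
    return traces


def pair_traces(traces) -> list[tuple[FrapTrace, FrapTrace]]:
    """Match sample and control traces sharing a trace id."""
    samples, controls = {}, {}
    for tr in traces:
        tid, _, role = tr.label.rpartition("/")
        (samples if role == "sample" else controls)[tid] = tr
    pairs = []
    for tid, s in samples.items():
        if tid not in controls:
            raise ValueError(f"trace {tid} has no matching control")
        pairs.append((s, controls[tid]))
    return pairs


def _sidecar(path) -> Path:
    return Path(str(path) + ".yaml")


def write_image(image: SpindleImage, path) -> None:
    """Write a spindle image as channel-major TIFF plus a YAML sidecar."""
    names = list(image.channels)
    pages = np.stack([image.channels[n] for n in names]).astype(np.float32)
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {
        "pixel_size_um": float(image.pixel_size),
        "poles": [[float(v) for v in p] for p in image.poles],
        "channels": names,
        "provenance": image.provenance,
        "n_z": 1,
    }
    with open(_sidecar(path), "w") as fh:
        yaml.safe_dump(meta, fh)


def read_image(path, project: bool = False) -> SpindleImage:
    """Read a TIFF + sidecar pair back into a :class:`SpindleImage`.

    If the sidecar declares ``n_z > 1`` the pages are grouped per channel
    and, with ``project=True``, reduced by maximum-intensity projection
    (required before 2-D analysis).
    """
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise ValueError(
            f"missing sidecar {sidecar}: pixel size is required for "
            "micrometre-scale results"
        )
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh)
    if "pixel_size_um" not in meta:
        raise ValueError("sidecar lacks pixel_size_um")
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    names = meta["channels"]
    n_z = int(meta.get("n_z", 1))
    channels = {}
    for i, name in enumerate(names):
        block = pages[i * n_z : (i + 1) * n_z]
        if n_z == 1:
            channels[name] = block[0]
        elif project:
            channels[name] = max_project(block)
        else:
            raise ValueError(
                "multi-z image: pass project=True to collapse the stack"
            )
    provenance = "projection" if (n_z > 1 and project) else meta.get(
        "provenance", "projection"
    )
    return SpindleImage(
        channels=channels,
        pixel_size=float(meta["pixel_size_um"]),
        poles=tuple(tuple(p) for p in meta["poles"]),
        provenance=provenance,
    )
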