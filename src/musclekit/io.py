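"""Reading and writing the package's on-disk formats.

Traces travel as two-column delimited text (time_s, value) with a JSON
sidecar holding the protocol, units and ground truth; images as
multi-channel TIFF with channel names and pixel size in the TIFF
metadata; expression matrices as delimited gene x sample tables; panels
and protocols as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import ForceTrace, StimulationProtocol
from .morphometry import MultiChannelImage
from .scoring import GenePanel

__all__ = [
    "write_trace", "read_trace", "write_image", "read_image",
    "write_expression", "read_expression", "read_panel", "write_panel",
    "read_protocol_yaml",
]


def write_trace(trace: ForceTrace, path, ground_truth: dict | None = None) -> None:
    """Write (time_s, value) delimited text plus a ``.json`` sidecar."""
    path = Path(path)
    arr = np.column_stack([trace.times, trace.values])
    header = f"time_s\t{'deflection_mm' if trace.units == 'mm' else 'force_mN'}"
    np.savetxt(path, arr, delimiter="\t", header=header, comments="")
    sidecar = {
        "sampling_rate": trace.sampling_rate,
        "units": trace.units,
        "stimulus_times": trace.stimulus_times.tolist(),
        "protocol": trace.protocol.to_dict() if trace.protocol else None,
        "metadata": trace.metadata,
    }
    if ground_truth is not None:
        sidecar["ground_truth"] = ground_truth
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1))


def read_trace(path) -> tuple[ForceTrace, dict | None]:
    """Read a trace written by :func:`write_trace`; returns (trace, gt)."""
    path = Path(path)
    arr = np.loadtxt(path, delimiter="\t", skiprows=1)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        protocol = (StimulationProtocol.from_dict(sidecar["protocol"])
                    if sidecar.get("protocol") else None)
        trace = ForceTrace(sampling_rate=sidecar["sampling_rate"],
                           values=arr[:, 1], units=sidecar["units"],
                           stimulus_times=np.asarray(sidecar["stimulus_times"]),
                           protocol=protocol,
                           metadata=sidecar.get("metadata", {}))
        return trace, sidecar.get("ground_truth")
    dt = float(np.median(np.diff(arr[:, 0])))
    return ForceTrace(sampling_rate=1.0 / dt, values=arr[:, 1]), None


def write_image(image: MultiChannelImage, path) -> None:
    """Write channels as a (C, H, W) TIFF with names and pixel size."""
    names = list(image.channels)
    stack = np.stack([image.channels[n].astype(np.float32) for n in names])
    meta = {"channel_names": names, "pixel_size_um": image.pixel_size,
            **image.metadata}
    tifffile.imwrite(str(path), stack, metadata=meta,
                     photometric="minisblack")


def read_image(path, pixel_size: float | None = None) -> MultiChannelImage:
    """Read a TIFF written by :func:`write_image`.

    ``pixel_size`` overrides (or supplies, for foreign files) the scale.
    """
    with tifffile.TiffFile(str(path)) as tf:
        stack = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if stack.ndim == 2:
        stack = stack[None]
    names = meta.get("channel_names") or [f"ch{i}" for i in range(stack.shape[0])]
    px = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
    if px is None:
        raise ValueError("pixel size missing from metadata; pass pixel_size=")
    extra = {k: v for k, v in meta.items()
             if k not in ("channel_names", "pixel_size_um", "shape")}
    return MultiChannelImage(channels={n: stack[i] for i, n in enumerate(names)},
                             pixel_size=float(px), metadata=extra)


def write_expression(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_panel(path) -> GenePanel:
    """Read a gene panel from YAML: {name: ..., members: [...]}."""
    d = yaml.safe_load(Path(path).read_text())
    return GenePanel(name=d["name"], members=tuple(d["members"]))


def write_panel(panel: GenePanel, path) -> None:
    Path(path).write_text(yaml.safe_dump(
        {"name": panel.name, "members": list(panel.members)}))


def read_protocol_yaml(path) -> StimulationProtocol:
    """Read a stimulation protocol from YAML (preset name or full fields)."""
    d = yaml.safe_load(Path(path).read_text())
    if isinstance(d, str):
        d = {"kind": d}
    kind = d.pop("kind")
    if kind == "twitch":
        return StimulationProtocol.twitch(**d)
    if kind == "force_frequency":
        return StimulationProtocol.force_frequency(**d)
    raise ValueError(f"unknown protocol kind {kind!r}")
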