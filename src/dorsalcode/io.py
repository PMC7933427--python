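"""Reading and writing the pipeline's on-disk formats.

Images travel as multi-page TIFF (one page per channel) with a JSON sidecar
(`<stem>.channels.json`) naming channel roles; label maps as 16-bit TIFF;
tables as CSV with fixed column names.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .simulate import ImageStack


def write_image_stack(stack: ImageStack, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, stack.data, photometric="minisblack")
    sidecar = path.with_suffix(".channels.json")
    sidecar.write_text(
        json.dumps(
            {"names": stack.channel_names, "roles": stack.channel_roles}, indent=2
        )
    )


def read_image_stack(path) -> ImageStack:
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    sidecar = path.with_suffix(".channels.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        names, roles = meta["names"], meta["roles"]
    else:  # sensible fallback: first page nuclear, rest probes
        names = ["nuclear"] + [f"probe{i}" for i in range(1, data.shape[0])]
        roles = ["nuclear"] + ["probe"] * (data.shape[0] - 1)
    return ImageStack(
        data=np.asarray(data, dtype=np.float32), channel_names=names, channel_roles=roles
    )


def write_label_map(labels: np.ndarray, path) -> None:
    labels = np.asarray(labels)
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 objects; cannot write 16-bit label map")
    tifffile.imwrite(Path(path), labels.astype(np.uint16), photometric="minisblack")


def read_label_map(path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.int32)
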