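"""File formats: multichannel TIFF with channel names, label TIFF, CSV
tables with provenance headers, spectral-library CSV.

CSV dialect: UTF-8, comma separated, header row, "." decimal, missing values
as empty fields. Every table written by the pipeline carries a provenance
comment line (config hash and seed) that readers skip transparently.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .unmix import SpectralLibrary

__all__ = [
    "write_multichannel_tiff",
    "read_multichannel_tiff",
    "write_label_tiff",
    "read_label_tiff",
    "write_table",
    "read_table",
    "write_library_csv",
    "read_library_csv",
]


def write_multichannel_tiff(
    path: str | Path,
    pixels: np.ndarray,
    channel_names: list[str],
    um_per_px: float | None = None,
) -> None:
    """Write a (C, H, W) stack as one TIFF page per channel.

    Channel names and pixel size are stored in the shaped-TIFF JSON
    metadata, which ``tifffile`` round-trips.
    """
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[0] != len(channel_names):
        raise ValueError("pixels must be (C, H, W) matching channel_names")
    meta = {"axes": "CYX", "channel_names": list(channel_names)}
    if um_per_px is not None:
        meta["um_per_px"] = um_per_px
    kwargs = {"photometric": "minisblack"}
    if pixels.shape[0] > 1:
        kwargs["planarconfig"] = "separate"
    tifffile.imwrite(Path(path), pixels, metadata=meta, **kwargs)


def read_multichannel_tiff(path: str | Path) -> tuple[np.ndarray, list[str], float | None]:
    """Read a multichannel TIFF; returns (pixels, channel_names, um_per_px)."""
    with tifffile.TiffFile(Path(path)) as tf:
        pixels = tf.asarray()
        meta = (tf.shaped_metadata or [{}])[0]
    if pixels.ndim == 2:
        pixels = pixels[None]
    names = list(meta.get("channel_names", [f"channel_{i}" for i in range(pixels.shape[0])]))
    return pixels, names, meta.get("um_per_px")


def write_label_tiff(path: str | Path, labels: dict[str, np.ndarray]) -> None:
    """Write named integer label images as a multipage TIFF."""
    names = list(labels)
    stack = np.stack([np.asarray(labels[n], dtype=np.int32) for n in names])
    write_multichannel_tiff(path, stack, names)


def read_label_tiff(path: str | Path) -> dict[str, np.ndarray]:
    pixels, names, _ = read_multichannel_tiff(path)
    return {n: pixels[i].astype(np.int32) for i, n in enumerate(names)}


def write_table(
    path: str | Path,
    df: pd.DataFrame,
    config_hash: str | None = None,
    seed: int | None = None,
) -> None:
    """Write a CSV table with an optional provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if config_hash is not None or seed is not None:
            fh.write(f"# provenance: config_hash={config_hash} seed={seed}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), comment="#")


def read_provenance(path: str | Path) -> dict[str, str]:
    """Parse the provenance comment of a pipeline CSV (empty if absent)."""
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    out: dict[str, str] = {}
    if first.startswith("# provenance:"):
        for tok in first.split(":", 1)[1].split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                out[k] = v
    return out


def write_library_csv(path: str | Path, library: SpectralLibrary) -> None:
    """Library as CSV: rows = spectral bands, columns = fluorophores."""
    library.to_frame().to_csv(Path(path), index_label="band")


def read_library_csv(path: str | Path) -> SpectralLibrary:
    df = pd.read_csv(Path(path), index_col="band")
    return SpectralLibrary.from_frame(df)
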