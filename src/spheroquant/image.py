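"""Multi-channel image container and lossless TIFF round-trip.

All imaging operations in the package consume and produce
:class:`MultiChannelImage`: a dict-like bundle of equally shaped 2D float
rasters addressed by channel name (e.g. ``brightfield``, ``CTR``, ``PI``,
``dapi``).  Coordinates are pixel-space, origin top-left, x to the right and
y down; an optional physical pixel size (μm/px) may be carried along but no
operation converts to physical units unless it is present.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = ["MultiChannelImage", "read_image", "write_image"]


@dataclass
class MultiChannelImage:
    """Named-channel 2D pixel raster.

    Parameters
    ----------
    channels : dict of str -> ndarray
        One 2D array per channel; all channels must share a shape and hold
        finite, non-negative intensities.
    pixel_size_um : float, optional
        Physical edge length of one pixel in micrometres.
    provenance : str
        Free-form tag recording where the image came from (file path,
        generator call, ...).
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float | None = None
    provenance: str = ""
    _shape: tuple[int, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("MultiChannelImage needs at least one channel")
        shapes = {name: np.asarray(arr).shape for name, arr in self.channels.items()}
        uniq = set(shapes.values())
        if len(uniq) != 1:
            raise ValueError(f"channel shapes disagree: {shapes}")
        (shape,) = uniq
        if len(shape) != 2:
            raise ValueError(f"channels must be 2D, got shape {shape}")
        for name, arr in self.channels.items():
            arr = np.asarray(arr, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} contains non-finite values")
            if (arr < 0).any():
                raise ValueError(f"channel {name!r} contains negative intensities")
            self.channels[name] = arr
        self._shape = shape

    @property
    def shape(self) -> tuple[int, int]:
        return self._shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"channel {name!r} not present; available: {self.channel_names}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self.channels


def write_image(img: MultiChannelImage, path) -> None:
    """Write as a multi-page float32 TIFF, channel names in the description tag."""
    names = img.channel_names
    stack = np.stack([img.channels[n].astype(np.float32) for n in names])
    meta = {"channel_names": names}
    if img.pixel_size_um is not None:
        meta["pixel_size_um"] = img.pixel_size_um
    tifffile.imwrite(path, stack, description=json.dumps(meta))


def read_image(path, channel_names: list[str] | None = None) -> MultiChannelImage:
    """Read a single- or multi-page TIFF into a :class:`MultiChannelImage`.

    Channel names are taken from the JSON description written by
    :func:`write_image` when present; otherwise from ``channel_names``;
    otherwise pages are named ``page0``, ``page1``, ...

    Raises
    ------
    ValueError
        If a requested channel name is missing (the message lists what is
        available) or page shapes disagree.
    """
    with tifffile.TiffFile(path) as tif:
        pages = [p.asarray() for p in tif.pages]
        desc = tif.pages[0].description or ""
    if not pages:
        raise ValueError(f"{path}: no image pages")
    arr0 = pages[0]
    if arr0.ndim == 3:  # stack stored in one page
        pages = list(arr0)
    shapes = {p.shape for p in pages}
    if len(shapes) != 1:
        raise ValueError(f"{path}: page shapes disagree: {sorted(shapes)}")

    meta: dict = {}
    try:
        meta = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        pass
    names = meta.get("channel_names")
    if names is None:
        names = channel_names or [f"page{i}" for i in range(len(pages))]
    if len(names) != len(pages):
        raise ValueError(
            f"{path}: {len(names)} channel names for {len(pages)} pages "
            f"(available pages: {list(range(len(pages)))})"
        )
    if channel_names is not None and names is not channel_names:
        missing = [c for c in channel_names if c not in names]
        if missing:
            raise ValueError(
                f"{path}: requested channels {missing} not found; available: {names}"
            )
    channels = {n: np.asarray(p, dtype=float) for n, p in zip(names, pages)}
    return MultiChannelImage(
        channels,
        pixel_size_um=meta.get("pixel_size_um"),
        provenance=str(path),
    )
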