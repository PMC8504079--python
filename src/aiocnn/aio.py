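"""Artificial image objects (AIOs): genes as pixels, expression as intensity.

An AIO is an image tensor in which every pixel position is permanently
assigned to one gene; a sample's image carries that sample's rescaled
(0-255) expression at each gene's pixel.  Genes fill the image in their
genome-position order: row-major within a channel, channel-major across
channels, 0-based.  16,384 genes exactly fill a 128 x 128 grayscale image
(the first 128 genes form the first row) or a 64 x 64 x 4 multi-channel
image (the first 4,096 genes form the first channel).

Because the mapping depends only on the gene order and the configuration,
the same gene occupies the same coordinate in every sample's image, and the
map is exactly invertible — any pixel a classifier attends to can be traced
back to its gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import BoundsError, FormatError, MissingGeneError, SizingError
from .expression import ScaledMatrix

__all__ = [
    "AIOConfig",
    "PixelMap",
    "AIOTensor",
    "make_pixel_map",
    "build_aio",
    "build_aios",
    "gene_at",
    "save_aios_npz",
    "load_aios_npz",
    "save_aio_png",
    "load_aio_png",
]


@dataclass(frozen=True)
class AIOConfig:
    """Image geometry: ``channels`` x ``height`` x ``width`` pixels.

    ``pad_policy`` controls gene lists smaller than the capacity:
    ``"zero"`` pads trailing pixels with intensity 0, ``"error"`` refuses.
    """

    height: int
    width: int
    channels: int = 1
    pad_policy: str = "zero"

    def __post_init__(self) -> None:
        if min(self.height, self.width, self.channels) < 1:
            raise SizingError("height, width and channels must be positive")
        if self.pad_policy not in ("zero", "error"):
            raise SizingError(f"unknown pad policy {self.pad_policy!r}")

    @property
    def capacity(self) -> int:
        return self.height * self.width * self.channels

    @classmethod
    def parse(cls, text: str, pad_policy: str = "zero") -> "AIOConfig":
        """Parse ``"128x128"`` / ``"64x64x4"`` style geometry strings."""
        parts = [int(p) for p in text.lower().split("x")]
        if len(parts) == 2:
            h, w = parts
            c = 1
        elif len(parts) == 3:
            h, w, c = parts
        else:
            raise SizingError(f"cannot parse AIO geometry {text!r}")
        return cls(height=h, width=w, channels=c, pad_policy=pad_policy)


@dataclass
class PixelMap:
    """Invertible gene <-> (channel, row, col) assignment for one config."""

    genes: list[str]
    config: AIOConfig

    def __post_init__(self) -> None:
        self._index = {g: i for i, g in enumerate(self.genes)}
        if len(self._index) != len(self.genes):
            raise SizingError("pixel map gene list contains duplicates")

    def __len__(self) -> int:
        return len(self.genes)

    def coord_of(self, gene: str) -> tuple[int, int, int]:
        """Forward map: gene -> (channel, row, col)."""
        try:
            i = self._index[gene]
        except KeyError:
            raise MissingGeneError(f"gene {gene!r} is not mapped")
        return self._coord_of_index(i)

    def _coord_of_index(self, i: int) -> tuple[int, int, int]:
        hw = self.config.height * self.config.width
        c, j = divmod(i, hw)
        r, k = divmod(j, self.config.width)
        return (c, r, k)

    def gene_at(self, coord: tuple[int, int, int]) -> str | None:
        """Inverse map: (channel, row, col) -> gene, or None for padding."""
        c, r, k = coord
        cfg = self.config
        if not (0 <= c < cfg.channels and 0 <= r < cfg.height and 0 <= k < cfg.width):
            raise BoundsError(
                f"coordinate {coord} outside "
                f"{cfg.channels}x{cfg.height}x{cfg.width}"
            )
        i = (c * cfg.height + r) * cfg.width + k
        return self.genes[i] if i < len(self.genes) else None

    def to_frame(self) -> pd.DataFrame:
        coords = [self._coord_of_index(i) for i in range(len(self.genes))]
        return pd.DataFrame(
            {
                "gene": self.genes,
                "channel": [c for c, _, _ in coords],
                "row": [r for _, r, _ in coords],
                "col": [k for _, _, k in coords],
            }
        )

    def save(self, path: str | Path) -> None:
        df = self.to_frame()
        df.attrs = {}
        with open(path, "w") as fh:
            fh.write(f"# aio {self.config.height}x{self.config.width}"
                     f"x{self.config.channels} pad={self.config.pad_policy}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def load(cls, path: str | Path) -> "PixelMap":
        with open(path) as fh:
            header = fh.readline().strip()
            df = pd.read_csv(fh, sep="\t")
        geom = header.split()[2]
        pad = header.split("pad=")[1]
        cfg = AIOConfig.parse(geom, pad_policy=pad)
        return make_pixel_map(df["gene"].astype(str).tolist(), cfg)


@dataclass
class AIOTensor:
    """One sample's image object: integer intensities (C, H, W) in [0, 255]."""

    sample_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3:
            raise SizingError("AIO tensor must be (channels, height, width)")
        if v.min(initial=0) < 0 or v.max(initial=0) > 255:
            raise SizingError("AIO intensities must lie in [0, 255]")
        self.values = v.astype(np.uint8)


def make_pixel_map(order: Sequence[str], config: AIOConfig) -> PixelMap:
    """Assign each gene of ``order`` to its pixel under ``config``.

    Gene i (0-based) goes to channel ``i // (H*W)``, then row-major within
    the channel.  Orders longer than the capacity always fail; shorter
    orders fail under ``pad_policy="error"`` and leave trailing zero pixels
    under ``"zero"``.
    """
    n = len(order)
    if n > config.capacity:
        raise SizingError(
            f"{n} genes exceed the {config.capacity}-pixel capacity of "
            f"{config.height}x{config.width}x{config.channels}"
        )
    if n < config.capacity and config.pad_policy == "error":
        raise SizingError(
            f"{n} genes under-fill the {config.capacity}-pixel capacity "
            f"and pad_policy is 'error'"
        )
    return PixelMap(genes=list(order), config=config)


def gene_at(pmap: PixelMap, coord: tuple[int, int, int]) -> str | None:
    """Module-level alias of :meth:`PixelMap.gene_at`."""
    return pmap.gene_at(coord)


def build_aio(
    sample_id: str,
    gene_values: Mapping[str, int],
    pmap: PixelMap,
) -> AIOTensor:
    """Materialize one sample's AIO from a gene -> intensity mapping."""
    cfg = pmap.config
    flat = np.zeros(cfg.capacity, dtype=np.uint8)
    for i, g in enumerate(pmap.genes):
        if g not in gene_values:
            raise MissingGeneError(f"no value for mapped gene {g!r}")
        flat[i] = gene_values[g]
    return AIOTensor(
        sample_id=sample_id,
        values=flat.reshape(cfg.channels, cfg.height, cfg.width),
    )


def build_aios(scaled: ScaledMatrix, pmap: PixelMap) -> np.ndarray:
    """Materialize a whole cohort: (n_samples, C, H, W) uint8 tensor stack.

    The scaled matrix's column order must equal the pixel map's gene list
    (both derive from the same genome-position order), which makes the
    construction a reshape plus zero padding.
    """
    if list(scaled.gene_order) != list(pmap.genes):
        raise MissingGeneError("scaled-matrix gene order differs from pixel map")
    cfg = pmap.config
    n = scaled.shape[0]
    flat = np.zeros((n, cfg.capacity), dtype=np.uint8)
    flat[:, : len(pmap.genes)] = scaled.values
    return flat.reshape(n, cfg.channels, cfg.height, cfg.width)


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------

def save_aios_npz(path: str | Path, tensors: np.ndarray,
                  sample_ids: Sequence[str], pmap: PixelMap | None = None) -> None:
    """Write an (N, C, H, W) stack with sample ids to an ``.npz`` container.

    When a pixel map is given, a delimited-text companion
    ``<path>.pixelmap.tsv`` records the gene <-> coordinate table.
    """
    tensors = np.asarray(tensors, dtype=np.uint8)
    np.savez_compressed(path, tensors=tensors,
                        sample_ids=np.asarray(sample_ids, dtype=str))
    if pmap is not None:
        pmap.save(str(path) + ".pixelmap.tsv")


def load_aios_npz(path: str | Path) -> tuple[np.ndarray, list[str]]:
    with np.load(path, allow_pickle=False) as z:
        return z["tensors"].astype(np.uint8), [str(s) for s in z["sample_ids"]]


_PNG_MODES = {1: "L", 3: "RGB", 4: "RGBA"}


def save_aio_png(path: str | Path, tensor: AIOTensor | np.ndarray) -> None:
    """Write one AIO losslessly as PNG (1 -> grayscale, 3 -> RGB, 4 -> RGBA).

    Channel semantics are positional; the color mapping is purely a storage
    convenience.  Channel counts without a PNG mode raise ``FormatError``.
    """
    from PIL import Image

    values = tensor.values if isinstance(tensor, AIOTensor) else np.asarray(tensor)
    c = values.shape[0]
    if c not in _PNG_MODES:
        raise FormatError(f"cannot store a {c}-channel AIO as PNG")
    if c == 1:
        img = Image.fromarray(values[0].astype(np.uint8), mode="L")
    else:
        img = Image.fromarray(
            np.moveaxis(values, 0, -1).astype(np.uint8), mode=_PNG_MODES[c]
        )
    img.save(path, format="PNG")


def load_aio_png(path: str | Path) -> np.ndarray:
    """Read a PNG written by :func:`save_aio_png` back to (C, H, W) uint8."""
    from PIL import Image

    arr = np.asarray(Image.open(path))
    if arr.ndim == 2:
        return arr[None, :, :].astype(np.uint8)
    return np.moveaxis(arr, -1, 0).astype(np.uint8)
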