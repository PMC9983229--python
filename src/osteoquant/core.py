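"""Core containers shared across the pipeline.

The central object is :class:`ImageStack`, a calibrated multi-dimensional
fluorescence stack (time x z x y x x x channel) carrying the physical voxel
sizes and the frame interval needed to express every downstream measurement
in micrometres and minutes rather than pixels and frames.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

__all__ = ["ImageStack"]


@dataclass
class ImageStack:
    """A calibrated fluorescence image stack.

    Parameters
    ----------
    data
        Intensity array whose dimensions follow ``axes`` (default
        ``"TZYXC"``: time, z, y, x, channel).
    channel_names
        One name per entry of the ``C`` axis.  For raw acquisitions these
        are detection bands; after spectral unmixing they are fluorophores.
    pixel_size_um
        Lateral (y and x) pixel size in micrometres.
    z_step_um
        Axial step in micrometres, or ``None`` when the stack has no z axis
        (e.g. after a maximum-intensity projection).
    frame_interval_s
        Time between consecutive frames in seconds, or ``None`` for a
        single snapshot.
    """

    data: np.ndarray
    channel_names: tuple[str, ...]
    pixel_size_um: float
    z_step_um: float | None = None
    frame_interval_s: float | None = None
    axes: str = "TZYXC"

    def __post_init__(self) -> None:
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != len(self.axes):
            raise ValueError(
                f"data has {self.data.ndim} dimensions but axes is {self.axes!r}"
            )
        if "C" in self.axes and self.data.shape[self.axis("C")] != len(self.channel_names):
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[self.axis('C')]} channels"
            )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.z_step_um is not None and self.z_step_um <= 0:
            raise ValueError("z_step_um must be positive")
        if "Z" in self.axes and self.z_step_um is None:
            raise ValueError("stack has a Z axis but no z_step_um")

    # -- axis bookkeeping -------------------------------------------------

    def axis(self, label: str) -> int:
        idx = self.axes.find(label)
        if idx < 0:
            raise ValueError(f"stack has no {label!r} axis (axes={self.axes!r})")
        return idx

    @property
    def has_z(self) -> bool:
        return "Z" in self.axes

    @property
    def n_frames(self) -> int:
        return self.data.shape[self.axis("T")]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None

    def channel(self, name: str) -> np.ndarray:
        """Return one channel as an array without the C axis."""
        return np.take(self.data, self.channel_index(name), axis=self.axis("C"))

    def with_data(self, data: np.ndarray, **changes) -> "ImageStack":
        return replace(self, data=data, **changes)

    @property
    def voxel_volume_um3(self) -> float:
        if self.z_step_um is None:
            raise ValueError("stack is 2D; voxel volume undefined")
        return self.pixel_size_um**2 * self.z_step_um

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um**2

    # -- OME-TIFF round trip ----------------------------------------------

    def to_tiff(self, path: str | Path) -> None:
        """Write the stack as OME-TIFF with voxel calibration metadata."""
        # store with the channel axis before Y/X (the OME-favoured layout;
        # a trailing channel axis is misread as RGB-style samples)
        store_axes = self.axes.replace("C", "")
        insert_at = store_axes.index("Y")
        store_axes = store_axes[:insert_at] + "C" + store_axes[insert_at:]
        store = np.moveaxis(
            self.data, self.axis("C"), store_axes.index("C")
        )
        metadata = {
            "axes": store_axes,
            "PhysicalSizeX": self.pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": self.pixel_size_um,
            "PhysicalSizeYUnit": "µm",
            "Channel": {"Name": list(self.channel_names)},
        }
        if self.z_step_um is not None:
            metadata["PhysicalSizeZ"] = self.z_step_um
            metadata["PhysicalSizeZUnit"] = "µm"
        if self.frame_interval_s is not None:
            metadata["TimeIncrement"] = self.frame_interval_s
            metadata["TimeIncrementUnit"] = "s"
        tifffile.imwrite(
            Path(path),
            store.astype(np.float32),
            ome=True,
            metadata=metadata,
        )

    @classmethod
    def from_tiff(cls, path: str | Path) -> "ImageStack":
        with tifffile.TiffFile(Path(path)) as tf:
            series = tf.series[0]
            data = series.asarray()
            axes = series.axes.replace("S", "C")
            ome = tf.ome_metadata
        pixel_size = 1.0
        z_step = None
        interval = None
        names: list[str] = []
        if ome:
            root = ET.fromstring(ome)
            ns = {"ome": root.tag.split("}")[0].strip("{")}
            pix = root.find(".//ome:Pixels", ns)
            if pix is not None:
                pixel_size = float(pix.get("PhysicalSizeX", 1.0))
                if pix.get("PhysicalSizeZ") is not None:
                    z_step = float(pix.get("PhysicalSizeZ"))
                if pix.get("TimeIncrement") is not None:
                    interval = float(pix.get("TimeIncrement"))
                names = [
                    ch.get("Name") or f"ch{i}"
                    for i, ch in enumerate(pix.findall("ome:Channel", ns))
                ]
        # normalise axis order and fill missing singleton axes
        target = "TZYXC" if "Z" in axes else "TYXC"
        for label in target:
            if label not in axes:
                data = np.expand_dims(data, axis=0)
                axes = label + axes
        order = [axes.index(label) for label in target]
        data = np.transpose(data, order)
        if not names:
            names = [f"ch{i}" for i in range(data.shape[-1])]
        return cls(
            data=data,
            channel_names=tuple(names),
            pixel_size_um=pixel_size,
            z_step_um=z_step,
            frame_interval_s=interval,
            axes=target,
        )
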