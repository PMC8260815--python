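"""Density-slice container and its plain-text grid format.

A pQCT scan of the tibia is represented here as a rectangular grid of
volumetric bone mineral density values (mg/cm^3) with a known pixel size.
Grid axes are tied to anatomy through an orientation tag mapping anatomical
directions (anterior, medial) to grid axes; ``+x`` points along increasing
column index and ``+y`` along decreasing row index (image "up").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DensitySlice", "read_slice", "write_slice"]

#: segmentation thresholds (mg/cm^3) defining the outer bone border per site
SEGMENTATION_THRESHOLD = {"distal": 169.0, "shaft": 280.0}

#: below this density, pixels inside the periosteal envelope are marrow
MARROW_THRESHOLD = 100.0

_AXES = {"+x", "-x", "+y", "-y"}


@dataclass
class DensitySlice:
    """A single axial cross-section of volumetric density.

    Parameters
    ----------
    values
        2-D array of densities in mg/cm^3.
    pixel_mm
        Edge length of the square pixels in mm (scanner default 0.8).
    site
        ``"shaft"`` (mid-tibia, 50% site) or ``"distal"`` (5% site); selects
        the segmentation threshold.
    orientation
        Mapping of anatomical directions to grid axes, e.g.
        ``{"anterior": "+y", "medial": "+x"}``.  May be ``None``, in which
        case polar sectors cannot be labelled anatomically.
    """

    values: np.ndarray
    pixel_mm: float = 0.8
    site: str = "shaft"
    orientation: dict[str, str] | None = field(
        default_factory=lambda: {"anterior": "+y", "medial": "+x"}
    )

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("slice grid must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("slice grid contains non-finite values")
        if self.pixel_mm <= 0:
            raise ValueError("pixel size must be positive")
        if self.site not in SEGMENTATION_THRESHOLD:
            raise ValueError(f"unknown site {self.site!r}")
        if self.orientation is not None:
            bad = set(self.orientation.values()) - _AXES
            if bad:
                raise ValueError(f"invalid orientation axes {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_mm**2

    def pixel_coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-centre coordinates (x, y) in mm, y increasing upward."""
        nr, nc = self.values.shape
        x = (np.arange(nc) + 0.5) * self.pixel_mm
        y = (nr - np.arange(nr) - 0.5) * self.pixel_mm
        return np.meshgrid(x, y)

    def axis_vector(self, direction: str) -> np.ndarray:
        """Unit (x, y) vector of an anatomical direction from the tag."""
        if self.orientation is None or direction not in self.orientation:
            raise KeyError(f"orientation tag does not define {direction!r}")
        axis = self.orientation[direction]
        sign = 1.0 if axis[0] == "+" else -1.0
        return np.array([sign, 0.0]) if axis[1] == "x" else np.array([0.0, sign])


def _format_orientation(orientation: dict[str, str]) -> str:
    return ",".join(f"{k}:{v}" for k, v in sorted(orientation.items()))


def _parse_orientation(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.split(","):
        key, _, axis = part.partition(":")
        out[key.strip()] = axis.strip()
    return out


def write_slice(slc: DensitySlice, path) -> None:
    """Write a slice in the text grid format (round-trips exactly)."""
    with open(path, "w") as fh:
        fh.write(f"# pixel_mm={slc.pixel_mm!r}\n")
        if slc.orientation is not None:
            fh.write(f"# orientation={_format_orientation(slc.orientation)}\n")
        fh.write(f"# site={slc.site}\n")
        for row in slc.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_slice(path) -> DensitySlice:
    """Read a slice written by :func:`write_slice`."""
    pixel_mm = 0.8
    site = "shaft"
    orientation: dict[str, str] | None = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition("=")
                key = key.strip()
                value = value.strip()
                if key == "pixel_mm":
                    pixel_mm = float(value)
                elif key == "site":
                    site = value
                elif key == "orientation":
                    orientation = _parse_orientation(value)
                continue
            rows.append([float(tok) for tok in line.split()])
    if not rows:
        raise ValueError(f"no grid data in {path}")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError("ragged grid rows")
    return DensitySlice(
        np.array(rows, dtype=float), pixel_mm=pixel_mm, site=site, orientation=orientation
    )
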