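"""Hyperspectral cube container, rectangular class windows, and file I/O.

A :class:`SpectrumCube` is a rows x cols x steps array of extinction values on
a shared :class:`~irdecide.grid.SpectralGrid`, tagged with a case identifier
(one patient/tissue section) and a preconditioning tag.  Training and testing
regions are rectangular :class:`RegionWindow`s drawn in predominantly
single-class tissue; extracting their pixels yields a flat
:class:`LabeledSpectra` matrix for model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import h5py
import numpy as np
import pandas as pd

from .grid import SpectralGrid, make_grid

__all__ = [
    "SpectrumCube",
    "RegionWindow",
    "LabeledSpectra",
    "restrict",
    "decimate",
    "extract_windows",
    "read_cube",
    "write_cube",
    "read_windows",
    "write_windows",
]

PRECONDITION_TAGS = ("raw", "bc", "bc_ratio", "bc_norm")

TUMOR = +1
NONTUMOR = -1

_CONTAINER_VERSION = 1


@dataclass
class SpectrumCube:
    """rows x cols x count extinction cube on a shared wavenumber grid."""

    grid: SpectralGrid
    data: np.ndarray  # (rows, cols, count), float
    case_id: str
    pixel_edge: float = 6.25  # um, square pixels
    precondition_tag: str = "raw"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-D (rows, cols, steps)")
        if self.data.shape[2] != self.grid.count:
            raise ValueError(
                f"cube third dimension {self.data.shape[2]} does not match "
                f"grid count {self.grid.count}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube data must be finite")
        if self.precondition_tag not in PRECONDITION_TAGS:
            raise ValueError(f"unknown precondition tag {self.precondition_tag!r}")

    @property
    def shape(self):
        return self.data.shape

    def flat_spectra(self) -> np.ndarray:
        """View the cube as an (rows*cols) x count spectra matrix."""
        r, c, n = self.data.shape
        return self.data.reshape(r * c, n)


@dataclass(frozen=True)
class RegionWindow:
    """0-based half-open pixel window [row0,row1) x [col0,col1)."""

    row0: int
    col0: int
    row1: int
    col1: int
    label: str  # tumor | nontumor | lipid | lymphocyte
    role: str = "train"  # train | test

    def __post_init__(self):
        if self.row1 <= self.row0 or self.col1 <= self.col0:
            raise ValueError("window must have positive extent")
        if self.role not in ("train", "test"):
            raise ValueError(f"unknown window role {self.role!r}")

    @property
    def n_pixels(self) -> int:
        return (self.row1 - self.row0) * (self.col1 - self.col0)

    def pixels(self):
        for r in range(self.row0, self.row1):
            for c in range(self.col0, self.col1):
                yield r, c


@dataclass
class LabeledSpectra:
    """Flat n x count spectra matrix with +-1 labels and per-row case ids."""

    spectra: np.ndarray
    labels: np.ndarray  # +1 tumor / positive class, -1 nontumor / negative
    case_ids: np.ndarray
    grid: SpectralGrid
    precondition_tag: str = "raw"

    def __post_init__(self):
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.case_ids = np.asarray(self.case_ids)
        n = self.spectra.shape[0]
        if self.spectra.ndim != 2 or self.spectra.shape[1] != self.grid.count:
            raise ValueError("spectra must be n x grid.count")
        if self.labels.shape != (n,) or self.case_ids.shape != (n,):
            raise ValueError("labels/case_ids length must match spectra rows")
        bad = set(np.unique(self.labels)) - {-1, 1}
        if bad:
            raise ValueError(f"labels must be in {{-1,+1}}, found {sorted(bad)}")

    @property
    def n(self) -> int:
        return self.spectra.shape[0]

    def subset(self, mask: np.ndarray) -> "LabeledSpectra":
        return LabeledSpectra(
            self.spectra[mask],
            self.labels[mask],
            self.case_ids[mask],
            self.grid,
            self.precondition_tag,
        )


def _restrict_grid(grid: SpectralGrid, wmin: float, wmax: float):
    if wmax <= wmin:
        raise ValueError(f"wmax ({wmax}) must exceed wmin ({wmin})")
    keep = (grid.values >= wmin) & (grid.values <= wmax)
    if not keep.any():
        raise ValueError(
            f"range [{wmin}, {wmax}] cm^-1 has empty intersection with grid"
        )
    idx = np.flatnonzero(keep)
    vals = grid.values[idx]
    new = make_grid(vals[0], vals[-1], grid.step) if vals.size > 1 else make_grid(
        vals[0], vals[0], grid.step
    )
    return new, idx


def restrict(x, wmin: float, wmax: float):
    """Keep exactly the grid points v with wmin <= v <= wmax (cm^-1).

    Works on either a :class:`SpectrumCube` or :class:`LabeledSpectra`; the
    new grid endpoints are retained grid values.
    """
    wmin, wmax = sorted((float(wmin), float(wmax)))
    new_grid, idx = _restrict_grid(x.grid, wmin, wmax)
    if isinstance(x, SpectrumCube):
        return replace(x, grid=new_grid, data=x.data[:, :, idx])
    if isinstance(x, LabeledSpectra):
        return LabeledSpectra(
            x.spectra[:, idx], x.labels, x.case_ids, new_grid, x.precondition_tag
        )
    raise TypeError(f"cannot restrict {type(x).__name__}")


def decimate(x, keep_every: int):
    """Keep every ``keep_every``-th grid point, anchored at the high end.

    The new step is the old step times ``keep_every``; ``keep_every=1`` is the
    identity.
    """
    keep_every = int(keep_every)
    if keep_every < 1:
        raise ValueError(f"keep_every must be >= 1, got {keep_every}")
    if keep_every == 1:
        return x
    idx = np.arange(0, x.grid.count, keep_every)
    vals = x.grid.values[idx]
    if vals.size > 1:
        new_grid = make_grid(vals[0], vals[-1], x.grid.step * keep_every)
    else:
        new_grid = make_grid(vals[0], vals[0], x.grid.step * keep_every)
    if isinstance(x, SpectrumCube):
        return replace(x, grid=new_grid, data=x.data[:, :, idx])
    if isinstance(x, LabeledSpectra):
        return LabeledSpectra(
            x.spectra[:, idx], x.labels, x.case_ids, new_grid, x.precondition_tag
        )
    raise TypeError(f"cannot decimate {type(x).__name__}")


def extract_windows(
    cube: SpectrumCube,
    windows,
    role_filter: str = "both",
    positive_label: str = "tumor",
    negative_label: str = "nontumor",
) -> LabeledSpectra:
    """Flatten window pixels into a labeled spectra matrix.

    Windows whose label is ``positive_label`` map to +1, ``negative_label`` to
    -1; any other label (lipid, lymphocyte) is skipped unless named as the
    positive class of a secondary model.  Overlapping windows of the same
    label emit each pixel once.
    """
    if role_filter not in ("train", "test", "both"):
        raise ValueError(f"unknown role filter {role_filter!r}")
    rows, cols, _ = cube.data.shape
    seen = {}
    for w in windows:
        if role_filter != "both" and w.role != role_filter:
            continue
        if w.label == positive_label:
            lab = TUMOR
        elif w.label == negative_label:
            lab = NONTUMOR
        else:
            continue
        if w.row0 < 0 or w.col0 < 0 or w.row1 > rows or w.col1 > cols:
            raise ValueError(
                f"window {w} exceeds cube bounds {rows}x{cols}"
            )
        for pix in w.pixels():
            prev = seen.setdefault(pix, lab)
            if prev != lab:
                raise ValueError(
                    f"pixel {pix} labeled both {positive_label} and "
                    f"{negative_label} by overlapping windows"
                )
    if not seen:
        raise ValueError("no windows matched the requested roles/labels")
    pix = sorted(seen)
    spectra = np.array([cube.data[r, c] for r, c in pix])
    labels = np.array([seen[p] for p in pix], dtype=int)
    case_ids = np.array([cube.case_id] * len(pix))
    return LabeledSpectra(spectra, labels, case_ids, cube.grid, cube.precondition_tag)


def concat_labeled(parts) -> LabeledSpectra:
    """Stack LabeledSpectra from several cubes (same grid and tag)."""
    parts = list(parts)
    g = parts[0].grid
    tag = parts[0].precondition_tag
    for p in parts[1:]:
        if p.grid.count != g.count or not np.allclose(p.grid.values, g.values):
            raise ValueError("cannot concatenate spectra on different grids")
        if p.precondition_tag != tag:
            raise ValueError("cannot concatenate spectra with different tags")
    return LabeledSpectra(
        np.vstack([p.spectra for p in parts]),
        np.concatenate([p.labels for p in parts]),
        np.concatenate([p.case_ids for p in parts]),
        g,
        tag,
    )


# ---------------------------------------------------------------------------
# File I/O: HDF5 cube container, CSV window sidecar
# ---------------------------------------------------------------------------

def write_cube(cube: SpectrumCube, path) -> None:
    """Write a cube to a single-file HDF5 container."""
    with h5py.File(path, "w") as f:
        dset = f.create_dataset("extinction", data=cube.data)
        f.attrs["container_version"] = _CONTAINER_VERSION
        f.attrs["grid_start"] = cube.grid.start
        f.attrs["grid_end"] = cube.grid.end
        f.attrs["grid_step"] = cube.grid.step
        f.attrs["grid_count"] = cube.grid.count
        f.attrs["case_id"] = cube.case_id
        f.attrs["pixel_edge_um"] = cube.pixel_edge
        f.attrs["precondition_tag"] = cube.precondition_tag
        dset.attrs["units"] = "extinction (unitless)"


def read_cube(path) -> SpectrumCube:
    """Read a cube written by :func:`write_cube`; validates shape vs grid."""
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("container_version", -1))
        if version != _CONTAINER_VERSION:
            raise ValueError(f"unknown cube container version {version}")
        grid = make_grid(f.attrs["grid_start"], f.attrs["grid_end"], f.attrs["grid_step"])
        data = f["extinction"][()]
        if data.shape[2] != int(f.attrs["grid_count"]) or data.shape[2] != grid.count:
            raise ValueError(
                f"cube data has {data.shape[2]} steps but grid declares "
                f"{f.attrs['grid_count']}"
            )
        return SpectrumCube(
            grid=grid,
            data=data,
            case_id=str(f.attrs["case_id"]),
            pixel_edge=float(f.attrs["pixel_edge_um"]),
            precondition_tag=str(f.attrs["precondition_tag"]),
        )


def write_windows(windows, path) -> None:
    df = pd.DataFrame(
        [
            {
                "row0": w.row0,
                "col0": w.col0,
                "row1": w.row1,
                "col1": w.col1,
                "label": w.label,
                "role": w.role,
            }
            for w in windows
        ]
    )
    df.to_csv(path, index=False)


def read_windows(path):
    df = pd.read_csv(path)
    required = {"row0", "col0", "row1", "col1", "label", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"windows CSV missing columns {sorted(missing)}")
    return [
        RegionWindow(
            int(r.row0), int(r.col0), int(r.row1), int(r.col1), str(r.label), str(r.role)
        )
        for r in df.itertuples(index=False)
    ]
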