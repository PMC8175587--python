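"""Data model and I/O for retinal boundary-surface stacks.

An OCT macular volume, after layer segmentation, is summarised by 11 boundary
surfaces (inner limiting membrane down to the outer boundary of the retinal
pigment epithelium) sampled on the en-face A-scan grid, together with a
validity mask marking where segmentation succeeded and the positions of the
two anatomical landmarks used for spatial normalization (foveal center and
papillary / optic-nerve-head center).

Stacks are stored one-per-subject in an HDF5 container (11 named float grids,
the mask, geometry attributes, landmarks); a plain-text CSV export of the
same content is provided for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np

#: Retinal layers in inner-to-outer order. Layer k lies between surface k and k+1.
LAYER_NAMES = (
    "NFL", "GCL", "IPL", "INL", "OPL", "ONL", "IS/OS", "OSL", "OPR", "RPE",
)

#: Boundary surfaces in inner-to-outer order.
SURFACE_NAMES = (
    "ILM", "NFL-GCL", "GCL-IPL", "IPL-INL", "INL-OPL", "OPL-HFL",
    "BMEIS", "IS/OSJ", "IB_OPR", "IB_RPE", "OB_RPE",
)

N_SURFACES = 11
N_LAYERS = 10


class FormatError(ValueError):
    """Raised when a surface-stack file violates the format contract."""


class AdapterError(ValueError):
    """Raised by external-dataset adapters on unrecognized layouts."""


class DatasetNotPresentError(FileNotFoundError):
    """Raised when an optional external dataset has not been downloaded."""


@dataclass(frozen=True)
class ScanGeometry:
    """En-face sampling geometry of one OCT volume.

    Defaults correspond to a 6 x 6 mm macular raster of 512 A-scans per
    B-scan and 128 B-scans with voxel calibration 11.7 x 46.9 x 3.5 um
    (horizontal x vertical x depth).  ``row`` indexes B-scans (vertical,
    ``pixel_pitch_y``), ``col`` indexes A-scans (horizontal,
    ``pixel_pitch_x``); depth z increases away from the vitreous.
    """

    n_rows: int = 128
    n_cols: int = 512
    pixel_pitch_x: float = 11.7
    pixel_pitch_y: float = 46.9
    depth_step: float = 3.5
    eye: str = "right"

    def __post_init__(self):
        if min(self.pixel_pitch_x, self.pixel_pitch_y, self.depth_step) <= 0:
            raise ValueError("all pitches must be positive")
        if self.eye not in ("left", "right"):
            raise ValueError(f"eye must be 'left' or 'right', got {self.eye!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)


@dataclass
class SurfaceStack:
    """The 11 boundary-surface elevation grids of one eye.

    ``surfaces`` has shape ``(11, n_rows, n_cols)`` in um of depth;
    ``valid_mask`` is True where segmentation succeeded.  Landmarks are
    stored as fractional ``(row, col)`` positions; the papilla may lie
    outside the scanned grid (it is a coordinate, not a pixel).
    """

    geometry: ScanGeometry
    surfaces: np.ndarray
    valid_mask: np.ndarray
    fovea_rc: tuple[float, float]
    papilla_rc: tuple[float, float]
    subject_id: str = ""
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        """Check shapes and the depth-ordering invariant; raise FormatError."""
        shape = self.geometry.shape
        if self.surfaces.shape != (N_SURFACES,) + shape:
            raise FormatError(
                f"expected surfaces shape {(N_SURFACES,) + shape}, got {self.surfaces.shape}"
            )
        if self.valid_mask.shape != shape:
            raise FormatError(
                f"mask shape {self.valid_mask.shape} does not match grid {shape}"
            )
        for k in range(N_SURFACES - 1):
            bad = self.valid_mask & (self.surfaces[k] > self.surfaces[k + 1])
            if bad.any():
                raise FormatError(
                    f"crossing surfaces: surface {k + 1} > surface {k + 2} "
                    f"at {int(bad.sum())} valid points"
                )

    def copy(self) -> "SurfaceStack":
        return SurfaceStack(
            geometry=self.geometry,
            surfaces=self.surfaces.copy(),
            valid_mask=self.valid_mask.copy(),
            fovea_rc=tuple(self.fovea_rc),
            papilla_rc=tuple(self.papilla_rc),
            subject_id=self.subject_id,
            meta=dict(self.meta),
        )


def write_stack(stack: SurfaceStack, path: str | Path) -> None:
    """Write one stack to an HDF5 container (bit-exact round trip)."""
    stack.validate()
    path = Path(path)
    with h5py.File(path, "w") as f:
        for k in range(N_SURFACES):
            f.create_dataset(f"surface_{k + 1:02d}", data=stack.surfaces[k])
        f.create_dataset("valid_mask", data=stack.valid_mask.astype(np.uint8))
        g = stack.geometry
        f.attrs.update(
            {
                "n_rows": g.n_rows,
                "n_cols": g.n_cols,
                "pixel_pitch_x": g.pixel_pitch_x,
                "pixel_pitch_y": g.pixel_pitch_y,
                "depth_step": g.depth_step,
                "eye": g.eye,
                "fovea_rc": np.asarray(stack.fovea_rc, dtype=np.float64),
                "papilla_rc": np.asarray(stack.papilla_rc, dtype=np.float64),
                "subject_id": stack.subject_id,
            }
        )


def read_stack(path: str | Path) -> SurfaceStack:
    """Read a stack written by :func:`write_stack`; enforces the ordering invariant."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        missing = [
            f"surface_{k + 1:02d}"
            for k in range(N_SURFACES)
            if f"surface_{k + 1:02d}" not in f
        ]
        if missing:
            raise FormatError(f"missing surface datasets: {missing}")
        surfaces = np.stack([f[f"surface_{k + 1:02d}"][()] for k in range(N_SURFACES)])
        mask = f["valid_mask"][()].astype(bool)
        a = f.attrs
        geometry = ScanGeometry(
            n_rows=int(a["n_rows"]),
            n_cols=int(a["n_cols"]),
            pixel_pitch_x=float(a["pixel_pitch_x"]),
            pixel_pitch_y=float(a["pixel_pitch_y"]),
            depth_step=float(a["depth_step"]),
            eye=str(a["eye"]),
        )
        stack = SurfaceStack(
            geometry=geometry,
            surfaces=surfaces,
            valid_mask=mask,
            fovea_rc=tuple(np.asarray(a["fovea_rc"], dtype=float)),
            papilla_rc=tuple(np.asarray(a["papilla_rc"], dtype=float)),
            subject_id=str(a["subject_id"]),
        )
    stack.validate()
    return stack


def write_stack_csv(stack: SurfaceStack, directory: str | Path) -> None:
    """Plain-text export: one CSV grid per surface plus mask and metadata."""
    stack.validate()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for k in range(N_SURFACES):
        np.savetxt(directory / f"surface_{k + 1:02d}.csv", stack.surfaces[k], delimiter=",")
    np.savetxt(directory / "valid_mask.csv", stack.valid_mask.astype(int), fmt="%d", delimiter=",")
    g = stack.geometry
    meta = (
        f"n_rows,{g.n_rows}\nn_cols,{g.n_cols}\n"
        f"pixel_pitch_x,{g.pixel_pitch_x}\npixel_pitch_y,{g.pixel_pitch_y}\n"
        f"depth_step,{g.depth_step}\neye,{g.eye}\n"
        f"fovea_row,{stack.fovea_rc[0]}\nfovea_col,{stack.fovea_rc[1]}\n"
        f"papilla_row,{stack.papilla_rc[0]}\npapilla_col,{stack.papilla_rc[1]}\n"
        f"subject_id,{stack.subject_id}\n"
    )
    (directory / "meta.csv").write_text(meta)


def flip_left_eye(stack: SurfaceStack) -> SurfaceStack:
    """Left-right flip a left-eye stack so temporal/nasal sides match right eyes.

    Reverses column order in every surface grid and the mask, reflects
    landmark columns (c -> n_cols - 1 - c), and relabels the eye as
    right-equivalent.  Applied to a right eye it is a no-op (a copy is
    returned and a warning logged), so flip of a flipped stack restores
    the original geometry.
    """
    if stack.geometry.eye != "left":
        import logging

        logging.getLogger(__name__).warning(
            "flip_left_eye called on a %s eye (subject %s); no-op",
            stack.geometry.eye, stack.subject_id,
        )
        return stack.copy()
    n = stack.geometry.n_cols
    out = stack.copy()
    out.surfaces = stack.surfaces[:, :, ::-1].copy()
    out.valid_mask = stack.valid_mask[:, ::-1].copy()
    out.fovea_rc = (stack.fovea_rc[0], n - 1 - stack.fovea_rc[1])
    out.papilla_rc = (stack.papilla_rc[0], n - 1 - stack.papilla_rc[1])
    out.geometry = replace(stack.geometry, eye="right")
    out.meta = dict(stack.meta, flipped=True)
    return out


def read_figshare_thickness(path: str | Path):
    """Adapter for the study's deposited per-layer thickness dataset.

    The deposited archive's internal layout is not standardised; this
    adapter accepts a directory of per-subject, per-layer CSV grids named
    ``<subject>_layer<k>.csv`` (thickness in um) and returns a list of
    :class:`~retroughness.thickness.ThicknessMap`.  Anything else raises
    :class:`AdapterError` with a listing of what was found, so the dialect
    can be extended against the actual download.
    """
    from .thickness import ThicknessMap

    path = Path(path)
    if not path.exists():
        raise DatasetNotPresentError(
            f"thickness dataset not present at {path}; download it first"
        )
    files = sorted(path.glob("*_layer*.csv")) if path.is_dir() else []
    if not files:
        found = sorted(p.name for p in path.iterdir())[:20] if path.is_dir() else [path.name]
        raise AdapterError(
            "unrecognized thickness-dataset layout; expected a directory of "
            f"'<subject>_layer<k>.csv' grids, found: {found}"
        )
    maps = []
    for f in files:
        stem = f.stem
        subject, _, layer_part = stem.rpartition("_layer")
        try:
            layer_index = int(layer_part)
        except ValueError as e:
            raise AdapterError(f"cannot parse layer index from {f.name!r}") from e
        values = np.atleast_2d(np.loadtxt(f, delimiter=","))
        if (values[np.isfinite(values)] < 0).any():
            raise AdapterError(f"negative thickness values in {f.name!r}")
        mask = np.isfinite(values)
        geometry = ScanGeometry(n_rows=values.shape[0], n_cols=values.shape[1])
        maps.append(
            ThicknessMap(
                layer_index=layer_index,
                values=np.where(mask, values, np.nan),
                valid_mask=mask,
                geometry=geometry,
                normalized=False,
                subject_id=subject,
            )
        )
    return maps
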