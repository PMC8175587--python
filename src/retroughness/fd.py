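"""Grayscale differential box-counting (DBC) fractal dimension of thickness maps.

A thickness map restricted to the fovea-centered analysis square is treated
as a grayscale relief.  For each spatial box size s the en-face grid is
partitioned into s x s blocks; over each block a column of boxes of height
h = s * G / M (G gray levels, M image side) is stacked in the intensity
direction and the number of boxes needed to cover the local gray range is

    n_r = floor(max / h) - floor(min / h) + 1,

summed over blocks to give N_r.  The fractal dimension is the slope of the
ordinary least-squares regression of ln N_r on ln(grid subdivisions); it is
exactly 2 for a constant map and grows toward 3 with roughness.

Two border conventions are provided: the classic variant truncates
incomplete border blocks, while the integer-ratio variant covers borders
with shrunken blocks so every pixel is counted regardless of whether s
divides the image side.  Two thickness codings are provided: native depth
units (gray = thickness / depth step, rounded) and an affine min-max map
onto 0..255.  The study's robustness claim is that group conclusions agree
across both algorithms and both codings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .surfaces_io import N_LAYERS
from .thickness import ThicknessMap

ALGORITHMS = ("classic_dbc", "integer_ratio_dbc")
CODINGS = ("native_depth", "minmax_8bit")


@dataclass(frozen=True)
class BoxCountingConfig:
    """Configuration of the DBC estimator.

    ``scales`` are spatial box sizes in pixels (strictly increasing, each
    >= 2 and <= half the shorter image side); when None a near-geometric
    default schedule up to M/4 is derived from the image side.  ``fit_range``
    selects the scales entering the log-log regression (default: all).
    ``gray_levels`` is fixed at 256 for both codings so the box height is
    comparable across subjects.
    """

    algorithm: str = "integer_ratio_dbc"
    coding: str = "native_depth"
    scales: tuple[int, ...] | None = None
    fit_range: tuple[int, ...] | None = None
    gray_levels: int = 256
    depth_step_um: float = 3.5

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.coding not in CODINGS:
            raise ValueError(f"unknown coding {self.coding!r}")
        if self.scales is not None:
            s = tuple(self.scales)
            if len(s) < 3 or any(b <= a for a, b in zip(s, s[1:])) or s[0] < 2:
                raise ValueError("scales must be >= 2, strictly increasing, length >= 3")
        if self.fit_range is not None:
            if self.scales is not None and not set(self.fit_range) <= set(self.scales):
                raise ValueError("fit_range must be a subset of scales")
            if len(self.fit_range) < 3:
                raise ValueError("fit_range needs at least 3 scales")


@dataclass
class FDResult:
    """Fractal dimension of one map with box-size schedule and fit diagnostics."""

    fd: float
    counts: dict[int, int]
    scales_used: tuple[int, ...]
    r_squared: float
    slope: float
    intercept: float
    config: BoxCountingConfig
    layer_index: int | None = None
    subject_id: str = ""


def default_scales(side: int) -> tuple[int, ...]:
    """Near-geometric integer box sizes from 2 up to side // 4."""
    if side < 8:
        raise ValueError("image side must be >= 8")
    top = side // 4
    out, s = [], 2.0
    while round(s) <= top:
        v = int(round(s))
        if not out or v > out[-1]:
            out.append(v)
        s *= 1.4
    if out[-1] != top:
        out.append(top)
    return tuple(out)


def encode_gray(
    values: np.ndarray | ThicknessMap,
    coding: str = "native_depth",
    depth_step_um: float = 3.5,
    gray_levels: int = 256,
) -> tuple[np.ndarray, int]:
    """Quantize a thickness map (um) to integer gray levels.

    native_depth: gray = round(thickness / depth step); adding an integer
    multiple of the depth step to the whole map shifts all grays equally
    and leaves box counts unchanged.  minmax_8bit: affine map of
    [min, max] onto 0..255; a constant map becomes all zeros.
    """
    if isinstance(values, ThicknessMap):
        arr = values.values
        valid = values.valid_mask
    else:
        arr = np.asarray(values, dtype=float)
        valid = np.isfinite(arr)
    if not valid.any():
        raise ValueError("empty valid set: no pixels to encode")
    if coding == "native_depth":
        gray = np.rint(arr / depth_step_um)
    elif coding == "minmax_8bit":
        lo = arr[valid].min()
        hi = arr[valid].max()
        if hi == lo:
            gray = np.zeros_like(arr)
        else:
            gray = np.rint((gray_levels - 1) * (arr - lo) / (hi - lo))
    else:
        raise ValueError(f"unknown coding {coding!r}")
    gray = np.where(valid, gray, np.nan)
    return gray, gray_levels


def _block_reduce(gray: np.ndarray, s: int, ufunc) -> np.ndarray:
    idx_r = np.arange(0, gray.shape[0], s)
    idx_c = np.arange(0, gray.shape[1], s)
    return ufunc.reduceat(ufunc.reduceat(gray, idx_r, axis=0), idx_c, axis=1)


def dbc_count(
    gray: np.ndarray,
    s: int,
    gray_levels: int = 256,
    algorithm: str = "integer_ratio_dbc",
) -> int:
    """Number of boxes N_r covering the relief at spatial box size s.

    The box height is h = s * G / M with M the shorter image side.  The
    classic variant truncates incomplete border blocks; the integer-ratio
    variant covers borders with shrunken blocks so every pixel is counted.
    """
    gray = np.asarray(gray, dtype=float)
    n_rows, n_cols = gray.shape
    m = min(n_rows, n_cols)
    if not (2 <= s <= m // 2):
        raise ValueError(f"box size s={s} out of range [2, {m // 2}]")
    if np.isnan(gray).any():
        raise ValueError("gray grid must be fully valid for box counting")
    h = s * gray_levels / m
    if algorithm == "classic_dbc":
        work = gray[: (n_rows // s) * s, : (n_cols // s) * s]
    elif algorithm == "integer_ratio_dbc":
        work = gray
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    bmax = _block_reduce(work, s, np.maximum)
    bmin = _block_reduce(work, s, np.minimum)
    n_r = np.floor(bmax / h) - np.floor(bmin / h) + 1.0
    return int(n_r.sum())


def _subdivisions(side: int, s: int, algorithm: str) -> int:
    """Blocks per image side at box size s (the effective 1/r of the covering)."""
    return side // s if algorithm == "classic_dbc" else -(-side // s)


def fractal_dimension(
    tmap: ThicknessMap | np.ndarray, config: BoxCountingConfig = BoxCountingConfig()
) -> FDResult:
    """Estimate the fractal dimension of a fully valid square thickness map.

    OLS regression of ln N_r on ln(blocks per side); the slope is the FD.
    For a constant map every block needs exactly one box, the points are
    collinear with slope 2, and the estimate is 2.000 exactly.  The
    returned ``fd`` is clipped into the theoretical range [2, 3]; the
    unclipped slope is kept in ``slope``.
    """
    if isinstance(tmap, ThicknessMap):
        if not tmap.valid_mask.all():
            raise ValueError("fractal_dimension requires a fully valid map")
        values = tmap.values
        layer_index: int | None = tmap.layer_index
        subject_id = tmap.subject_id
    else:
        values = np.asarray(tmap, dtype=float)
        layer_index, subject_id = None, ""
    n_rows, n_cols = values.shape
    if n_rows != n_cols:
        raise ValueError(f"map must be square, got {values.shape}")
    side = n_rows
    gray, g_levels = encode_gray(
        values, config.coding, config.depth_step_um, config.gray_levels
    )
    scales = config.scales if config.scales is not None else default_scales(side)
    scales = tuple(s for s in scales if 2 <= s <= side // 2)
    fit = config.fit_range if config.fit_range is not None else scales
    fit = tuple(s for s in fit if s in scales)
    if len(fit) < 3:
        raise ValueError("fewer than 3 usable scales")

    counts = {
        s: dbc_count(gray, s, g_levels, config.algorithm) for s in scales
    }
    x = np.log([_subdivisions(side, s, config.algorithm) for s in fit])
    y = np.log([counts[s] for s in fit])
    slope, intercept = np.polyfit(x, y, 1)
    y_hat = slope * x + intercept
    ss_res = float(((y - y_hat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0.0 else max(0.0, 1.0 - ss_res / ss_tot)
    fd = float(np.clip(slope, 2.0, 3.0))
    assert 2.0 <= fd <= 3.0
    return FDResult(
        fd=fd,
        counts=counts,
        scales_used=fit,
        r_squared=r2,
        slope=float(slope),
        intercept=float(intercept),
        config=config,
        layer_index=layer_index,
        subject_id=subject_id,
    )


def roughness_table(
    maps: dict[tuple[str, int], ThicknessMap | np.ndarray],
    config: BoxCountingConfig = BoxCountingConfig(),
) -> pd.DataFrame:
    """Per-subject, per-layer FD table with 10-layer and 9-layer means.

    ``maps`` is keyed by (subject_id, layer_index).  Columns are
    ``fd_layer_1 .. fd_layer_10`` plus ``mean_fd_10`` (all layers) and
    ``mean_fd_9`` (neural layers only, excluding the pigment epithelium);
    subjects missing any layer have NaN in the affected cells and in the
    means.
    """
    subjects = sorted({k[0] for k in maps})
    rows = {}
    for subj in subjects:
        row = {}
        for layer in range(1, N_LAYERS + 1):
            key = (subj, layer)
            if key in maps:
                row[f"fd_layer_{layer}"] = fractal_dimension(maps[key], config).fd
            else:
                row[f"fd_layer_{layer}"] = np.nan
        layer_fds = np.array([row[f"fd_layer_{k}"] for k in range(1, N_LAYERS + 1)])
        row["mean_fd_10"] = layer_fds.mean()          # NaN if any layer missing
        row["mean_fd_9"] = layer_fds[:-1].mean()      # excludes RPE (layer 10)
        rows[subj] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "subject_id"
    return df


def robustness_configs(base: BoxCountingConfig) -> list[BoxCountingConfig]:
    """The 2 x 2 grid of (algorithm, coding) variants sharing base scales."""
    return [
        replace(base, algorithm=alg, coding=cod)
        for alg in ALGORITHMS
        for cod in CODINGS
    ]
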