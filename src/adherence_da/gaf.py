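"""Gramian angular fields: encoding a daily play-time series as an image.

A length-T series is min-max rescaled to [-1, 1], mapped to polar
coordinates (angle theta_i = arccos(x_i), radius r_i = i/T), and expanded
into the T x T Gramian matrix G_ij = cos(theta_i + theta_j) -- the
summation (GASF) form, which captures pairwise temporal correlations.  By
the angle-addition identity,

    G_ij = x_i * x_j - sqrt(1 - x_i^2) * sqrt(1 - x_j^2),

so G is symmetric with entries in [-1, 1] and diagonal 2*x_i^2 - 1.  Days
without play sit at the low end (rendered light/yellow under the default
colormap); long play sits at the high end (dark/blue), which makes the
images directly readable: light bands are lapses, dark blocks are
sustained engagement.

Rescaling is min-max rather than z-scoring because arccos requires
|x| <= 1; z-scored values routinely leave that domain.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from matplotlib import colormaps
from PIL import Image

from .cohort import ParticipantLog
from .errors import ConfigurationError
from .preprocessing import SplitConfig

__all__ = [
    "PolarSeries",
    "GAFImage",
    "rescale_to_unit",
    "to_polar",
    "gaf_matrix",
    "gaf_from_series",
    "render_gaf_image",
    "write_gaf_images",
]

#: Default colormap: -1 (no play) renders light yellow, +1 renders dark blue-violet.
DEFAULT_COLORMAP = "viridis_r"


@dataclass(frozen=True)
class PolarSeries:
    """Polar encoding of a unit-interval series: angles in [0, pi], radii i/T."""

    angles: np.ndarray
    radii: np.ndarray

    @property
    def T(self) -> int:
        return len(self.angles)


@dataclass(frozen=True)
class GAFImage:
    """Rendered Gramian angular field plus the matrix it was rendered from."""

    pixels: np.ndarray  # (T, T, 4) uint8 RGBA
    colormap_name: str
    matrix: np.ndarray


def rescale_to_unit(series: np.ndarray,
                    interval: tuple[float, float] = (-1.0, 1.0)) -> np.ndarray:
    """Min-max rescale into ``interval``; a constant series maps to the
    interval midpoint (0 for the default [-1, 1]).

    Both standard GAF normalizations are supported: [-1, 1] (the full
    arccos domain, the default for the core transform) and [0, 1].  The
    half-interval keeps angles in [0, pi/2], which makes the field
    *monotone* in play time -- pairs of no-play days land at the matrix
    minimum and pairs of long-play days at the maximum -- and is therefore
    used when rendering interpretable participant images.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty series")
    a, b = interval
    lo, hi = series.min(), series.max()
    if hi == lo:
        return np.full_like(series, (a + b) / 2.0)
    return a + (b - a) * (series - lo) / (hi - lo)


def to_polar(x: np.ndarray, tol: float = 1e-9) -> PolarSeries:
    """Angles arccos(x_i) and radii i/T (i 1-based); |x|>1+tol is an error."""
    x = np.asarray(x, dtype=float)
    over = np.abs(x) > 1.0 + tol
    if over.any():
        i = int(np.flatnonzero(over)[0])
        raise ValueError(f"value x[{i}]={x[i]:.6g} outside [-1, 1]")
    T = len(x)
    angles = np.arccos(np.clip(x, -1.0, 1.0))
    radii = np.arange(1, T + 1) / T
    return PolarSeries(angles, radii)


def gaf_matrix(polar: PolarSeries) -> np.ndarray:
    """Summation-form Gramian angular field G_ij = cos(theta_i + theta_j)."""
    th = polar.angles
    return np.cos(th[:, None] + th[None, :])


def gaf_from_series(series: np.ndarray,
                    interval: tuple[float, float] = (-1.0, 1.0)) -> np.ndarray:
    """Raw series -> GAF matrix (rescale, polar map, Gramian expansion)."""
    return gaf_matrix(to_polar(rescale_to_unit(series, interval)))


def render_gaf_image(G: np.ndarray,
                     colormap_name: str = DEFAULT_COLORMAP) -> GAFImage:
    """Deterministically map matrix entries in [-1, 1] to colormap colors."""
    try:
        cmap = colormaps[colormap_name]
    except KeyError:
        raise ConfigurationError(f"unknown colormap {colormap_name!r}") from None
    G = np.asarray(G, dtype=float)
    rgba = cmap((G + 1.0) / 2.0, bytes=True)
    return GAFImage(np.asarray(rgba, dtype=np.uint8), colormap_name, G)


def participant_gaf(log_: ParticipantLog, span: str = "full",
                    split: SplitConfig = SplitConfig()) -> np.ndarray:
    """GAF matrix of one participant's daily play-time series.

    ``span="full"`` uses the whole structured-phase record (the default
    used for clustering); ``span="train"`` restricts to the training days,
    for workflows that must avoid any use of test-period play time.
    The unit-interval normalization is used so the image reads
    monotonically: light (yellow) where the participant did not play,
    dark (blue) where they played long.
    """
    if span == "full":
        series = log_.durations()
    elif span == "train":
        first = log_.days[0].day_index
        series = log_.slice_days(first, first + split.train_days - 1).durations()
    else:
        raise ConfigurationError(f"span must be 'full' or 'train', got {span!r}")
    return gaf_from_series(series, interval=(0.0, 1.0))


def write_gaf_images(logs: list[ParticipantLog], out_dir: str | Path,
                     span: str = "full",
                     colormap_name: str = DEFAULT_COLORMAP) -> Path:
    """Render one PNG per participant plus a sidecar CSV mapping ids to paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    index_path = out_dir / "gaf_index.csv"
    with open(index_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["participant_id", "study_id", "image_path"])
        for lg in logs:
            img = render_gaf_image(participant_gaf(lg, span), colormap_name)
            path = out_dir / f"{lg.participant_id}.png"
            Image.fromarray(img.pixels, mode="RGBA").save(path)
            writer.writerow([lg.participant_id, lg.study_id, path.name])
    return index_path
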