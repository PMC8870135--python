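"""Nuclei counting for per-field well images.

A minimal segmentation chain for Hoechst-like nuclear stains: Gaussian
smoothing, global Otsu threshold, 8-connected component labeling, and an
area filter. Touching nuclei are not declumped (a documented limitation),
so counts are exact only for non-overlapping nuclei. Per-well counts are
the sum over the well's fields (by default 9 fields per well).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label, regionprops

from .errors import ValidationError

#: Default per-well field count of the acquisition layout.
DEFAULT_N_FIELDS = 9

_FIELD_FILE_RE = re.compile(
    r"^(?P<plate>.+)_(?P<well>[A-P]\d{2})_f(?P<field>\d+)\.(tif|tiff|png)$"
)


@dataclass
class NucleiCountResult:
    """Count and centroids (row, col in pixels) of nuclei in one field."""

    count: int
    centroids: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if self.count != len(self.centroids):
            raise ValidationError("count must equal number of centroids")


def count_nuclei(
    image: np.ndarray,
    smoothing_sigma: float = 1.0,
    min_area: float = 8.0,
    max_area: float = 500.0,
) -> NucleiCountResult:
    """Count nuclei in one grayscale field image.

    Pipeline: Gaussian smoothing -> global Otsu threshold -> 8-connected
    components -> area filter [min_area, max_area]. A constant image has no
    foreground and yields count 0. The count is invariant under uniform
    intensity scaling because the Otsu threshold scales with the image.
    """
    if smoothing_sigma <= 0 or min_area <= 0 or max_area <= 0:
        raise ValidationError("parameters must be positive")
    if min_area >= max_area:
        raise ValidationError("min_area must be < max_area")
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValidationError("expected a single-channel 2-D image")
    smoothed = gaussian(img, sigma=smoothing_sigma, preserve_range=True)
    if np.ptp(smoothed) == 0:
        return NucleiCountResult(0, [])
    mask = smoothed > threshold_otsu(smoothed)
    labeled = label(mask, connectivity=2)
    centroids = [
        tuple(r.centroid)
        for r in regionprops(labeled)
        if min_area <= r.area <= max_area
    ]
    return NucleiCountResult(len(centroids), centroids)


def aggregate_well_count(field_results: list[NucleiCountResult]) -> int:
    """Per-well nucleus count: the sum over the well's fields."""
    if len(field_results) == 0:
        raise ValidationError("a well needs at least one field")
    return sum(r.count for r in field_results)


def parse_field_filename(name: str) -> tuple[str, str, int]:
    """Parse ``<plate>_<well>_f<index>.tif`` into (plate, well, field index)."""
    m = _FIELD_FILE_RE.match(Path(name).name)
    if m is None:
        raise ValidationError(f"unrecognized field image name {name!r}")
    return m.group("plate"), m.group("well"), int(m.group("field"))


def count_image_directory(
    directory: str | Path, **count_kwargs
) -> "pd.DataFrame":
    """Count nuclei in every field image of a directory, summed per well.

    Files must follow the ``<plate>_<well>_f<index>.tif`` naming scheme
    (``.png`` accepted). Returns a DataFrame with columns
    ``plate_id, well, n_fields, nuclei_count``.
    """
    import pandas as pd
    from skimage.io import imread

    directory = Path(directory)
    wells: dict[tuple[str, str], list[NucleiCountResult]] = {}
    for path in sorted(directory.iterdir()):
        try:
            plate, well, _ = parse_field_filename(path.name)
        except ValidationError:
            continue
        wells.setdefault((plate, well), []).append(
            count_nuclei(imread(path), **count_kwargs)
        )
    rows = [
        {
            "plate_id": plate,
            "well": well,
            "n_fields": len(results),
            "nuclei_count": aggregate_well_count(results),
        }
        for (plate, well), results in sorted(wells.items())
    ]
    return pd.DataFrame(rows, columns=["plate_id", "well", "n_fields", "nuclei_count"])
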