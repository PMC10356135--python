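"""smFISH spot detection, marker-seeded cell segmentation and per-cell counting.

Spots are detected on a single probe channel of a 3-D stack: the top and
bottom z-slices are excluded (light reflection at the cell wall), a white
tophat with a ball structuring element isolates diffraction-limited bright
structures, the retained volume is normalized and thresholded, and each
connected component contributes one centroid. Cells are obtained by a
watershed seeded from manually annotated nucleus markers; spots are counted
per containing region, regions of occluded markers are dropped, and a cell
is called ON when it holds more than three mRNAs.

Coordinates are 0-based voxel indices in (z, y, x) order throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import gaussian
from skimage.morphology import ball, white_tophat
from skimage.segmentation import watershed

__all__ = [
    "MarkerSet",
    "detect_spots",
    "segment_cells",
    "assign_spots",
    "classify_on",
]

ON_COUNT_THRESHOLD = 3  # a cell is ON when strictly more mRNAs than this are counted


@dataclass
class MarkerSet:
    """Nucleus seed coordinates (z, y, x) with per-seed visibility flags.

    Seed ``i`` corresponds to watershed label ``i + 1``. Occluded seeds are
    segmented but their regions are excluded from counting.
    """

    coords: np.ndarray
    visible: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=int))
        if self.visible is None:
            self.visible = np.ones(len(self.coords), dtype=bool)
        self.visible = np.asarray(self.visible, dtype=bool)
        if self.visible.shape != (len(self.coords),):
            raise ValueError("visible flags must match the number of seeds")

    def __len__(self) -> int:
        return len(self.coords)

    def validate_bounds(self, shape: tuple[int, ...]) -> None:
        if np.any(self.coords < 0) or np.any(self.coords >= np.asarray(shape)):
            raise ValueError("marker seed outside image bounds")

    @classmethod
    def from_csv(cls, path) -> "MarkerSet":
        df = pd.read_csv(path)
        vis = df["visibility"].astype(str).str.lower().isin(["1", "true", "visible", "yes"])
        return cls(coords=df[["z", "y", "x"]].to_numpy(), visible=vis.to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "z": self.coords[:, 0],
                "y": self.coords[:, 1],
                "x": self.coords[:, 2],
                "visibility": np.where(self.visible, "visible", "occluded"),
            }
        ).to_csv(path, index=False)


def detect_spots(
    stack: np.ndarray,
    tophat_radius: int = 3,
    threshold: float = 0.3,
    connectivity: int = 3,
) -> pd.DataFrame:
    """Detect spot centroids in a 3-D probe channel.

    Returns a table with columns ``spot_id, z, y, x, n_voxels`` (0-based
    voxel coordinates, (z, y, x) order). ``threshold`` applies to the
    min-max normalized tophat response of the retained z-range; a flat
    response yields an empty table.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("expected a 3-D (z, y, x) stack")
    if stack.shape[0] < 3:
        raise ValueError("need at least 3 z-slices (top and bottom are excluded)")
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    if tophat_radius < 1:
        raise ValueError("tophat radius must be >= 1")

    work = stack.copy()
    work[0] = 0.0
    work[-1] = 0.0
    filtered = white_tophat(work, footprint=ball(tophat_radius))
    retained = filtered[1:-1]
    lo, hi = retained.min(), retained.max()
    if hi <= lo:
        return pd.DataFrame(columns=["spot_id", "z", "y", "x", "n_voxels"])
    norm = (filtered - lo) / (hi - lo)
    binary = norm >= threshold
    binary[0] = False
    binary[-1] = False
    labels, n = ndi.label(binary, structure=np.ones((3,) * 3) if connectivity == 3 else None)
    if n == 0:
        return pd.DataFrame(columns=["spot_id", "z", "y", "x", "n_voxels"])
    centroids = ndi.center_of_mass(binary, labels, index=np.arange(1, n + 1))
    sizes = ndi.sum_labels(binary, labels, index=np.arange(1, n + 1))
    cz, cy, cx = np.array(centroids).T
    return pd.DataFrame(
        {
            "spot_id": np.arange(1, n + 1),
            "z": cz,
            "y": cy,
            "x": cx,
            "n_voxels": sizes.astype(int),
        }
    )


def segment_cells(
    stack: np.ndarray,
    markers: MarkerSet,
    sigma: float = 2.0,
    relief: str = "intensity_inverse",
) -> np.ndarray:
    """Marker-seeded watershed partition of the volume into cell regions.

    The relief is the inverted Gaussian-smoothed image by default (bright
    nuclei become basins), or the Gaussian gradient magnitude with
    ``relief="gradient"``. Every voxel is assigned to exactly one seed's
    region; seed ``i`` produces label ``i + 1``. Occlusion flags live on the
    marker set, not in the label volume.
    """
    stack = np.asarray(stack, dtype=float)
    if len(markers) < 1:
        raise ValueError("need at least one seed")
    markers.validate_bounds(stack.shape)
    smoothed = gaussian(stack, sigma=sigma, preserve_range=True)
    if relief == "intensity_inverse":
        surface = -smoothed
    elif relief == "gradient":
        surface = ndi.gaussian_gradient_magnitude(stack, sigma=sigma)
    else:
        raise ValueError(f"unknown relief {relief!r}")
    seeds = np.zeros(stack.shape, dtype=np.int32)
    for i, (z, y, x) in enumerate(markers.coords, start=1):
        seeds[z, y, x] = i
    return watershed(surface, markers=seeds)


def classify_on(count: int, threshold: int = ON_COUNT_THRESHOLD) -> bool:
    """A cell is ON when strictly more than ``threshold`` mRNAs were counted."""
    if count < 0:
        raise ValueError("count must be non-negative")
    return count > threshold


def assign_spots(
    spots: pd.DataFrame,
    labels: np.ndarray,
    markers: MarkerSet,
    on_threshold: int = ON_COUNT_THRESHOLD,
) -> pd.DataFrame:
    """Count detected spots per visible cell region.

    Each spot is attributed to the region containing its (rounded) centroid;
    spots on background (label 0) are ignored and regions of occluded
    markers are dropped from the output. Visible cells with no spots appear
    with count 0. Returns columns ``cell_id, spot_count, on_flag``.
    """
    labels = np.asarray(labels)
    if spots.shape[0] > 0:
        coords = np.round(spots[["z", "y", "x"]].to_numpy()).astype(int)
        if np.any(coords < 0) or np.any(coords >= np.asarray(labels.shape)):
            raise ValueError("spot centroid outside the label volume: geometry mismatch")
        spot_labels = labels[coords[:, 0], coords[:, 1], coords[:, 2]]
    else:
        spot_labels = np.empty(0, dtype=int)
    rows = []
    for i in range(len(markers)):
        if not markers.visible[i]:
            continue
        cell_id = i + 1
        count = int((spot_labels == cell_id).sum())
        rows.append({"cell_id": cell_id, "spot_count": count, "on_flag": classify_on(count, on_threshold)})
    return pd.DataFrame(rows, columns=["cell_id", "spot_count", "on_flag"])
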