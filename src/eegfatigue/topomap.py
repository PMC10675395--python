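"""Electrode montage geometry and topographic-map rendering.

The 32 scalp electrodes of the 10-20 montage are projected from the unit
sphere to the plane by an azimuthal equidistant projection centred on the
vertex (Cz): projected radius equals arc distance from the vertex, azimuth
is preserved.  A 9x9 lattice is overlaid on the bounding square of the
projected disk and every channel snaps to its nearest cell (injectively).
Per-channel scalars (typically band RPSD values) are placed at their cells,
the remaining cells are filled by inverse-distance-squared interpolation,
the 9x9 grid is upsampled bicubically to 72x72, masked to the head disk and
min-max normalised — yielding the fixed-size image tensors the classifier
consumes (72x72x3: delta, theta and alpha maps by default).

Montage notes: the channel list ships the names "C7"/"C8" verbatim although
they are non-standard; they are placed at the standard T7/T8 coordinates
(alias table below).  Coordinates come from the bundled standard 10-20
positions, recentred on a best-fit sphere, left/right symmetrised, rotated
so Cz is the exact pole, and compressed into the upper hemisphere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, InputError

__all__ = [
    "CHANNEL_NAMES",
    "CHANNEL_ALIASES",
    "HOMOLOGOUS_PAIRS",
    "MIDLINE_CHANNELS",
    "Montage",
    "TopographicImage",
    "project_azimuthal",
    "build_grid",
    "standard_montage",
    "render_map",
    "compose_input",
]

GRID_SIZE = 9
IMAGE_SIZE = 72
UPSAMPLE = IMAGE_SIZE // GRID_SIZE
MASK_MARGIN = 1.05  # head disk radius = max projected radius * margin

#: The 32 channels, in the order the acquisition montage lists them.
CHANNEL_NAMES = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "C7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "Cz",
    "C4", "C8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
)

#: Non-standard names mapped to the standard electrode they occupy.
CHANNEL_ALIASES = {"C7": "T7", "C8": "T8"}

HOMOLOGOUS_PAIRS = (
    ("Fp1", "Fp2"), ("AF3", "AF4"), ("F3", "F4"), ("F7", "F8"),
    ("FC5", "FC6"), ("FC1", "FC2"), ("C3", "C4"), ("C7", "C8"),
    ("CP5", "CP6"), ("CP1", "CP2"), ("P3", "P4"), ("P7", "P8"),
    ("PO3", "PO4"), ("O1", "O2"),
)
MIDLINE_CHANNELS = ("Fz", "Cz", "Pz", "Oz")


@dataclass
class Montage:
    """Channel names with 3D unit-sphere points, 2D projections and cells."""

    names: tuple
    points3d: np.ndarray   # (32, 3) unit vectors, +x right, +y front, +z up
    points2d: np.ndarray   # (32, 2) azimuthal equidistant projection
    cells: tuple           # (row, col) per channel, 0-based, row 0 = front
    radius: float          # half-width of the bounding square

    def cell_of(self, name: str) -> tuple:
        return self.cells[self.names.index(name)]

    def to_json(self) -> str:
        import json
        return json.dumps({
            name: {
                "xyz": [round(v, 6) for v in self.points3d[i]],
                "xy": [round(v, 6) for v in self.points2d[i]],
                "cell": list(self.cells[i]),
            }
            for i, name in enumerate(self.names)
        }, indent=2)


@dataclass
class TopographicImage:
    """72x72x3 image tensor in [0, 1]; zero outside the head disk."""

    pixels: np.ndarray
    band_assignment: tuple
    state_label: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.shape != (IMAGE_SIZE, IMAGE_SIZE, 3):
            raise InputError(
                f"image must be {IMAGE_SIZE}x{IMAGE_SIZE}x3, "
                f"got {self.pixels.shape}"
            )


def project_azimuthal(scalp_point) -> np.ndarray:
    """Azimuthal equidistant projection of an upper-hemisphere unit vector.

    Radius = polar arc distance from the vertex, azimuth preserved; the
    vertex maps to the origin.
    """
    p = np.asarray(scalp_point, dtype=float)
    if p.shape != (3,):
        raise InputError("scalp point must be a 3-vector")
    norm = np.linalg.norm(p)
    if norm == 0:
        raise InputError("zero vector is not a scalp point")
    p = p / norm
    if p[2] < -1e-9:
        raise InputError("scalp point lies below the equator plane")
    theta = np.arccos(np.clip(p[2], -1.0, 1.0))
    s = np.hypot(p[0], p[1])
    if s == 0:
        return np.zeros(2)
    return theta * p[:2] / s


def _cell_centers(radius: float) -> np.ndarray:
    """Centres of the 9 lattice columns/rows in projected coordinates."""
    return -radius + (np.arange(GRID_SIZE) + 0.5) * 2 * radius / GRID_SIZE


def build_grid(names, points2d) -> tuple:
    """Snap projected channels to distinct cells of the 9x9 lattice.

    Each channel takes its nearest cell; if that cell is already occupied by
    an earlier channel, the later channel moves to its nearest free cell
    (ties broken in row-major scan order).  Returns ((row, col), ...) and
    the lattice half-width.
    """
    pts = np.asarray(points2d, dtype=float)
    if pts.shape != (len(names), 2):
        raise InputError("need one 2D point per channel")
    radius = float(np.linalg.norm(pts, axis=1).max())
    centers = _cell_centers(radius)
    taken: dict = {}
    for i, name in enumerate(names):
        x, y = pts[i]
        # row index grows front -> back, i.e. with decreasing y
        candidates = sorted(
            ((np.hypot(centers[c] - x, -centers[r] - y), r, c)
             for r in range(GRID_SIZE) for c in range(GRID_SIZE)),
            key=lambda t: (t[0], t[1], t[2]),
        )
        for _, r, c in candidates:
            if (r, c) not in taken:
                taken[(r, c)] = name
                break
        else:
            raise ConfigurationError(
                f"no free lattice cell left for channel {name}"
            )
    cell_by_name = {v: k for k, v in taken.items()}
    if len(cell_by_name) != len(names):
        raise ConfigurationError("lattice assignment is not injective")
    return tuple(cell_by_name[n] for n in names), radius


def _fit_sphere_center(points: np.ndarray) -> np.ndarray:
    a = np.hstack([2 * points, np.ones((len(points), 1))])
    b = (points ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    return sol[:3]


@lru_cache(maxsize=1)
def standard_montage() -> Montage:
    """The 32-channel montage with idealised unit-sphere geometry."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import mne
        std = mne.channels.make_standard_montage("standard_1020")
    pos = std.get_positions()["ch_pos"]
    pts = np.array([pos[CHANNEL_ALIASES.get(c, c)] for c in CHANNEL_NAMES])

    u = pts - _fit_sphere_center(pts)
    u /= np.linalg.norm(u, axis=1, keepdims=True)

    idx = {c: i for i, c in enumerate(CHANNEL_NAMES)}
    for left, right in HOMOLOGOUS_PAIRS:
        pl, pr = u[idx[left]], u[idx[right]]
        x = (abs(pl[0]) + abs(pr[0])) / 2
        y = (pl[1] + pr[1]) / 2
        z = (pl[2] + pr[2]) / 2
        u[idx[left]] = [-x, y, z]
        u[idx[right]] = [x, y, z]
    for c in MIDLINE_CHANNELS:
        u[idx[c], 0] = 0.0
    u /= np.linalg.norm(u, axis=1, keepdims=True)

    # rotate about the x axis so Cz is the exact pole (Cz has x = 0)
    cz = u[idx["Cz"]]
    ang = np.arctan2(cz[1], cz[2])
    ca, sa = np.cos(ang), np.sin(ang)
    rot = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    u = u @ rot.T

    # compress polar angles into the upper hemisphere (realistic head
    # geometry puts temporal electrodes slightly below the equator)
    theta = np.arccos(np.clip(u[:, 2], -1, 1))
    scale = min(1.0, (np.pi / 2) / theta.max())
    theta *= scale
    az = np.arctan2(u[:, 1], u[:, 0])
    u = np.column_stack([
        np.sin(theta) * np.cos(az),
        np.sin(theta) * np.sin(az),
        np.cos(theta),
    ])

    pts2d = np.array([project_azimuthal(p) for p in u])
    cells, radius = build_grid(CHANNEL_NAMES, pts2d)
    return Montage(CHANNEL_NAMES, u, pts2d, cells, radius)


def _disk_mask(radius: float) -> np.ndarray:
    px = -radius + (np.arange(IMAGE_SIZE) + 0.5) * 2 * radius / IMAGE_SIZE
    xx, yy = np.meshgrid(px, px)
    return np.hypot(xx, yy) <= radius * MASK_MARGIN


def render_map(values, montage: Montage | None = None) -> np.ndarray:
    """Render 32 per-channel scalars as a 72x72 topographic map in [0, 1].

    ``values`` is either a mapping channel-name -> value or an array aligned
    with the montage's channel order.  Empty cells are filled by
    inverse-distance-squared interpolation from the electrode cells, the
    grid is upsampled bicubically, masked to the head disk and min-max
    normalised (a constant input renders as 0.5 everywhere in-disk).
    """
    montage = montage or standard_montage()
    if hasattr(values, "keys"):
        try:
            v = np.array([float(values[n]) for n in montage.names])
        except KeyError as exc:
            raise InputError(f"missing channel value: {exc}") from exc
    else:
        v = np.asarray(values, dtype=float).ravel()
        if v.size != len(montage.names):
            raise InputError(
                f"expected {len(montage.names)} values, got {v.size}"
            )
    if not np.all(np.isfinite(v)):
        raise InputError("channel values must be finite")

    centers = _cell_centers(montage.radius)
    rows = np.array([rc[0] for rc in montage.cells])
    cols = np.array([rc[1] for rc in montage.cells])
    ex = centers[cols]
    ey = -centers[rows]

    gx, gy = np.meshgrid(centers, -centers)  # [row, col] in plane coords
    d2 = (gx[..., None] - ex) ** 2 + (gy[..., None] - ey) ** 2
    w = 1.0 / np.maximum(d2, 1e-12)
    grid = (w * v).sum(axis=-1) / w.sum(axis=-1)
    grid[rows, cols] = v  # electrode cells carry their exact values

    img = ndimage.zoom(grid, UPSAMPLE, order=3, mode="nearest",
                       grid_mode=True)
    mask = _disk_mask(montage.radius)
    inside = img[mask]
    lo, hi = inside.min(), inside.max()
    if hi - lo < 1e-12:
        img = np.where(mask, 0.5, 0.0)
    else:
        img = np.clip((img - lo) / (hi - lo), 0.0, 1.0)
        img[~mask] = 0.0
    return img


#: Default mapping of analysis bands onto the three image channels: beta is
#: dropped (the band that changes least with fatigue).
BAND3_ASSIGNMENT = ("delta", "theta", "alpha")


def compose_input(features, montage: Montage | None = None,
                  mode: str = "band3", band: str = "theta",
                  cmap: str = "viridis") -> TopographicImage:
    """Build the 72x72x3 classifier input from band features.

    mode "band3": delta, theta and alpha RPSD maps become the three image
    channels.  mode "rgb": the single configured band's map is rendered
    through a perceptual colormap.
    """
    montage = montage or standard_montage()
    rp = features.rpsd if hasattr(features, "rpsd") else features
    if mode == "band3":
        maps = []
        for b in BAND3_ASSIGNMENT:
            if b not in rp.columns:
                raise InputError(f"features lack band {b!r}")
            maps.append(render_map(rp[b].to_dict(), montage))
        pixels = np.stack(maps, axis=-1)
        assignment = BAND3_ASSIGNMENT
    elif mode == "rgb":
        if band not in rp.columns:
            raise InputError(f"features lack band {band!r}")
        single = render_map(rp[band].to_dict(), montage)
        import matplotlib
        rgba = matplotlib.colormaps[cmap](single)
        pixels = rgba[..., :3]
        pixels[~_disk_mask(montage.radius)] = 0.0
        assignment = (band,) * 3
    else:
        raise ConfigurationError(f"unknown compose mode {mode!r}")
    return TopographicImage(
        pixels=pixels,
        band_assignment=assignment,
        state_label=getattr(features, "state", None),
    )


def save_png(image: TopographicImage, path) -> None:
    import matplotlib.image
    matplotlib.image.imsave(str(path), np.clip(image.pixels, 0, 1))
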