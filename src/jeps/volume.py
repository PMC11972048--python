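"""CT / dose / structure preprocessing into the standardized model input.

The pipeline follows the clinical preprocessing recipe: stack CT slices by
axial position, resample CT and dose to a common voxel spacing by spline
interpolation, align the dose grid onto the CT lattice, rasterize the PTV
contours into a binary mask on that lattice, normalize CT by a 400/50
window/level filter (post-filter range -150..250 HU mapped to [0, 1]) and
dose by the 70 Gy maximum prescription, stack the three channels, crop a
fixed window centered axially on the parotid glands, and mirror left-sided
patients about the sagittal plane.

Array axis order is (depth/axial, height, width[, channels]) throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import Polygon

log = logging.getLogger(__name__)

HU_WINDOW = 400.0
HU_LEVEL = 50.0
DOSE_RANGE_GY = 70.0
DEFAULT_SPACING = (2.5, 2.0, 2.0)           # (axial, height, width) mm
DEFAULT_WINDOW = (90, 128, 128)             # (depth, height, width) voxels
CHANNELS = ("ct", "dose", "mask")


@dataclass
class VoxelGrid:
    """A 3D scalar field on a regular axial grid."""

    values: np.ndarray                       # (D, H, W)
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("VoxelGrid requires a non-empty 3D array")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be strictly positive")

    @property
    def shape(self):
        return self.values.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin_mm[axis] + np.arange(self.shape[axis]) * self.spacing_mm[axis]


@dataclass
class StructureSet:
    """Named planar contours: ROI name -> list of (z_mm, Nx2 (x, y) mm polygons)."""

    contours: dict[str, list]

    def names(self):
        return sorted(self.contours)

    def __getitem__(self, name):
        if name not in self.contours:
            raise KeyError(
                f"ROI {name!r} not present; available: {self.names()}")
        return self.contours[name]


@dataclass
class MultiChannelVolume:
    """The model's spatial input: (depth, height, width, 3) with channels
    (CT, dose, mask), values in [0, 1], mask binary."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    patient_id: str = ""
    mirrored: bool = False


def resample_to_spacing(grid: VoxelGrid, target_spacing) -> VoxelGrid:
    """Cubic-spline resample onto the target spacing, preserving extent."""
    target = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target):
        raise ValueError("target spacing must be positive")
    old = grid.spacing_mm
    new_shape = tuple(max(1, int(np.floor((n - 1) * o / t)) + 1)
                      for n, o, t in zip(grid.shape, old, target))
    idx = np.meshgrid(*(np.arange(n) * t / o for n, t, o in zip(new_shape, target, old)),
                      indexing="ij")
    vals = ndimage.map_coordinates(grid.values.astype(float), idx, order=3, mode="nearest")
    return VoxelGrid(vals, target, grid.origin_mm)


def align_dose_to_ct(dose: VoxelGrid, ct: VoxelGrid) -> VoxelGrid:
    """Spline-resample the dose onto the CT lattice; outside the dose
    extent the dose is zero."""
    lo = [max(d0, c0) for d0, c0 in zip(dose.origin_mm, ct.origin_mm)]
    hi = [min(d0 + (n - 1) * s, c0 + (m - 1) * t)
          for d0, n, s, c0, m, t in zip(dose.origin_mm, dose.shape, dose.spacing_mm,
                                        ct.origin_mm, ct.shape, ct.spacing_mm)]
    if any(h < l for l, h in zip(lo, hi)):
        raise ValueError("dose and CT extents are disjoint")
    coords = np.meshgrid(*(((c0 + np.arange(m) * t) - d0) / s
                           for c0, m, t, d0, s in zip(ct.origin_mm, ct.shape,
                                                      ct.spacing_mm, dose.origin_mm,
                                                      dose.spacing_mm)),
                         indexing="ij")
    vals = ndimage.map_coordinates(dose.values.astype(float), coords, order=3,
                                   mode="constant", cval=0.0)
    # cubic splines may undershoot slightly on a non-negative field
    np.maximum(vals, 0.0, out=vals)
    return VoxelGrid(vals, ct.spacing_mm, ct.origin_mm)


def _fill_polygon(poly_xy_idx: np.ndarray, shape_hw) -> np.ndarray:
    """Binary in-plane mask: voxel centers inside or on the snapped polygon."""
    mask = np.zeros(shape_hw, dtype=bool)
    snapped = np.rint(poly_xy_idx)
    poly = Polygon(snapped)
    if not poly.is_valid:
        poly = poly.buffer(0)
    if poly.is_empty or poly.area == 0:
        for x, y in snapped:
            r, c = int(y), int(x)
            if 0 <= r < shape_hw[0] and 0 <= c < shape_hw[1]:
                mask[r, c] = True
        return mask
    minx, miny, maxx, maxy = poly.bounds
    c0, c1 = max(0, int(np.floor(minx))), min(shape_hw[1] - 1, int(np.ceil(maxx)))
    r0, r1 = max(0, int(np.floor(miny))), min(shape_hw[0] - 1, int(np.ceil(maxy)))
    if c1 < c0 or r1 < r0:
        return mask
    cc, rr = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
    inside = shapely.intersects_xy(poly, cc.ravel().astype(float),
                                   rr.ravel().astype(float))
    mask[r0:r1 + 1, c0:c1 + 1] = inside.reshape(rr.shape)
    return mask


def rasterize_structure(ss: StructureSet, name: str, ct: VoxelGrid) -> VoxelGrid:
    """Slice-wise contour filling on the CT lattice.

    Contour vertices are snapped to the nearest voxel centers; a voxel is
    inside if its center lies inside or on the polygon boundary.  Contours
    between slices are assigned to the nearest slice.
    """
    entries = ss[name]
    if not entries:
        raise ValueError(f"ROI {name!r} has no contours")
    out = np.zeros(ct.shape, dtype=np.uint8)
    for z_mm, poly_mm in entries:
        k = int(np.rint((z_mm - ct.origin_mm[0]) / ct.spacing_mm[0]))
        if not 0 <= k < ct.shape[0]:
            continue
        poly_idx = np.stack([
            (np.asarray(poly_mm)[:, 0] - ct.origin_mm[2]) / ct.spacing_mm[2],
            (np.asarray(poly_mm)[:, 1] - ct.origin_mm[1]) / ct.spacing_mm[1],
        ], axis=1)
        out[k] |= _fill_polygon(poly_idx, ct.shape[1:])
    return VoxelGrid(out, ct.spacing_mm, ct.origin_mm)


def parotid_axial_center(ss: StructureSet, ct: VoxelGrid,
                         names=("Parotid_L", "Parotid_R")) -> int:
    """Voxel index of the midpoint of the union of both parotids' axial extents."""
    zs = []
    for name in names:
        try:
            entries = ss[name]
        except KeyError as e:
            raise ValueError(str(e)) from None
        if not entries:
            raise ValueError(f"parotid ROI {name!r} has no contours")
        zs.extend(z for z, _ in entries)
    center_mm = (min(zs) + max(zs)) / 2.0
    return int(np.rint((center_mm - ct.origin_mm[0]) / ct.spacing_mm[0]))


def crop_volume(stacked: np.ndarray, center_axial: int, window) -> np.ndarray:
    """Fixed-size crop: axial window centered on ``center_axial``, in-plane
    windows centered on the grid center; out-of-extent regions zero-filled."""
    stacked = np.asarray(stacked)
    if stacked.ndim != 4:
        raise ValueError("expected a 4D (D, H, W, C) array")
    window = tuple(int(w) for w in window)
    if any(w <= 0 for w in window):
        raise ValueError("window must be positive")
    starts = [center_axial - window[0] // 2,
              (stacked.shape[1] - window[1]) // 2,
              (stacked.shape[2] - window[2]) // 2]
    out = np.zeros((*window, stacked.shape[3]), dtype=stacked.dtype)
    src, dst = [], []
    for ax, (s, w) in enumerate(zip(starts, window)):
        lo, hi = max(s, 0), min(s + w, stacked.shape[ax])
        if hi <= lo:
            return out
        src.append(slice(lo, hi))
        dst.append(slice(lo - s, hi - s))
    out[dst[0], dst[1], dst[2], :] = stacked[src[0], src[1], src[2], :]
    return out


def hu_window_normalize(ct: VoxelGrid) -> VoxelGrid:
    """Window/level 400/50 then min-max to [0, 1] over [-150, 250] HU."""
    lo = HU_LEVEL - HU_WINDOW / 2.0
    hi = HU_LEVEL + HU_WINDOW / 2.0
    vals = (np.clip(ct.values, lo, hi) - lo) / (hi - lo)
    return replace(ct, values=vals)


def dose_normalize(dose: VoxelGrid, max_dose_gy: float = DOSE_RANGE_GY) -> VoxelGrid:
    """Min-max standardization of dose over [0, 70] Gy."""
    if (dose.values < 0).any():
        raise ValueError("negative dose voxels: corrupt input")
    vals = np.clip(dose.values / max_dose_gy, 0.0, 1.0)
    return replace(dose, values=vals)


def assemble_channels(ct: VoxelGrid, dose: VoxelGrid, mask: VoxelGrid) -> np.ndarray:
    """Stack (CT, dose, mask) along a trailing channels axis."""
    shapes = {g.shape for g in (ct, dose, mask)}
    if len(shapes) != 1:
        raise ValueError(f"channel shapes differ: ct={ct.shape} dose={dose.shape} "
                         f"mask={mask.shape}")
    return np.stack([ct.values, dose.values, mask.values], axis=-1)


def sagittal_mirror(vol: MultiChannelVolume, ipsilateral_side: str) -> MultiChannelVolume:
    """Flip the width (left-right) axis for left-sided patients."""
    if ipsilateral_side == "left":
        return MultiChannelVolume(vol.values[:, :, ::-1, :].copy(), vol.spacing_mm,
                                  vol.patient_id, mirrored=not vol.mirrored)
    if ipsilateral_side not in ("right", "unknown"):
        raise ValueError(f"ipsilateral_side must be left/right/unknown, "
                         f"got {ipsilateral_side!r}")
    if ipsilateral_side == "unknown":
        log.info("ipsilateral side unknown for %s; volume left unmirrored",
                 vol.patient_id or "<patient>")
    return vol


def preprocess_patient(ct: VoxelGrid, dose: VoxelGrid, ss: StructureSet,
                       ipsilateral_side: str = "right",
                       target_spacing=DEFAULT_SPACING,
                       window=DEFAULT_WINDOW,
                       ptv_name: str = "PTV",
                       patient_id: str = "",
                       return_raw: bool = False):
    """Full preprocessing chain producing the standardized model input.

    With ``return_raw`` the aligned pre-normalization CT and PTV mask are
    also returned (the radiomics extraction input).
    """
    ct_rs = resample_to_spacing(ct, target_spacing)
    dose_al = align_dose_to_ct(dose, ct_rs)
    mask = rasterize_structure(ss, ptv_name, ct_rs)
    center = parotid_axial_center(ss, ct_rs)
    stacked = assemble_channels(hu_window_normalize(ct_rs), dose_normalize(dose_al), mask)
    cropped = crop_volume(stacked, center, window)
    vol = MultiChannelVolume(cropped.astype(np.float32), tuple(target_spacing),
                             patient_id=patient_id)
    vol = sagittal_mirror(vol, ipsilateral_side)
    if return_raw:
        return vol, ct_rs, mask
    return vol
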