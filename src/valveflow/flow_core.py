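"""Core data model and I/O for three-directional, time-resolved velocity fields.

A whole-heart 4D-flow acquisition encodes one velocity component per
gradient direction, giving a 5-axis array ``(X, Y, Z, component, phase)``
in cm/s.  Geometry lives in a NIfTI-style affine mapping 0-based voxel
indices to physical millimetre coordinates; timing is a list of mid-phase
times (ms after the R-wave) plus the RR interval.  The velocity-encoding
limit Venc bounds the measurable range: true velocities beyond ±Venc alias
(wrap) back into ``[-venc, +venc)`` by multiples of 2·Venc.

On disk a dataset is three one-component 4D NIfTI files (``vx``, ``vy``,
``vz``) plus a JSON sidecar with Venc, phase timing and the wrapped flag.
NIfTI has no standard multi-component vector convention, so separate files
are the unambiguous choice.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

#: sidecar filename written next to the three component images
SIDECAR_NAME = "flow.json"
#: component file stems, indexed by component axis
COMPONENT_STEMS = ("vx", "vy", "vz")

_REQUIRED_SIDECAR_KEYS = ("venc_cm_s", "phase_times_ms", "rr_ms", "wrapped")


class FlowDatasetError(ValueError):
    """Invalid flow dataset contents or metadata."""


@dataclass
class FlowDataset:
    """A 4D three-directional velocity field with geometry and timing.

    Parameters
    ----------
    velocities
        Array ``(X, Y, Z, 3, n_phases)`` of velocity in cm/s; component
        axis is ordered (x, y, z) along *world* axes.
    spacing
        Voxel size per axis in mm (strictly positive).
    phase_times
        Mid-phase trigger times in ms from the R-wave, strictly increasing
        and all below ``rr_interval``.
    rr_interval
        Cardiac cycle length in ms.
    venc
        Velocity-encoding limit in cm/s.
    grid_to_world
        4x4 invertible affine taking 0-based voxel indices to world mm.
    wrapped
        True if the stored values are still aliased into ``[-venc, venc)``.
    """

    velocities: np.ndarray
    spacing: tuple[float, float, float]
    phase_times: np.ndarray
    rr_interval: float
    venc: float
    grid_to_world: np.ndarray
    wrapped: bool = False

    def __post_init__(self) -> None:
        self.velocities = np.asarray(self.velocities, dtype=np.float64)
        self.phase_times = np.asarray(self.phase_times, dtype=np.float64)
        self.grid_to_world = np.asarray(self.grid_to_world, dtype=np.float64)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.velocities.ndim != 5 or self.velocities.shape[3] != 3:
            raise FlowDatasetError(
                f"velocities must be (X, Y, Z, 3, P); got {self.velocities.shape}"
            )
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise FlowDatasetError(f"spacing must be positive on all axes: {self.spacing}")
        if self.phase_times.shape != (self.velocities.shape[4],):
            raise FlowDatasetError("one phase time per reconstructed phase is required")
        if np.any(np.diff(self.phase_times) <= 0):
            raise FlowDatasetError("phase_times must be strictly increasing")
        if np.any(self.phase_times >= self.rr_interval):
            raise FlowDatasetError("phase_times must all lie before rr_interval")
        if not self.venc > 0:
            raise FlowDatasetError("venc must be positive")
        if self.grid_to_world.shape != (4, 4) or abs(np.linalg.det(self.grid_to_world)) < 1e-12:
            raise FlowDatasetError("grid_to_world must be an invertible 4x4 affine")
        if self.wrapped:
            v = self.velocities
            if v.size and (v.min() < -self.venc or v.max() >= self.venc):
                raise FlowDatasetError(
                    "dataset flagged wrapped but stores values outside [-venc, +venc)"
                )

    # -- convenience geometry -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.velocities.shape[:3]

    @property
    def n_phases(self) -> int:
        return self.velocities.shape[4]

    @property
    def world_to_grid(self) -> np.ndarray:
        return np.linalg.inv(self.grid_to_world)

    def world_points_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm points ``(N, 3)`` to continuous voxel indices."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        homo = np.c_[pts, np.ones(len(pts))]
        return (homo @ self.world_to_grid.T)[:, :3]

    def voxel_centers_world(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape ``(X, Y, Z, 3)``."""
        nx, ny, nz = self.shape
        idx = np.stack(
            np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"),
            axis=-1,
        ).astype(np.float64)
        homo = np.concatenate([idx, np.ones(idx.shape[:-1] + (1,))], axis=-1)
        return homo @ self.grid_to_world.T[:, :3]

    def copy(self) -> "FlowDataset":
        return replace(self, velocities=self.velocities.copy())


def validate_mask(mask: np.ndarray, dataset: FlowDataset) -> np.ndarray:
    """Check a voxel mask is boolean and congruent with one dataset phase."""
    m = np.asarray(mask)
    if m.dtype != bool:
        m = m.astype(bool)
    if m.shape != dataset.shape:
        raise FlowDatasetError(f"mask shape {m.shape} != grid shape {dataset.shape}")
    return m


# -- I/O ----------------------------------------------------------------------


def write_flow_dataset(dataset: FlowDataset, directory: str | Path) -> dict[str, Path]:
    """Write three 4D component NIfTIs plus a JSON sidecar.

    Float values are stored as float64, so the round trip through
    :func:`load_flow_dataset` is lossless.  Returns the paths written.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for c, stem in enumerate(COMPONENT_STEMS):
        img = nib.Nifti1Image(
            np.asarray(dataset.velocities[:, :, :, c, :], dtype=np.float64),
            dataset.grid_to_world,
        )
        path = directory / f"{stem}.nii.gz"
        nib.save(img, path)
        paths[stem] = path
    sidecar = {
        "venc_cm_s": dataset.venc,
        "phase_times_ms": list(map(float, dataset.phase_times)),
        "rr_ms": float(dataset.rr_interval),
        "wrapped": bool(dataset.wrapped),
        "spacing_mm": list(dataset.spacing),
    }
    sidecar_path = directory / SIDECAR_NAME
    sidecar_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    paths["sidecar"] = sidecar_path
    return paths


def load_flow_dataset(directory: str | Path) -> FlowDataset:
    """Load a dataset written by :func:`write_flow_dataset`.

    ``directory`` holds ``vx.nii.gz``, ``vy.nii.gz``, ``vz.nii.gz`` and
    ``flow.json``.  The three component volumes must be congruent 4D
    images; the sidecar must declare Venc, phase timing and the wrapped
    flag.
    """
    directory = Path(directory)
    sidecar_path = directory / SIDECAR_NAME
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    missing = [k for k in _REQUIRED_SIDECAR_KEYS if k not in sidecar]
    if missing:
        raise FlowDatasetError(f"sidecar missing required keys: {missing}")

    volumes = []
    affine = None
    for stem in COMPONENT_STEMS:
        path = directory / f"{stem}.nii.gz"
        if not path.exists():
            raise FileNotFoundError(f"missing component image {path}")
        img = nib.load(path)
        data = np.asarray(img.dataobj, dtype=np.float64)
        if data.ndim != 4:
            raise FlowDatasetError(f"{path} is not a 4D image")
        if volumes and data.shape != volumes[0].shape:
            raise FlowDatasetError(
                f"component shape mismatch: {data.shape} vs {volumes[0].shape}"
            )
        if affine is None:
            affine = img.affine
        elif not np.allclose(img.affine, affine):
            raise FlowDatasetError("component affines disagree")
        volumes.append(data)

    velocities = np.stack(volumes, axis=3)
    spacing = sidecar.get(
        "spacing_mm", list(np.linalg.norm(affine[:3, :3], axis=0))
    )
    return FlowDataset(
        velocities=velocities,
        spacing=tuple(spacing),
        phase_times=np.asarray(sidecar["phase_times_ms"], dtype=np.float64),
        rr_interval=float(sidecar["rr_ms"]),
        venc=float(sidecar["venc_cm_s"]),
        grid_to_world=affine,
        wrapped=bool(sidecar["wrapped"]),
    )


def write_mask(mask: np.ndarray, dataset: FlowDataset, path: str | Path) -> Path:
    """Persist a voxel mask as a uint8 NIfTI sharing the dataset geometry."""
    m = validate_mask(mask, dataset)
    path = Path(path)
    nib.save(nib.Nifti1Image(m.astype(np.uint8), dataset.grid_to_world), path)
    return path


def load_mask(path: str | Path, dataset: FlowDataset) -> np.ndarray:
    m = np.asarray(nib.load(Path(path)).dataobj) > 0
    return validate_mask(m, dataset)


# -- point sampling -----------------------------------------------------------


def sample_velocity(
    dataset: FlowDataset, points: np.ndarray, phase: int
) -> tuple[np.ndarray, np.ndarray]:
    """Trilinearly sample the velocity field at world-mm points.

    Points outside the convex hull of voxel centres return the zero vector
    and are flagged in the returned boolean out-of-bounds mask (so
    measurement planes may slightly overhang the imaged volume, as clinical
    reformatting tools allow).

    Returns ``(velocities (N, 3) cm/s, out_of_bounds (N,) bool)``; a single
    3-vector input returns ``((3,), bool)``.
    """
    if not 0 <= phase < dataset.n_phases:
        raise IndexError(f"phase {phase} out of range [0, {dataset.n_phases})")
    pts = np.asarray(points, dtype=np.float64)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite sample point")
    vox = dataset.world_points_to_voxel(pts)
    shape = np.asarray(dataset.shape, dtype=np.float64)
    oob = np.any((vox < 0) | (vox > shape - 1), axis=1)
    coords = vox.T  # (3, N)
    out = np.zeros((len(pts), 3))
    for c in range(3):
        out[:, c] = ndimage.map_coordinates(
            dataset.velocities[:, :, :, c, phase],
            coords,
            order=1,
            mode="constant",
            cval=0.0,
        )
    out[oob] = 0.0
    if single:
        return out[0], bool(oob[0])
    return out, oob


# -- Venc aliasing ------------------------------------------------------------


def wrap_to_venc(values: np.ndarray, venc: float) -> np.ndarray:
    """Map velocities into ``[-venc, +venc)`` by multiples of 2·venc.

    Values already in range pass through bit-exactly (the wrap count is
    zero, so no arithmetic is applied to them).
    """
    k = np.floor((np.asarray(values) + venc) / (2.0 * venc))
    return values - 2.0 * venc * k


class UnwrapError(RuntimeError):
    """Phase unwrapping failed to resolve aliased voxels."""


def unwrap_velocity(
    dataset: FlowDataset,
    component: int | str,
    region: np.ndarray,
) -> FlowDataset:
    """Correct Venc aliasing of one velocity component inside a region.

    Aliasing maps a true velocity v to ``v - 2k·venc`` for the integer k
    that lands the value in ``[-venc, +venc)``; correction must recover k
    per voxel.  Unwrapping is *temporal*: each voxel's velocity-time
    series over the cardiac cycle is unwrapped with period 2·venc
    (jumps larger than venc between consecutive phases are treated as
    wraps), exploiting that blood accelerates smoothly on the 30-phase
    timing while jet edges may be spatially undersampled at the
    acquisition voxel size.  Assumes each voxel is alias-free at the first
    reconstructed phase (early systole is quiescent relative to Venc).
    Values outside ``region`` are untouched.

    The operation is idempotent: the correction is derived from the
    re-wrapped values, so applying it to already-unwrapped data returns
    the same field.
    """
    comp = {"x": 0, "y": 1, "z": 2}.get(component, component)
    if comp not in (0, 1, 2):
        raise ValueError(f"unknown component {component!r}")
    mask = validate_mask(region, dataset)
    if not mask.any():
        raise ValueError("unwrap region is empty")

    venc = dataset.venc
    out = dataset.velocities.copy()
    series = wrap_to_venc(out[:, :, :, comp, :][mask], venc)  # (n_voxels, P)
    corrected = np.unwrap(series, axis=1, period=2.0 * venc)
    n_changed = int(np.count_nonzero(np.abs(corrected - series) > venc / 2))
    out[:, :, :, comp, :][mask] = corrected
    logger.info(
        "unwrap component %s: corrected %d voxel-samples over %d region voxels x %d phases",
        comp, n_changed, int(mask.sum()), dataset.n_phases,
    )
    return replace(dataset, velocities=out, wrapped=False)


def unwrap_dataset(dataset: FlowDataset, region: np.ndarray | None = None) -> FlowDataset:
    """Unwrap all three components (full grid by default)."""
    if region is None:
        region = np.ones(dataset.shape, dtype=bool)
    out = dataset
    for comp in range(3):
        out = unwrap_velocity(out, comp, region)
    return out
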