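"""Data model and IO for time-resolved three-directional velocity fields.

A 4D-flow acquisition yields one velocity vector per voxel per timeframe over
a single, temporally periodic cardiac cycle: the first and last frames are
consecutive, so frame arithmetic is modulo the number of frames.  This module
holds the in-memory containers (:class:`VelocityField4D`,
:class:`LVSegmentation`, :class:`SubjectRecord`), readers/writers for NPZ and
NIfTI encodings, the spatiotemporal velocity sampler used by the pathline
integrator, and the tabular result writer.

Conventions (used throughout the package):

* voxel indices are 0-based; the world position of voxel centre ``i`` is
  ``origin + i * spacing`` (mm);
* a voxel *contains* the half-open box ``centre +/- spacing/2`` with the
  boundary belonging to the lower-index voxel;
* internal units are mm, ms and cm/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "VelocityField4D",
    "LVSegmentation",
    "SubjectRecord",
    "load_velocity_field",
    "save_velocity_field",
    "sample_velocity",
    "containing_voxel",
    "mask_lookup",
    "write_component_table",
    "read_component_table",
]

#: 1 cm/s expressed in mm/ms (the integrator's native velocity unit).
CM_PER_S_TO_MM_PER_MS = 0.01


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(-1)
    if v.size == 1:
        v = np.repeat(v, 3)
    if v.size != 3:
        raise ValueError(f"{name} must be a scalar or length-3 sequence")
    return v


@dataclass
class VelocityField4D:
    """Periodic 3D+t three-component velocity dataset with grid geometry.

    Parameters
    ----------
    data:
        Array of shape ``(nx, ny, nz, n_frames, 3)`` holding velocity in cm/s.
    voxel_spacing:
        Per-axis voxel edge length in mm.
    frame_interval:
        Temporal resolution in ms.
    venc:
        Velocity-encoding limit in cm/s.  Samples whose per-direction
        magnitude exceeds it are flagged with a warning, not rejected:
        residual aliasing is a data-quality issue, not a container error.
    origin:
        World position (mm) of the centre of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    voxel_spacing: np.ndarray
    frame_interval: float
    venc: float = 100.0
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 5 or self.data.shape[-1] != 3:
            raise ValueError(
                "data must have shape (nx, ny, nz, n_frames, 3); got "
                f"{self.data.shape}"
            )
        if self.data.shape[3] < 2:
            raise ValueError("n_frames must be >= 2")
        self.voxel_spacing = _as_vec3(self.voxel_spacing, "voxel_spacing")
        if np.any(self.voxel_spacing <= 0):
            raise ValueError("voxel_spacing must be positive")
        self.frame_interval = float(self.frame_interval)
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.venc <= 0:
            raise ValueError("venc must be positive")
        self.origin = _as_vec3(self.origin, "origin")
        n_aliased = int(np.sum(np.abs(self.data) > self.venc))
        if n_aliased:
            warnings.warn(
                f"{n_aliased} velocity samples exceed venc={self.venc} cm/s "
                "in magnitude (possible residual aliasing)",
                stacklevel=2,
            )

    # -- geometry helpers -------------------------------------------------
    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def cycle_length(self) -> float:
        """Duration of one cardiac cycle in ms."""
        return self.n_frames * self.frame_interval

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_spacing)) / 1000.0

    def voxel_centers(self, mask: np.ndarray | None = None) -> np.ndarray:
        """World coordinates (mm) of voxel centres, optionally mask-selected.

        Raster (C) order, so results are deterministic run to run.
        """
        if mask is None:
            idx = np.indices(self.grid_shape).reshape(3, -1).T
        else:
            idx = np.argwhere(np.asarray(mask, dtype=bool))
        return self.origin + idx * self.voxel_spacing

    def copy_with(self, **kwargs) -> "VelocityField4D":
        return replace(self, **kwargs)


@dataclass
class LVSegmentation:
    """Endocardial masks at the ED and ES timeframes.

    ``ed_mask_cine`` lives on the (generally anisotropic) cine acquisition
    grid described by ``cine_spacing``/``cine_origin``; ``es_mask`` is on the
    flow grid.  The ED/ES frame indices are inputs: the original analysis
    picks them by visual inspection of valve positions, which is outside this
    package's scope.
    """

    ed_mask_cine: np.ndarray
    es_mask: np.ndarray
    ed_frame: int
    es_frame: int
    cine_spacing: np.ndarray = field(default_factory=lambda: np.full(3, 3.0))
    cine_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.ed_mask_cine = np.asarray(self.ed_mask_cine, dtype=bool)
        self.es_mask = np.asarray(self.es_mask, dtype=bool)
        if self.ed_frame == self.es_frame:
            raise ValueError("ed_frame and es_frame must differ")
        if self.ed_frame < 0 or self.es_frame < 0:
            raise ValueError("frame indices must be non-negative")
        for name, m in (("ed_mask_cine", self.ed_mask_cine), ("es_mask", self.es_mask)):
            if not m.any():
                raise ValueError(f"{name} is empty")
        self.cine_spacing = _as_vec3(self.cine_spacing, "cine_spacing")
        self.cine_origin = _as_vec3(self.cine_origin, "cine_origin")
        self._warn_if_disconnected()

    def _warn_if_disconnected(self) -> None:
        from scipy import ndimage

        for name, m in (("ed_mask_cine", self.ed_mask_cine), ("es_mask", self.es_mask)):
            _, n = ndimage.label(m)
            if n > 1:
                warnings.warn(
                    f"{name} has {n} connected components; expected a single "
                    "LV cavity",
                    stacklevel=3,
                )


@dataclass
class SubjectRecord:
    subject_id: str
    heart_rate: float  # beats/min
    visit_label: str = "scan1"

    def __post_init__(self) -> None:
        if self.heart_rate <= 0:
            raise ValueError("heart_rate must be positive")


# ---------------------------------------------------------------------------
# Velocity sampling
# ---------------------------------------------------------------------------

def containing_voxel(
    positions: np.ndarray,
    origin: np.ndarray,
    spacing: np.ndarray,
) -> np.ndarray:
    """Index of the voxel containing each world position.

    Voxel ``i`` covers ``(centre - s/2, centre + s/2]``: a point exactly on a
    face belongs to the lower-index voxel, which keeps ties deterministic.
    Indices may fall outside the grid; callers bounds-check.
    """
    p = np.asarray(positions, dtype=float)
    return np.ceil((p - origin) / spacing - 0.5).astype(np.int64)


def mask_lookup(
    positions: np.ndarray,
    mask: np.ndarray,
    origin: np.ndarray,
    spacing: np.ndarray,
) -> np.ndarray:
    """True where the voxel containing each position is inside ``mask``.

    Positions outside the grid are outside the mask.
    """
    idx = containing_voxel(positions, origin, spacing)
    shape = np.asarray(mask.shape)
    ok = np.all((idx >= 0) & (idx < shape), axis=-1)
    out = np.zeros(ok.shape, dtype=bool)
    if np.any(ok):
        sel = idx[ok]
        out[ok] = mask[sel[:, 0], sel[:, 1], sel[:, 2]]
    return out


def sample_velocity(
    fld: VelocityField4D,
    positions: np.ndarray,
    time_ms,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample velocity (cm/s) at world positions and a time on the cycle.

    Trilinear interpolation in space between voxel centres; linear
    interpolation in time between the two bracketing frames with periodic
    wrap-around (the acquisition forms a closed loop in time).  Positions
    outside the convex hull of voxel centres return the zero vector with the
    out-of-bounds flag set; the function is total.

    Parameters
    ----------
    positions:
        Array of shape ``(3,)`` or ``(n, 3)`` in mm.
    time_ms:
        Scalar time, or per-position array; wrapped modulo the cycle length.

    Returns
    -------
    (velocity, out_of_bounds):
        ``velocity`` has the shape of ``positions``; ``out_of_bounds`` is a
        boolean array over positions.
    """
    p = np.asarray(positions, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    n = p.shape[0]

    nx, ny, nz = fld.grid_shape
    nt = fld.n_frames

    # fractional voxel coordinates
    f = (p - fld.origin) / fld.voxel_spacing
    inside = np.all(f >= 0.0, axis=1) & np.all(
        f <= np.array([nx - 1, ny - 1, nz - 1]), axis=1
    )

    fc = np.clip(f, 0.0, np.array([nx, ny, nz]) - 1.0)
    i0 = np.minimum(fc.astype(np.int64), np.array([nx - 2, ny - 2, nz - 2]))
    i0 = np.maximum(i0, 0)
    w = fc - i0  # in [0, 1]

    # bracketing frames, periodic
    t = np.broadcast_to(np.asarray(time_ms, dtype=float), (n,))
    tf = np.mod(t, fld.cycle_length) / fld.frame_interval
    k0 = tf.astype(np.int64) % nt
    k1 = (k0 + 1) % nt
    wt = tf - np.floor(tf)

    flat = fld.data.reshape(-1, nt, 3)

    def gather(dx: int, dy: int, dz: int) -> np.ndarray:
        idx = ((i0[:, 0] + dx) * ny + (i0[:, 1] + dy)) * nz + (i0[:, 2] + dz)
        v0 = flat[idx, k0]
        v1 = flat[idx, k1]
        return v0 * (1.0 - wt)[:, None] + v1 * wt[:, None]

    out = np.zeros((n, 3))
    for dx in (0, 1):
        wx = (1.0 - w[:, 0]) if dx == 0 else w[:, 0]
        for dy in (0, 1):
            wy = (1.0 - w[:, 1]) if dy == 0 else w[:, 1]
            for dz in (0, 1):
                wz = (1.0 - w[:, 2]) if dz == 0 else w[:, 2]
                wgt = wx * wy * wz
                if np.any(wgt):
                    out += wgt[:, None] * gather(dx, dy, dz)

    out[~inside] = 0.0
    oob = ~inside
    if single:
        return out[0], oob[0]
    return out, oob


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_NPZ_KEYS = ("data", "voxel_spacing", "frame_interval", "venc", "origin")


def save_velocity_field(fld: VelocityField4D, path) -> Path:
    """Write the native NPZ bundle (velocity plus all grid metadata)."""
    path = Path(path)
    np.savez_compressed(
        path,
        data=fld.data,
        voxel_spacing=fld.voxel_spacing,
        frame_interval=fld.frame_interval,
        venc=fld.venc,
        origin=fld.origin,
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def save_velocity_field_nifti(fld: VelocityField4D, basepath) -> list[Path]:
    """Write one 4D NIfTI per velocity direction plus a YAML sidecar.

    Produces ``<base>_vx.nii.gz``, ``_vy``, ``_vz`` and ``<base>.yaml`` with
    the metadata a NIfTI header cannot carry (venc).
    """
    import nibabel as nib

    basepath = Path(basepath)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(fld.voxel_spacing)
    affine[:3, 3] = fld.origin
    paths = []
    for d, suffix in enumerate(("vx", "vy", "vz")):
        img = nib.Nifti1Image(np.ascontiguousarray(fld.data[..., d]), affine)
        img.header.set_xyzt_units("mm", "msec")
        img.header.set_zooms((*fld.voxel_spacing, fld.frame_interval))
        p = basepath.parent / f"{basepath.name}_{suffix}.nii.gz"
        nib.save(img, p)
        paths.append(p)
    sidecar = basepath.parent / f"{basepath.name}.yaml"
    with open(sidecar, "w") as fh:
        yaml.safe_dump(
            {
                "venc_cm_s": float(fld.venc),
                "frame_interval_ms": float(fld.frame_interval),
            },
            fh,
        )
    paths.append(sidecar)
    return paths


def _load_nifti(paths: Sequence, sidecar: dict) -> VelocityField4D:
    import nibabel as nib

    vols, spacing, origin, dt = [], None, None, None
    for p in paths:
        img = nib.load(str(p))
        arr = np.asarray(img.dataobj, dtype=float)
        if arr.ndim == 5:  # single file holding all three directions
            if arr.shape[-1] != 3:
                raise ValueError(
                    f"5D NIfTI must have 3 components on the last axis; got {arr.shape}"
                )
            vols = [arr[..., d] for d in range(3)]
        elif arr.ndim == 4:
            vols.append(arr)
        else:
            raise ValueError(
                f"velocity NIfTI must be 4D (one direction) or 5D; got {arr.ndim}D"
            )
        zooms = img.header.get_zooms()
        spacing = np.asarray(zooms[:3], dtype=float)
        origin = np.asarray(img.affine[:3, 3], dtype=float)
        if len(zooms) > 3 and zooms[3] > 0:
            dt = float(zooms[3])
    if len(vols) != 3:
        raise ValueError(f"expected 3 velocity directions, got {len(vols)}")
    if "frame_interval_ms" in sidecar:
        dt = float(sidecar["frame_interval_ms"])
    if dt is None or dt <= 0:
        raise ValueError(
            "missing timing metadata: frame_interval (not in NIfTI header; "
            "provide a YAML sidecar with 'frame_interval_ms')"
        )
    venc = sidecar.get("venc_cm_s")
    if venc is None:
        raise ValueError(
            "missing metadata: venc (provide a YAML sidecar with 'venc_cm_s')"
        )
    data = np.stack(vols, axis=-1)
    return VelocityField4D(data, spacing, dt, float(venc), origin)


def load_velocity_field(path, format: str | None = None, sidecar=None) -> VelocityField4D:
    """Load a velocity field from NPZ or NIfTI.

    Parameters
    ----------
    path:
        NPZ path, a single 5D NIfTI path, or a sequence of three 4D NIfTI
        paths (one per velocity direction).
    format:
        ``"npz"`` or ``"nifti4d"``; inferred from the suffix when omitted.
    sidecar:
        Optional YAML path or dict supplying ``frame_interval_ms`` /
        ``venc_cm_s`` when the NIfTI header lacks them.  For single-path
        loads, ``<stem>.yaml`` next to the file is picked up automatically.
    """
    multi = isinstance(path, (list, tuple))
    if format is None:
        probe = Path(path[0] if multi else path)
        format = "npz" if probe.suffix == ".npz" else "nifti4d"

    if format == "npz":
        if multi:
            raise ValueError("NPZ loading takes a single path")
        with np.load(Path(path)) as npz:
            missing = [k for k in _NPZ_KEYS if k not in npz]
            if missing:
                raise ValueError(f"NPZ bundle is missing keys: {missing}")
            return VelocityField4D(
                npz["data"],
                npz["voxel_spacing"],
                float(npz["frame_interval"]),
                float(npz["venc"]),
                npz["origin"],
            )

    if format == "nifti4d":
        paths = list(path) if multi else [path]
        side: dict = {}
        if sidecar is None:
            p0 = Path(paths[0])
            name = p0.name
            for suffix in (".nii.gz", ".nii"):
                if name.endswith(suffix):
                    name = name[: -len(suffix)]
                    break
            for stem in (name, name.rsplit("_", 1)[0]):
                cand = p0.parent / f"{stem}.yaml"
                if cand.exists():
                    sidecar = cand
                    break
        if isinstance(sidecar, dict):
            side = sidecar
        elif sidecar is not None:
            with open(sidecar) as fh:
                side = yaml.safe_load(fh) or {}
        return _load_nifti(paths, side)

    raise ValueError(f"unknown format {format!r}")


def save_mask_nifti(mask: np.ndarray, spacing, origin, path) -> Path:
    import nibabel as nib

    affine = np.eye(4)
    affine[:3, :3] = np.diag(_as_vec3(spacing, "spacing"))
    affine[:3, 3] = _as_vec3(origin, "origin")
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine)
    nib.save(img, str(path))
    return Path(path)


def load_mask_nifti(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Load a binary mask; returns (mask, spacing, origin)."""
    import nibabel as nib

    img = nib.load(str(path))
    mask = np.asarray(img.dataobj) > 0
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    return mask, spacing, origin


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

#: canonical column order of the per-subject result table
_COMPONENTS = ("direct_flow", "retained_inflow", "delayed_ejection_flow", "residual_volume")


def component_table_row(
    subject: SubjectRecord,
    result,
    indices,
) -> dict:
    """Flatten one analysis into a table row (see ``write_component_table``)."""
    row = {
        "subject_id": subject.subject_id,
        "visit": subject.visit_label,
        "heart_rate_bpm": subject.heart_rate,
        "edv_ml": indices.edv,
        "esv_ml": indices.esv,
        "sv_ml": indices.sv,
        "ef_pct": indices.ef,
        "cardiac_output_l_min": indices.cardiac_output,
    }
    for comp in _COMPONENTS:
        row[f"{comp}_ml"] = result.volumes_ml[comp]
        row[f"{comp}_pct_edv"] = result.pct_edv[comp]
        row[f"{comp}_ke_ed_uJ"] = result.ke_at_ed_uJ[comp]
        row[f"{comp}_ke_ed_uJ_per_ml"] = result.ke_at_ed_uJ_per_ml[comp]
    row["qc_inflow_ml"] = result.qc.inflow_ml
    row["qc_outflow_ml"] = result.qc.outflow_ml
    row["qc_rel_diff"] = result.qc.relative_difference
    row["qc_pass"] = result.qc.passed
    return row


def write_component_table(rows: Sequence[dict], path) -> pd.DataFrame:
    """Write per-subject x visit component results as CSV.

    ``rows`` are dicts as produced by :func:`component_table_row`.  Numeric
    fields round-trip at better than 6 significant digits.
    """
    if len(rows) == 0:
        raise ValueError("no results to write")
    df = pd.DataFrame(list(rows))
    df.to_csv(path, index=False, float_format="%.10g")
    return df


def read_component_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
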