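"""Background phase-offset correction, mask resampling and LV volumetrics.

Phase-contrast velocity data carry a spatially smooth spurious baseline
(eddy-current phase offsets).  Following standard practice the offset is
modelled per velocity direction as a full third-order polynomial in space,
fitted by ordinary least squares to voxels identified as static tissue, and
subtracted at every timeframe.  The polynomial basis uses world coordinates
centred on the field-of-view midpoint and scaled to [-1, 1] per axis for
numerical conditioning; coefficients are reported in that scaled basis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .flow_io import VelocityField4D, LVSegmentation, containing_voxel

__all__ = [
    "PolynomialOffsetModel",
    "VolumetricIndices",
    "identify_static_tissue",
    "polynomial_exponents",
    "polynomial_basis",
    "fit_background_polynomial",
    "evaluate_offset",
    "apply_phase_correction",
    "resample_ed_mask",
    "compute_volumetric_indices",
]

POLY_ORDER = 3


def polynomial_exponents(order: int = POLY_ORDER) -> np.ndarray:
    """Exponent triples (a, b, c) with a+b+c <= order, deterministic order.

    Sorted by (total degree, a, b, c); 20 terms for a full cubic.
    """
    terms = [
        (a, b, c)
        for a in range(order + 1)
        for b in range(order + 1)
        for c in range(order + 1)
        if a + b + c <= order
    ]
    terms.sort(key=lambda t: (sum(t), t))
    return np.array(terms, dtype=int)


def _fov_center_scale(fld: VelocityField4D) -> tuple[np.ndarray, np.ndarray]:
    half = (np.asarray(fld.grid_shape) - 1) / 2.0 * fld.voxel_spacing
    center = fld.origin + half
    scale = np.where(half > 0, half, 1.0)
    return center, scale


def polynomial_basis(
    positions: np.ndarray,
    center: np.ndarray,
    scale: np.ndarray,
    order: int = POLY_ORDER,
) -> np.ndarray:
    """Design matrix of scaled monomials at world positions, shape (n, 20)."""
    u = (np.atleast_2d(positions) - center) / scale
    expo = polynomial_exponents(order)
    return (
        u[:, 0:1] ** expo[:, 0][None, :]
        * u[:, 1:2] ** expo[:, 1][None, :]
        * u[:, 2:3] ** expo[:, 2][None, :]
    )


@dataclass
class PolynomialOffsetModel:
    """Per-direction third-order polynomial background offset.

    ``coefficients`` has shape (3, 20): one row per velocity direction, in
    the scaled-monomial basis defined by ``center``/``scale`` and
    :func:`polynomial_exponents`.
    """

    coefficients: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    rms_residual: np.ndarray = field(default_factory=lambda: np.zeros(3))
    n_fit_voxels: int = 0
    order: int = POLY_ORDER

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        n_terms = len(polynomial_exponents(self.order))
        if self.coefficients.shape != (3, n_terms):
            raise ValueError(
                f"coefficients must have shape (3, {n_terms}); got "
                f"{self.coefficients.shape}"
            )


def identify_static_tissue(
    fld: VelocityField4D,
    threshold_cm_s: float = 2.0,
) -> np.ndarray:
    """Mask of voxels behaving like static (chest-wall) tissue.

    A voxel qualifies when the temporal standard deviation of its speed is
    below ``threshold_cm_s`` and its temporal mean speed is below twice that,
    which keeps steadily flowing voxels out even when their speed is constant.
    """
    speed = np.linalg.norm(fld.data, axis=-1)  # (nx, ny, nz, nt)
    mask = (speed.std(axis=-1) < threshold_cm_s) & (
        speed.mean(axis=-1) < 2.0 * threshold_cm_s
    )
    if not mask.any():
        raise ValueError(
            "no static-tissue voxels found; increase threshold_cm_s "
            f"(currently {threshold_cm_s})"
        )
    return mask


def fit_background_polynomial(
    fld: VelocityField4D,
    static_mask: np.ndarray,
    min_static_voxels: int = 200,
) -> PolynomialOffsetModel:
    """OLS fit of the time-averaged velocity in static voxels on the cubic basis.

    A single spatial polynomial per direction is fitted to the temporal mean:
    background offsets are temporally static by physical origin, so per-frame
    fits would only add noise.
    """
    static_mask = np.asarray(static_mask, dtype=bool)
    n_static = int(static_mask.sum())
    if n_static < min_static_voxels:
        raise ValueError(
            f"static mask has {n_static} voxels; at least {min_static_voxels} "
            "are required for a stable cubic fit"
        )
    center, scale = _fov_center_scale(fld)
    pos = fld.voxel_centers(static_mask)
    X = polynomial_basis(pos, center, scale)
    y = fld.data[static_mask].mean(axis=1)  # (n_static, 3) temporal mean
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError(
            "rank-deficient polynomial design (static voxels may be coplanar); "
            f"rank {rank} < {X.shape[1]}"
        )
    resid = y - X @ coef
    rms = np.sqrt(np.mean(resid**2, axis=0))
    return PolynomialOffsetModel(coef.T, center, scale, rms, n_static)


def evaluate_offset(model: PolynomialOffsetModel, positions: np.ndarray) -> np.ndarray:
    """Offset velocity (cm/s) predicted by the model at world positions."""
    X = polynomial_basis(np.atleast_2d(positions), model.center, model.scale, model.order)
    return X @ model.coefficients.T


def apply_phase_correction(
    fld: VelocityField4D,
    model: PolynomialOffsetModel,
) -> VelocityField4D:
    """Subtract the fitted offset from every voxel at every timeframe.

    Returns a new field; the input is untouched.  Because the subtracted
    surface is constant in time, temporal differences v(t1) - v(t2) are
    preserved exactly, and refitting on the corrected field yields a null
    model (the correction is a projection).
    """
    pos = fld.voxel_centers()
    offset = evaluate_offset(model, pos).reshape(*fld.grid_shape, 3)
    data = fld.data - offset[:, :, :, None, :]
    return fld.copy_with(data=data)


def resample_ed_mask(seg: LVSegmentation, fld: VelocityField4D) -> np.ndarray:
    """Nearest-neighbour resampling of the ED cine mask onto the flow grid.

    A flow voxel is inside when its centre falls inside an inside cine voxel
    (centre exactly on a cine-voxel face belongs to the lower-index voxel).
    Nearest-neighbour keeps the mask binary; the resampled voxel count times
    the flow voxel volume defines the EDV used for pathline seeding.
    """
    centers = fld.voxel_centers()
    idx = containing_voxel(centers, seg.cine_origin, seg.cine_spacing)
    shape = np.asarray(seg.ed_mask_cine.shape)
    ok = np.all((idx >= 0) & (idx < shape), axis=-1)
    inside = np.zeros(len(centers), dtype=bool)
    if np.any(ok):
        sel = idx[ok]
        inside[ok] = seg.ed_mask_cine[sel[:, 0], sel[:, 1], sel[:, 2]]
    mask = inside.reshape(fld.grid_shape)
    if not mask.any():
        raise ValueError(
            "resampled ED mask is empty; cine and flow grids do not overlap "
            "in world space"
        )
    return mask


@dataclass
class VolumetricIndices:
    """Standard LV volumetric indices derived from the two masks."""

    edv: float  # ml
    esv: float  # ml
    sv: float  # ml
    ef: float  # %
    cardiac_output: float  # L/min

    def __post_init__(self) -> None:
        if not self.edv > self.esv >= 0:
            raise ValueError("requires EDV > ESV >= 0")


def compute_volumetric_indices(
    ed_mask_flow: np.ndarray,
    es_mask: np.ndarray,
    voxel_volume_ml: float,
    heart_rate: float,
) -> VolumetricIndices:
    """EDV/ESV from voxel counts; SV = EDV - ESV; EF = 100 SV/EDV; CO = SV x HR.

    Raises when ESV >= EDV, which almost always means the masks are swapped.
    """
    ed_mask_flow = np.asarray(ed_mask_flow, dtype=bool)
    es_mask = np.asarray(es_mask, dtype=bool)
    if not ed_mask_flow.any() or not es_mask.any():
        raise ValueError("masks must be non-empty")
    edv = float(ed_mask_flow.sum()) * voxel_volume_ml
    esv = float(es_mask.sum()) * voxel_volume_ml
    if esv >= edv:
        raise ValueError(
            f"ESV ({esv:.1f} ml) >= EDV ({edv:.1f} ml); ED and ES masks are "
            "likely swapped"
        )
    sv = edv - esv
    ef = 100.0 * sv / edv
    co = sv * heart_rate / 1000.0
    return VolumetricIndices(edv, esv, sv, ef, co)
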