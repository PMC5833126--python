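"""Synthetic 4D velocity phantoms with exact flow-component ground truth.

The generator builds a temporally periodic, ventricle-like dataset at 4D-flow
acquisition geometry (3 mm isotropic voxels, ~52 ms frames, VENC 100 cm/s):
a chamber (an elliptical cylinder, tilted obliquely to the grid so voxel
sampling does not quantise the truth coarsely) carrying a compartmental
transport flow, inside a torso-like envelope of static tissue, with optional
additive Gaussian velocity noise and an injectable third-order polynomial
background offset.

The transport field is separable and affine along the chamber axis,

    u(xi, t) = g(t) * (alpha * xi + u0) * w(x) * e,

where ``xi`` is the along-axis coordinate, ``g`` is periodic and piecewise
linear between frames, ``w`` tapers smoothly to zero outside the envelope
and ``e`` is the axis direction.  Inside the envelope core the flow map from
ED to any frame-aligned time is then affine and available in closed form
(``xi -> e^{a tau} xi + u0 (e^{a tau} - 1)/a`` with ``tau`` the accumulated
integral of ``g``), which makes the component label of every seed exact by
construction: the generator *solves* for ``alpha``, ``u0``, ``g`` and the ES
cavity window so that the four label regions occupy prescribed fractions of
the chamber.  Ground-truth labels must be exact, so verifiability takes
precedence over fluid-dynamical realism: the field is not a Navier-Stokes
solution and is divergence-free only up to the affine stretch and taper
(the residual divergence is reported).

Cross-sections perpendicular to the axis are never advected, so a seed's
inside/outside status at ES reduces to its along-axis coordinate; the ES
mask voxelisation is shared between truth and pipeline, keeping the two
comparable to integration error alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Callable

import numpy as np

from .flow_io import (
    LVSegmentation,
    SubjectRecord,
    VelocityField4D,
    mask_lookup,
)
from .pathlines import es_spans
from .preprocess import polynomial_basis, polynomial_exponents

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "ScanDataset",
    "generate_phantom",
    "realize",
    "oracle_fractions",
    "make_scan_pair",
    "uniform_phantom",
    "ellipsoid_mask",
]

_COMPONENT_ORDER = (
    "direct_flow",
    "retained_inflow",
    "delayed_ejection_flow",
    "residual_volume",
)


@dataclass
class PhantomSpec:
    """Parameters of one synthetic dataset.

    ``fractions`` are the target (direct, retained, delayed, residual)
    shares of the ED chamber volume.  ``ed_speed_cm_s`` sets the flow speed
    at the ED timepoint at the chamber centre; the default gives direct-flow
    kinetic energy of the magnitude seen in vivo (a few uJ/ml).
    ``anatomy_offset`` rigidly translates the chamber within the FOV and is
    how scan-rescan repositioning is emulated.
    """

    grid_shape: tuple[int, int, int] = (48, 36, 36)
    voxel_spacing: float = 3.0        # mm, isotropic
    n_frames: int = 20
    frame_interval: float = 52.0      # ms
    venc: float = 100.0               # cm/s
    ed_frame: int = 0
    es_frame: int = 8
    fractions: tuple[float, float, float, float] = (0.38, 0.16, 0.16, 0.30)
    chamber_length: float = 48.0      # mm along the axis
    chamber_radii: tuple[float, float] = (16.0, 14.0)  # mm, elliptical section
    axis: tuple[float, float, float] = (0.72, 0.50, 0.48)
    jet_strength: float = 0.45
    ed_speed_cm_s: float = 12.0
    noise_sigma: float = 0.0          # cm/s, per voxel/frame/direction
    background_poly: np.ndarray | None = None  # (3, 20), scaled basis, cm/s
    anatomy_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if f.size != 4 or np.any(f < 0):
            raise ValueError("fractions must be four non-negative numbers")
        if abs(f.sum() - 1.0) > 1e-8:
            raise ValueError(f"fractions must sum to 1; got {f.sum()}")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.ed_speed_cm_s > self.venc:
            raise ValueError("ed_speed_cm_s exceeds venc")
        if self.background_poly is not None:
            bp = np.asarray(self.background_poly, dtype=float)
            n_terms = len(polynomial_exponents())
            if bp.shape != (3, n_terms):
                raise ValueError(
                    f"background_poly must have shape (3, {n_terms})"
                )


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom."""

    labels: np.ndarray                 # (n_seeds,) component-name strings
    label_volume: np.ndarray           # int8 grid, -1 outside the ED mask
    fractions: dict                    # realised seed-count fractions
    spec_fractions: dict               # requested fractions
    discretisation_error: float        # max |realised - requested|
    analytic_velocity: Callable        # (points(n,3) mm, t ms) -> ((n,3) cm/s, oob)
    static_mask: np.ndarray            # envelope-exterior voxels (true rest)
    seeds: np.ndarray                  # (n_seeds, 3) mm, raster order
    es_window: tuple[float, float]     # ES cavity extent along the axis (mm)
    edv_ml: float
    esv_ml: float
    clip_count: int
    max_divergence_per_ms: float       # residual divergence report
    transport: dict                    # solved flow-program parameters
    geometry: dict                     # grid geometry needed by the oracle


@dataclass
class ScanDataset:
    """One realised acquisition: field, masks, truth, subject metadata."""

    field: VelocityField4D
    segmentation: LVSegmentation
    truth: PhantomTruth
    subject: SubjectRecord


# ---------------------------------------------------------------------------
# transport solve
# ---------------------------------------------------------------------------

@dataclass
class _Transport:
    """Solved 1-D flow program along the chamber axis.

    The velocity is separable, ``u(xi, t) = g(t) U(xi)``; the spatial
    profile is either uniform (``U = u0``) or a downward-opening quadratic
    ``U = u0 (1 + lin q + curv q^2)`` with ``curv < 0`` and
    ``q = (xi - m)/S``.  The quadratic vanishes at two stagnation points
    bracketing the chamber, which bounds every trajectory and keeps the
    flow map in closed form through ``H(xi) = int dxi / U`` (a log ratio of
    the distances to the two roots), so ``xi(t) = H^{-1}(H(xi0) + tau(t))``
    with ``tau = int g dt``.  The linear tilt ``lin`` is the knob that
    balances the pseudo-time lengths of the two cavity-resident intervals
    when the requested fractions are asymmetric.
    """

    kind: str          # "curved" | "uniform"
    u0: float          # mm/ms per unit g
    window: tuple[float, float]
    tau_f: float
    tau_b: float
    g_ed: float
    chamber: tuple[float, float]
    m: float = 0.0     # profile centre (mm along axis)
    S: float = 1.0     # profile length scale (mm)
    curv: float = 0.0  # dimensionless, < 0 for the curved kind
    lin: float = 0.0   # dimensionless tilt

    def _roots(self) -> tuple[float, float]:
        c, d = self.curv, self.lin
        disc = np.sqrt(d * d - 4.0 * c)  # always real for c < 0
        qp = (-d - disc) / (2.0 * c)     # positive root (c < 0)
        qm = (-d + disc) / (2.0 * c)     # negative root
        return qm, qp

    def profile(self, xi) -> np.ndarray:
        xi = np.asarray(xi, dtype=float)
        if self.kind == "uniform":
            return np.full_like(xi, self.u0)
        q = (xi - self.m) / self.S
        return self.u0 * (1.0 + self.lin * q + self.curv * q * q)

    def H(self, xi) -> np.ndarray:
        xi = np.asarray(xi, dtype=float)
        if self.kind == "uniform":
            return xi / self.u0
        qm, qp = self._roots()
        q = (xi - self.m) / self.S
        K = self.S / (self.u0 * (-self.curv) * (qp - qm))
        return K * np.log((q - qm) / (qp - q))

    def flow_map(self, xi, tau) -> np.ndarray:
        """Position after accumulated pseudo-time tau, exact."""
        if self.kind == "uniform":
            return np.asarray(xi, dtype=float) + self.u0 * np.asarray(tau, dtype=float)
        qm, qp = self._roots()
        K = self.S / (self.u0 * (-self.curv) * (qp - qm))
        E = np.exp((self.H(xi) + np.asarray(tau, dtype=float)) / K)
        return self.m + self.S * (qm + E * qp) / (1.0 + E)


#: fixed profile curvature of the curved transport branch
_CURV = -0.18


def _solve_transport(
    spec: PhantomSpec,
    t_fwd: float,
    t_back: float,
    fractions=None,
) -> _Transport:
    """Solve the flow program realising the requested fractions exactly.

    Along the axis the ED chamber is ``[-L/2, L/2]``.  The label regions are
    laid out contiguously: blood inside the cavity at the preceding ES
    occupies ``P = [-L/2, -L/2 + (f_del+f_res) L]`` at ED, and blood inside
    at the next ES occupies ``Q = [-L/2 + f_del L, -L/2 + (f_del+f_res+
    f_ret) L]``.  Requiring one ES window whose backward image is ``P`` and
    whose forward preimage is ``Q`` reduces, for a separable field, to the
    shape condition ``H(P1)-H(P0) = H(Q1)-H(Q0)``; the profile centre ``m``
    is placed (symmetry when |P| = |Q|, a 1-D root-find otherwise) so the
    condition holds, after which the window and the pseudo-time budgets
    follow in closed form.  Degenerate fraction patterns with an empty
    cavity overlap on one side are built with a uniform translation and an
    off-chamber window instead.
    """
    f_dir, f_ret, f_del, f_res = (
        float(x) for x in (spec.fractions if fractions is None else fractions)
    )
    L = spec.chamber_length
    X0, X1 = -L / 2.0, L / 2.0
    T = spec.n_frames * spec.frame_interval
    LP = (f_del + f_res) * L   # length inside at preceding ES
    LQ = (f_res + f_ret) * L   # length inside at next ES
    margin = 4.0
    jet_peak = 1.0 + float(spec.jet_strength)  # centre-line speed factor
    v_ed = spec.ed_speed_cm_s * 0.01 / jet_peak  # mm/ms, section-mean line

    def uniform(u0, a, M, tau_f, tau_b):
        # degenerate patterns run at a capped amplitude so the oscillatory
        # excursion (~ v T / 2 pi) stays inside the FOV
        v_eff = min(v_ed, 0.04)
        return _Transport(
            "uniform", u0, (a, a + M), tau_f, tau_b,
            g_ed=v_eff / u0, chamber=(X0, X1),
        )

    if LP <= 0.0 and LQ <= 0.0:
        # pure direct flow: the ES window sits just beyond the chamber top
        # and the net half-cycle transport is small, so no endpoint reaches
        # it at either ES while flow still oscillates at the requested speed
        u0 = 0.08
        return uniform(u0, X1 + 1.5 * margin, 0.15 * L, 2.0 / u0, 0.0)
    if LP <= 0.0 or LQ <= 0.0:
        # a single empty cavity-overlap side has no transport programme in
        # this family (the window would have to sit a full chamber length
        # away, outside the FOV)
        raise ValueError(
            f"infeasible fractions {spec.fractions}: patterns with exactly "
            "one of (delayed+residual, retained+residual) equal to zero are "
            "not realisable by the phantom's transport geometry"
        )
    if f_dir <= 0.0 and f_ret <= 0.0 and f_del <= 0.0:
        # pure residual volume: a static chamber entirely inside the window
        u0 = 0.08
        return uniform(u0, X0 - margin, L + 2 * margin, 0.0, 0.0)

    # A slab of direct flow sits below the delayed-ejection region (the
    # "neither resident" class may occupy both chamber ends), so that every
    # ES-window edge has seeded blood on both sides at both ES timepoints:
    # otherwise velocity noise diffuses endpoints across an edge with
    # nothing diffusing back, biasing the resident components low.
    w_low = min(6.0, 0.4 * f_dir * L)
    P0 = X0 + w_low
    P1 = P0 + LP
    Q0 = P0 + f_del * L
    Q1 = Q0 + LQ
    S = L
    m = 0.25 * (P0 + P1 + Q0 + Q1)

    def trial(lin: float) -> _Transport:
        return _Transport("curved", 1.0, (0.0, 0.0), 0.0, 0.0, 1.0, (X0, X1),
                          m=m, S=S, curv=_CURV, lin=lin)

    def h_len_diff(lin: float) -> float:
        # H(P1)-H(P0) - (H(Q1)-H(Q0)) at unit u0 (scale-free).  The whole
        # chamber must sit strictly inside the profile's stagnation points.
        tr = trial(lin)
        qm, qp = tr._roots()
        q = (np.array([P0, P1, Q0, Q1, X0, X1]) - m) / S
        if q.min() <= qm + 0.02 or q.max() >= qp - 0.02:
            return np.nan
        h = tr.H(np.array([P0, P1, Q0, Q1]))
        return float((h[1] - h[0]) - (h[3] - h[2]))

    if np.isclose(LP, LQ):
        lin = 0.0
    else:
        from scipy.optimize import brentq

        grid = np.linspace(-1.3, 1.3, 261)
        vals = np.array([h_len_diff(x) for x in grid])
        ok = np.isfinite(vals)
        g_ok, v_ok = grid[ok], vals[ok]
        brackets = [
            (g_ok[i], g_ok[i + 1])
            for i in range(len(v_ok) - 1)
            if v_ok[i] == 0.0 or v_ok[i] * v_ok[i + 1] < 0
        ]
        if not brackets:
            raise ValueError(
                "infeasible fractions: no transport profile realises the "
                f"requested pattern {spec.fractions}"
            )
        # prefer the root closest to the untilted profile
        lo, hi = min(brackets, key=lambda br: abs(0.5 * (br[0] + br[1])))
        lin = float(brentq(h_len_diff, lo, hi, xtol=1e-13))

    q_c = -m / S
    u_rel_center = 1.0 + lin * q_c + _CURV * q_c * q_c
    if u_rel_center < 0.2:
        raise ValueError(
            "infeasible fractions: the transport profile stagnates at the "
            "chamber centre"
        )
    u0 = v_ed / u_rel_center

    tr = _Transport("curved", u0, (0.0, 0.0), 0.0, 0.0, 1.0, (X0, X1),
                    m=m, S=S, curv=_CURV, lin=lin)
    tau_c = float(tr.H(P0) - tr.H(Q0))
    # Only the sum tau_f + tau_b is pinned by the fraction layout; the split
    # is chosen so each half-cycle transports blood by roughly a quarter
    # chamber length (large systolic wash-out, matching diastolic refill),
    # which both looks physiological and makes endpoint displacements span
    # several voxels so the ES-mask voxel lattice is well dithered.  When
    # the profile tilt amplifies the fast end's displacement, the wash-out
    # target is shrunk until the net transport stays within the FOV budget.
    jet_hi = 1.0 + float(spec.jet_strength)
    ends = np.array([X0, X1])
    for d_win in (0.25 * L, 0.15 * L, 0.08 * L, 0.04 * L):
        tau_f = float(tr.H(Q0 + d_win) - tr.H(Q0))
        tau_b = tau_c - tau_f
        disp = np.concatenate(
            [
                tr.flow_map(ends, tau_f * jet_hi) - ends,
                tr.flow_map(ends, -tau_b * jet_hi) - ends,
            ]
        )
        if np.all(np.isfinite(disp)) and np.max(np.abs(disp)) <= 0.5 * L:
            break
    a = float(tr.flow_map(Q0, tau_f))
    b = float(tr.flow_map(Q1, tau_f))
    tr.window = (a, b)
    tr.tau_f, tr.tau_b = tau_f, tau_b
    return tr


def _chain_weights(start: int, span: int, n: int, dt: float) -> np.ndarray:
    """Trapezoid weights over frames start..start+span, folded modulo n."""
    w = np.zeros(n)
    for j in range(span + 1):
        k = (start + j) % n
        w[k] += dt * (0.5 if j in (0, span) else 1.0)
    return w


def _solve_g(
    spec: PhantomSpec,
    transport: _Transport,
    fwd_frames: int,
    back_frames: int,
) -> np.ndarray:
    """Frame samples of g(t) meeting the two tau integrals and the ED value.

    g is represented by its samples (piecewise linear between frames,
    periodic), so the integral constraints are exact trapezoid sums.  A
    three-function harmonic basis anchored at the ED frame is fitted to the
    three constraints.
    """
    n = spec.n_frames
    dt = spec.frame_interval
    ed = spec.ed_frame
    k = np.arange(n)
    phase = 2.0 * np.pi * (k - ed) / n
    bases = [np.ones(n), np.cos(phase), np.sin(phase)]

    w_f = _chain_weights(ed, fwd_frames, n, dt)
    w_b = _chain_weights((ed - back_frames) % n, back_frames, n, dt)

    def solve_with(basis_list):
        B = np.column_stack(basis_list)
        A = np.vstack([w_f @ B, w_b @ B, B[ed]])
        rhs = np.array([transport.tau_f, transport.tau_b, transport.g_ed])
        sol, res, rank, _ = np.linalg.lstsq(A, rhs, rcond=None)
        ok = rank == 3 and np.allclose(A @ sol, rhs, atol=1e-9 * max(1.0, np.abs(rhs).max()))
        return (B @ sol) if ok else None

    g = solve_with(bases)
    if g is None:  # degenerate placement of ED/ES; add a second harmonic
        g = solve_with([np.ones(n), np.cos(phase), np.sin(2 * phase)])
    if g is None:
        raise ValueError(
            "could not construct a flow program for this ED/ES frame layout"
        )
    return g


def _g_interp(g: np.ndarray, dt: float, t) -> np.ndarray:
    """Piecewise-linear periodic interpolation of the frame samples."""
    n = len(g)
    tf = np.mod(np.asarray(t, dtype=float), n * dt) / dt
    k0 = tf.astype(int) % n
    w = tf - np.floor(tf)
    return g[k0] * (1.0 - w) + g[(k0 + 1) % n] * w


def _tau_profile(g: np.ndarray, dt: float, t_lo: float, t_hi: float, t_ed: float,
                 sub: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """tau(t) = integral of g from t_ed, on a dense grid over [t_lo, t_hi].

    The dense grid subdivides every frame interval, so the trapezoid rule is
    exact for the piecewise-linear g.
    """
    n_pts = int(np.ceil((t_hi - t_lo) / dt)) * sub + 1
    t = np.linspace(t_lo, t_hi, n_pts)
    if not np.any(np.isclose(t, t_ed)):
        t = np.sort(np.append(t, t_ed))
    gv = _g_interp(g, dt, t)
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (gv[1:] + gv[:-1]) * np.diff(t))])
    i_ed = int(np.argmin(np.abs(t - t_ed)))
    return t, cum - cum[i_ed]


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _axis_frame(axis) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    e = np.asarray(axis, dtype=float)
    e = e / np.linalg.norm(e)
    tmp = np.array([0.0, 0.0, 1.0]) if abs(e[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    f1 = np.cross(e, tmp)
    f1 /= np.linalg.norm(f1)
    f2 = np.cross(e, f1)
    return e, f1, f2


def _cos_ramp(x: np.ndarray) -> np.ndarray:
    """1 for x<=0, 0 for x>=1, smooth cosine in between."""
    xc = np.clip(x, 0.0, 1.0)
    return 0.5 * (1.0 + np.cos(np.pi * xc))


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[VelocityField4D, LVSegmentation, PhantomTruth]:
    """Build the velocity field, ED/ES masks and exact ground truth.

    The continuum layout is calibrated in a short deterministic fixed-point
    loop: the interior label cuts are adjusted until the voxel-seeded truth
    fractions reproduce the requested ones (the voxelised ES lookup shifts
    effective cut positions by a fraction of a voxel, and the jet average is
    exact only to first order; the loop absorbs both).  Raises
    ``ValueError`` when the requested geometry (chamber plus the mid-cycle
    pathline excursions implied by the flow program) does not fit inside the
    grid.
    """
    shape = tuple(spec.grid_shape)
    sp = float(spec.voxel_spacing)
    spacing = np.full(3, sp)
    origin = np.zeros(3)
    n, dt = spec.n_frames, spec.frame_interval
    fwd_frames, back_frames = es_spans(spec.ed_frame, spec.es_frame, n)
    t_fwd, t_back = fwd_frames * dt, back_frames * dt
    t_ed = spec.ed_frame * dt
    jet = float(spec.jet_strength)

    e, f1, f2 = _axis_frame(spec.axis)
    r1, r2 = spec.chamber_radii
    pad, taper = 3.0, 6.0
    es_pad = 0.9 * sp
    center = origin + (np.asarray(shape) - 1) / 2.0 * spacing + np.asarray(
        spec.anatomy_offset, dtype=float
    )

    # voxel-centre coordinates in the chamber frame
    idx = np.indices(shape).reshape(3, -1).T
    pts = origin + idx * spacing
    rel = pts - center
    xi = rel @ e
    eta1 = rel @ f1
    eta2 = rel @ f2
    rho = np.sqrt((eta1 / r1) ** 2 + (eta2 / r2) ** 2)
    rho_es = np.sqrt((eta1 / (r1 + es_pad)) ** 2 + (eta2 / (r2 + es_pad)) ** 2)

    # chamber (ED) mask and seeds are independent of the flow program.
    # The ES cross-section is padded by most of a voxel radius: trajectories
    # never move radially, so a seed's status at ES is decided by its
    # along-axis coordinate alone, and the pad stops endpoints of
    # radial-boundary seeds from being voxel-quantised out of the cavity.
    X0, X1 = -spec.chamber_length / 2.0, spec.chamber_length / 2.0
    ed_mask = ((rho <= 1.0) & (xi >= X0) & (xi <= X1)).reshape(shape)
    seed_idx = np.argwhere(ed_mask)
    seeds = origin + seed_idx * spacing
    rel_seed = seeds - center
    xi0 = rel_seed @ e
    rho_seed2 = ((rel_seed @ f1) / r1) ** 2 + ((rel_seed @ f2) / r2) ** 2
    s_seed = 1.0 + jet * (1.0 - 2.0 * rho_seed2)
    n_seeds = len(seeds)

    spec_f = np.asarray(spec.fractions, dtype=float)

    def build_program(frac):
        tr = _solve_transport(spec, t_fwd, t_back, fractions=frac)
        g = _solve_g(spec, tr, fwd_frames, back_frames)
        t_dense, tau_dense = _tau_profile(g, dt, t_ed - t_back, t_ed + t_fwd, t_ed)
        a_win, b_win = tr.window
        es_mask = (
            (rho_es <= 1.0) & (xi >= a_win) & (xi <= b_win)
        ).reshape(shape)
        tau_F = float(np.interp(t_ed + t_fwd, t_dense, tau_dense))
        tau_P = float(np.interp(t_ed - t_back, t_dense, tau_dense))
        p_next = seeds + (tr.flow_map(xi0, tau_F * s_seed) - xi0)[:, None] * e
        p_prev = seeds + (tr.flow_map(xi0, tau_P * s_seed) - xi0)[:, None] * e
        in_next = mask_lookup(p_next, es_mask, origin, spacing)
        in_prev = mask_lookup(p_prev, es_mask, origin, spacing)
        counts = np.array(
            [
                np.sum(~in_prev & ~in_next),
                np.sum(~in_prev & in_next),
                np.sum(in_prev & ~in_next),
                np.sum(in_prev & in_next),
            ],
            dtype=float,
        )
        return {
            "transport": tr,
            "g": g,
            "t_dense": t_dense,
            "tau_dense": tau_dense,
            "es_mask": es_mask,
            "in_next": in_next,
            "in_prev": in_prev,
            "realized": counts / n_seeds,
        }

    # fixed-point calibration of the interior cuts (only meaningful for
    # non-degenerate fraction patterns; converges in a few iterations
    # because the realised fractions respond with near-unit gain)
    calibrate = np.all(spec_f > 0.0)
    frac = spec_f.copy()
    prog = build_program(frac)
    best = (float(np.max(np.abs(prog["realized"] - spec_f))), prog)
    if calibrate:
        for _ in range(10):
            err = spec_f - prog["realized"]
            if np.max(np.abs(err)) < 2.5e-3:
                break
            # damped unit-gain update, kept within a feasible neighbourhood
            frac = np.clip(frac + 0.6 * err, 5e-3, None)
            frac = np.clip(frac / frac.sum(), spec_f - 0.08, spec_f + 0.08)
            frac = frac / frac.sum()
            try:
                prog = build_program(frac)
            except ValueError:
                break  # stepped outside the feasible set; keep the best
            gap = float(np.max(np.abs(prog["realized"] - spec_f)))
            if gap < best[0]:
                best = (gap, prog)
    prog = best[1]

    transport: _Transport = prog["transport"]
    g = prog["g"]
    a_win, b_win = transport.window
    es_mask = prog["es_mask"]
    in_next, in_prev = prog["in_next"], prog["in_prev"]
    t_dense, tau_dense = prog["t_dense"], prog["tau_dense"]

    def envelope(tau_d):
        # pathline excursion envelope along the axis over the full cycle,
        # covering the fastest (jet core) and slowest (wall) lines
        xi_traj = np.stack(
            [
                transport.flow_map(x, tau_d * sfac)
                for x in (X0, X1)
                for sfac in (1.0 - jet, 1.0 + jet)
            ]
        )
        if not np.all(np.isfinite(xi_traj)):
            raise ValueError(
                "flow program drives chamber blood through a stagnation "
                "point; reduce ed_speed_cm_s or chamber_length"
            )
        return (
            float(min(xi_traj.min(), a_win)) - 3.0,
            float(max(xi_traj.max(), b_win)) + 3.0,
        )

    def fits(lo, hi):
        # per-axis extreme of the tilted elliptical envelope: axial reach
        # plus the quadrature reach of the two cross-section radii
        xi_reach = max(abs(lo), abs(hi)) + taper
        r1_out, r2_out = r1 + pad + taper, r2 + pad + taper
        reach = np.abs(e) * xi_reach + np.sqrt(
            (f1 * r1_out) ** 2 + (f2 * r2_out) ** 2
        )
        lo_ok = center - reach >= origin - 0.5 * spacing
        hi_ok = center + reach <= origin + (np.asarray(shape) - 0.5) * spacing
        return bool(np.all(lo_ok) and np.all(hi_ok))

    # The mid-cycle excursion scales with the oscillation amplitude of g,
    # while the component labels depend only on the pinned half-cycle
    # integrals of g; when the excursion overflows the FOV the flow is
    # re-solved at reduced amplitude (lower peak speed, identical truth).
    xi_lo, xi_hi = envelope(tau_dense)
    for _ in range(5):
        if fits(xi_lo, xi_hi):
            break
        transport.g_ed *= 0.75
        g = _solve_g(spec, transport, fwd_frames, back_frames)
        t_dense, tau_dense = _tau_profile(
            g, dt, t_ed - t_back, t_ed + t_fwd, t_ed
        )
        xi_lo, xi_hi = envelope(tau_dense)
    if not fits(xi_lo, xi_hi):
        raise ValueError(
            "phantom geometry (chamber plus flow excursions of "
            f"[{xi_lo:.1f}, {xi_hi:.1f}] mm along the axis) does not fit "
            f"inside the {shape} grid; enlarge the grid or reduce "
            "chamber_length/ed_speed_cm_s"
        )

    # smooth envelope: 1 in the core, cosine-tapered to 0 outside
    rho_core = np.sqrt((eta1 / (r1 + pad)) ** 2 + (eta2 / (r2 + pad)) ** 2)
    rho_out = 1.0 + taper / min(r1 + pad, r2 + pad)
    w_r = _cos_ramp((rho_core - 1.0) / (rho_out - 1.0))
    mid = 0.5 * (xi_lo + xi_hi)
    half = 0.5 * (xi_hi - xi_lo)
    w_xi = _cos_ramp((np.abs(xi - mid) - half) / taper)
    w_env = w_r * w_xi

    # parabolic-like jet: fast core, slow wall, zero area-mean over the
    # section.  Each axial line runs the same flow program at its own rate,
    # so endpoint displacements vary by several voxels within every cut
    # plane (dithering the ES-mask voxel lattice across seeds) while the
    # section-averaged transport is preserved to first order
    s_line = 1.0 + jet * (1.0 - 2.0 * rho**2)
    U = transport.profile(xi) * s_line * w_env  # mm/ms per unit g
    profile = (U[:, None] * e[None, :]).reshape(*shape, 3) * 100.0  # cm/s

    data = profile[:, :, :, None, :] * g[None, None, None, :, None]

    if spec.background_poly is not None:
        half_ext = (np.asarray(shape) - 1) / 2.0 * spacing
        fov_center = origin + half_ext
        X = polynomial_basis(pts, fov_center, half_ext)
        offset = (X @ np.asarray(spec.background_poly, dtype=float).T).reshape(
            *shape, 3
        )
        data = data + offset[:, :, :, None, :]

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma > 0:
        data = data + rng.normal(0.0, spec.noise_sigma, size=data.shape)

    clip_count = int(np.sum(np.abs(data) > spec.venc))
    data = np.clip(data, -spec.venc, spec.venc)

    fld = VelocityField4D(data, spacing, dt, spec.venc, origin)

    seg = LVSegmentation(
        ed_mask_cine=ed_mask,
        es_mask=es_mask,
        ed_frame=spec.ed_frame,
        es_frame=spec.es_frame,
        cine_spacing=spacing,
        cine_origin=origin,
    )

    labels = np.empty(n_seeds, dtype="U32")
    labels[(~in_prev) & (~in_next)] = "direct_flow"
    labels[(~in_prev) & in_next] = "retained_inflow"
    labels[in_prev & (~in_next)] = "delayed_ejection_flow"
    labels[in_prev & in_next] = "residual_volume"

    label_volume = np.full(shape, -1, dtype=np.int8)
    code = {name: i for i, name in enumerate(_COMPONENT_ORDER)}
    label_volume[tuple(seed_idx.T)] = [code[l] for l in labels]

    fractions = {
        name: float(np.sum(labels == name)) / n_seeds for name in _COMPONENT_ORDER
    }
    spec_fr = dict(zip(_COMPONENT_ORDER, spec.fractions))
    disc = max(abs(fractions[k] - spec_fr[k]) for k in _COMPONENT_ORDER)

    # analytic (noise- and offset-free) velocity handle for the oracle
    r1c, r2c = r1 + pad, r2 + pad

    def analytic_velocity(points, t):
        p = np.atleast_2d(np.asarray(points, dtype=float))
        relp = p - center
        xip = relp @ e
        e1 = relp @ f1
        e2 = relp @ f2
        rc = np.sqrt((e1 / r1c) ** 2 + (e2 / r2c) ** 2)
        wv = _cos_ramp((rc - 1.0) / (rho_out - 1.0)) * _cos_ramp(
            (np.abs(xip - mid) - half) / taper
        )
        gv = float(_g_interp(g, dt, t))
        sv = 1.0 + jet * (1.0 - 2.0 * ((e1 / r1) ** 2 + (e2 / r2) ** 2))
        speed = gv * transport.profile(xip) * sv * wv * 100.0  # cm/s
        return speed[:, None] * e[None, :], np.zeros(len(p), dtype=bool)

    # residual divergence: dU/dxi inside the core plus taper gradients;
    # report the worst instantaneous value (per ms)
    g_max = float(np.max(np.abs(g)))
    core_sel = w_env > 0
    dU_max = (
        0.0 if transport.kind == "uniform"
        else float(np.max(np.abs(
            2.0 * transport.u0 * transport.curv
            * (xi[core_sel] - transport.m) / transport.S**2
        )))
    )
    core_u_max = float(np.max(np.abs(transport.profile(xi[core_sel]))))
    max_div = g_max * (dU_max + core_u_max * np.pi / (2.0 * taper))

    vox_ml = fld.voxel_volume_ml
    truth = PhantomTruth(
        labels=labels,
        label_volume=label_volume,
        fractions=fractions,
        spec_fractions=spec_fr,
        discretisation_error=disc,
        analytic_velocity=analytic_velocity,
        static_mask=(w_env == 0.0).reshape(shape),
        seeds=seeds,
        es_window=(a_win, b_win),
        edv_ml=n_seeds * vox_ml,
        esv_ml=float(es_mask.sum()) * vox_ml,
        clip_count=clip_count,
        max_divergence_per_ms=max_div,
        transport={
            "kind": transport.kind,
            "u0": transport.u0,
            "window": transport.window,
            "tau_f": transport.tau_f,
            "tau_b": transport.tau_b,
            "m": transport.m,
            "curv": transport.curv,
            "lin": transport.lin,
            "g": g,
        },
        geometry={
            "origin": origin,
            "spacing": spacing,
            "shape": shape,
            "ed_frame": spec.ed_frame,
            "es_frame": spec.es_frame,
            "frame_interval": dt,
            "n_frames": n,
            "voxel_volume_ml": vox_ml,
            "es_mask": es_mask,
            "seed_idx": seed_idx,
        },
    )
    return fld, seg, truth


def realize(spec: PhantomSpec, subject_id: str = "phantom", visit: str = "scan1") -> ScanDataset:
    """Generate a phantom and wrap it with subject metadata.

    The heart rate is the one implied by the cycle length.
    """
    fld, seg, truth = generate_phantom(spec)
    hr = 60000.0 / fld.cycle_length
    return ScanDataset(fld, seg, truth, SubjectRecord(subject_id, hr, visit))


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def oracle_fractions(
    truth: PhantomTruth,
    dense_factor: int = 2,
    step: float | None = None,
) -> dict:
    """Reference fractions from dense sub-voxel seeding on the analytic field.

    Integrates ``dense_factor**3`` sub-seeds per ED voxel with RK4 directly
    on the analytic velocity function (no grid interpolation), classifies
    each by its ES endpoints against the same voxelised ES mask the pipeline
    uses, and returns volume fractions with each sub-seed carrying
    ``1/dense_factor**3`` of a voxel.
    """
    from .pathlines import integrate_pathline

    geo = truth.geometry
    dt = geo["frame_interval"]
    if step is None:
        step = dt / 40.0
    fwd, back = es_spans(geo["ed_frame"], geo["es_frame"], geo["n_frames"])
    t_ed = geo["ed_frame"] * dt
    spacing = geo["spacing"]

    df = int(dense_factor)
    offs = (np.arange(df) + 0.5) / df - 0.5
    sub = np.stack(np.meshgrid(offs, offs, offs, indexing="ij"), axis=-1).reshape(-1, 3)
    seeds = (truth.seeds[:, None, :] + sub[None, :, :] * spacing).reshape(-1, 3)

    sampler = truth.analytic_velocity
    _, pf, _, _ = integrate_pathline(
        sampler, seeds, t_ed, t_ed + fwd * dt, step, store_every=10**9
    )
    _, pb, _, _ = integrate_pathline(
        sampler, seeds, t_ed, t_ed - back * dt, step, store_every=10**9
    )
    in_next = mask_lookup(pf[:, -1], geo["es_mask"], geo["origin"], spacing)
    in_prev = mask_lookup(pb[:, -1], geo["es_mask"], geo["origin"], spacing)

    n_sub = len(seeds)
    return {
        "direct_flow": float(np.sum(~in_prev & ~in_next)) / n_sub,
        "retained_inflow": float(np.sum(~in_prev & in_next)) / n_sub,
        "delayed_ejection_flow": float(np.sum(in_prev & ~in_next)) / n_sub,
        "residual_volume": float(np.sum(in_prev & in_next)) / n_sub,
    }


# ---------------------------------------------------------------------------
# paired designs
# ---------------------------------------------------------------------------

def make_scan_pair(
    spec: PhantomSpec,
    mode: str = "rescan",
    seed_pair: tuple[int, int] | None = None,
    reposition_mm: float = 1.5,
    fraction_jitter: float = 0.03,
    interval_scale_sd: float = 0.07,
) -> tuple[ScanDataset, ScanDataset]:
    """Two acquisitions of one subject.

    ``rescan`` keeps the anatomy and flow program identical and varies only
    the noise realisation and a small rigid FOV repositioning (uniform within
    ``reposition_mm`` per axis, i.e. within one voxel) — the technique-error
    sources of a same-visit repeat.  ``interval`` additionally perturbs the
    flow program before regenerating: the component fractions are jittered
    (Gaussian, sd ``fraction_jitter``, renormalised) and the cycle timing
    rescaled (heart-rate-like change, lognormal-free Gaussian factor of sd
    ``interval_scale_sd``), emulating physiological variability between
    visits weeks apart.
    """
    if mode not in ("rescan", "interval"):
        raise ValueError("mode must be 'rescan' or 'interval'")
    if seed_pair is None:
        seed_pair = (spec.seed, spec.seed + 10007)
    rng = np.random.default_rng([int(seed_pair[0]) % (2**31), int(seed_pair[1]) % (2**31), 7])

    spec1 = replace(spec, seed=int(seed_pair[0]) % (2**31))
    shift = rng.uniform(-reposition_mm, reposition_mm, size=3)
    spec2 = replace(
        spec,
        seed=int(seed_pair[1]) % (2**31),
        anatomy_offset=tuple(np.asarray(spec.anatomy_offset) + shift),
    )
    if mode == "interval":
        f = np.asarray(spec.fractions, dtype=float)
        f2 = np.clip(f + rng.normal(0.0, fraction_jitter, size=4), 1e-3, None)
        f2 = f2 / f2.sum()
        # retained inflow and delayed ejection are physiologically coupled
        # (over a steady state the delayed ejection largely is the previous
        # cycle's retained inflow, and cavity volume must be conserved), so
        # their jittered difference is kept within the transport geometry's
        # realisable range
        asym_cap = 0.045
        asym = f2[1] - f2[2]
        if abs(asym) > asym_cap:
            mean_rd = 0.5 * (f2[1] + f2[2])
            f2[1] = mean_rd + 0.5 * asym_cap * np.sign(asym)
            f2[2] = mean_rd - 0.5 * asym_cap * np.sign(asym)
        scale = float(np.clip(rng.normal(1.0, interval_scale_sd), 0.8, 1.2))
        spec2 = replace(
            spec2,
            fractions=tuple(f2),
            frame_interval=spec.frame_interval * scale,
        )
    ds1 = realize(spec1, visit="scan1")
    ds2 = realize(spec2, visit="scan2")
    return ds1, ds2


# ---------------------------------------------------------------------------
# simple auxiliary phantoms
# ---------------------------------------------------------------------------

def uniform_phantom(
    speed_cm_s: float = 12.1,
    direction=(1.0, 0.0, 0.0),
    grid_shape=(32, 32, 32),
    voxel_spacing: float = 3.0,
    n_frames: int = 20,
    frame_interval: float = 52.0,
    venc: float = 100.0,
    ed_frame: int = 0,
    es_frame: int = 8,
) -> tuple[VelocityField4D, LVSegmentation]:
    """Spatially and temporally uniform velocity with a central cubic mask.

    Every seed's speed is ``speed_cm_s`` at all times (in particular at ED),
    and all blood transits the mask within the cycle, so the whole EDV is
    direct flow and the closed-form kinetic energy ``1/2 rho v^2`` applies
    exactly per millilitre.
    """
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    shape = tuple(grid_shape)
    data = np.broadcast_to(
        speed_cm_s * d, (*shape, n_frames, 3)
    ).copy()
    fld = VelocityField4D(data, np.full(3, voxel_spacing), frame_interval, venc)
    lo = [s // 2 - 5 for s in shape]
    mask = np.zeros(shape, dtype=bool)
    mask[lo[0]:lo[0] + 10, lo[1]:lo[1] + 10, lo[2]:lo[2] + 10] = True
    es = np.zeros(shape, dtype=bool)  # ES cavity shifted by one voxel ring
    es[lo[0]:lo[0] + 9, lo[1]:lo[1] + 10, lo[2]:lo[2] + 10] = True
    seg = LVSegmentation(mask, es, ed_frame, es_frame,
                         cine_spacing=np.full(3, voxel_spacing))
    return fld, seg


def ellipsoid_mask(
    shape,
    spacing,
    center,
    semiaxes,
    origin=(0.0, 0.0, 0.0),
) -> np.ndarray:
    """Voxelised ellipsoid (centre-inside rule) on an arbitrary grid."""
    spacing = np.asarray(spacing, dtype=float) * np.ones(3)
    idx = np.indices(tuple(shape)).reshape(3, -1).T
    pts = np.asarray(origin, dtype=float) + idx * spacing
    u = (pts - np.asarray(center, dtype=float)) / np.asarray(semiaxes, dtype=float)
    return (np.sum(u**2, axis=1) <= 1.0).reshape(tuple(shape))
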