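"""Pathline emission and integration through the periodic velocity field.

One pathline is emitted from the centre of each voxel of the resampled ED
mask and represents the fixed blood volume of that voxel.  Trajectories are
advanced with classical fixed-step fourth-order Runge-Kutta on
``dx/dt = v(x, t)``, forwards in time from ED to the next ES and backwards
from ED to the preceding ES; because the acquisition is a closed temporal
loop, the two intervals together tile exactly one cardiac cycle.

Out-of-FOV policy: once a particle's position leaves the convex hull of
voxel centres its position is frozen and the pathline flagged.  Ejected blood
legitimately exits the imaging volume; downstream classification treats
frozen positions as outside the LV.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterator

import numpy as np

from .flow_io import (
    CM_PER_S_TO_MM_PER_MS,
    VelocityField4D,
    sample_velocity,
)

__all__ = ["Pathline", "PathlineBundle", "emit_seeds", "integrate_pathline", "track_all"]

Sampler = Callable[[np.ndarray, float], tuple[np.ndarray, np.ndarray]]


def _as_sampler(field_or_sampler) -> Sampler:
    if isinstance(field_or_sampler, VelocityField4D):
        fld = field_or_sampler
        return lambda p, t: sample_velocity(fld, p, t)
    return field_or_sampler


@dataclass
class Track:
    """One direction of travel: positions/velocities at stored timesteps."""

    times: np.ndarray      # (n_steps,) ms, strictly monotone; times[0] is ED
    positions: np.ndarray  # (n_steps, 3) mm
    velocities: np.ndarray  # (n_steps, 3) cm/s
    left_fov: bool


@dataclass
class Pathline:
    """A single seed's bidirectional trajectory and its blood volume."""

    seed: np.ndarray       # mm, ED voxel centre
    volume_ml: float       # one flow-voxel volume
    forward: Track         # ED -> next ES
    backward: Track        # ED -> preceding ES (times decreasing)


class PathlineBundle:
    """All pathlines of one dataset, stored as dense arrays.

    Behaves as a sequence of :class:`Pathline`; the array layout keeps
    classification and kinetic-energy summation vectorised.
    """

    def __init__(
        self,
        seeds: np.ndarray,
        volume_ml: float,
        t_forward: np.ndarray,
        pos_forward: np.ndarray,
        vel_forward: np.ndarray,
        left_fov_forward: np.ndarray,
        t_backward: np.ndarray,
        pos_backward: np.ndarray,
        vel_backward: np.ndarray,
        left_fov_backward: np.ndarray,
    ) -> None:
        self.seeds = seeds
        self.volume_ml = float(volume_ml)
        self.t_forward = t_forward
        self.pos_forward = pos_forward
        self.vel_forward = vel_forward
        self.left_fov_forward = left_fov_forward
        self.t_backward = t_backward
        self.pos_backward = pos_backward
        self.vel_backward = vel_backward
        self.left_fov_backward = left_fov_backward

    def __len__(self) -> int:
        return len(self.seeds)

    def __getitem__(self, i: int) -> Pathline:
        return Pathline(
            seed=self.seeds[i],
            volume_ml=self.volume_ml,
            forward=Track(
                self.t_forward,
                self.pos_forward[i],
                self.vel_forward[i],
                bool(self.left_fov_forward[i]),
            ),
            backward=Track(
                self.t_backward,
                self.pos_backward[i],
                self.vel_backward[i],
                bool(self.left_fov_backward[i]),
            ),
        )

    def __iter__(self) -> Iterator[Pathline]:
        for i in range(len(self)):
            yield self[i]

    @property
    def forward_endpoints(self) -> np.ndarray:
        return self.pos_forward[:, -1]

    @property
    def backward_endpoints(self) -> np.ndarray:
        return self.pos_backward[:, -1]

    @property
    def total_volume_ml(self) -> float:
        return len(self) * self.volume_ml


def emit_seeds(ed_mask_flow: np.ndarray, fld: VelocityField4D) -> np.ndarray:
    """One seed per inside voxel centre, in deterministic raster order."""
    ed_mask_flow = np.asarray(ed_mask_flow, dtype=bool)
    if not ed_mask_flow.any():
        raise ValueError("ED mask is empty; no seeds to emit")
    return fld.voxel_centers(ed_mask_flow)


def integrate_pathline(
    field_or_sampler,
    seeds: np.ndarray,
    t_start: float,
    t_end: float,
    step: float,
    store_every: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """RK4 advance of seeds from ``t_start`` to ``t_end`` (ms, unwrapped).

    ``t_end < t_start`` integrates backwards (dt < 0).  The interval is split
    into ``ceil(|span| / step)`` equal substeps so the final sample lands on
    ``t_end`` exactly.  The sampler wraps time periodically, so unwrapped
    times may extend beyond one cycle in either direction.

    Returns ``(times, positions, velocities, left_fov)`` with shapes
    ``(S,)``, ``(n, S, 3)``, ``(n, S, 3)``, ``(n,)`` where ``S`` covers the
    stored steps (every ``store_every``-th, endpoints always included).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    sampler = _as_sampler(field_or_sampler)
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    n = len(seeds)
    span = t_end - t_start
    n_steps = max(1, int(np.ceil(abs(span) / step)))
    h = span / n_steps

    store_idx = list(range(0, n_steps + 1, max(1, store_every)))
    if store_idx[-1] != n_steps:
        store_idx.append(n_steps)
    store_set = set(store_idx)

    times = t_start + np.array(store_idx, dtype=float) * h
    pos_out = np.empty((n, len(store_idx), 3))
    vel_out = np.empty((n, len(store_idx), 3))

    p = seeds.copy()
    frozen = np.zeros(n, dtype=bool)
    c = CM_PER_S_TO_MM_PER_MS
    out_col = 0

    for k in range(n_steps + 1):
        t = t_start + k * h
        v1, oob = sampler(p, t)
        frozen |= oob
        v1 = np.where(frozen[:, None], 0.0, v1)
        if k in store_set:
            pos_out[:, out_col] = p
            vel_out[:, out_col] = v1
            out_col += 1
        if k == n_steps:
            break
        # RK4 stages (velocities converted cm/s -> mm/ms)
        k1 = v1 * c
        v2, _ = sampler(p + 0.5 * h * k1, t + 0.5 * h)
        k2 = v2 * c
        v3, _ = sampler(p + 0.5 * h * k2, t + 0.5 * h)
        k3 = v3 * c
        v4, _ = sampler(p + h * k3, t + h)
        k4 = v4 * c
        dp = (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        p = np.where(frozen[:, None], p, p + dp)
        if not np.all(np.isfinite(p)):
            bad = np.where(~np.all(np.isfinite(p), axis=1))[0]
            raise RuntimeError(
                f"non-finite pathline position for seed indices {bad[:10].tolist()} "
                f"at t={t + h:.2f} ms"
            )

    return times, pos_out, vel_out, frozen


def es_spans(ed_frame: int, es_frame: int, n_frames: int) -> tuple[int, int]:
    """Frame spans (forward to next ES, backward to preceding ES), wrapped.

    The two spans always sum to ``n_frames``: together the tracks cover
    exactly one cycle.
    """
    if not (0 <= ed_frame < n_frames and 0 <= es_frame < n_frames):
        raise ValueError("ed_frame and es_frame must lie in [0, n_frames)")
    if ed_frame == es_frame:
        raise ValueError("ed_frame and es_frame must differ")
    fwd = (es_frame - ed_frame) % n_frames
    return fwd, n_frames - fwd


def track_all(
    fld: VelocityField4D,
    ed_mask_flow: np.ndarray,
    ed_frame: int,
    es_frame: int,
    step: float | None = None,
    store_every: int = 1,
) -> PathlineBundle:
    """Track every ED-mask voxel over one full cycle (forward and backward)."""
    fwd_frames, back_frames = es_spans(ed_frame, es_frame, fld.n_frames)
    dt = fld.frame_interval
    if step is None:
        step = dt / 10.0
    t_ed = ed_frame * dt
    seeds = emit_seeds(ed_mask_flow, fld)

    tf, pf, vf, lf = integrate_pathline(
        fld, seeds, t_ed, t_ed + fwd_frames * dt, step, store_every
    )
    tb, pb, vb, lb = integrate_pathline(
        fld, seeds, t_ed, t_ed - back_frames * dt, step, store_every
    )
    return PathlineBundle(
        seeds, fld.voxel_volume_ml, tf, pf, vf, lf, tb, pb, vb, lb
    )
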