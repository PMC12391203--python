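"""Forward kinematics, marker Jacobians and weighted inverse kinematics.

Inverse kinematics solves, frame by frame, the weighted least-squares
problem

    min_q  sum_i  w_i || x_i_measured - x_i_model(q) ||^2

over the independent coordinates (locked and coupled coordinates are
honoured through the model's linear coupling map).  The solver is a damped
Gauss-Newton (Levenberg-style lambda adaptation) with analytic geometric
Jacobians; trajectories are tracked sequentially with warm starts from the
previous frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Pose:
    """Rigid transform body frame -> lab frame."""

    R: np.ndarray
    t: np.ndarray

    def apply(self, x):
        return self.R @ np.asarray(x, float) + self.t


@dataclass
class CoordinateTrajectory:
    """Time series of generalized coordinates (independent set of a model)."""

    times: np.ndarray
    names: list
    q: np.ndarray                       # frames x coordinates

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.q = np.asarray(self.q, float)
        if self.q.shape != (len(self.times), len(self.names)):
            raise ValueError("coordinate trajectory shape mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def rate(self):
        return 1.0 / np.mean(np.diff(self.times))


@dataclass
class MarkerTrajectorySet:
    """Lab-frame marker positions (m) with a per-frame visibility mask."""

    times: np.ndarray
    names: list
    positions: np.ndarray               # frames x markers x 3, metres
    mask: np.ndarray = None             # frames x markers, True = visible
    up_axis: str = "Y"

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.positions = np.asarray(self.positions, float)
        n, m = len(self.times), len(self.names)
        if self.positions.shape != (n, m, 3):
            raise ValueError("marker trajectory shape mismatch")
        if self.mask is None:
            self.mask = np.ones((n, m), bool)
        else:
            self.mask = np.asarray(self.mask, bool)
        if np.any(np.diff(self.times)) and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def index(self, name):
        return self.names.index(name)

    @property
    def rate(self):
        return 1.0 / np.mean(np.diff(self.times))

    @property
    def up_index(self):
        return "XYZ".index(self.up_axis.upper())


@dataclass
class IKFrameResult:
    q: np.ndarray
    marker_sq_error: np.ndarray         # per-marker squared error, m^2 (nan if hidden)
    converged: bool
    iterations: int
    rank_deficient: bool = False

    @property
    def objective(self):
        return float(np.nansum(self.marker_sq_error))


@dataclass
class IKTrajectoryResult:
    trajectory: CoordinateTrajectory
    frames: list
    virtual: np.ndarray                 # frames x markers x 3, model markers
    all_converged: bool


# ---------------------------------------------------------------------------
# forward kinematics
# ---------------------------------------------------------------------------

def _axis_angle(axis, angle):
    """Rotation matrix about a unit axis (Rodrigues)."""
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    C = 1.0 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C]])


@dataclass
class FKState:
    """Poses plus per-coordinate world axes/points for Jacobians/dynamics."""

    R: dict
    p: dict
    axis_w: np.ndarray                  # n_full x 3 world axis per joint coord
    point_w: np.ndarray                 # n_full x 3 world point (rot axes)
    is_rot: np.ndarray
    markers: np.ndarray
    q_full: np.ndarray
    joint_centre: dict                  # body -> its joint's world centre


def _body_paths(model):
    """body -> list of full coordinate indices on the root-to-body path."""
    if getattr(model, "_paths", None) is None:
        paths = {"ground": []}
        for j in model.joints:
            idx = [model.coord_index[c.name] for c in j.coords]
            paths[j.child] = paths[j.parent] + idx
        model._paths = paths
    return model._paths


def fk_state(model, q_ind):
    q_full = model.full_q(np.asarray(q_ind, float))
    n_full = len(model.coords)
    axis_w = np.zeros((n_full, 3))
    point_w = np.zeros((n_full, 3))
    is_rot = np.zeros(n_full, bool)
    R = {"ground": np.eye(3)}
    p = {"ground": np.zeros(3)}
    centre = {}
    for j in model.joints:
        Rp, pp = R[j.parent], p[j.parent]
        c0 = pp + Rp @ j.location_in_parent
        nt = j.n_trans
        d = np.zeros(3)
        for k in range(nt):
            gi = model.coord_index[j.coords[k].name]
            u = Rp @ j.axes[k]
            axis_w[gi] = u
            d += u * q_full[gi]
        c1 = c0 + d
        Rcur = Rp
        for k in range(nt, len(j.coords)):
            gi = model.coord_index[j.coords[k].name]
            n = Rcur @ j.axes[k]
            axis_w[gi] = n
            point_w[gi] = c1
            is_rot[gi] = True
            Rcur = Rcur @ _axis_angle(j.axes[k], q_full[gi])
        R[j.child] = Rcur
        p[j.child] = c1 - Rcur @ j.location_in_child
        centre[j.child] = c1

    markers = np.empty((len(model.markers), 3))
    for i, m in enumerate(model.markers):
        markers[i] = p[m.body] + R[m.body] @ m.offset
    return FKState(R, p, axis_w, point_w, is_rot, markers, q_full, centre)


def forward_kinematics(model, q):
    """Body poses and lab-frame marker positions at coordinates ``q``.

    ``q`` covers the independent coordinates; coupling and locked values are
    applied internally.  Values outside declared coordinate ranges are
    permitted (solvers may pass through them transiently).
    """
    st = fk_state(model, q)
    poses = {name: Pose(st.R[name], st.p[name]) for name in st.R}
    return poses, st.markers


def marker_positions(model, q):
    return fk_state(model, q).markers


def marker_jacobian(model, q, marker_subset=None, method="analytic", eps=1e-7):
    """d(marker positions)/d(independent coordinates), (3m x n_ind).

    ``method`` is ``analytic`` (geometric Jacobian, default) or ``fd``
    (central differences); both honour coupling.
    """
    if method == "fd":
        q = np.asarray(q, float)
        sel = _marker_sel(model, marker_subset)
        cols = []
        for i in range(len(q)):
            dq = np.zeros_like(q)
            dq[i] = eps
            xp = marker_positions(model, q + dq)[sel]
            xm = marker_positions(model, q - dq)[sel]
            cols.append(((xp - xm) / (2 * eps)).ravel())
        return np.column_stack(cols)
    st = fk_state(model, q)
    return _analytic_jacobian(model, st, marker_subset)


def _marker_sel(model, marker_subset):
    if marker_subset is None:
        return np.arange(len(model.markers))
    name_to_i = {m.name: i for i, m in enumerate(model.markers)}
    return np.array([name_to_i[n] for n in marker_subset])


def _analytic_jacobian(model, st, marker_subset=None):
    paths = _body_paths(model)
    sel = _marker_sel(model, marker_subset)
    n_full = len(model.coords)
    J_full = np.zeros((3 * len(sel), n_full))
    for row, mi in enumerate(sel):
        m = model.markers[mi]
        x = st.markers[mi]
        for gi in paths[m.body]:
            if st.is_rot[gi]:
                col = np.cross(st.axis_w[gi], x - st.point_w[gi])
            else:
                col = st.axis_w[gi]
            J_full[3 * row:3 * row + 3, gi] = col
    C, _ = model.coupling()
    return J_full @ C


# ---------------------------------------------------------------------------
# inverse kinematics
# ---------------------------------------------------------------------------

def resolve_weights(model, weights=None):
    """Per-marker weight vector from None / array / {group: weight} dict."""
    m = len(model.markers)
    if weights is None:
        return np.array([mk.weight for mk in model.markers])
    w = np.asarray(weights, float) if not isinstance(weights, dict) else None
    if w is not None:
        if w.shape != (m,):
            raise ValueError("weight vector length mismatch")
        return w
    return np.array([float(weights.get(mk.group, 1.0)) for mk in model.markers])


def _wrap_indices(model):
    """Independent rotational coordinates safe to wrap by 2*pi.

    Wrapping preserves the pose only when the coordinate drives nothing else
    (its coupling column is a single unit entry): a 2*pi wrap of a coupling
    driver would shift its dependents by ratio * 2*pi.
    """
    if getattr(model, "_wrap_ind", None) is None:
        C, _ = model.coupling()
        idx = []
        for k, c in enumerate(model.independent):
            col = C[:, k]
            if c.kind == "rotational" and np.count_nonzero(col) == 1 \
                    and abs(col.sum() - 1.0) < 1e-12:
                idx.append(k)
        model._wrap_ind = np.array(idx, int)
    return model._wrap_ind


def _wrap(model, q):
    idx = _wrap_indices(model)
    if idx.size:
        q[idx] = (q[idx] + np.pi) % (2.0 * np.pi) - np.pi
    return q


def solve_ik_frame(model, measured, weights=None, q_init=None, mask=None,
                   gtol=1e-10, max_iter=100):
    """Weighted least-squares coordinate fit for one frame of marker data.

    ``measured`` is (n_markers, 3) in model marker order; hidden markers are
    excluded via ``mask`` (or NaN entries).  Returns an
    :class:`IKFrameResult`; non-convergence is reported, not raised.
    """
    measured = np.asarray(measured, float)
    n_mark = len(model.markers)
    if mask is None:
        mask = ~np.isnan(measured).any(axis=1)
    vis = np.flatnonzero(mask)
    w = resolve_weights(model, weights)
    sw = np.sqrt(np.repeat(w[vis], 3))
    q = (model.default_q() if q_init is None else np.asarray(q_init, float)).copy()
    n_ind = len(q)
    rank_deficient = 3 * len(vis) < n_ind

    def residual(qv):
        x = marker_positions(model, qv)
        return ((measured[vis] - x[vis]).ravel() * sw, x)

    r, x = residual(q)
    cost = r @ r
    lam = 1e-3
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        J = _analytic_jacobian(model, fk_state(model, q),
                               [model.markers[i].name for i in vis])
        J = J * sw[:, None]
        if it == 1 and not rank_deficient:
            rank_deficient = np.linalg.matrix_rank(J, tol=1e-10) < n_ind
        g = J.T @ r
        if np.max(np.abs(g), initial=0.0) < gtol or cost < 1e-20:
            converged = True
            break
        A = J.T @ J
        diagA = np.diag(A).copy()
        diagA[diagA < 1e-12] = 1e-12
        accepted = False
        for _ in range(25):
            try:
                dq = np.linalg.solve(A + lam * np.diag(diagA), g)
            except np.linalg.LinAlgError:
                lam *= 10
                continue
            r_new, x_new = residual(q + dq)
            cost_new = r_new @ r_new
            if cost_new <= cost:
                q = _wrap(model, q + dq)
                step = np.max(np.abs(dq))
                r, x, cost = r_new, x_new, cost_new
                lam = max(lam / 3.0, 1e-12)
                accepted = True
                if step < 1e-13:
                    converged = True
                break
            lam *= 10
        if not accepted or converged:
            converged = converged or not accepted and cost < 1e-16
            if not accepted:
                # damping exhausted: we are at a (possibly local) minimum
                converged = np.max(np.abs(g), initial=0.0) < 1e-6
            break

    err = np.full(n_mark, np.nan)
    err[vis] = np.sum((measured[vis] - x[vis]) ** 2, axis=1)
    return IKFrameResult(q, err, converged, it, rank_deficient)


def solve_ik_trajectory(model, trajset: MarkerTrajectorySet, weights=None,
                        q_init=None, gtol=1e-10, max_iter=100):
    """Track a whole trial; each frame warm-starts from the previous solution.

    Markers in the model but absent from ``trajset`` are treated as occluded
    throughout.
    """
    w = resolve_weights(model, weights)
    col = {n: i for i, n in enumerate(trajset.names)}
    n_frames = len(trajset.times)
    n_mark = len(model.markers)
    measured = np.full((n_frames, n_mark, 3), np.nan)
    mask = np.zeros((n_frames, n_mark), bool)
    for i, m in enumerate(model.markers):
        j = col.get(m.name)
        if j is not None:
            measured[:, i] = trajset.positions[:, j]
            mask[:, i] = trajset.mask[:, j]
    mask &= ~np.isnan(measured).any(axis=2)

    q = model.default_q() if q_init is None else np.asarray(q_init, float)
    frames = []
    Q = np.empty((n_frames, len(q)))
    virtual = np.empty((n_frames, n_mark, 3))
    for f in range(n_frames):
        res = solve_ik_frame(model, measured[f], w, q, mask[f],
                             gtol=gtol, max_iter=max_iter)
        q = res.q
        Q[f] = q
        virtual[f] = marker_positions(model, q)
        frames.append(res)
    traj = CoordinateTrajectory(trajset.times, model.independent_names, Q)
    return IKTrajectoryResult(traj, frames, virtual,
                              all(r.converged for r in frames))


def select_stance_window(events, times):
    """Frame index range for stance plus 10% of stance before foot strike.

    ``events`` is (foot_strike, foot_off) in seconds.  The window is
    [strike - 0.1*(off - strike), off], clipped to the trial, returned as an
    inclusive (first, last) index pair (first frame at or after the window
    start, last frame at or before its end).
    """
    strike, off = events
    times = np.asarray(times, float)
    if off <= strike:
        raise ValueError("foot-off must follow foot-strike")
    if off < times[0] or strike > times[-1]:
        raise ValueError("stance events lie outside the trial")
    start = max(strike - 0.1 * (off - strike), times[0])
    end = min(off, times[-1])
    first = int(np.searchsorted(times, start - 1e-12, side="left"))
    last = int(np.searchsorted(times, end + 1e-12, side="right")) - 1
    return first, last
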