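"""Inverse dynamics: filtering, differentiation, recursive Newton-Euler.

The equations of motion are evaluated without any reserve actuators: every
generalized force is reported as-is, and the six generalized forces of the
pelvis-to-ground free joint are the *residual* forces and moments — the
dynamic inconsistency between the tracked kinematics and the measured
external loads.  A dynamically perfect trial would have zero residuals.

The algorithm is a world-frame recursive Newton-Euler: an outward pass
propagates angular velocity, angular acceleration and linear acceleration
down the tree from the generalized coordinates and their derivatives, and an
inward pass accumulates the inter-segmental wrenches, projecting each onto
its joint's motion axes.  Coupled (constrained) coordinates are expanded
before the recursion and generalized forces are reported for the independent
coordinates only, so a coupling driver receives the ratio-weighted sum of
its joints' torques.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .geometry import GRAVITY
from .kinematics import CoordinateTrajectory, _axis_angle


@dataclass
class ExternalLoad:
    """Ground-reaction load applied to one body.

    ``force`` (N) acts at the centre of pressure ``cop`` (m, lab frame);
    ``free_moment`` (N m, lab frame) is the couple about the cop.
    """

    body: str
    times: np.ndarray
    force: np.ndarray                   # frames x 3
    cop: np.ndarray                     # frames x 3
    free_moment: np.ndarray             # frames x 3

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        for attr in ("force", "cop", "free_moment"):
            a = np.asarray(getattr(self, attr), float)
            if a.shape != (len(self.times), 3):
                raise ValueError(f"external load {attr} shape mismatch")
            if not np.all(np.isfinite(a)):
                raise ValueError(f"external load {attr} contains non-finite values")
            setattr(self, attr, a)

    def resampled(self, times):
        """Linear interpolation onto a new time base."""
        times = np.asarray(times, float)
        out = {}
        for attr in ("force", "cop", "free_moment"):
            a = getattr(self, attr)
            out[attr] = np.column_stack(
                [np.interp(times, self.times, a[:, k]) for k in range(3)])
        return ExternalLoad(self.body, times, out["force"], out["cop"],
                            out["free_moment"])


@dataclass
class GeneralizedForces:
    """Per-coordinate generalized forces (N m rotational, N translational)."""

    times: np.ndarray
    names: list
    tau: np.ndarray                     # frames x independent coordinates

    def column(self, name):
        return self.tau[:, self.names.index(name)]


@dataclass
class ResidualSeries:
    """The six pelvis-to-ground residuals.

    Force channels are ordered anterior-posterior, superior-inferior (up),
    medial-lateral; moment channels pelvis tilt, list, rotation — the free
    joint's coordinate order.
    """

    times: np.ndarray
    forces: np.ndarray                  # frames x 3, N
    moments: np.ndarray                 # frames x 3, N m
    force_labels: tuple = ("anterior_posterior", "superior_inferior",
                           "medial_lateral")
    moment_labels: tuple = ("tilt", "list", "rotation")


# ---------------------------------------------------------------------------
# filtering and differentiation
# ---------------------------------------------------------------------------

def lowpass_filter(series, cutoff, rate, order=4, axis=0):
    """Zero-phase (forward-backward) Butterworth low pass.

    End effects are handled by filtfilt's reflected padding.  ``cutoff`` must
    lie below the Nyquist frequency.
    """
    series = np.asarray(series, float)
    if cutoff >= rate / 2.0:
        raise ValueError(f"cutoff {cutoff} Hz is at or above Nyquist ({rate / 2} Hz)")
    b, a = signal.butter(order, cutoff / (rate / 2.0))
    padlen = min(3 * (max(len(a), len(b)) - 1), series.shape[axis] - 2)
    return signal.filtfilt(b, a, series, axis=axis, padlen=max(padlen, 0))


def differentiate(traj: CoordinateTrajectory, dt_tol=1e-6):
    """First and second time derivatives by central differences.

    Interior frames use second-order central differences; the ends use
    second-order one-sided stencils.  Requires (near-)uniform sampling.
    """
    t = traj.times
    if len(t) < 3:
        raise ValueError("need at least 3 frames to differentiate")
    dt = np.diff(t)
    if np.max(np.abs(dt - dt.mean())) > dt_tol * max(1.0, abs(dt.mean())):
        raise ValueError("non-uniform sampling beyond tolerance")
    qd = np.gradient(traj.q, t, axis=0, edge_order=2)
    qdd = np.gradient(qd, t, axis=0, edge_order=2)
    return qd, qdd


# ---------------------------------------------------------------------------
# spatial kinematics (outward pass)
# ---------------------------------------------------------------------------

@dataclass
class _BodyState:
    R: np.ndarray
    p: np.ndarray
    w: np.ndarray                       # angular velocity, lab frame
    al: np.ndarray                      # angular acceleration
    a: np.ndarray                       # origin linear acceleration
    c1: np.ndarray                      # joint centre (after translation)
    xcom: np.ndarray
    acom: np.ndarray


def spatial_states(model, q_full, qd_full, qdd_full):
    """Outward pass: per-body spatial state plus world coordinate axes.

    Returns (states dict, axis_w, is_rot) where ``axis_w[i]`` is the world
    axis of full coordinate ``i`` (rotation axes pass through the owning
    joint's centre).
    """
    n_full = len(model.coords)
    axis_w = np.zeros((n_full, 3))
    is_rot = np.zeros(n_full, bool)
    zero = np.zeros(3)
    states = {"ground": _BodyState(np.eye(3), zero, zero, zero, zero, zero,
                                   zero, zero)}
    vel = {"ground": zero}
    for j in model.joints:
        ps = states[j.parent]
        vp = vel[j.parent]
        r = ps.R @ j.location_in_parent
        c0 = ps.p + r
        v_c0 = vp + np.cross(ps.w, r)
        a_c0 = ps.a + np.cross(ps.al, r) + np.cross(ps.w, np.cross(ps.w, r))

        nt = j.n_trans
        d = np.zeros(3)
        du = np.zeros(3)                # sum u_m qd_m
        ddu = np.zeros(3)               # sum u_m qdd_m
        for k in range(nt):
            gi = model.coord_index[j.coords[k].name]
            u = ps.R @ j.axes[k]
            axis_w[gi] = u
            d += u * q_full[gi]
            du += u * qd_full[gi]
            ddu += u * qdd_full[gi]
        c1 = c0 + d
        v_c1 = v_c0 + du + np.cross(ps.w, d)
        a_c1 = (a_c0 + ddu + 2.0 * np.cross(ps.w, du)
                + np.cross(ps.al, d) + np.cross(ps.w, np.cross(ps.w, d)))

        w = ps.w.copy()
        al = ps.al.copy()
        Rcur = ps.R
        for k in range(nt, len(j.coords)):
            gi = model.coord_index[j.coords[k].name]
            n = Rcur @ j.axes[k]
            axis_w[gi] = n
            is_rot[gi] = True
            al = al + n * qdd_full[gi] + np.cross(w, n) * qd_full[gi]
            w = w + n * qd_full[gi]
            Rcur = Rcur @ _axis_angle(j.axes[k], q_full[gi])

        rc = -Rcur @ j.location_in_child
        p = c1 + rc
        v = v_c1 + np.cross(w, rc)
        a = a_c1 + np.cross(al, rc) + np.cross(w, np.cross(w, rc))

        body = model.bodies[j.child]
        rcom = Rcur @ body.com
        xcom = p + rcom
        acom = a + np.cross(al, rcom) + np.cross(w, np.cross(w, rcom))
        states[j.child] = _BodyState(Rcur, p, w, al, a, c1, xcom, acom)
        vel[j.child] = v
    return states, axis_w, is_rot


# ---------------------------------------------------------------------------
# inverse dynamics
# ---------------------------------------------------------------------------

def _gravity_vector(gravity):
    g = np.zeros(3)
    g[1] = -float(gravity)
    return g


def _frame_loads(loads, model):
    """Validate and group resampled loads by body."""
    by_body = {}
    for ld in loads:
        if ld.body not in model.bodies:
            raise ValueError(f"external load references unknown body {ld.body!r}")
        by_body.setdefault(ld.body, []).append(ld)
    return by_body


def _inward_pass(model, states, axis_w, is_rot, loads_f, gvec):
    """One frame's inward force pass; returns full-coordinate tau."""
    F, N = {}, {}
    for name, body in model.bodies.items():
        st = states[name]
        Iw = st.R @ body.inertia @ st.R.T
        F[name] = body.mass * (st.acom - gvec)
        N[name] = Iw @ st.al + np.cross(st.w, Iw @ st.w)

    tau = np.zeros(len(model.coords))
    fjoint, njoint = {}, {}
    for j in reversed(model.joints):
        b = j.child
        st = states[b]
        c1 = st.c1
        f = F[b].copy()
        n = N[b] + np.cross(st.xcom - c1, F[b])
        for fe, cop, me in loads_f.get(b, ()):
            f -= fe
            n -= np.cross(cop - c1, fe) + me
        for jc in model.children.get(b, ()):
            cb = jc.child
            f += fjoint[cb]
            n += njoint[cb] + np.cross(states[cb].c1 - c1, fjoint[cb])
        fjoint[b], njoint[b] = f, n
        for c in j.coords:
            gi = model.coord_index[c.name]
            tau[gi] = axis_w[gi] @ (n if is_rot[gi] else f)
    return tau


def inverse_dynamics(model, traj: CoordinateTrajectory, qdot=None, qddot=None,
                     loads=(), gravity=GRAVITY):
    """Generalized forces that realize the motion under the given loads.

    ``traj`` holds the independent coordinates; derivatives are computed by
    central differences when not supplied.  No reserve actuators exist:
    whatever the joints cannot explain lands in the pelvis residuals.
    """
    if list(traj.names) != model.independent_names:
        raise ValueError("trajectory coordinates do not match the model")
    if qdot is None or qddot is None:
        qdot, qddot = differentiate(traj)
    C, d = model.coupling()
    Qf = traj.q @ C.T + d
    Qdf = qdot @ C.T
    Qddf = qddot @ C.T

    by_body = _frame_loads(loads, model)
    res_by_body = {b: [ld.resampled(traj.times) for ld in lds]
                   for b, lds in by_body.items()}
    gvec = _gravity_vector(gravity)

    n_frames = len(traj.times)
    tau_ind = np.empty((n_frames, len(model.independent)))
    for f in range(n_frames):
        states, axis_w, is_rot = spatial_states(model, Qf[f], Qdf[f], Qddf[f])
        loads_f = {b: [(ld.force[f], ld.cop[f], ld.free_moment[f]) for ld in lds]
                   for b, lds in res_by_body.items()}
        tau_full = _inward_pass(model, states, axis_w, is_rot, loads_f, gvec)
        tau_ind[f] = C.T @ tau_full
    return GeneralizedForces(traj.times, model.independent_names, tau_ind)


def extract_residuals(forces: GeneralizedForces, model):
    """Slice the six pelvis free-joint generalized forces."""
    free = [j for j in model.joints if j.kind == "free6"]
    if not free:
        raise ValueError("model has no free joint")
    names = [c.name for c in free[0].coords]
    idx = [forces.names.index(n) for n in names]
    return ResidualSeries(forces.times, forces.tau[:, idx[:3]],
                          forces.tau[:, idx[3:]])


def whole_body_pelvis_residual(model, q, qd, qdd, loads_f=(), gravity=GRAVITY):
    """Closed-form momentum-balance pelvis residual for one state.

    Independent oracle for the recursive algorithm: sums m*a and the rate of
    angular momentum over every body, subtracts gravity and the external
    loads, and projects force and moment onto the free joint's coordinate
    axes.  ``loads_f`` is a list of (force, cop, free_moment) triples.
    """
    C, dvec = model.coupling()
    states, axis_w, is_rot = spatial_states(model, C @ q + dvec, C @ qd, C @ qdd)
    gvec = _gravity_vector(gravity)
    free = [j for j in model.joints if j.kind == "free6"][0]
    c1 = states[free.child].c1

    Fres = np.zeros(3)
    Mres = np.zeros(3)
    for name, body in model.bodies.items():
        st = states[name]
        Iw = st.R @ body.inertia @ st.R.T
        fb = body.mass * (st.acom - gvec)
        Fres += fb
        Mres += np.cross(st.xcom - c1, fb) + Iw @ st.al + np.cross(st.w, Iw @ st.w)
    for fe, cop, me in loads_f:
        fe = np.asarray(fe, float)
        Fres -= fe
        Mres -= np.cross(np.asarray(cop, float) - c1, fe) + np.asarray(me, float)

    out = np.empty(6)
    for k, c in enumerate(free.coords):
        gi = model.coord_index[c.name]
        out[k] = axis_w[gi] @ (Mres if is_rot[gi] else Fres)
    return out


def run_inverse_dynamics(model, traj, loads=(), cutoff=20.0,
                         filter_loads=True, gravity=GRAVITY):
    """The full processing pipeline: filter, differentiate, solve.

    Coordinates are low-pass filtered at ``cutoff`` (zero-phase Butterworth);
    by default the external loads get the identical treatment before being
    interpolated to the kinematic frames.
    """
    rate = traj.rate
    qf = lowpass_filter(traj.q, cutoff, rate)
    ftraj = CoordinateTrajectory(traj.times, traj.names, qf)
    use_loads = []
    for ld in loads:
        if filter_loads:
            lrate = 1.0 / np.mean(np.diff(ld.times))
            ld = ExternalLoad(ld.body, ld.times,
                              lowpass_filter(ld.force, cutoff, lrate),
                              lowpass_filter(ld.cop, cutoff, lrate),
                              lowpass_filter(ld.free_moment, cutoff, lrate))
        use_loads.append(ld)
    forces = inverse_dynamics(model, ftraj, loads=use_loads, gravity=gravity)
    return forces, extract_residuals(forces, model)
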