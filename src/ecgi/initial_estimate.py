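"""Initial estimates of activation and repolarization.

Activation: the fastest-route algorithm.  Every ventricular-surface node is
tried as an initial focus; its candidate activation map is the surface
geodesic distance divided by a candidate conduction velocity.  The candidate
whose forward-computed QRS correlates best with the measured QRS wins, and
further foci are added greedily (activation time = minimum over foci) while
the correlation keeps improving significantly.

Repolarization: for sinus beats an estimate inversely dependent on the
activation times (concordant T-wave physiology: early-activated regions
repolarize late); for ectopic beats the activation estimate delayed by the
J-point-to-T-end interval (discordant T-wave: repolarization follows
activation).

Fiducials (QRS onset, J-point, T-end) are threshold crossings of the RMS
curve of the body-surface ECG.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .mesh_geometry import TriSurface, all_pairs_geodesics
from .source_model import BodySurfaceECG, TimingMap, TMPTemplate, UPSTROKE_MS, _upstroke
from .volume_conductor import TransferMatrix

__all__ = [
    "FiducialSet",
    "detect_fiducials",
    "fastest_route_activation",
    "initial_rep_sinus",
    "initial_rep_ectopic",
    "DEFAULT_VELOCITIES",
]

#: candidate propagation velocities along the myocardial surface (m/s)
DEFAULT_VELOCITIES = (0.6, 0.8, 1.0)


@dataclass(frozen=True)
class FiducialSet:
    """QRS onset, J-point (end of QRS) and T-wave end, in ms."""

    onset: float
    j_point: float
    t_end: float

    def __post_init__(self):
        if not (self.onset < self.j_point < self.t_end):
            raise ValueError("fiducials must satisfy onset < J-point < T-end")

    @property
    def jt_interval(self) -> float:
        return self.t_end - self.j_point


def _smooth(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x
    k = np.ones(w) / w
    return np.convolve(x, k, mode="same")


def detect_fiducials(
    rms: np.ndarray,
    dt: float = 1.0,
    t0: float = 0.0,
    frac: float = 0.05,
    qrs_search_ms: float = 250.0,
    smooth_ms: float = 5.0,
) -> FiducialSet:
    """Fiducials from the RMS curve by fractional threshold crossings.

    QRS onset / J-point bracket the contiguous supra-threshold region around
    the QRS peak (threshold ``frac`` of the peak, raised to twice the
    baseline noise floor when needed); T-end is the last crossing of the same
    fraction of the T-peak after the J-point.
    """
    rms = np.asarray(rms, dtype=float)
    if rms.ndim != 1 or len(rms) < 10:
        raise ValueError("RMS curve too short")
    sm = _smooth(rms, max(1, int(round(smooth_ms / dt))))
    n_qrs = min(len(sm), int(round(qrs_search_ms / dt)))
    ip = int(np.argmax(sm[:n_qrs]))
    peak = sm[ip]
    floor = np.median(sm[: max(3, int(5 / dt))])
    thr = max(frac * peak, 2.0 * floor)
    if peak <= thr or peak <= 0:
        raise ValueError("QRS threshold never crossed (flat or noise-only signal)")
    i = ip
    while i > 0 and sm[i - 1] > thr:
        i -= 1
    onset = i
    j = ip
    while j < len(sm) - 1 and sm[j + 1] > thr:
        j += 1
    j_point = j
    after = sm[j_point + 1 :]
    if len(after) < 5:
        raise ValueError("record ends at the J-point; no T-wave")
    it = int(np.argmax(after)) + j_point + 1
    t_peak = sm[it]
    thr_t = max(frac * t_peak, 2.0 * floor)
    if t_peak <= thr_t:
        raise ValueError("T-wave threshold never crossed")
    above = np.nonzero(sm[it:] > thr_t)[0]
    t_end = it + int(above.max())
    return FiducialSet(
        onset=t0 + dt * onset, j_point=t0 + dt * j_point, t_end=t0 + dt * t_end
    )


def _qrs_scores(
    A: np.ndarray,
    tau_cands: np.ndarray,
    t_qrs: np.ndarray,
    meas: np.ndarray,
    upstroke_ms: float,
    chunk: int = 96,
) -> np.ndarray:
    """Correlation between measured QRS and the forward QRS of each candidate
    activation map (rows of ``tau_cands``)."""
    nc, n = tau_cands.shape
    ne, nt = A.shape[0], len(t_qrs)
    m0 = meas - meas.mean()
    nm = np.linalg.norm(m0)
    scores = np.empty(nc)
    for s in range(0, nc, chunk):
        tc = tau_cands[s : s + chunk]
        u = t_qrs[None, None, :] - tc[:, :, None]  # (c, n, t)
        U = _upstroke(u, upstroke_ms)
        # one GEMM per chunk: A (e,n) @ U reshaped to (n, c*t)
        E = (A @ np.moveaxis(U, 0, 1).reshape(n, -1)).reshape(ne, len(tc), nt)
        E = np.moveaxis(E, 1, 0)  # (c, e, t)
        E0 = E - E.mean(axis=(1, 2), keepdims=True)
        num = np.einsum("cet,et->c", E0, m0)
        den = np.linalg.norm(E0.reshape(len(tc), -1), axis=1) * nm
        with np.errstate(invalid="ignore", divide="ignore"):
            scores[s : s + chunk] = np.where(den > 0, num / den, -np.inf)
    return scores


def fastest_route_activation(
    surface: TriSurface,
    transfer: TransferMatrix,
    ecg: BodySurfaceECG,
    velocities=DEFAULT_VELOCITIES,
    template: TMPTemplate | None = None,
    fiducials: FiducialSet | None = None,
    geodesics: np.ndarray | None = None,
    max_foci: int = 5,
    improvement_tol: float = 0.01,
) -> tuple[TimingMap, list[dict]]:
    """Fastest-route initial activation estimate with greedy focus addition.

    Returns the winning activation map (ms, on the recording clock) and the
    list of selected foci (vertex index, position, velocity, correlation
    after adding the focus).
    """
    from .source_model import rms_curve

    if len(velocities) == 0:
        raise ValueError("at least one candidate velocity required")
    if fiducials is None:
        fiducials = detect_fiducials(rms_curve(ecg), dt=ecg.dt, t0=ecg.t0)
    upstroke = template.upstroke_ms if template is not None else UPSTROKE_MS
    t = ecg.time
    qmask = (t >= fiducials.onset) & (t <= fiducials.j_point)
    t_qrs = t[qmask]
    meas = ecg.data[:, qmask]
    A = transfer.A
    n = A.shape[1]
    D = all_pairs_geodesics(surface) if geodesics is None else geodesics

    # the RMS-threshold onset only approximates the true stimulus instant, so
    # candidates are scored over a small grid of global time shifts as well
    shifts = np.arange(-8.0, 8.1, 4.0)
    best = None  # (score, tau, vertex, velocity, shift)
    for v in velocities:
        for dt0 in shifts:
            tau_c = fiducials.onset + dt0 + D / v * 1000.0
            sc = _qrs_scores(A, tau_c, t_qrs, meas, upstroke)
            k = int(np.argmax(sc))
            if best is None or sc[k] > best[0]:
                best = (float(sc[k]), tau_c[k], k, v, dt0)
    score, tau, v0, vel, shift = best
    if score <= 0:
        warnings.warn("no focus candidate reached positive QRS correlation")
    foci = [{"vertex": int(v0), "position": surface.vertices[v0].tolist(),
             "velocity": vel, "correlation": score}]

    while len(foci) < max_foci:
        cand = np.minimum(tau[None, :], fiducials.onset + shift + D / vel * 1000.0)
        sc = _qrs_scores(A, cand, t_qrs, meas, upstroke)
        k = int(np.argmax(sc))
        if sc[k] - score <= improvement_tol:
            break
        score = float(sc[k])
        tau = cand[k]
        foci.append({"vertex": int(k), "position": surface.vertices[k].tolist(),
                     "velocity": vel, "correlation": score, "delay": 0.0})

    # refine per-focus onset delays (multifocal rhythms fire staggered, not
    # synchronously) by cyclic coordinate search on the QRS correlation
    if len(foci) > 1:
        delays = np.zeros(len(foci))
        grid = np.arange(0.0, 21.0, 4.0)
        for _ in range(2):
            for i in range(len(foci)):
                trial_delays = np.tile(delays, (len(grid), 1))
                trial_delays[:, i] = grid
                maps = np.stack([
                    np.min(fiducials.onset + shift + td[:, None] + D[[f["vertex"] for f in foci]] / vel * 1000.0, axis=0)
                    for td in trial_delays
                ])
                sc = _qrs_scores(A, maps, t_qrs, meas, upstroke)
                delays[i] = grid[int(np.argmax(sc))]
                score = max(score, float(sc.max()))
        for f, d in zip(foci, delays):
            f["delay"] = float(d)
            f["correlation"] = score
        tau = np.min(
            fiducials.onset + shift + delays[:, None] + D[[f["vertex"] for f in foci]] / vel * 1000.0,
            axis=0,
        )
    return TimingMap(tau, surface.vertex_areas()), foci


def initial_rep_sinus(
    tau0: TimingMap,
    fiducials: FiducialSet,
    alpha: float = 0.5,
    min_apd: float = 120.0,
    anchor: float | None = None,
) -> TimingMap:
    """Sinus initial repolarization: inversely dependent on activation.

    ``rho0_j = rho_bar - alpha * (tau_j - tau_bar)`` with the mean
    ``rho_bar`` anchored midway between the J-point and the T-end by
    default; passing ``anchor`` overrides it (the pipeline anchors at the
    dominant-T template's own 20% crossing, which tracks the mean
    repolarization time implied by the measured T-wave).  Clipped so every
    node keeps at least ``min_apd`` between activation and repolarization.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    tau = tau0.times
    rho_bar = 0.5 * (fiducials.j_point + fiducials.t_end) if anchor is None else float(anchor)
    rho = rho_bar - alpha * (tau - tau.mean())
    clipped = rho < tau + min_apd
    if clipped.mean() > 0.2:
        warnings.warn(
            f"sinus repolarization estimate clipped at {clipped.mean():.0%} of vertices"
        )
    return TimingMap(np.maximum(rho, tau + min_apd), tau0.areas)


def initial_rep_ectopic(tau0: TimingMap, fiducials: FiducialSet) -> TimingMap:
    """Ectopic initial repolarization: activation delayed by the J-point to
    T-end interval (discordant T-wave)."""
    return TimingMap(tau0.times + fiducials.jt_interval, tau0.areas)
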