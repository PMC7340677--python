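"""Transmembrane-potential template and the linear forward ECG.

The EDL source strength at ventricular-surface node j is the local
transmembrane potential TMP_j(t), parameterized by an activation time tau_j
and a repolarization time rho_j.  Depolarization is a (numerically smoothed)
Heaviside upstroke; the repolarizing limb is the flipped integral of the
dominant T-wave of the measured body-surface ECG, shifted and stretched per
node so that the waveform has lost 80% of its plateau amplitude exactly at
t = rho_j.  Body-surface potentials follow linearly:

    phi_i(t) = sum_j A_ij TMP_j(t)

Deliberately absent from the template: the phase-1 notch (spike-and-dome) of
real action potentials; the gold-standard simulator includes it, so template
mismatch is part of the validation conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volume_conductor import TransferMatrix

__all__ = [
    "BodySurfaceECG",
    "TMPTemplate",
    "TimingMap",
    "rms_curve",
    "dominant_t_wave",
    "build_template",
    "tmp_at",
    "tmp_matrix",
    "forward_ecg",
    "add_noise",
    "read_ecg_csv",
    "write_ecg_csv",
]

#: plateau amplitude of the TMP waveform (mV); the same value is used by the
#: forward simulator and the inverse template so the EDL strength scale cancels
PLATEAU_MV = 100.0

#: upstroke width (ms) of the smoothed Heaviside; the waveform is exactly 0
#: before tau and exactly 1 from tau + UPSTROKE_MS on
UPSTROKE_MS = 2.0


@dataclass
class BodySurfaceECG:
    """Electrode x sample potential matrix (mV) on a uniform time grid (ms)."""

    data: np.ndarray
    dt: float = 1.0
    t0: float = 0.0

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ECG contains non-finite samples")

    @property
    def n_electrodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def time(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_samples)


@dataclass
class TimingMap:
    """Per-vertex activation or repolarization times (ms) with vertex areas."""

    times: np.ndarray
    areas: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.areas is not None:
            self.areas = np.asarray(self.areas, dtype=float)

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class TMPTemplate:
    """Normalized TMP waveform: unit plateau, repolarization limb r(s).

    ``s`` measures time since the local upstroke.  ``r`` is 1 on the plateau
    and decreases monotonically to 0; ``s20`` is the time since upstroke at
    which r crosses 0.2 (an 80% amplitude decrease).  Stretching a node's
    waveform by ``s20 / (rho - tau)`` therefore puts its 0.2-crossing exactly
    at the repolarization time.
    """

    s: np.ndarray
    r: np.ndarray
    s20: float
    amplitude: float = PLATEAU_MV
    upstroke_ms: float = UPSTROKE_MS

    def r_at(self, s) -> np.ndarray:
        return np.interp(s, self.s, self.r, left=1.0, right=0.0)

    def drds_at(self, s) -> np.ndarray:
        dr = np.gradient(self.r, self.s)
        return np.interp(s, self.s, dr, left=0.0, right=0.0)


def rms_curve(ecg: BodySurfaceECG) -> np.ndarray:
    """Root-mean-square over electrodes at each sample."""
    if ecg.n_electrodes < 1 or ecg.n_samples < 1:
        raise ValueError("empty ECG")
    return np.sqrt(np.mean(ecg.data**2, axis=0))


def dominant_t_wave(
    ecg: BodySurfaceECG,
    t_window: tuple[float, float],
    method: str = "svd",
    noise_floor: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Dominant T-wave: one waveform summarizing the common repolarization
    shape of all leads inside ``t_window`` (ms).

    ``method='svd'`` takes the first right singular vector of the windowed
    signal matrix (rank-1 temporal factor); ``method='rms'`` uses the RMS
    curve shape instead.  The sign is fixed so that the running integral of
    the output increases overall (its flipped integral is then
    non-increasing), and the peak is normalized to 1.

    Returns ``(waveform, window_times)``.
    """
    t = ecg.time
    lo, hi = t_window
    mask = (t >= lo) & (t <= hi)
    if mask.sum() < 4:
        raise ValueError("T window does not cover enough samples")
    seg = ecg.data[:, mask]
    if np.sqrt(np.mean(seg**2)) <= noise_floor:
        raise ValueError("no T-wave energy inside the window")
    if method == "svd":
        seg0 = seg - seg.mean(axis=1, keepdims=True)
        _, _, vt = np.linalg.svd(seg0, full_matrices=False)
        w = vt[0]
        # align with the mean-signal polarity, then enforce positive integral
        ref = seg.mean(axis=0)
        if np.dot(w, ref) < 0:
            w = -w
    elif method == "rms":
        w = np.sqrt(np.mean(seg**2, axis=0))
        w = w - w.min()  # remove the noise floor so the integral is shape-driven
    else:
        raise ValueError(f"unknown dominant-T method {method!r}")
    if np.trapezoid(w, t[mask]) < 0:
        w = -w
    w = w / np.abs(w).max()
    return w, t[mask]


def build_template(
    dominant_t: np.ndarray,
    t_dom: np.ndarray,
    t_onset: float,
    amplitude: float = PLATEAU_MV,
    upstroke_ms: float = UPSTROKE_MS,
) -> TMPTemplate:
    """Repolarization template from a dominant T-wave.

    The flipped (reversed-sign cumulative) integral of the dominant T-wave,
    normalized to run from 1 down to 0, forms the repolarizing limb; time is
    referenced to ``t_onset`` (QRS onset, standing in for the mean upstroke)
    so the limb sits after a unit plateau.
    """
    w = np.asarray(dominant_t, dtype=float)
    t_dom = np.asarray(t_dom, dtype=float)
    if not (np.all(np.isfinite(w)) and np.all(np.isfinite(t_dom))):
        raise ValueError("non-finite dominant T-wave input")
    ci = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1]) * np.diff(t_dom))])
    total = ci[-1]
    if total <= 0:
        raise ValueError("dominant T-wave has non-positive integral; fix the sign first")
    r = 1.0 - ci / total
    r = np.clip(r, 0.0, 1.0)
    r = np.minimum.accumulate(r)  # enforce monotone non-increase
    s = t_dom - t_onset
    if s[0] > 0:  # prepend the plateau
        s = np.concatenate([[0.0], s])
        r = np.concatenate([[1.0], r])
    below = np.nonzero(r <= 0.2)[0]
    if len(below) == 0:
        raise ValueError("repolarization limb never reaches the 0.2 level")
    k = below[0]
    if k == 0:
        raise ValueError("repolarization limb starts at or below the 0.2 level")
    # linear interpolation of the first downward 0.2-crossing
    s20 = s[k - 1] + (r[k - 1] - 0.2) / (r[k - 1] - r[k]) * (s[k] - s[k - 1])
    return TMPTemplate(s=s, r=r, s20=float(s20), amplitude=amplitude, upstroke_ms=upstroke_ms)


def _upstroke(u: np.ndarray, width: float) -> np.ndarray:
    """Smoothstep from 0 at u=0 to 1 at u=width (cubic, C1)."""
    x = np.clip(u / width, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def tmp_at(template: TMPTemplate, tau: float, rho: float, t_grid: np.ndarray) -> np.ndarray:
    """TMP waveform of a single node (mV): 0 before tau, plateau after the
    upstroke, and exactly 20% of the plateau at t = rho."""
    if rho <= tau:
        raise ValueError("repolarization time must exceed activation time")
    return tmp_matrix(template, np.array([tau]), np.array([rho]), t_grid)[0]


def tmp_matrix(
    template: TMPTemplate,
    tau: np.ndarray,
    rho: np.ndarray,
    t_grid: np.ndarray,
    derivatives: bool = False,
):
    """Vectorized per-node TMP matrix M (n_nodes x n_samples), optionally with
    analytic partial derivatives with respect to tau_j and rho_j."""
    tau = np.asarray(tau, dtype=float)[:, None]
    rho = np.asarray(rho, dtype=float)[:, None]
    if np.any(rho <= tau):
        raise ValueError("repolarization time must exceed activation time at every node")
    t = np.asarray(t_grid, dtype=float)[None, :]
    u = t - tau
    c = template.s20 / (rho - tau)
    s = c * u
    U = _upstroke(u, template.upstroke_ms)
    r = template.r_at(s)
    M = template.amplitude * U * r
    if not derivatives:
        return M
    rp = template.drds_at(s)
    # ds/dtau = s20 (t - rho) / (rho - tau)^2 ; ds/drho = -s / (rho - tau)
    ds_dtau = template.s20 * (t - rho) / (rho - tau) ** 2
    ds_drho = -s / (rho - tau)
    x = np.clip(u / template.upstroke_ms, 0.0, 1.0)
    dU_dtau = -6.0 * x * (1.0 - x) / template.upstroke_ms
    dM_dtau = template.amplitude * (dU_dtau * r + U * rp * ds_dtau)
    dM_drho = template.amplitude * U * rp * ds_drho
    return M, dM_dtau, dM_drho


def forward_ecg(
    transfer: TransferMatrix | np.ndarray,
    tau: TimingMap | np.ndarray,
    rho: TimingMap | np.ndarray,
    template: TMPTemplate,
    t_grid: np.ndarray,
) -> BodySurfaceECG:
    """Linear forward ECG: phi(t) = A @ TMP(t)."""
    A = transfer.A if isinstance(transfer, TransferMatrix) else np.asarray(transfer)
    tau_v = tau.times if isinstance(tau, TimingMap) else np.asarray(tau, dtype=float)
    rho_v = rho.times if isinstance(rho, TimingMap) else np.asarray(rho, dtype=float)
    if A.shape[1] != len(tau_v) or len(tau_v) != len(rho_v):
        raise ValueError("transfer matrix / timing map dimensions disagree")
    t_grid = np.asarray(t_grid, dtype=float)
    M = tmp_matrix(template, tau_v, rho_v, t_grid)
    dt = float(t_grid[1] - t_grid[0]) if len(t_grid) > 1 else 1.0
    return BodySurfaceECG(A @ M, dt=dt, t0=float(t_grid[0]))


def add_noise(ecg: BodySurfaceECG, sigma_uv: float, seed: int) -> BodySurfaceECG:
    """Additive i.i.d. zero-mean Gaussian noise, sigma given in microvolts."""
    if sigma_uv < 0:
        raise ValueError("noise sigma must be non-negative")
    if sigma_uv == 0:
        return BodySurfaceECG(ecg.data.copy(), dt=ecg.dt, t0=ecg.t0)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma_uv / 1000.0, size=ecg.data.shape)  # uV -> mV
    return BodySurfaceECG(ecg.data + noise, dt=ecg.dt, t0=ecg.t0)


# ---------------------------------------------------------------------------
# delimited-text I/O (rows = samples, columns = electrodes)


def write_ecg_csv(path, ecg: BodySurfaceECG, electrode_ids=None) -> None:
    if electrode_ids is None:
        electrode_ids = [f"e{i:03d}" for i in range(ecg.n_electrodes)]
    df = pd.DataFrame(ecg.data.T, columns=list(electrode_ids))
    df.insert(0, "t_ms", ecg.time)
    df.to_csv(path, index=False)


def read_ecg_csv(path) -> BodySurfaceECG:
    df = pd.read_csv(path)
    t = df["t_ms"].to_numpy()
    data = df.drop(columns=["t_ms"]).to_numpy().T
    dt = float(t[1] - t[0]) if len(t) > 1 else 1.0
    return BodySurfaceECG(data, dt=dt, t0=float(t[0]))
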