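"""Independent gold-standard beat simulator.

Produces "true" activation/repolarization maps and forward body-surface ECGs
against which the inverse method is validated.  The simulator deliberately
differs from the inverse machinery in two ways, guarding against the inverse
crime of validating a method on data produced by the identical model:

* the forward transfer matrix is built on a once-subdivided (4x faces)
  ventricular surface, while the inverse only ever sees the coarse mesh;
* the forward TMP waveform carries a phase-1 notch (spike-and-dome) and a
  logistic repolarization limb, while the inverse template is notch-free and
  derived from the measured dominant T-wave.

Activation spreads from the stimulus sites as surface geodesic distance over
a uniform conduction velocity (a fastest-route stand-in for 3-D monodomain
propagation).  Action-potential duration couples linearly to activation time
(slope > 1 reverses the repolarization sequence, as in sinus rhythm where
early-activated regions repolarize late) plus a smooth spatially correlated
random field.  Gold-standard maps are transferred to the inverse mesh by
nearest-neighbor interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .mesh_geometry import (
    InvalidGeometryError,
    TorsoPhantom,
    TriSurface,
    geodesic_distances,
    is_refinement_of,
    subdivide,
)
from .source_model import PLATEAU_MV, BodySurfaceECG, TimingMap, add_noise
from .volume_conductor import TransferMatrix, assemble_bem, transfer_matrix

__all__ = [
    "BeatSpec",
    "GoldStandardBeat",
    "StimulusSite",
    "beats_catalog",
    "simulate_beat",
    "fine_heart_surface",
    "fine_transfer_matrix",
    "resolve_site",
    "gold_tmp_matrix",
]


@dataclass(frozen=True)
class StimulusSite:
    """Geometric stimulus selector on the ventricular cup.

    ``label`` restricts the candidate vertices (epicardial/endocardial);
    ``azimuth`` (rad) and ``height`` (0 apex .. 1 base) pick the location.
    """

    label: str
    azimuth: float
    height: float
    onset_ms: float = 0.0


@dataclass(frozen=True)
class BeatSpec:
    """Conditions of one simulated beat."""

    name: str
    beat_type: str  # 'sinus' | 'ectopic'
    stimuli: tuple[StimulusSite, ...]
    velocity: float = 0.8  # conduction velocity along the surface, m/s
    apd_base: float = 250.0  # mean action-potential duration, ms
    apd_slope: float = 0.5  # APD decrease per ms of activation delay
    apd_noise_sd: float = 15.0  # SD of the spatial APD field, ms
    apd_noise_corr: float = 0.02  # correlation length of that field, m
    rho_space_constant: float = 0.010  # electrotonic smoothing length of rho, m
    noise_uv: float = 20.0  # body-surface noise SD, microvolts
    stim_time: float = 10.0  # stimulus instant on the recording clock, ms
    duration: float = 500.0  # record length, ms
    dt: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.velocity <= 0:
            raise ValueError("conduction velocity must be positive")
        if self.apd_base <= 0:
            raise ValueError("APD must be positive")


@dataclass
class GoldStandardBeat:
    """Simulated truth: fine-mesh maps, inverse-mesh maps, clean/noisy ECGs."""

    spec: BeatSpec
    heart_fine: TriSurface
    tau_fine: np.ndarray
    rho_fine: np.ndarray
    tau: TimingMap
    rho: TimingMap
    ecg_clean: BodySurfaceECG
    ecg_noisy: BodySurfaceECG
    stimulus_vertices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def with_noise(self, sigma_uv: float, seed: int) -> "GoldStandardBeat":
        """Same beat re-contaminated at a different noise level."""
        return replace(
            self,
            spec=replace(self.spec, noise_uv=sigma_uv, seed=seed),
            ecg_noisy=add_noise(self.ecg_clean, sigma_uv, seed),
        )


# ---------------------------------------------------------------------------
# stimulus-site resolution


def resolve_site(surface: TriSurface, site: StimulusSite) -> int:
    """Vertex index best matching a geometric stimulus selector."""
    if surface.labels is None:
        raise ValueError("stimulus resolution requires vertex labels")
    v = surface.vertices
    center = v.mean(axis=0)
    z_apex, z_base = v[:, 2].min(), v[:, 2].max()
    h = (v[:, 2] - z_apex) / (z_base - z_apex)
    az = np.arctan2(v[:, 1] - center[1], v[:, 0] - center[0])
    daz = np.abs(np.angle(np.exp(1j * (az - site.azimuth))))
    cand = np.nonzero(surface.labels == site.label)[0]
    if len(cand) == 0:
        raise ValueError(f"no vertices labelled {site.label!r}")
    score = (h[cand] - site.height) ** 2 + (0.3 * daz[cand]) ** 2
    return int(cand[np.argmin(score)])


# ---------------------------------------------------------------------------
# beat catalog (the three study conditions)


def beats_catalog() -> list[BeatSpec]:
    """The three study beats: a sinus-like multifocal endocardial beat and two
    single-focus ectopic beats (right-ventricular-base analog and septal
    analog), all at the 20 uV baseline noise level.

    The sinus beat uses an APD-activation slope above one, reproducing the
    concordant-T physiology in which repolarization runs opposite to
    activation; the ectopic beats use a slope below one (discordant T,
    repolarization following activation).
    """
    sinus_sites = (
        StimulusSite("endocardial", 0.0, 0.05, 0.0),
        StimulusSite("endocardial", 0.0, 0.45, 4.0),
        StimulusSite("endocardial", np.pi / 2, 0.45, 8.0),
        StimulusSite("endocardial", np.pi, 0.45, 6.0),
        StimulusSite("endocardial", -np.pi / 2, 0.45, 10.0),
    )
    return [
        BeatSpec(
            name="beat1",
            beat_type="sinus",
            stimuli=sinus_sites,
            apd_slope=2.0,
            apd_noise_sd=25.0,
            apd_noise_corr=0.035,
            seed=101,
        ),
        BeatSpec(
            name="beat2",
            beat_type="ectopic",
            stimuli=(StimulusSite("epicardial", 0.0, 0.85, 0.0),),
            apd_slope=0.5,
            apd_noise_sd=25.0,
            apd_noise_corr=0.03,
            seed=102,
        ),
        BeatSpec(
            name="beat3",
            beat_type="ectopic",
            stimuli=(StimulusSite("endocardial", np.pi, 0.5, 0.0),),
            apd_slope=0.5,
            apd_noise_sd=25.0,
            apd_noise_corr=0.03,
            seed=103,
        ),
    ]


# ---------------------------------------------------------------------------
# gold-standard TMP waveform (notched; not the inverse template)


def gold_tmp_matrix(
    tau: np.ndarray,
    rho: np.ndarray,
    t_grid: np.ndarray,
    amplitude: float = PLATEAU_MV,
) -> np.ndarray:
    """Per-node TMP matrix with upstroke, phase-1 notch and logistic limb.

    The repolarization limb crosses 20% of the plateau exactly at rho.  The
    notch is a 10% amplitude dip of 5 ms duration immediately after the
    upstroke.
    """
    tau = np.asarray(tau, dtype=float)[:, None]
    rho = np.asarray(rho, dtype=float)[:, None]
    apd = rho - tau
    if np.any(apd <= 0):
        raise ValueError("rho must exceed tau everywhere")
    t = np.asarray(t_grid, dtype=float)[None, :]
    s = t - tau
    x = np.clip(s / 1.5, 0.0, 1.0)  # 1.5 ms upstroke
    up = x * x * (3.0 - 2.0 * x)
    notch = 1.0 - 0.1 * np.sin(np.pi * np.clip((s - 1.5) / 5.0, 0.0, 1.0)) ** 2
    k = 0.08 * apd
    s0 = apd - k * np.log(4.0)  # logistic limb pinned to 0.2 at s = apd
    rep = 1.0 / (1.0 + np.exp(np.clip((s - s0) / k, -40.0, 40.0)))
    return amplitude * up * notch * rep


# ---------------------------------------------------------------------------
# correlated APD field


def _kernel_smooth(vertices: np.ndarray, f: np.ndarray, length: float) -> np.ndarray:
    """Gaussian kernel smoothing of a vertex field over euclidean distance
    (mixes the endocardial and epicardial layers across the thin wall)."""
    if length <= 0:
        return f
    d2 = ((vertices[:, None, :] - vertices[None, :, :]) ** 2).sum(axis=2)
    K = np.exp(-0.5 * d2 / length**2)
    return (K @ f) / K.sum(axis=1)


def _transmural_average(surface: TriSurface, f: np.ndarray) -> np.ndarray:
    """Average a vertex field with its nearest opposite-wall counterpart.

    Equalizes endocardial/epicardial values across the thin wall while
    preserving all tangential structure; basal-band vertices keep their own
    value."""
    lab = surface.labels
    out = f.astype(float).copy()
    endo = np.nonzero(lab == "endocardial")[0]
    epi = np.nonzero(lab == "epicardial")[0]
    if len(endo) and len(epi):
        for a, b in ((endo, epi), (epi, endo)):
            _, k = cKDTree(surface.vertices[b]).query(surface.vertices[a])
            out[a] = 0.5 * (f[a] + f[b[k]])
    return out


def _correlated_field(
    vertices: np.ndarray, sd: float, corr_len: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth zero-mean random field with the requested SD, built by Gaussian
    kernel smoothing of vertex white noise."""
    if sd == 0:
        return np.zeros(len(vertices))
    d2 = ((vertices[:, None, :] - vertices[None, :, :]) ** 2).sum(axis=2)
    K = np.exp(-0.5 * d2 / corr_len**2)
    z = K @ rng.standard_normal(len(vertices))
    z -= z.mean()
    s = z.std()
    return z * (sd / s) if s > 0 else z


# ---------------------------------------------------------------------------
# simulation


def fine_heart_surface(phantom: TorsoPhantom) -> TriSurface:
    """Once-subdivided ventricular surface used by the forward model."""
    return subdivide(phantom.heart)


def fine_transfer_matrix(
    phantom: TorsoPhantom,
    heart_fine: TriSurface | None = None,
    preset: str = "A",
) -> tuple[TransferMatrix, TriSurface]:
    """Forward transfer matrix on the refined ventricular surface.

    Shares the torso/lung/blood surfaces and the electrode set with the
    inverse model; only the cardiac discretization differs.
    """
    if heart_fine is None:
        heart_fine = fine_heart_surface(phantom)
    surfaces = dict(phantom.surfaces)
    surfaces["heart"] = heart_fine
    fine = TorsoPhantom(surfaces, dict(phantom.tissue), phantom.electrodes, dict(phantom.config))
    geo = assemble_bem(fine)
    return transfer_matrix(geo, preset), heart_fine


def simulate_beat(
    phantom: TorsoPhantom,
    spec: BeatSpec,
    transfer_fine: TransferMatrix | None = None,
    heart_fine: TriSurface | None = None,
) -> GoldStandardBeat:
    """Simulate one gold-standard beat on the refined ventricular surface.

    ``transfer_fine``/``heart_fine`` may be passed to reuse one forward BEM
    assembly across beats and noise levels; ``heart_fine`` must then be a
    subdivision refinement of the phantom's ventricular surface.
    """
    if heart_fine is None:
        if transfer_fine is not None:
            raise ValueError("heart_fine must accompany a precomputed transfer matrix")
        heart_fine = fine_heart_surface(phantom)
    if not is_refinement_of(heart_fine, phantom.heart):
        raise InvalidGeometryError("forward mesh is not a refinement of the inverse mesh")
    if transfer_fine is None:
        transfer_fine, heart_fine = fine_transfer_matrix(phantom, heart_fine)

    # activation: fastest-route spread from the stimuli
    stim_coarse = np.array(
        [resolve_site(phantom.heart, s) for s in spec.stimuli], dtype=int
    )
    tau_fine = np.full(heart_fine.n_vertices, np.inf)
    for site, v0 in zip(spec.stimuli, stim_coarse):
        # coarse vertex ids remain valid on the refined mesh; wall-crossing
        # links make the spread behave like 3-D myocardial propagation
        d = geodesic_distances(heart_fine, [int(v0)], transmural=True)
        tau_fine = np.minimum(tau_fine, site.onset_ms + d / spec.velocity * 1000.0)
    tau_fine += spec.stim_time

    # repolarization: linear APD-activation coupling + smooth spatial field.
    # APD couples to the transmurally averaged activation time: regional
    # (cm-scale) heterogeneity drives APD, while electrotonic coupling
    # equalizes it across the thin wall, so the millisecond-scale transmural
    # activation delay does not imprint an APD gradient.
    rng = np.random.default_rng(spec.seed)
    tau_ref = _transmural_average(heart_fine, tau_fine)
    field = _correlated_field(heart_fine.vertices, spec.apd_noise_sd, spec.apd_noise_corr, rng)
    # decorrelate the sampled field from the activation reference so the
    # configured slope is the realized coupling (a single long-wavelength
    # draw can otherwise align with activation by chance and cancel it)
    tc = tau_ref - tau_ref.mean()
    if tc.std() > 0 and field.std() > 0:
        field = field - (field @ tc) / (tc @ tc) * tc
        field *= spec.apd_noise_sd / field.std()
    apd = (
        spec.apd_base
        - spec.apd_slope * (tau_ref - tau_ref.mean())
        + field
    )
    apd = np.maximum(apd, 80.0)  # physiological floor
    rho_fine = tau_fine + apd
    # electrotonic coupling makes repolarization spatially low-pass: smooth
    # the repolarization field over ~1 cm so it carries the low spatial
    # frequencies of real repolarization rather than the activation
    # wavefront's ridge structure
    rho_fine = _kernel_smooth(heart_fine.vertices, rho_fine, spec.rho_space_constant)
    rho_fine = np.maximum(rho_fine, tau_fine + 60.0)

    t_grid = np.arange(0.0, spec.duration, spec.dt)
    M = gold_tmp_matrix(tau_fine, rho_fine, t_grid)
    clean = BodySurfaceECG(transfer_fine.A @ M, dt=spec.dt, t0=0.0)
    noisy = add_noise(clean, spec.noise_uv, spec.seed + 7919)

    # nearest-neighbor transfer of the maps to the inverse mesh
    tree = cKDTree(heart_fine.vertices)
    _, nn = tree.query(phantom.heart.vertices)
    areas = phantom.heart.vertex_areas()
    tau_c = TimingMap(tau_fine[nn], areas)
    rho_c = TimingMap(rho_fine[nn], areas)
    return GoldStandardBeat(
        spec=spec,
        heart_fine=heart_fine,
        tau_fine=tau_fine,
        rho_fine=rho_fine,
        tau=tau_c,
        rho=rho_c,
        ecg_clean=clean,
        ecg_noisy=noisy,
        stimulus_vertices=stim_coarse,
    )
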