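"""Accuracy metrics and the robustness study runner.

Metrics follow the validation conventions of EDL inverse studies: RMSE,
Pearson correlation and the interquartile range of absolute differences
between true and reconstructed timing maps; relative difference (RD,
Frobenius-norm ratio) and correlation between measured and reconstructed
ECGs; signal-to-noise ratio in dB.

``run_study`` sweeps the study design: every beat against the five
conductivity presets at baseline noise, and every beat against the four
noise levels with the matched preset — emitting one report row per case.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .gold_standard import GoldStandardBeat, beats_catalog, fine_transfer_matrix, simulate_beat
from .inverse_solver import InverseResult, RegularizationConfig, SolverOptions
from .mesh_geometry import make_torso_phantom
from .pipeline import InverseContext, invert_beat
from .source_model import BodySurfaceECG, TimingMap
from .volume_conductor import assemble_bem, transfer_matrix

__all__ = ["metrics", "rd", "snr_db", "run_study", "REPORT_COLUMNS"]

log = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "beat", "beat_type", "study", "preset", "noise_uv",
    "lam_rep", "rmse_ms", "iqr_lo_ms", "iqr_hi_ms",
    "cor_rep_pattern", "cor_ecg", "rd_ecg", "snr_db",
    "rmse_endo_ms", "rmse_epi_ms", "lam_dep", "reg_dep", "reg_rep",
    "cor_act_pattern", "status",
]


def metrics(truth: TimingMap | np.ndarray, estimate: TimingMap | np.ndarray):
    """RMSE (ms), Pearson correlation, and IQR of absolute differences (ms).

    The correlation is undefined (returned as NaN) for a constant estimate.
    """
    t = truth.times if isinstance(truth, TimingMap) else np.asarray(truth, dtype=float)
    e = estimate.times if isinstance(estimate, TimingMap) else np.asarray(estimate, dtype=float)
    if t.shape != e.shape:
        raise ValueError("timing maps must share the vertex set")
    diff = e - t
    rmse = float(np.sqrt(np.mean(diff**2)))
    tc, ec = t - t.mean(), e - e.mean()
    nt, ne = np.linalg.norm(tc), np.linalg.norm(ec)
    cor = float(tc @ ec / (nt * ne)) if nt > 0 and ne > 0 else float("nan")
    q25, q75 = np.percentile(np.abs(diff), [25.0, 75.0])
    return rmse, cor, (float(q25), float(q75))


def rd(ecg_a: BodySurfaceECG | np.ndarray, ecg_b: BodySurfaceECG | np.ndarray) -> float:
    """Relative difference: ||a - b||_F / ||a||_F."""
    a = ecg_a.data if isinstance(ecg_a, BodySurfaceECG) else np.asarray(ecg_a, dtype=float)
    b = ecg_b.data if isinstance(ecg_b, BodySurfaceECG) else np.asarray(ecg_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("ECG shapes disagree")
    na = np.linalg.norm(a)
    if na == 0:
        raise ValueError("zero reference ECG")
    return float(np.linalg.norm(a - b) / na)


def snr_db(clean: BodySurfaceECG | np.ndarray, noisy: BodySurfaceECG | np.ndarray) -> float:
    """Signal-to-noise ratio 10*log10(||clean||^2 / ||noisy - clean||^2) in dB.

    NaN when the two records are identical (infinite SNR)."""
    c = clean.data if isinstance(clean, BodySurfaceECG) else np.asarray(clean, dtype=float)
    n = noisy.data if isinstance(noisy, BodySurfaceECG) else np.asarray(noisy, dtype=float)
    if c.shape != n.shape:
        raise ValueError("ECG shapes disagree")
    p_noise = float(np.sum((n - c) ** 2))
    if p_noise == 0:
        return float("nan")
    return float(10.0 * np.log10(np.sum(c**2) / p_noise))


def _row(
    beat: GoldStandardBeat,
    study: str,
    preset: str,
    noise_uv: float,
    res: InverseResult | None,
    labels,
    status: str = "ok",
) -> dict:
    row = dict.fromkeys(REPORT_COLUMNS, np.nan)
    row.update(beat=beat.spec.name, beat_type=beat.spec.beat_type, study=study,
               preset=preset, noise_uv=noise_uv, status=status)
    row["snr_db"] = snr_db(beat.ecg_clean, beat.ecg_noisy)
    if res is None:
        return row
    rmse, cor, iqr = metrics(beat.rho, res.rho)
    _, cor_act, _ = metrics(beat.tau, res.tau)
    row.update(
        lam_rep=res.lam_rep, lam_dep=res.lam_dep,
        rmse_ms=rmse, iqr_lo_ms=iqr[0], iqr_hi_ms=iqr[1],
        cor_rep_pattern=cor, cor_act_pattern=cor_act,
        cor_ecg=res.cor_ecg, rd_ecg=res.rd_ecg,
        reg_dep=res.reg_dep, reg_rep=res.reg_rep,
    )
    if labels is not None:
        for cls, col in (("endocardial", "rmse_endo_ms"), ("epicardial", "rmse_epi_ms")):
            m = labels == cls
            if m.any():
                row[col] = float(
                    np.sqrt(np.mean((res.rho.times[m] - beat.rho.times[m]) ** 2))
                )
    return row


def run_study(config: dict | None = None, out_dir=None) -> pd.DataFrame:
    """Run the conductivity and noise robustness study and return the report.

    Config keys (all optional): ``phantom`` (phantom config mapping),
    ``beats`` (names from the catalog), ``presets``, ``noise_levels_uv``,
    ``baseline_noise_uv``, ``seed``, ``solver`` (SolverOptions fields),
    ``reg`` (RegularizationConfig fields).  Deterministic under fixed seeds;
    failed rows are flagged and the study continues.
    """
    cfg = config or {}
    seed = int(cfg.get("seed", 0))
    phantom = make_torso_phantom(cfg.get("phantom"))
    presets = list(cfg.get("presets", ["A", "A1", "A2", "A3", "A4"]))
    noise_levels = list(cfg.get("noise_levels_uv", [20.0, 40.0, 60.0, 80.0]))
    baseline = float(cfg.get("baseline_noise_uv", 20.0))
    wanted = cfg.get("beats")
    specs = [b for b in beats_catalog() if wanted is None or b.name in wanted]
    opts = SolverOptions(**cfg.get("solver", {}))
    reg_cfg = RegularizationConfig(**cfg.get("reg", {}))
    select_lambdas = bool(cfg.get("select_lambdas", True))

    log.info("assembling BEM systems")
    tm_fine, heart_fine = fine_transfer_matrix(phantom)
    geo = assemble_bem(phantom)
    transfers = {p: transfer_matrix(geo, p) for p in presets}
    ctx = InverseContext.build(phantom.heart)
    labels = phantom.heart.labels

    rows = []
    results: dict[tuple, InverseResult] = {}

    def invert(beat: GoldStandardBeat, preset: str):
        return invert_beat(
            ctx, transfers[preset], beat.ecg_noisy,
            mode="sinus" if beat.spec.beat_type == "sinus" else "ectopic",
            reg_cfg=reg_cfg, options=opts, select_lambdas=select_lambdas,
        )

    for k, spec in enumerate(specs):
        from dataclasses import replace

        spec = replace(spec, seed=(seed * 1009 + spec.seed) % (2**31), noise_uv=baseline)
        beat = simulate_beat(phantom, spec, transfer_fine=tm_fine, heart_fine=heart_fine)
        # (i) conductivity sub-study at baseline noise
        for preset in presets:
            log.info("beat %s / preset %s", spec.name, preset)
            try:
                res = invert(beat, preset)
                results[(spec.name, preset, baseline)] = res
                rows.append(_row(beat, "conductivity", preset, baseline, res, labels))
            except Exception as exc:  # noqa: BLE001 - study must continue
                log.warning("row failed: %s", exc)
                rows.append(_row(beat, "conductivity", preset, baseline, None, labels, status=f"failed: {exc}"))
        # (ii) noise sub-study with the matched preset
        for sigma in noise_levels:
            key = (spec.name, presets[0], sigma)
            if sigma == baseline and key in results:
                rows.append(_row(beat, "noise", presets[0], sigma, results[key], labels))
                continue
            log.info("beat %s / noise %g uV", spec.name, sigma)
            nb = beat.with_noise(sigma, (seed * 1013 + spec.seed + int(sigma)) % (2**31))
            try:
                res = invert(nb, presets[0])
                rows.append(_row(nb, "noise", presets[0], sigma, res, labels))
            except Exception as exc:  # noqa: BLE001
                log.warning("row failed: %s", exc)
                rows.append(_row(nb, "noise", presets[0], sigma, None, labels, status=f"failed: {exc}"))

    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "report.csv", index=False)
        with open(out / "study_config.json", "w") as fh:
            json.dump({"seed": seed, "presets": presets, "noise_levels_uv": noise_levels}, fh, indent=1)
    return report
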