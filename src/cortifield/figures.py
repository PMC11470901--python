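"""Deterministic regeneration of the package's illustrative figures.

Each figure has a shipped YAML configuration under ``cortifield/configs``;
``reproduce_figure`` regenerates the figure's data files (CSV, carrying the
config hash in a header comment) and a rendered PNG.  Grid sizes and
coefficient values in the shipped configs are illustrative choices matching
the qualitative features of the phenomena, except where a quantity is
pinned (the power-spectrum configuration fixes the -2/-4 slope bands and
the 100 Hz crossover through the units map: 1 model frequency unit = 1 Hz
at wave speed c = 10 mm/s).
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = ["load_config", "config_hash", "reproduce_figure", "FIGURES"]

FIGURES = ("fig2", "fig3", "fig4", "fig5", "fig6")


def load_config(name: str) -> dict:
    """Load a shipped YAML config by bare name (e.g. 'fig2')."""
    ref = resources.files("cortifield") / "configs" / f"{name}.yaml"
    return yaml.safe_load(ref.read_text())


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]


def _write_csv(path: Path, header_cols, rows, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_sha256={cfg_hash}\n")
        fh.write(",".join(header_cols) + "\n")
        for row in rows:
            fh.write(",".join(f"{v:.12g}" for v in row) + "\n")


def _spectrum_data(cfg: dict):
    from cortifield.dynamics import QuarticParams
    from cortifield.spectra import (
        gradient_transition_frequency,
        loglog_slope,
        power_spectrum_frequency,
    )

    params = QuarticParams(c0=cfg["c0"], a2=cfg["a2"], a3=cfg["a3"])
    f = np.logspace(np.log10(cfg["f_min"]), np.log10(cfg["f_max"]),
                    cfg["n_samples"])
    spec = power_spectrum_frequency(f, params, c=cfg["c"],
                                    hz_per_unit=cfg.get("hz_per_unit", 1.0))
    logf, logP = np.log(spec.f), np.log(spec.P)
    local = np.gradient(logP, logf)
    slopes = {
        "low": loglog_slope(spec, *cfg["low_band"]),
        "high": loglog_slope(spec, *cfg["high_band"]),
    }
    f_star = gradient_transition_frequency(params, cfg["c"],
                                           cfg.get("hz_per_unit", 1.0))
    return spec, local, slopes, f_star


def _fig2(cfg: dict, outdir: Path, h: str) -> list:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    spec, local, slopes, f_star = _spectrum_data(cfg)
    csv = outdir / "fig2_spectrum.csv"
    _write_csv(csv, ["f", "P", "local_slope"],
               zip(spec.f, spec.P, local), h)
    meta = outdir / "fig2_summary.json"
    meta.write_text(json.dumps({
        "config_sha256": h,
        "low_band_slope": slopes["low"],
        "high_band_slope": slopes["high"],
        "transition_frequency_hz": f_star,
    }, indent=2, sort_keys=True) + "\n")

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.loglog(spec.f, spec.P, lw=1.5)
    ax.axvline(f_star, ls="--", color="grey")
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("power")
    ax.set_title(f"slopes {slopes['low']:.2f} / {slopes['high']:.2f}, "
                 f"crossover {f_star:.0f} Hz")
    fig.tight_layout()
    fig.savefig(outdir / "fig2.png", dpi=120)
    plt.close(fig)
    return [csv, meta, outdir / "fig2.png"]


def _fig3(cfg: dict, outdir: Path, h: str) -> list:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from cortifield.dynamics import LimitCycleParams
    from cortifield.fixtures import RunConfig
    from cortifield.grid_fields import GridSpec
    from cortifield.limit_cycle import (
        Harmonic,
        build_phase_solution,
        render_phase_field,
    )

    g = cfg["grid"]
    grid = GridSpec(nx=g["nx"], ny=g["ny"], dx=g["dx"], dy=g["dy"],
                    boundary=g.get("boundary", "periodic"))
    params = LimitCycleParams(c1=cfg["c1"], c2=cfg.get("c2", -1.0),
                              c3=cfg.get("c3", 1.0))
    files = []
    fig, axes = plt.subplots(1, len(cfg["panels"]), figsize=(4 * len(cfg["panels"]), 4))
    for ax, panel in zip(np.atleast_1d(axes), cfg["panels"]):
        harmonics = [
            Harmonic(A0=hm["A0"],
                     omega=float(np.sqrt(cfg["c1"]) * np.hypot(*hm["k"])),
                     kx=hm["k"][0], ky=hm["k"][1])
            for hm in panel.get("harmonics", [])
        ]
        sol = build_phase_solution(panel["b2"], panel["b3"], harmonics, params)
        state = render_phase_field(sol, grid, t=cfg.get("t", 0.0))
        csv = outdir / f"fig3_{panel['name']}_activity.csv"
        _write_csv(csv, [f"col{j}" for j in range(grid.ny)],
                   state.phi.real, h)
        files.append(csv)
        im = ax.imshow(state.phi.real.T, origin="lower", cmap="RdBu_r")
        ax.set_title(panel["name"])
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    png = outdir / "fig3.png"
    fig.savefig(png, dpi=120)
    plt.close(fig)
    files.append(png)
    return files


def _fig4(cfg: dict, outdir: Path, h: str) -> list:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from cortifield.fronts import FrontParams, LogisticRamp, seizure_onset_waveform

    ramp = LogisticRamp(**cfg["ramp"])
    fp = FrontParams(a2=cfg.get("a2", 1.0), phi_l=cfg.get("phi_l", 1.0),
                     k_m=cfg["k_m"], a0=cfg["a0"], r0=cfg["r0"], ramp=ramp)
    times = np.linspace(0.0, cfg["t_max"], cfg["n_samples"])
    from cortifield.fronts import DEFAULT_WAVE_SPEED, phase_relaxation_closed_form

    theta = phase_relaxation_closed_form(cfg.get("x_obs", 0.0), times, fp.k_m)
    wave = seizure_onset_waveform(
        times, fp, theta_fn=lambda t: phase_relaxation_closed_form(
            cfg.get("x_obs", 0.0), t, fp.k_m))
    csv = outdir / "fig4_onset.csv"
    _write_csv(csv, ["t", "re_phi", "abs_phi", "theta"],
               zip(times, wave.real, np.abs(wave), theta), h)
    fig, ax = plt.subplots(figsize=(7, 3))
    ax.plot(times, wave.real, lw=0.8)
    ax.set_xlabel("time (model units)")
    ax.set_ylabel("Re phi")
    ax.set_title("onset: fast low-amplitude transient, then slow high-amplitude rhythm")
    fig.tight_layout()
    png = outdir / "fig4.png"
    fig.savefig(png, dpi=120)
    plt.close(fig)
    return [csv, png]


def _fig_patterns(cfg: dict, outdir: Path, h: str, tag: str) -> list:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from cortifield.fixtures import make_plane_wave
    from cortifield.grid_fields import GridSpec
    from cortifield.tessellation import (
        TessellationSpec,
        build_g_distance,
        build_g_nearest_neighbour,
        diagonalize,
        render_pattern,
    )

    g = cfg["tile_grid"]
    tile_grid = GridSpec(nx=g["nx"], ny=g["ny"], dx=g["dx"], dy=g["dy"],
                         boundary=g.get("boundary", "periodic"))
    spec = TessellationSpec(cfg["tiling"]["P"], cfg["tiling"]["Q"], tile_grid)
    kind = cfg["connectivity"]
    if kind == "nn":
        G = build_g_nearest_neighbour(spec, cfg.get("strength", 1.0))
    elif kind in ("dist1", "dist2"):
        G = build_g_distance(spec, cfg.get("strength", 1.0),
                             exponent=int(kind[-1]))
    else:
        raise ValueError(f"unknown connectivity {kind!r}")
    pset = diagonalize(G)
    base = make_plane_wave(tile_grid, 1.0, tuple(cfg["base"]["k"]))
    indices = cfg["indices"]
    files = []
    fig, axes = plt.subplots(1, len(indices), figsize=(4 * len(indices), 4))
    for ax, idx in zip(np.atleast_1d(axes), indices):
        factors = pset.pattern(idx).reshape(spec.n_tiles_x, spec.n_tiles_y)
        csv = outdir / f"{tag}_pattern{idx}_factors.csv"
        _write_csv(csv, [f"col{j}" for j in range(spec.n_tiles_y)], factors, h)
        files.append(csv)
        sheet = render_pattern(pset, idx, spec, base)
        im = ax.imshow(sheet.phi.real.T, origin="lower", cmap="RdBu_r")
        ax.set_title(f"pattern {idx} (D={pset.D[idx]:.3f})")
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    png = outdir / f"{tag}.png"
    fig.savefig(png, dpi=120)
    plt.close(fig)
    files.append(png)
    return files


def reproduce_figure(which: str, outdir) -> list:
    """Regenerate one figure's data (CSV/JSON, config-hashed) and PNG.

    Deterministic: repeated invocation writes byte-identical data files.
    """
    if which not in FIGURES:
        raise ValueError(f"unknown figure {which!r}; choose from {FIGURES}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = load_config(which)
    h = config_hash(cfg)
    if which == "fig2":
        return _fig2(cfg, outdir, h)
    if which == "fig3":
        return _fig3(cfg, outdir, h)
    if which == "fig4":
        return _fig4(cfg, outdir, h)
    return _fig_patterns(cfg, outdir, h, which)
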