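"""Scenario configuration, runners, fixtures, and standard outputs.

A scenario is a named, fully configured experiment:

* ``calibrate`` — build the requested variants, write the calibration log.
* ``pes_cell`` / ``pes_cable`` — S1–S4 PES per variant, tidy CSV output.
* ``table1`` — 2-D PES for HF and the eight HF+AM centres across sheet
  sizes; ``table2`` — HF, HF+DS, and the eight HF+AM′ centres at one size.
  At full scale (16–24 cm sheets, 2-s horizon) these are long-running
  experiments; the ``reduced`` scenario runs the same pipelines on the
  desk-scale geometry (see :data:`REDUCED_SHEET`).
* ``reduced`` — the reduced-geometry reentry-induction comparison.

Every run writes a provenance block (config echo + package version), and
the whole pipeline is deterministic: there is no random number generator
anywhere in the package.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, classify, pes, tissue, variants
from .params import ModelParams

#: Desk-scale 2-D geometry: the same pyramidic gradient construction on a
#: small sheet.  The coarser grid requires a somewhat larger diffusion
#: coefficient so the depolarization front stays resolved (front width
#: ~ D/CV must exceed dx); at this scale premature-beat conduction block
#: and wave break are reproduced, while sustained rotation remains a
#: full-scale phenomenon.  See docs/methods.md.
REDUCED_SHEET = dict(length=6.0, dx=0.04, dt=0.02, diffusion=1.5e-3,
                     stim_size=0.16)
REDUCED_HORIZON = 1200.0
REDUCED_N_S1 = 4

FULL_SIZES = {"small": 16.0, "medium": 20.0, "large": 24.0}


class ConfigError(ValueError):
    pass


@dataclass
class ScenarioConfig:
    """Validated configuration of one scenario run."""

    scenario: str
    variants: list[str] = field(default_factory=lambda: ["control"])
    out_dir: str = "runs"
    bcl: float = 400.0
    n_s1: int = 8
    erp_increment: float | None = None
    length: float | None = None
    dx: float | None = None
    dt: float | None = None
    diffusion: float | None = None
    horizon: float = 2000.0
    snapshot_ms: float = 0.0

    _SCENARIOS = ("calibrate", "pes_cell", "pes_cable", "table1", "table2",
                  "reduced")

    def __post_init__(self):
        if self.scenario not in self._SCENARIOS:
            raise ConfigError(
                f"scenario: unknown value '{self.scenario}' "
                f"(choose from {', '.join(self._SCENARIOS)})")
        reg = variants.VariantRegistry()
        known = set(reg.labels())
        for v in self.variants:
            if v.lower() not in known:
                raise ConfigError(f"variants: unknown variant label '{v}'")
        for key in ("bcl", "n_s1", "horizon"):
            if getattr(self, key) is not None and getattr(self, key) <= 0:
                raise ConfigError(f"{key}: must be positive")
        # numeric-stability guards for explicit integration
        if self.dt is not None and self.dx is not None:
            diff = self.diffusion if self.diffusion is not None else 0.001
            if diff * self.dt / (self.dx ** 2) > 0.25:
                raise ConfigError(
                    "dt/dx/diffusion: violates the explicit-Euler "
                    "stability bound D*dt/dx^2 <= 0.25")
        if self.dt is not None and self.dt > 0.05:
            raise ConfigError("dt: larger than 0.05 ms is not supported")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _provenance(cfg: ScenarioConfig) -> dict:
    return dict(package="cardiopes", version=__version__,
                config=cfg.to_dict(), config_digest=cfg.digest())


def _write_provenance(out: Path, cfg: ScenarioConfig):
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "provenance.json", "w") as fh:
        json.dump(_provenance(cfg), fh, indent=2)


def save_snapshot(path: Path, frames: np.ndarray, frame_times: np.ndarray,
                  dx: float):
    """Field snapshots: a flat binary array with a JSON sidecar."""
    np.save(str(path) + ".npy", frames)
    with open(str(path) + ".json", "w") as fh:
        json.dump(dict(shape=list(frames.shape), dtype=str(frames.dtype),
                       dx=dx, times_ms=[float(t) for t in frame_times]), fh)


def run_scenario(cfg: ScenarioConfig, registry=None) -> dict:
    """Execute a scenario, write its artifacts, and return a summary."""
    out = Path(cfg.out_dir) / f"{cfg.scenario}-{cfg.digest()}"
    _write_provenance(out, cfg)
    reg = registry or variants.VariantRegistry()
    log_lines = []
    summary: dict = {"scenario": cfg.scenario, "out_dir": str(out)}

    if cfg.scenario == "calibrate":
        rows = []
        for label in cfg.variants:
            p = reg.get(label)
            rows.append(dict(variant=label, **{
                k: getattr(p, k) for k in ("g_na", "g_cal", "g_kr", "g_ks",
                                           "g_k1", "g_to", "eh_shift",
                                           "tauh_scale")}))
            log_lines.append(f"{label}: calibrated")
        df = pd.DataFrame(rows)
        df.to_csv(out / "variants.csv", index=False)
        summary["variants"] = rows

    elif cfg.scenario in ("pes_cell", "pes_cable"):
        proto = pes.ProtocolSpec(bcl=cfg.bcl, n_s1=cfg.n_s1,
                                 erp_increment=cfg.erp_increment or 1.0)
        frames = []
        for label in cfg.variants:
            p = reg.get(label)
            if cfg.scenario == "pes_cell":
                res = pes.run_pes_cell(p, proto)
            else:
                spec = pes.CableSpec(length=cfg.length or 5.0,
                                     dx=cfg.dx or 0.01,
                                     diffusion=cfg.diffusion or 0.001,
                                     dt=cfg.dt or 0.001)
                res = pes.run_pes_cable(p, proto, spec)
            frames.append(res.to_frame())
            log_lines.append(
                f"{label}: mean PRR {res.mean_prr:.2f} ms, "
                f"DI_min {res.di_min:.2f} ms")
        df = pd.concat(frames, ignore_index=True)
        df.to_csv(out / "pes.csv", index=False)
        summary["n_rows"] = len(df)

    elif cfg.scenario in ("table1", "table2", "reduced"):
        if cfg.scenario == "table1":
            centers = ["hf"] + [f"hf+am{i}" for i in range(1, 9)]
            sizes = dict(FULL_SIZES)
            geo = dict(dx=0.02, dt=0.01, diffusion=0.001)
            horizon, n_s1 = cfg.horizon, cfg.n_s1
        elif cfg.scenario == "table2":
            centers = (["hf", "hf+ds"] + [f"hf+am{i}p" for i in range(1, 9)])
            sizes = {"medium": FULL_SIZES["medium"]}
            geo = dict(dx=0.02, dt=0.01, diffusion=0.001)
            horizon, n_s1 = cfg.horizon, cfg.n_s1
        else:
            centers = cfg.variants if cfg.variants != ["control"] else ["hf"]
            sizes = {"reduced": cfg.length or REDUCED_SHEET["length"]}
            geo = dict(dx=cfg.dx or REDUCED_SHEET["dx"],
                       dt=cfg.dt or REDUCED_SHEET["dt"],
                       diffusion=cfg.diffusion or REDUCED_SHEET["diffusion"],
                       stim_size=REDUCED_SHEET["stim_size"])
            horizon = min(cfg.horizon, REDUCED_HORIZON)
            n_s1 = min(cfg.n_s1, REDUCED_N_S1)
        rows = []
        for size_name, L in sizes.items():
            for center in centers:
                row = run_sheet_case(reg, center, L, geo, n_s1=n_s1,
                                     horizon=horizon,
                                     snapshot_dir=(out if cfg.snapshot_ms > 0
                                                   else None),
                                     snapshot_ms=cfg.snapshot_ms)
                row["size"] = size_name
                rows.append(row)
                log_lines.append(f"{center} @ {size_name}: {row['label']}")
        df = pd.DataFrame(rows)
        df.to_csv(out / "outcomes.csv", index=False)
        summary["outcomes"] = rows

    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return summary


def run_sheet_case(reg, center_label: str, length: float, geo: dict,
                   n_s1: int = 8, horizon: float = 2000.0,
                   snapshot_dir: Path | None = None,
                   snapshot_ms: float = 0.0) -> dict:
    """One 2-D PES + classification case (corner = drug-free control)."""
    corner = reg.get("control")
    center = reg.get(center_label)
    spec = tissue.GradientSheetSpec(corner_params=corner,
                                    center_params=center,
                                    length=length, **geo)
    fld = tissue.build_gradient_sheet(spec)
    proto = pes.ProtocolSpec(erp_increment=5.0, n_s1=n_s1)
    run = tissue.run_pes_2d(fld, proto, horizon=horizon)
    outcome = classify.classify(run)
    grad = tissue.measure_apd_gradient(run)
    if snapshot_dir is not None and snapshot_ms > 0:
        keep = slice(None, None,
                     max(1, int(round(snapshot_ms /
                                      np.median(np.diff(run.frame_times))))))
        save_snapshot(snapshot_dir / f"frames-{center_label}-{length:g}cm",
                      run.frames[keep], run.frame_times[keep], spec.dx)
    return dict(center=center_label, length=length,
                gradient_ms_per_cm=round(grad, 2),
                erps=",".join(f"{e:.0f}" for e in run.erps),
                label=outcome.label, wave_break=outcome.wave_break,
                sustained=outcome.sustained_2s,
                extra_beats=outcome.n_extra_beats)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

def make_fixture(kind: str) -> tuple[dict, dict]:
    """Reduced, fast configurations plus the property manifest the test
    suite checks against them.

    Kinds: ``uniform_sheet``, ``gradient_sheet_small``, ``spiral_synthetic``,
    ``cable_short``.
    """
    if kind == "uniform_sheet":
        cfg = dict(length=1.6, dx=0.04, dt=0.02, diffusion=1.5e-4)
        manifest = dict(expect="spatially uniform evolution",
                        extra_beats=0)
        return cfg, manifest
    if kind == "gradient_sheet_small":
        cfg = dict(**REDUCED_SHEET, horizon=REDUCED_HORIZON,
                   n_s1=REDUCED_N_S1)
        manifest = dict(expect="HF centre more inducible than HF+AM centre")
        return cfg, manifest
    if kind == "spiral_synthetic":
        cfg = dict(ny=60, nx=60, period_ms=150.0, amp=30.0, vstar=-55.0,
                   wavelength_nodes=40.0, duration_ms=600.0, frame_ms=4.0)
        manifest = dict(n_singularities=1,
                        rotations=cfg["duration_ms"] / cfg["period_ms"])
        return cfg, manifest
    if kind == "cable_short":
        cfg = dict(length=2.5, dx=0.01, diffusion=0.001, dt=0.001)
        manifest = dict(expect="finite positive CV")
        return cfg, manifest
    raise ConfigError(f"unknown fixture kind '{kind}'")


def synthetic_spiral(cfg: dict) -> tuple[np.ndarray, np.ndarray]:
    """A prescribed rigidly rotating spiral voltage field (ground truth for
    the classifier): V = V* + A·cos(θ + 2πr/λ − ωt)."""
    ny, nx = cfg["ny"], cfg["nx"]
    y, x = np.mgrid[0:ny, 0:nx]
    th = np.arctan2(y - ny / 2 + 0.5, x - nx / 2 + 0.5)
    r = np.hypot(y - ny / 2 + 0.5, x - nx / 2 + 0.5)
    times = np.arange(0.0, cfg["duration_ms"], cfg["frame_ms"])
    om = 2.0 * np.pi / cfg["period_ms"]
    frames = (cfg["vstar"] + cfg["amp"] *
              np.cos(th + 2.0 * np.pi * r / cfg["wavelength_nodes"]
                     - om * times[:, None, None])).astype(np.float32)
    return frames, times
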