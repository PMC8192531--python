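"""Structured run configuration, pipeline driver and result IO.

A single YAML config drives any combination of stages (KMC mixture
sweep, fixed-K_eq k_off sweep, rheology curves, morphometrics on
generated phantoms).  Keys carry their units explicitly (``force_pN``,
``t_window_s``) because unit mistakes are the dominant failure mode in
this parameter space; unknown keys are rejected with their path.
Re-running an unchanged config reproduces every stochastic output
bit-for-bit.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .gate import DiffusionModel, GateGeometry, MixtureSpec
from .kinetics import BUILTIN_PAIRS, HostGuestPair, validate_detailed_balance
from .kmc import sweep_koff_fixed_Keq, sweep_mixtures
from .morphometrics import circularity, multicellularity, nuclear_cyto_ratio
from .rheology import dynamic_moduli, half_relaxation_time, relaxation_modulus, spectrum_from_mixture
from .synthetic import PhantomSpec, gen_masks, gen_two_channel_image

__all__ = ["RunConfig", "run_config", "write_results", "read_results", "ResultsError"]

log = logging.getLogger("gatekmc")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PairConfig(_Strict):
    k_on_per_M_s: float
    k_off0_per_s: float
    x_dagger_nm: float = 0.01
    temperature_K: float = 310.0
    measured_Keq_per_M: float | None = None

    def build(self, name: str) -> HostGuestPair:
        pair = HostGuestPair(
            name=name,
            k_on=self.k_on_per_M_s,
            k_off0=self.k_off0_per_s,
            x_dagger=self.x_dagger_nm,
            temperature=self.temperature_K,
        )
        if self.measured_Keq_per_M is not None:
            validate_detailed_balance(pair, self.measured_Keq_per_M)
        return pair


class DiffusionConfig(_Strict):
    D0_nm2_s: float = 1e6
    alpha_per_pN: float = 0.01


class GeometryConfig(_Strict):
    n_units: int = 4
    valency: int = 2
    capture_distance_nm: float = 1.0
    local_host_concentration_M: float = 0.01
    diffusion: DiffusionConfig = Field(default_factory=DiffusionConfig)
    correlated_units: bool = False

    def build(self) -> GateGeometry:
        return GateGeometry(
            n_units=self.n_units,
            valency=self.valency,
            capture_distance=self.capture_distance_nm,
            local_host_concentration=self.local_host_concentration_M,
            diffusion=DiffusionModel(self.diffusion.D0_nm2_s, self.diffusion.alpha_per_pN),
            correlated_units=self.correlated_units,
        )


class KMCConfig(_Strict):
    mixtures: list[str | float] = Field(default_factory=lambda: ["A80C20", "A50C50", "A20C80"])
    force_pN: float = 10.0
    t_window_s: float = 0.01
    n_replicates: int = 100_000
    t_max_s: float | None = None


class KoffSweepConfig(_Strict):
    k_off_per_s: list[float]
    K_eq_per_M: float = 1e5
    force_pN: float = 10.0
    t_window_s: float = 0.01
    n_replicates: int = 10_000


class RheologyConfig(_Strict):
    mixtures: list[str | float] = Field(default_factory=lambda: ["A80C20", "A50C50", "A20C80"])
    total_modulus_Pa: float = 1000.0
    plateau_Pa: float = 0.0
    n_time_samples: int = 200
    frequency_Hz: float = 0.1


class PhantomConfig(_Strict):
    shape: str = "disk"
    size: int = 256
    radius: float = 60.0
    aspect: float = 1.0
    n_arms: int = 4
    n_nuclei: int = 3
    nucleus_radius: float = 12.0
    nucleus_mean: float = 200.0
    cytoplasm_mean: float = 100.0
    noise_sd: float = 0.0
    n_cells: int = 1


class MorphometricsConfig(_Strict):
    phantoms: list[PhantomConfig] = Field(default_factory=lambda: [PhantomConfig()])


class RunConfig(_Strict):
    """Validated top-level configuration; stages are optional blocks."""

    seed: int = 0
    pairs: dict[str, PairConfig] = Field(default_factory=dict)
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    kmc: KMCConfig | None = None
    koff_sweep: KoffSweepConfig | None = None
    rheology: RheologyConfig | None = None
    morphometrics: MorphometricsConfig | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls.model_validate(raw)
        except ValidationError as err:
            paths = "; ".join(
                "/".join(str(p) for p in e["loc"]) + f": {e['msg']}" for e in err.errors()
            )
            raise ValueError(f"invalid config {path}: {paths}") from err

    def resolved_pairs(self) -> tuple[HostGuestPair, HostGuestPair]:
        """(fast, slow) pairs: user overrides or the built-in chemistries."""
        fast = self.pairs["fast"].build("fast") if "fast" in self.pairs else BUILTIN_PAIRS["CD-ADA"]
        slow = self.pairs["slow"].build("slow") if "slow" in self.pairs else BUILTIN_PAIRS["CD-CA"]
        return fast, slow


def _mixture(entry: str | float) -> MixtureSpec:
    if isinstance(entry, str):
        return MixtureSpec.from_label(entry)
    return MixtureSpec(p_fast=float(entry))


def run_config(path: str | Path, out_dir: str | Path, seed: int | None = None) -> dict:
    """Execute every stage requested by a config file.

    Writes one tidy CSV per stage plus ``manifest.json`` (fully resolved
    config, package version and seed — sufficient to reproduce every
    table) and ``run.log``.  Stage failures are isolated: a failing
    stage is recorded in the manifest and does not abort the others.
    Returns the manifest dict.
    """
    cfg = RunConfig.from_yaml(path)
    if seed is not None:
        cfg = cfg.model_copy(update={"seed": seed})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    fast, slow = cfg.resolved_pairs()
    geometry = cfg.geometry.build()
    tables: dict[str, pd.DataFrame] = {}
    errors: dict[str, str] = {}

    def _stage(name, fn):
        try:
            log.info("stage %s: start", name)
            tables[name] = fn()
            log.info("stage %s: ok (%d rows)", name, len(tables[name]))
        except Exception as exc:  # isolate per stage
            log.exception("stage %s failed", name)
            errors[name] = f"{type(exc).__name__}: {exc}"

    if cfg.kmc is not None:
        k = cfg.kmc
        _stage(
            "kmc_mixtures",
            lambda: sweep_mixtures(
                [_mixture(m) for m in k.mixtures],
                force=k.force_pN,
                t_window=k.t_window_s,
                n_replicates=k.n_replicates,
                seed=cfg.seed,
                fast_pair=fast,
                slow_pair=slow,
                geometry=geometry,
                t_max=k.t_max_s,
            ),
        )
    if cfg.koff_sweep is not None:
        s = cfg.koff_sweep
        _stage(
            "koff_sweep",
            lambda: sweep_koff_fixed_Keq(
                s.k_off_per_s,
                K_eq=s.K_eq_per_M,
                force=s.force_pN,
                t_window=s.t_window_s,
                n_replicates=s.n_replicates,
                seed=cfg.seed,
                geometry=geometry,
            ),
        )
    if cfg.rheology is not None:
        r = cfg.rheology
        _stage("rheology", lambda: _rheology_table(r, fast, slow))
    if cfg.morphometrics is not None:
        m = cfg.morphometrics
        _stage("morphometrics", lambda: _morphometrics_table(m, cfg.seed))

    manifest = {
        "package": "gatekmc",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.model_dump(mode="json"),
        "tables": sorted(tables),
        "stage_errors": errors,
    }
    write_results(out, tables, manifest)
    log.removeHandler(handler)
    handler.close()
    return manifest


def _rheology_table(r: RheologyConfig, fast, slow) -> pd.DataFrame:
    rows = []
    omega = 2 * np.pi * r.frequency_Hz
    for entry in r.mixtures:
        mix = _mixture(entry)
        spec = spectrum_from_mixture(
            mix, total_modulus=r.total_modulus_Pa, fast_pair=fast, slow_pair=slow, plateau=r.plateau_Pa
        )
        taus = [tau for _, tau in spec.modes]
        t = np.logspace(np.log10(min(taus) / 100), np.log10(max(taus) * 10), r.n_time_samples)
        g = relaxation_modulus(spec, t)
        t_half, censored = half_relaxation_time(t, g)
        gp, gpp = dynamic_moduli(spec, omega)
        rows.append(
            {
                "label": mix.label or f"p_fast={mix.p_fast:g}",
                "p_fast": mix.p_fast,
                "total_modulus_Pa": spec.total_modulus,
                "half_relaxation_time_s": t_half,
                "half_time_censored": censored,
                "frequency_Hz": r.frequency_Hz,
                "Gp_Pa": gp,
                "Gpp_Pa": gpp,
            }
        )
    return pd.DataFrame(rows)


def _morphometrics_table(m: MorphometricsConfig, seed: int) -> pd.DataFrame:
    rows = []
    for i, ph in enumerate(m.phantoms):
        spec = PhantomSpec(seed=seed + i, **ph.model_dump())
        if spec.shape == "cluster":
            phantom = gen_masks(spec)
            # nuclei channel for the multicellularity call
            img = gen_two_channel_image(
                PhantomSpec(
                    shape="disk",
                    size=spec.size,
                    radius=spec.radius,
                    nucleus_radius=spec.nucleus_radius,
                    nucleus_mean=spec.nucleus_mean,
                    cytoplasm_mean=spec.cytoplasm_mean,
                    noise_sd=spec.noise_sd,
                    seed=spec.seed,
                )
            )
            nuclei = _cluster_nuclei_mask(spec)
            mc = multicellularity(phantom.mask, nuclei)
            for _, row in mc.iterrows():
                rows.append(
                    {
                        "phantom": i,
                        "shape": spec.shape,
                        "object_id": int(row["cluster_id"]),
                        "metric": "n_nuclei",
                        "value": float(row["n_nuclei"]),
                        "truth": float(spec.n_nuclei),
                    }
                )
                rows.append(
                    {
                        "phantom": i,
                        "shape": spec.shape,
                        "object_id": int(row["cluster_id"]),
                        "metric": "multicellular",
                        "value": float(row["multicellular"]),
                        "truth": float(spec.n_nuclei > 2),
                    }
                )
            del img
        else:
            phantom = gen_masks(spec)
            df = circularity(phantom.mask)
            for _, row in df.iterrows():
                rows.append(
                    {
                        "phantom": i,
                        "shape": spec.shape,
                        "object_id": int(row["object_id"]),
                        "metric": "circularity",
                        "value": float(row["circularity"]),
                        "truth": float(phantom.truth["circularity"]),
                    }
                )
            tc = gen_two_channel_image(
                PhantomSpec(
                    shape="disk",
                    size=spec.size,
                    radius=spec.radius,
                    nucleus_radius=spec.nucleus_radius,
                    nucleus_mean=spec.nucleus_mean,
                    cytoplasm_mean=spec.cytoplasm_mean,
                    noise_sd=spec.noise_sd,
                    n_cells=spec.n_cells,
                    seed=spec.seed,
                )
            )
            nc = nuclear_cyto_ratio(tc.intensity, tc.nucleus_mask, tc.cell_mask)
            for _, row in nc.iterrows():
                rows.append(
                    {
                        "phantom": i,
                        "shape": "two-channel",
                        "object_id": int(row["cell_id"]),
                        "metric": "nc_ratio",
                        "value": float(row["ratio"]),
                        "truth": float(tc.truth["ratio"]),
                    }
                )
    return pd.DataFrame(rows)


def _cluster_nuclei_mask(spec: PhantomSpec):
    """Label image of the nuclei recorded in a cluster phantom's truth."""
    from skimage import draw as _draw

    from .morphometrics import LabeledMask

    phantom = gen_masks(spec)
    nuclei = np.zeros_like(phantom.mask.labels)
    for k, (cy, cx) in enumerate(phantom.truth["nucleus_centers"], start=1):
        rr, cc = _draw.disk((cy, cx), spec.nucleus_radius, shape=nuclei.shape)
        nuclei[rr, cc] = k
    return LabeledMask(nuclei, spec.pixel_size)


# ---------------------------------------------------------------------------
# Result serialization
# ---------------------------------------------------------------------------


class ResultsError(ValueError):
    """Malformed result files (named file and problem)."""


_REQUIRED_COLUMNS = {
    "kmc_mixtures": ("label", "p_fast", "opening_probability"),
    "koff_sweep": ("k_off_per_s", "mean_open_time_s", "opening_probability"),
    "rheology": ("label", "half_relaxation_time_s", "Gp_Pa", "Gpp_Pa"),
    "morphometrics": ("metric", "value", "truth"),
}


def write_results(out_dir: str | Path, tables: dict[str, pd.DataFrame], manifest: dict) -> None:
    """Write tidy CSV tables and a JSON manifest; deterministic output."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_results(out_dir: str | Path) -> tuple[dict[str, pd.DataFrame], dict]:
    """Lossless round-trip of :func:`write_results` output."""
    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise ResultsError(f"{manifest_path}: missing manifest")
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as err:
        raise ResultsError(f"{manifest_path}: line {err.lineno}: {err.msg}") from err
    for key in ("package", "version", "seed", "tables"):
        if key not in manifest:
            raise ResultsError(f"{manifest_path}: missing manifest key {key!r}")
    tables = {}
    for name in manifest["tables"]:
        path = out / f"{name}.csv"
        if not path.exists():
            raise ResultsError(f"{path}: table listed in manifest but file missing")
        try:
            tables[name] = pd.read_csv(path)
        except pd.errors.ParserError as err:
            raise ResultsError(f"{path}: {err}") from err
        for col in _REQUIRED_COLUMNS.get(name, ()):
            if col not in tables[name].columns:
                raise ResultsError(f"{path}: missing required column {col!r}")
    return tables, manifest
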