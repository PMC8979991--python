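"""End-to-end orchestration: SI stage, fit stage, manifests and file outputs.

Every stage is a plain function over in-memory objects; the file-reading
wrappers and the CLI are thin layers on top, so composing the stages by hand
gives bit-identical results to ``run_full``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import CoverageError, ValidationError
from .pbcor import PBParams, SIEstimate, compute_si, si_table
from .regression import (
    DiagnosticsReport,
    bootstrap_cis,
    build_regression_table,
    fit_robust,
    pearson_screen,
    residual_diagnostics,
)
from .simulate import StudyScenario, default_study_scenario, generate_study
from .timeseries import (
    AreaSpec,
    EnvSeries,
    build_window,
    default_areas,
    load_env_series,
    load_recruitment,
    window_mean_sst,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegressionSettings:
    tuning_k: float = 1.345
    tol: float = 1e-8
    max_iter: int = 50
    n_boot: int = 2999
    conf_level: float = 0.95
    stratify_by_area: bool = False


@dataclass
class PipelineConfig:
    """Paths, area calendars and estimator settings for one pipeline run."""

    env_path: str
    recruitment_path: str
    out_dir: str
    areas: list[AreaSpec] = field(default_factory=default_areas)
    pb: PBParams = field(default_factory=PBParams)
    regression: RegressionSettings = field(default_factory=RegressionSettings)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        areas = [
            AreaSpec(
                a["area_id"],
                a.get("name", a["area_id"]),
                survey_month=int(a["survey_month"]),
                spawning_start_month=int(a.get("spawning_start_month", 4)),
            )
            for a in raw.get("areas", [])
        ] or default_areas()
        seed = int(raw.get("seed", 0))
        pb_raw = dict(raw.get("pb", {}))
        pb_raw.setdefault("seed", seed)
        return cls(
            env_path=raw["env_path"],
            recruitment_path=raw["recruitment_path"],
            out_dir=raw.get("out_dir", "outputs"),
            areas=areas,
            pb=PBParams(**pb_raw),
            regression=RegressionSettings(**raw.get("regression", {})),
            seed=seed,
        )

    def config_hash(self) -> str:
        payload = {
            "env_path": str(self.env_path),
            "recruitment_path": str(self.recruitment_path),
            "areas": [asdict(a) for a in self.areas],
            "pb": asdict(self.pb),
            "regression": asdict(self.regression),
            "seed": self.seed,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def load_environment(
    config: PipelineConfig,
) -> dict[str, dict[str, EnvSeries]]:
    """Load CHL, MLD and SST for every configured area from the long-format CSV."""
    env: dict[str, dict[str, EnvSeries]] = {}
    for area in config.areas:
        env[area.area_id] = {}
        for var in ("CHL", "MLD", "SST"):
            try:
                env[area.area_id][var] = load_env_series(
                    config.env_path, area_id=area.area_id, variable=var
                )
            except ValidationError as exc:
                raise ValidationError(
                    f"environment input lacks {var} for area {area.area_id}: {exc}"
                ) from exc
    return env


def feasible_recruit_years(area: AreaSpec, chl: EnvSeries, mld: EnvSeries) -> list[int]:
    """Recruitment years whose observation window both series fully cover."""
    years = []
    start = max(chl.start, mld.start)
    end = min(chl.end, mld.end)
    for year in range(start.year, end.year + 2):
        window = build_window(area, year)
        if window.months[0] >= start and window.months[-1] <= end:
            years.append(year)
    return years


def compute_si_stage(
    env: dict[str, dict[str, EnvSeries]],
    areas: list[AreaSpec],
    pb: PBParams,
) -> tuple[list[SIEstimate], dict[tuple[str, int], float]]:
    """SI and windowed-mean SST for every area and feasible recruitment year."""
    estimates: list[SIEstimate] = []
    sst_means: dict[tuple[str, int], float] = {}
    failures: list[str] = []
    for area in areas:
        series = env[area.area_id]
        years = feasible_recruit_years(area, series["CHL"], series["MLD"])
        if not years:
            failures.append(f"{area.area_id}: no fully covered window")
            continue
        for year in years:
            try:
                est = compute_si(series["CHL"], series["MLD"], area, year, pb)
                window = build_window(area, year)
                sst_means[(area.area_id, year)] = window_mean_sst(
                    series["SST"], window
                )
                estimates.append(est)
            except CoverageError as exc:
                failures.append(f"{area.area_id}/{year}: {exc}")
    if failures:
        raise CoverageError("SI stage failed for: " + "; ".join(failures))
    return estimates, sst_means


def run_si_stage(config: PipelineConfig):
    """File-level SI stage: load env inputs, compute SI, write si_table.csv."""
    env = load_environment(config)
    estimates, sst_means = compute_si_stage(env, config.areas, config.pb)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = si_table(estimates)
    table.to_csv(out_dir / "si_table.csv", index=False)
    sst_frame = pd.DataFrame(
        [
            {"area_id": a, "recruit_year": y, "sst_mean": v}
            for (a, y), v in sorted(sst_means.items())
        ]
    )
    sst_frame.to_csv(out_dir / "sst_table.csv", index=False)
    logger.info("SI stage: %d area-year estimates", len(estimates))
    return estimates, sst_means, table


def run_fit_stage(
    config: PipelineConfig,
    estimates: list[SIEstimate],
    sst_means: dict[tuple[str, int], float],
    recruits,
):
    """Regression stage: pooled table, robust fit, bootstrap CIs, diagnostics."""
    table = build_regression_table(recruits, estimates, sst_means)
    reg = config.regression
    fit = fit_robust(table, reg.tuning_k, reg.tol, reg.max_iter)
    cis = bootstrap_cis(
        table,
        tuning_k=reg.tuning_k,
        tol=reg.tol,
        max_iter=reg.max_iter,
        n_boot=reg.n_boot,
        conf_level=reg.conf_level,
        seed=config.seed,
        stratify_by_area=reg.stratify_by_area,
    )
    diagnostics = residual_diagnostics(fit, table)

    screens = {}
    for area in {e.area_id for e in estimates}:
        pairs = sorted(
            (e.recruit_year, e.rho_pb) for e in estimates if e.area_id == area
        )
        si_vec = [rho for _, rho in pairs]
        sst_vec = [sst_means[(area, y)] for y, _ in pairs]
        screens[area] = pearson_screen(si_vec, sst_vec)

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cis.to_frame().to_csv(out_dir / "fit_table.csv", index=False)
    diagnostics.to_frame().to_csv(out_dir / "diagnostics.csv", index=False)
    pd.DataFrame(
        [
            {"area_id": a, "pearson_rho": r, "p_value": p}
            for a, (r, p) in sorted(screens.items())
        ]
    ).to_csv(out_dir / "pearson_screen.csv", index=False)
    logger.info(
        "fit stage: n=%d rows, coefficients %s",
        len(table),
        np.round(cis.estimates, 4).tolist(),
    )
    return table, fit, cis, diagnostics, screens


@dataclass
class PipelineResult:
    si_estimates: list
    sst_means: dict
    regression_table: pd.DataFrame
    fit: object
    cis: object
    diagnostics: DiagnosticsReport
    screens: dict
    manifest: dict


def run_full(
    config: PipelineConfig, simulate: StudyScenario | None = None
) -> PipelineResult:
    """Optional simulation, SI stage, fit stage, manifest — the whole pipeline."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if simulate is not None:
        paths = generate_study(simulate, out_dir / "inputs")
        config.env_path = str(paths["env"])
        config.recruitment_path = str(paths["recruitment"])
    estimates, sst_means, _ = run_si_stage(config)
    recruits = load_recruitment(config.recruitment_path)
    table, fit, cis, diagnostics, screens = run_fit_stage(
        config, estimates, sst_means, recruits
    )
    manifest = {
        "sipipe_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_si_estimates": len(estimates),
        "n_regression_rows": int(len(table)),
        "n_boot": config.regression.n_boot,
        "pb_beta": config.pb.beta,
        "converged": bool(fit.converged),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return PipelineResult(
        estimates, sst_means, table, fit, cis, diagnostics, screens, manifest
    )


def run_synthetic(
    out_dir, seed: int = 0, n_boot: int = 2999, conf_level: float = 0.95,
    beta: float = 0.2,
) -> PipelineResult:
    """Convenience wrapper: default synthetic study through the full pipeline."""
    scenario = default_study_scenario(seed=seed)
    config = PipelineConfig(
        env_path="",
        recruitment_path="",
        out_dir=str(out_dir),
        areas=[a.area_spec for a in scenario.areas],
        pb=PBParams(beta=beta, conf_level=conf_level, n_boot=n_boot, seed=seed),
        regression=RegressionSettings(n_boot=n_boot, conf_level=conf_level),
        seed=seed,
    )
    return run_full(config, simulate=scenario)
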