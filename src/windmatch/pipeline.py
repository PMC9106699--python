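"""End-to-end orchestration of the four-stage analysis.

Stage 1 defines the North-East-wind treatment, stage 2 builds the matched
pairwise experiment, stage 3 runs the Neymanian analysis, stage 4 the
quantitative bias and falsification checks.  ``run_pipeline`` executes all
stages from one config, writes tidy CSV artifacts plus a human-readable
report, and is deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import balance as _balance
from .datasets import (NE_SECTOR, POLLUTANTS, add_lags_and_leads, impute_missing,
                       read_daily_dataset, write_daily_dataset)
from .inference import complete_randomization_variance, lead_lag_effects, pair_differences
from .matching import MatchedPairSet, MatchingConstraints, match_pairs, matching_summary
from .sensitivity import negative_control_check, sensitivity_curve
from .simulate import SyntheticConfig, generate_dataset, inject_missingness

logger = logging.getLogger(__name__)

DEFAULT_GAMMAS = tuple(round(g, 1) for g in np.arange(1.0, 3.0001, 0.1))


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; serializable to YAML."""
    input_csv: str | None = None
    schema: dict | None = None
    synthetic: SyntheticConfig | None = None
    missingness: dict | None = None      # per-variable rates for synthetic runs
    impute: bool = True
    impute_exclude: tuple = ("pm25",)
    sector: tuple = NE_SECTOR
    constraints: MatchingConstraints = field(default_factory=MatchingConstraints)
    outcomes: tuple = POLLUTANTS
    offsets: tuple = (-1, 0, 1)
    gammas: tuple = DEFAULT_GAMMAS
    alpha: float = 0.05
    seed: int = 0
    outdir: str = "pipeline_out"

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        if self.synthetic is not None:
            payload["synthetic"] = dataclasses.asdict(self.synthetic)
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(payload), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if kwargs.get("synthetic") is not None:
            syn = kwargs["synthetic"]
            if isinstance(syn, dict):
                syn_kwargs = dict(syn)
                from .simulate import (ConfounderModel, HumidityModel, PollutantModel,
                                       TemperatureModel, WindDirectionModel, WindSpeedModel)
                casts = {"temperature": TemperatureModel, "wind_direction": WindDirectionModel,
                         "wind_speed": WindSpeedModel, "humidity": HumidityModel,
                         "confounder": ConfounderModel}
                for key, klass in casts.items():
                    if isinstance(syn_kwargs.get(key), dict):
                        syn_kwargs[key] = klass(**syn_kwargs[key])
                if isinstance(syn_kwargs.get("pollutants"), dict):
                    syn_kwargs["pollutants"] = {
                        p: PollutantModel(**v) if isinstance(v, dict) else v
                        for p, v in syn_kwargs["pollutants"].items()}
                if "rainfall_probs" in syn_kwargs:
                    syn_kwargs["rainfall_probs"] = tuple(syn_kwargs["rainfall_probs"])
                if "sector" in syn_kwargs:
                    syn_kwargs["sector"] = tuple(syn_kwargs["sector"])
                kwargs["synthetic"] = SyntheticConfig(**syn_kwargs)
        if isinstance(kwargs.get("constraints"), dict):
            ck = dict(kwargs["constraints"])
            if "exact_vars" in ck:
                ck["exact_vars"] = tuple(ck["exact_vars"])
            kwargs["constraints"] = MatchingConstraints(**ck)
        for key in ("sector", "outcomes", "offsets", "gammas", "impute_exclude"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def _plain(obj):
    """Recursively convert tuples/numpy scalars for clean YAML output."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _load_stage(config: PipelineConfig, outdir: Path, log):
    if config.input_csv is not None:
        df = read_daily_dataset(config.input_csv, schema=config.schema,
                                sector=config.sector)
        log(f"stage data: read {len(df)} days from {config.input_csv}")
        truth = None
    else:
        syn = config.synthetic or SyntheticConfig()
        sds = generate_dataset(syn, seed=config.seed)
        if config.missingness:
            sds = inject_missingness(sds, config.missingness, seed=config.seed)
        df = sds.observed
        truth = sds.truth
        log(f"stage data: simulated {len(df)} days (seed {config.seed})")
        truth.to_csv(outdir / "truth.csv", index=False, date_format="%Y-%m-%d")
    if config.impute and df[[c for c in POLLUTANTS if c in df.columns]].isna().any().any():
        df = impute_missing(df, exclude=config.impute_exclude, seed=config.seed)
        n_imp = int(df.filter(like="imputed_").to_numpy().sum())
        log(f"stage data: imputed {n_imp} cells (excluded: {config.impute_exclude})")
    write_daily_dataset(df, outdir / "dataset.csv")
    return df


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all four stages; returns the artifact directory.

    Artifacts: dataset.csv (+truth.csv for synthetic input), pairs.csv,
    balance.csv, balance_summary.csv, estimates.csv, sensitivity.csv,
    negative_controls.csv, precision.csv, report.txt, config.yaml,
    pipeline.log.  Any stage failure aborts with a stage-named message;
    artifacts written so far are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(f"{time.strftime('%Y-%m-%d %H:%M:%S')} {msg}")

    def flush_log() -> None:
        (outdir / "pipeline.log").write_text("\n".join(log_lines) + "\n")

    config.to_yaml(outdir / "config.yaml")
    stage = "data"
    try:
        df = _load_stage(config, outdir, log)

        stage = "matching"
        pairs = match_pairs(df, config.constraints)
        df = add_lags_and_leads(df, [o for o in config.outcomes if o in df.columns]
                                + ["w"], sorted({-1, 1} | set(config.offsets) - {0}))
        pairs.to_csv(outdir / "pairs.csv")
        summary = matching_summary(df, pairs)
        log(f"stage matching: J={pairs.j} of {pairs.n_treated} treated "
            f"(fraction {summary['matched_fraction']:.3f})")

        stage = "balance"
        btab = _balance.balance_table(df, pairs, by_month=True)
        btab.to_csv(outdir / "balance.csv", index=False)
        bsum = _balance.balance_summary(btab)
        bsum.to_csv(outdir / "balance_summary.csv", index=False)
        log("stage balance: table written")

        report = [
            "Matched-pair analysis of North-East wind effects on air pollutants",
            "=" * 66,
            f"seed: {config.seed}",
            "",
            "Stage 2 - matching",
            f"  treated days: {pairs.n_treated}   control days: {pairs.n_control}",
            f"  matched pairs J = {pairs.j} "
            f"(fraction of treated matched: {summary['matched_fraction']:.3f})",
            "",
        ]

        if pairs.j < 2:
            report += ["Stage 3 - inference", "  skipped: J < 2, no estimates possible"]
            log("stage inference: skipped (J < 2)")
        else:
            stage = "balance-report"
            piv = {(r["stage"], r["type"]): r["mean_statistic"] for _, r in bsum.iterrows()}
            report += [
                "Stage 2 - covariate balance (mean statistic)",
                f"  continuous SMD before: {piv.get(('before', 'continuous'), float('nan')):.3f}"
                f"   after: {piv.get(('after', 'continuous'), float('nan')):.3f}",
                f"  categorical pp before: {piv.get(('before', 'categorical'), float('nan')):.2f}"
                f"   after: {piv.get(('after', 'categorical'), float('nan')):.2f}",
                "",
            ]

            stage = "inference"
            outcomes = [o for o in config.outcomes if o in df.columns]
            est = lead_lag_effects(df, pairs, outcomes, config.offsets)
            est.to_csv(outdir / "estimates.csv", index=False)
            log(f"stage inference: {len(est)} outcome x offset estimates")
            report.append("Stage 3 - Neyman estimates (µg/m³)")
            for _, r in est.iterrows():
                report.append(
                    f"  {r['outcome']:>5} offset {int(r['offset']):+d}: "
                    f"tau_hat={r['tau_hat']:.2f} "
                    f"95% CI ({r['ci95_low']:.2f}, {r['ci95_high']:.2f}) "
                    f"J={int(r['j'])}")
            report.append("")

            stage = "sensitivity"
            sens_rows = []
            for outcome in outcomes:
                try:
                    d = pair_differences(df, pairs, outcome, 0)
                except ValueError:
                    continue
                curve = sensitivity_curve(d, config.gammas, alpha=config.alpha)
                curve.insert(0, "outcome", outcome)
                curve.insert(1, "offset", 0)
                sens_rows.append(curve)
            sens = pd.concat(sens_rows, ignore_index=True) if sens_rows else pd.DataFrame()
            sens.to_csv(outdir / "sensitivity.csv", index=False)
            neg = negative_control_check(df, pairs, outcomes)
            neg.to_csv(outdir / "negative_controls.csv", index=False)
            prec = pd.DataFrame([
                {**dataclasses.asdict(c), "precision_ratio": c.precision_ratio}
                for c in (complete_randomization_variance(df, pairs, o) for o in outcomes)
            ])
            prec.to_csv(outdir / "precision.csv", index=False)
            log("stage sensitivity: gamma curves, negative controls, precision written")

            report.append("Stage 4 - sensitivity")
            if not sens.empty:
                g2 = sens[np.isclose(sens["gamma"], 2.0)]
                for _, r in g2.iterrows():
                    report.append(
                        f"  {r['outcome']:>5} Gamma=2.0 interval: "
                        f"({r['ci_low']:.2f}, {r['ci_high']:.2f})")
            for _, r in neg.iterrows():
                flag = "  <- FLAG" if r["flag_nonzero"] else ""
                report.append(
                    f"  negative control {r['outcome']:>5} (t-1): "
                    f"tau_hat={r['tau_hat']:.2f} "
                    f"95% CI ({r['ci95_low']:.2f}, {r['ci95_high']:.2f}){flag}")
            for _, r in prec.iterrows():
                report.append(
                    f"  precision {r['outcome']:>5}: se_pairwise={r['se_pairwise']:.3f} "
                    f"se_complete={r['se_complete']:.3f} ratio={r['precision_ratio']:.3f}")
    except Exception as exc:
        log(f"stage {stage} FAILED: {exc}")
        flush_log()
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "report.txt").write_text("\n".join(report) + "\n")
    log("report written")
    flush_log()
    return outdir


def polar_summary(df: pd.DataFrame, pollutant: str, n_sectors: int = 8,
                  speed_bins: int = 3) -> pd.DataFrame:
    """Mean concentration per (wind-direction sector × wind-speed bin).

    A plain binned summary (no smoothing) of how concentrations vary over
    the wind rose; empty cells are reported with NaN means.
    """
    if n_sectors < 4:
        raise ValueError("n_sectors must be >= 4")
    wd = df["wind_direction"].to_numpy(dtype=float)
    ws = df["wind_speed"].to_numpy(dtype=float)
    y = df[pollutant].to_numpy(dtype=float)
    keep = ~np.isnan(wd) & ~np.isnan(ws) & ~np.isnan(y)
    width = 360.0 / n_sectors
    sector = np.floor(wd[keep] / width).astype(int)
    edges = np.linspace(ws[keep].min(), ws[keep].max() + 1e-9, speed_bins + 1)
    sbin = np.clip(np.digitize(ws[keep], edges) - 1, 0, speed_bins - 1)
    rows = []
    for s in range(n_sectors):
        for b in range(speed_bins):
            cell = (sector == s) & (sbin == b)
            rows.append({
                "sector_low_deg": s * width, "sector_high_deg": (s + 1) * width,
                "speed_bin": b, "speed_low": edges[b], "speed_high": edges[b + 1],
                "mean_concentration": float(y[keep][cell].mean()) if cell.any() else float("nan"),
                "count": int(cell.sum()),
            })
    return pd.DataFrame(rows)
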