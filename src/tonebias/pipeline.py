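"""End-to-end orchestration: simulate cohorts, fit models, analyse biases,
regenerate figures, and write a machine-readable summary.

Runs are reproducible from (config, seed): all randomness derives from the
master seed, and a config hash is recorded in the run manifest, the summary
and every analysis table.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import benchmarks
from .analysis import choice_bias_timecourse, contraction_magnitude, psychometric_curve
from .fitting import compare_models, fit_sigma
from .observers import DEFAULT_SIGMA_DISTRIBUTION, CohortSpec, simulate_cohort
from .perceptron import optimize_params
from .protocols import PROTOCOLS, exclusion_test, get_protocol, write_trial_log

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    protocols: list[str] = field(default_factory=lambda: list(PROTOCOLS))
    n_observers: int = 12
    n_trials: int = 220
    observer_kind: str = "static"
    a_policy: "float | str" = "optimal"
    b0: float = 0.0
    learning_rate: float = 0.0
    sigma_distribution: dict = field(
        default_factory=lambda: dict(DEFAULT_SIGMA_DISTRIBUTION)
    )
    n_bins: int = 9
    window: int = 20
    fit_models: bool = True
    make_figures: bool = True
    seed: int = 0
    outdir: str = "tonebias_run"

    def validate(self) -> None:
        for name in self.protocols:
            get_protocol(name)
        if self.n_trials % 4 != 0:
            raise ValueError(
                f"n_trials={self.n_trials} must be divisible by 4 so the "
                "75/25 possible/impossible split is exact"
            )
        if self.n_observers < 1:
            raise ValueError("n_observers must be >= 1")
        if self.n_trials % self.window != 0:
            raise ValueError("window must divide n_trials")

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class PipelineResult:
    outdir: Path
    summary: dict


def _log_line(fh, message: str) -> None:
    fh.write(f"[{time.strftime('%Y-%m-%d %H:%M:%S')}] {message}\n")
    fh.flush()


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run simulate -> fit -> analyze -> report for every configured protocol."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    written: list[str] = []

    with open(outdir / "run.log", "w") as logfh:
        _log_line(logfh, f"config hash {chash}, master seed {config.seed}")

        cohorts: dict[str, tuple[list, pd.DataFrame]] = {}
        manifests = []
        for k, protocol in enumerate(config.protocols):
            spec = CohortSpec(
                n_observers=config.n_observers,
                protocol=protocol,
                observer_kind=config.observer_kind,
                sigma_distribution=config.sigma_distribution,
                a_policy=config.a_policy,
                b0=config.b0,
                learning_rate=config.learning_rate,
                n_trials=config.n_trials,
                master_seed=config.seed * 1000 + k,
            )
            logs, manifest = simulate_cohort(spec)
            cohorts[protocol] = (logs, manifest)
            log_dir = outdir / "logs" / protocol
            log_dir.mkdir(parents=True, exist_ok=True)
            for log in logs:
                p = log_dir / f"{log.observer_id}.csv"
                write_trial_log(log, p)
                written.append(str(p.relative_to(outdir)))
            manifest = manifest.copy()
            manifest["excluded"] = [
                exclusion_test(log).decision == "exclude" for log in logs
            ]
            manifest["config_hash"] = chash
            manifests.append(manifest)
            _log_line(
                logfh,
                f"simulated {protocol}: {len(logs)} observers, "
                f"{int(manifest['excluded'].sum())} excluded by the chance screen",
            )
        manifest_df = pd.concat(manifests, ignore_index=True)
        manifest_df.to_csv(outdir / "manifest.csv", index=False)
        written.append("manifest.csv")

        fit_rows = []
        dll_by_protocol: dict[str, np.ndarray] = {}
        if config.fit_models:
            for protocol, (logs, _) in cohorts.items():
                fits_p = [fit_sigma("optimal_perceptron", log, protocol) for log in logs]
                fits_c = [fit_sigma("psychometric", log, protocol) for log in logs]
                comp = compare_models(fits_p, fits_c)
                dll_by_protocol[protocol] = comp.dll_per_trial
                for fit in (*fits_p, *fits_c):
                    fit_rows.append(
                        {
                            "observer_id": fit.observer_id,
                            "protocol": protocol,
                            "model": fit.model,
                            "sigma_hat": fit.sigma_hat,
                            "loglik": fit.loglik,
                            "n_trials_used": fit.n_trials_used,
                            "converged": fit.converged,
                            "config_hash": chash,
                        }
                    )
                _log_line(
                    logfh,
                    f"fitted {protocol}: Perceptron favoured for "
                    f"{comp.fraction_favoring_perceptron:.0%} of observers "
                    f"(sign-test p={comp.p_value:.3g})",
                )
            pd.DataFrame(fit_rows).to_csv(outdir / "fits.csv", index=False)
            written.append("fits.csv")

        curve_rows, bias_rows, tc_rows = [], [], []
        for protocol, (logs, _) in cohorts.items():
            for region in ("all", "I", "II", "III"):
                curve = psychometric_curve(logs, region=region, n_bins=config.n_bins)
                for c, p, s, n in zip(
                    curve.bin_centers, curve.proportion, curve.sem, curve.n_trials
                ):
                    curve_rows.append(
                        {
                            "protocol": protocol,
                            "region": region,
                            "delta": c,
                            "proportion": p,
                            "sem": s,
                            "n_trials": n,
                            "config_hash": chash,
                        }
                    )
            for obs_log, summary in zip(
                logs, contraction_magnitude(logs, per_observer=True)
            ):
                bias_rows.append(
                    {
                        "protocol": protocol,
                        "observer_id": obs_log.observer_id,
                        "contraction_magnitude": summary.contraction_magnitude,
                        "impossible_contrast": summary.impossible_contrast,
                        "choice_bias": summary.choice_bias,
                        "degenerate": summary.degenerate,
                        "config_hash": chash,
                    }
                )
            tc = choice_bias_timecourse(logs, window=config.window)
            for t, m, s, n in zip(tc.trial_mid, tc.mean, tc.sem, tc.n_observers):
                tc_rows.append(
                    {
                        "protocol": protocol,
                        "trial_mid": t,
                        "mean": m,
                        "sem": s,
                        "n_observers": n,
                        "config_hash": chash,
                    }
                )
        pd.DataFrame(curve_rows).to_csv(outdir / "curves.csv", index=False)
        pd.DataFrame(bias_rows).to_csv(outdir / "bias.csv", index=False)
        pd.DataFrame(tc_rows).to_csv(outdir / "timecourse.csv", index=False)
        written += ["curves.csv", "bias.csv", "timecourse.csv"]

        _log_line(logfh, "computing reference quantities")
        b_worst, per_sigma = benchmarks.max_abs_optimal_b()
        straddle_pct, n_straddle = benchmarks.straddling_accuracy_percent(
            seed=config.seed
        )
        optimizer_table = {}
        for protocol in config.protocols:
            res = optimize_params(0.1, protocol)
            optimizer_table[protocol] = {"a": res.a, "b": res.b}
        bias_df = pd.DataFrame(bias_rows)
        summary = {
            "config": config.to_dict(),
            "config_hash": chash,
            "seed": config.seed,
            "optimal_weight_noise_free": benchmarks.optimal_weight_noise_free(),
            "max_abs_optimal_b_control": b_worst,
            "optimal_ab_by_sigma_control": {
                str(s): list(ab) for s, ab in per_sigma.items()
            },
            "straddling_accuracy_percent": straddle_pct,
            "n_straddling_trials": n_straddle,
            "impossible_trial_percent": benchmarks.impossible_trial_percent(
                config.n_trials, config.seed
            ),
            "exclusion_threshold_percent": benchmarks.exclusion_threshold_percent(),
            "optimal_ab_sigma_0.1_by_protocol": optimizer_table,
            "mean_contraction_magnitude_by_protocol": {
                protocol: float(
                    bias_df.loc[bias_df.protocol == protocol, "contraction_magnitude"].mean()
                )
                for protocol in config.protocols
            },
            "mean_dll_per_trial_by_protocol": {
                protocol: float(np.mean(dll)) for protocol, dll in dll_by_protocol.items()
            },
        }

        if config.make_figures:
            from . import figures  # deferred: pulls in matplotlib

            fig_dir = outdir / "figures"
            timecourses = {
                protocol: choice_bias_timecourse(logs, window=config.window)
                for protocol, (logs, _) in cohorts.items()
            }
            figures.fig_choice_timecourse(timecourses, fig_dir / "choice_timecourse.png")
            for protocol, (logs, _) in cohorts.items():
                figures.fig_region_curves(
                    logs, fig_dir / f"region_curves_{protocol}.png", title=protocol
                )
            figures.fig_optimal_a_vs_sigma(
                np.linspace(0.0, 0.3, 13), fig_dir / "optimal_a_vs_sigma.png"
            )
            if dll_by_protocol.get("control") is not None:
                figures.fig_dll_histogram(
                    dll_by_protocol["control"], fig_dir / "dll_histogram.png"
                )
            labels = list(config.protocols)
            values, errors = [], []
            for protocol in labels:
                sel = bias_df.loc[bias_df.protocol == protocol, "contraction_magnitude"]
                values.append(float(sel.mean()))
                errors.append(float(sel.std(ddof=1) / np.sqrt(len(sel))) if len(sel) > 1 else 0.0)
            figures.fig_bias_bars(labels, values, errors, fig_dir / "bias_magnitude.png")
            for protocol in labels:
                figures.fig_optimal_region_curves(
                    0.1, protocol, fig_dir / f"optimal_region_curves_{protocol}.png"
                )
            written += [str(p.relative_to(outdir)) for p in sorted(fig_dir.glob("*"))]
            _log_line(logfh, f"figures written to {fig_dir}")

        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        run_manifest = {"config_hash": chash, "files": sorted(written + ["summary.json"])}
        with open(outdir / "run_manifest.json", "w") as fh:
            json.dump(run_manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        _log_line(logfh, "done")
    return PipelineResult(outdir=outdir, summary=summary)
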