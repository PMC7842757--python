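"""Figure regeneration for pipeline runs.

Every figure is saved together with the tidy CSV table it was drawn from,
so no number exists only inside an image.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .analysis import Timecourse, expected_curve, psychometric_curve
from .perceptron import PerceptronParams, optimize_params, response_surface
from .protocols import BASE_FREQ_HZ, D_HALF_RANGE, M_HALF_RANGE, TrialLog

__all__ = [
    "fig_choice_timecourse",
    "fig_region_curves",
    "fig_response_surface",
    "fig_optimal_a_vs_sigma",
    "fig_dll_histogram",
    "fig_bias_bars",
    "fig_optimal_region_curves",
]

_PROTOCOL_COLORS = {
    "control": "black",
    "enhance_f1gt": "tab:blue",
    "suppress_f1gt": "tab:red",
    "enhance_contraction": "tab:purple",
    "suppress_contraction": "tab:green",
}
_REGION_COLORS = {"I": "tab:red", "II": "black", "III": "tab:blue", "all": "black"}


def _save(fig, table: pd.DataFrame, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    table.to_csv(path.with_suffix(".csv"), index=False)


def fig_choice_timecourse(timecourses: dict[str, Timecourse], path) -> None:
    """Impossible-trial choice rate vs trial number, one line per protocol."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    rows = []
    for name, tc in timecourses.items():
        ax.errorbar(
            tc.trial_mid, tc.mean, yerr=tc.sem, marker="o", ms=4,
            color=_PROTOCOL_COLORS.get(name, None), label=name,
        )
        for t, m, s, n in zip(tc.trial_mid, tc.mean, tc.sem, tc.n_observers):
            rows.append({"protocol": name, "trial_mid": t, "mean": m,
                         "sem": s, "n_observers": n})
    ax.axhline(0.5, color="gray", lw=0.8, ls=":")
    ax.set_xlabel("trial")
    ax.set_ylabel('P(report "f1>f2") on impossible trials')
    ax.set_ylim(0, 1)
    ax.legend(fontsize=7)
    _save(fig, pd.DataFrame(rows), path)


def fig_region_curves(logs: list[TrialLog], path, title: str = "") -> None:
    """Per-region psychometric curves of a simulated cohort."""
    fig, ax = plt.subplots(figsize=(4.2, 3.5))
    rows = []
    for region in ("I", "II", "III"):
        curve = psychometric_curve(logs, region=region)
        ax.errorbar(
            curve.bin_centers, curve.proportion, yerr=curve.sem,
            marker="o", ms=4, color=_REGION_COLORS[region], label=f"region {region}",
        )
        for c, p, s, n in zip(curve.bin_centers, curve.proportion, curve.sem,
                              curve.n_trials):
            rows.append({"region": region, "delta": c, "proportion": p,
                         "sem": s, "n_trials": n})
    ax.set_xlabel("log f1 - log f2")
    ax.set_ylabel('P("f1>f2")')
    ax.set_title(title, fontsize=9)
    ax.legend(fontsize=7)
    _save(fig, pd.DataFrame(rows), path)


def fig_response_surface(params: PerceptronParams, path) -> None:
    """Response-probability map in the log f1 x log f2 plane with quadrant
    split at 1 kHz."""
    span = M_HALF_RANGE + D_HALF_RANGE
    f = BASE_FREQ_HZ * np.exp(np.linspace(-span, span, 121))
    P = response_surface(params, f, f)
    fig, ax = plt.subplots(figsize=(4, 3.5))
    im = ax.pcolormesh(np.log(f / BASE_FREQ_HZ), np.log(f / BASE_FREQ_HZ),
                       P.T, cmap="RdBu_r", vmin=0, vmax=1, shading="auto")
    ax.axhline(0, color="k", lw=0.6)
    ax.axvline(0, color="k", lw=0.6)
    fig.colorbar(im, ax=ax, label='P("f1>f2")')
    ax.set_xlabel("log f1 (re 1 kHz)")
    ax.set_ylabel("log f2 (re 1 kHz)")
    table = pd.DataFrame(P, index=f, columns=f).reset_index(names="f1_hz")
    _save(fig, table, path)


def fig_optimal_a_vs_sigma(sigmas: np.ndarray, path, protocol: str = "control") -> None:
    """Optimal contraction weight a* as a function of the noise level."""
    results = [optimize_params(float(s), protocol) for s in sigmas]
    a_star = [r.a for r in results]
    b_star = [r.b for r in results]
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.plot(sigmas, a_star, "o-", color="k")
    ax.set_xlabel("sigma (log units)")
    ax.set_ylabel("optimal a")
    ax.set_ylim(0, 1.05)
    table = pd.DataFrame({"sigma": sigmas, "a_star": a_star, "b_star": b_star})
    _save(fig, table, path)


def fig_dll_histogram(dll: np.ndarray, path) -> None:
    """Histogram of per-observer ΔLL/trial (Perceptron minus psychometric)."""
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.hist(dll, bins=15, color="tab:gray", edgecolor="k")
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("ΔLL per trial (Perceptron - psychometric)")
    ax.set_ylabel("observers")
    _save(fig, pd.DataFrame({"dll_per_trial": dll}), path)


def fig_bias_bars(labels: list[str], values: list[float], errors: list[float],
                  path, ylabel: str = "contraction magnitude") -> None:
    """Bar plot of group bias magnitudes with cross-observer SEM."""
    fig, ax = plt.subplots(figsize=(3.5, 3))
    x = np.arange(len(labels))
    ax.bar(x, values, yerr=errors, color="tab:gray", edgecolor="k", capsize=3)
    ax.set_xticks(x, labels, rotation=30, ha="right", fontsize=7)
    ax.set_ylabel(ylabel)
    _save(fig, pd.DataFrame({"group": labels, "value": values, "sem": errors}), path)


def fig_optimal_region_curves(sigma: float, protocol: str, path) -> None:
    """Expected per-region curves of the protocol-optimised Perceptron."""
    res = optimize_params(sigma, protocol)
    params = PerceptronParams(res.a, res.b, sigma)
    fig, ax = plt.subplots(figsize=(4.2, 3.5))
    rows = []
    for region in ("I", "II", "III"):
        centers, probs = expected_curve(params, region)
        ax.plot(centers, probs, "o-", color=_REGION_COLORS[region],
                label=f"region {region}")
        rows.extend({"region": region, "delta": c, "probability": p}
                    for c, p in zip(centers, probs))
    ax.set_xlabel("log f1 - log f2")
    ax.set_ylabel('P("f1>f2")')
    ax.set_title(f"optimal Perceptron, {protocol}, sigma={sigma}", fontsize=8)
    ax.legend(fontsize=7)
    _save(fig, pd.DataFrame(rows), path)
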