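"""Summary figures: spacing vs position, mean spacing vs GLG width with
both deposition-rate prediction lines, and estimated days per GLG.

Plots are artifacts for inspection; all numbers live in the CSV tables.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .model import DEFAULT_CONSTANTS, ChronologyConstants, SpacingMeasurement


def plot_spacing_vs_position(
    measurements: Sequence[SpacingMeasurement],
    glg: tuple[str, str],
    path: Path,
) -> Path:
    """Scatter of individual spacings along one GLG's growth axis."""
    xs = [m.position_um for m in measurements if m.glg_ref == glg]
    ys = [m.spacing_um for m in measurements if m.glg_ref == glg]
    fig, ax = plt.subplots(figsize=(7, 3.2))
    ax.plot(xs, ys, "k.", ms=4)
    ax.set_xlabel("distance from GLG start (μm)")
    ax.set_ylabel("incremental line spacing (μm)")
    ax.set_title(f"{glg[0]}-{glg[1]}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_spacing_vs_width(
    day_table: pd.DataFrame,
    summary_table: pd.DataFrame,
    path: Path,
    constants: ChronologyConstants = DEFAULT_CONSTANTS,
) -> Path:
    """Mean spacing (±3·SE) against GLG width with both prediction lines."""
    body = summary_table[summary_table["glg"] != "Average"]
    fig, ax = plt.subplots(figsize=(5.5, 4))
    t = np.linspace(body["thickness_um"].min() * 0.9, body["thickness_um"].max() * 1.1, 50)
    ax.plot(t, t / constants.days_per_year, "r-", label="1 GLG/yr")
    ax.plot(t, t / constants.days_per_half_year, "b-", label="2 GLG/yr")
    ax.errorbar(
        body["thickness_um"],
        body["mean_um"],
        yerr=body["three_se_um"],
        fmt="k^",
        capsize=3,
        label="GLGs",
    )
    ax.plot(
        body["thickness_um"].mean(), body["mean_um"].mean(), "gD", ms=9, label="mean"
    )
    ax.set_xlabel("GLG width (μm)")
    ax.set_ylabel("mean incremental line spacing (μm)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_estimated_days(
    day_table: pd.DataFrame,
    path: Path,
    constants: ChronologyConstants = DEFAULT_CONSTANTS,
) -> Path:
    """Estimated days per GLG with the annual and semi-annual references."""
    body = day_table[day_table["glg"] != "Average"]
    x = np.arange(len(body))
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.axhline(constants.days_per_year, color="r", label=f"{constants.days_per_year:.0f} d")
    ax.axhline(
        constants.days_per_half_year, color="b", label=f"{constants.days_per_half_year:.1f} d"
    )
    ax.errorbar(
        x,
        body["days"],
        yerr=[body["err_minus"], body["err_plus"]],
        fmt="k^",
        capsize=3,
    )
    ax.plot(len(body) / 2 - 0.5, body["days"].mean(), "gD", ms=9, label="mean")
    ax.set_xticks(x, body["glg"], rotation=45, ha="right")
    ax.set_ylabel("estimated days in GLG")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
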