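"""Plain per-condition renderings of the weekly series and model fits."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .weekgrid import week_of_year


def plot_condition(
    series_df: pd.DataFrame,
    historical_df: pd.DataFrame | None,
    path: Path,
    condition: str,
) -> Path:
    """2020 weekly contact percentage against the 2017-19 historical mean."""
    df = series_df.copy()
    ws = pd.DatetimeIndex(df["week_start"])
    fig, ax = plt.subplots(figsize=(7, 3.5))
    cur = df[ws.year == 2020]
    if len(cur):
        ax.plot(
            pd.DatetimeIndex(cur["week_start"]),
            100 * cur["proportion"],
            color="tab:red",
            label="2020",
        )
        if historical_df is not None and len(historical_df):
            woy = week_of_year(cur["week_start"])
            hist = (
                historical_df.set_index("week_of_year")["mean"]
                .reindex(woy)
                .to_numpy()
            )
            ax.plot(
                pd.DatetimeIndex(cur["week_start"]),
                100 * hist,
                color="tab:gray",
                linestyle="--",
                label="2017-19 mean",
            )
    ax.set_ylabel("% of population with contacts")
    ax.set_title(condition)
    ax.legend(loc="best", frameon=False)
    fig.autofmt_xdate()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return Path(path)


def plot_fit(fitted_df: pd.DataFrame, path: Path, condition: str) -> Path:
    """Observed vs fitted weekly proportions from the ITS model."""
    fig, ax = plt.subplots(figsize=(7, 3.5))
    ws = pd.DatetimeIndex(fitted_df["week_start"])
    ax.plot(ws, 100 * fitted_df["observed"], color="0.6", lw=0.8, label="observed")
    ax.plot(ws, 100 * fitted_df["fitted"], color="tab:blue", label="fitted")
    ax.set_ylabel("% with contacts")
    ax.set_title(condition)
    ax.legend(loc="best", frameon=False)
    fig.autofmt_xdate()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return Path(path)


def plot_run(results: dict, outdir) -> list[Path]:
    """Write one series plot and one fit plot per condition in a run."""
    outdir = Path(outdir)
    paths = []
    series = results.get("series")
    hist = results.get("historical")
    fitted = results.get("fitted_curves")
    conditions = (
        series["condition"].unique() if series is not None else []
    )
    for cond in conditions:
        s = series[series["condition"] == cond]
        h = hist[hist["condition"] == cond] if hist is not None else None
        paths.append(
            plot_condition(s, h, outdir / f"series_{cond}.png", cond)
        )
        if fitted is not None:
            f = fitted[fitted["condition"] == cond]
            if len(f):
                paths.append(plot_fit(f, outdir / f"fit_{cond}.png", cond))
    return paths
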