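"""Optional static renderings of the run outputs (requires matplotlib).

Reads the CSVs a completed run wrote and produces three PNGs next to them:
exceedance counts per date, mean exceedance duration per date, and the
hour-by-heat-wave-day heat map.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def render_figures(out_dir: str | Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    produced: list[Path] = []

    counts = pd.read_csv(out_dir / "fig2_counts.csv", parse_dates=["date"])
    durations = pd.read_csv(out_dir / "fig3_durations.csv", parse_dates=["date"])
    heatmap = pd.read_csv(out_dir / "fig4_heatmap.csv", index_col="hour")

    for frame, column, ylabel, name in (
        (counts, "n_houses_at_or_above", "houses at or above threshold", "fig2_counts.png"),
        (durations, "mean_duration_hours", "mean duration (h)", "fig3_durations.png"),
    ):
        fig, ax = plt.subplots(figsize=(9, 3))
        ax.bar(frame["date"], frame[column], width=0.9)
        ax.set_ylabel(ylabel)
        ax.set_xlabel("date")
        fig.autofmt_xdate()
        path = out_dir / name
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        produced.append(path)

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(heatmap.to_numpy(), aspect="auto", origin="lower", cmap="inferno")
    ax.set_xticks(range(len(heatmap.columns)), heatmap.columns, rotation=45, ha="right")
    ax.set_ylabel("hour of day")
    fig.colorbar(im, ax=ax, label="mean indoor temperature (°C)")
    path = out_dir / "fig4_heatmap.png"
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    produced.append(path)
    return produced
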