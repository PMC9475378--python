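"""Score-table and correlation report writing."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

SCORE_COLUMNS = ["id", "scale", "method", "score"]
CORR_COLUMNS = ["scale", "method", "pearson_r", "n"]


def write_scores_csv(scores: pd.DataFrame, path) -> None:
    """Write the score table with a stable column order."""
    if scores.empty:
        raise ValueError("score table is empty")
    scores.loc[:, SCORE_COLUMNS].to_csv(path, index=False)


def read_scores_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SCORE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_report(scores: pd.DataFrame, correlations: pd.DataFrame | None,
                 out_dir, heatmap: bool = False) -> list[Path]:
    """Write scores (and correlations) as CSV; optionally a correlation heatmap.

    Returns the list of files written.  Output is byte-stable for identical
    inputs: fixed column order, default float formatting, no timestamps.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    scores_path = out_dir / "scores.csv"
    write_scores_csv(scores, scores_path)
    written.append(scores_path)
    if correlations is not None and not correlations.empty:
        corr_path = out_dir / "correlations.csv"
        correlations.loc[:, CORR_COLUMNS].to_csv(corr_path, index=False)
        written.append(corr_path)
        if heatmap:
            written.append(_heatmap(correlations, out_dir / "correlations.png"))
    return written


def _heatmap(correlations: pd.DataFrame, path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = correlations.pivot(index="scale", columns="method", values="pearson_r")
    fig, ax = plt.subplots(figsize=(1.2 * len(pivot.columns) + 3, 0.45 * len(pivot) + 2))
    im = ax.imshow(pivot.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r", aspect="auto")
    ax.set_xticks(range(len(pivot.columns)), pivot.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(pivot.index)), pivot.index)
    for i in range(pivot.shape[0]):
        for j in range(pivot.shape[1]):
            ax.text(j, i, f"{pivot.iat[i, j]:.2f}", ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax, label="Pearson r")
    ax.set_title("Score vs. experimental HIC retention")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
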