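"""Optional rendering of sweep summaries (requires matplotlib)."""

from __future__ import annotations

import pandas as pd

_QUANTITIES = {
    "beta": ("mean_beta", "ci_beta_low", "ci_beta_high",
             "parameter estimate (% signal change)"),
    "t": ("mean_t", "ci_t_low", "ci_t_high", "t-statistic"),
    "rss": ("mean_rss", None, None, "residual sum of squares"),
}

_MODEL_COLORS = {"hrf": "tab:red", "boxcar": "tab:blue"}


def plot_summary(summary: pd.DataFrame, quantity: str, path) -> None:
    """One panel per (TR, ISI) cell: mean ± 95% CI versus tSNR, per model."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if quantity not in _QUANTITIES:
        raise ValueError(f"quantity must be one of {sorted(_QUANTITIES)}")
    mean_col, lo_col, hi_col, ylabel = _QUANTITIES[quantity]
    cells = sorted(set(zip(summary["TR"], summary["ISI"])))
    ncol = min(5, len(cells))
    nrow = -(-len(cells) // ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.6 * nrow),
                             squeeze=False, sharex=True)
    for ax, (tr, isi) in zip(axes.ravel(), cells):
        cell = summary[(summary["TR"] == tr) & (summary["ISI"] == isi)]
        for model, g in cell.groupby("model"):
            g = g.sort_values("tsnr_db")
            color = _MODEL_COLORS.get(model)
            ax.plot(g["tsnr_db"], g[mean_col], label=model, color=color)
            if lo_col is not None:
                ax.fill_between(g["tsnr_db"], g[lo_col], g[hi_col],
                                alpha=0.25, color=color)
        if quantity in ("t", "rss"):
            ax.set_yscale("log")
        ax.set_title(f"TR={tr:g}s, ISI={isi:g}s", fontsize=9)
        ax.set_xlabel("tSNR (dB)")
        ax.set_ylabel(ylabel, fontsize=8)
    for ax in axes.ravel()[len(cells):]:
        ax.set_visible(False)
    axes[0, 0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
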