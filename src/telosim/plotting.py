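"""Matplotlib renderings of the standard views of a run or sweep."""

from __future__ import annotations

import numpy as np

from .observables import RunRecord


def plot_run(record: RunRecord, fig=None):
    """Three-panel trajectory view: N(t), telomere distribution, <M>(t)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if fig is None:
        fig, axes = plt.subplots(3, 1, figsize=(6, 9), sharex=True)
    else:
        axes = fig.subplots(3, 1, sharex=True)
    t = record.times
    axes[0].plot(t, record.population_size, lw=1)
    axes[0].axhline(record.params.longevity_threshold, ls="--", c="gray", lw=0.8)
    axes[0].set_ylabel("dividing cells N")
    if record.telomere_histogram is not None:
        h = record.telomere_histogram.astype(float).T
        n_t = h.shape[1]
        axes[1].pcolormesh(t[:n_t], record.histogram_edges[:-1] / 1000.0, h,
                           cmap="viridis", shading="auto")
    axes[1].plot(t, record.mean_telomere / 1000.0, "w:" ,lw=1.5)
    axes[1].axhline(record.params.critical_telomere / 1000.0, c="r", lw=0.8)
    axes[1].set_ylabel("telomere length (kb)")
    axes[2].plot(t, record.mean_mutations, lw=1)
    axes[2].set_ylabel("mean mutations <M>")
    axes[2].set_xlabel("time (cell doublings)")
    fig.tight_layout()
    return fig


def plot_sweep(table, fig=None):
    """Heatmaps of R_M and R_L over the (realized <D>, CV) grid."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    df = table.ratios_frame()
    if fig is None:
        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    else:
        axes = fig.subplots(1, 2)
    for ax, col, label in ((axes[0], "r_m", "$R_M$"), (axes[1], "r_l", "$R_L$")):
        sc = ax.scatter(df["realized_damage"], df["cv"], c=df[col],
                        cmap="coolwarm", vmin=min(0.5, df[col].min()),
                        vmax=max(1.5, df[col].max()), s=120, marker="s")
        fig.colorbar(sc, ax=ax, label=label)
        ax.set_xlabel(r"realized mean damage $\langle D\rangle$")
        ax.set_ylabel(r"damage CV $\sigma_D/\langle D\rangle$")
        ax.set_title(label)
    fig.tight_layout()
    return fig
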