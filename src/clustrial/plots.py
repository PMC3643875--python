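"""Optional figures: type-I-error-vs-ICC panels and the power-loss curve."""

from __future__ import annotations

from pathlib import Path

import numpy as np


def plot_study_panels(study, path: str | Path) -> None:
    """One panel per (J, N) design: type I error against ICC by mechanism and analysis."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = study.table
    designs = sorted(set(zip(t["n_clusters"], t["n_patients"])))
    fig, axes = plt.subplots(1, len(designs), figsize=(4 * len(designs), 3.2), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, (j, n) in zip(axes, designs):
        sub = t[(t["n_clusters"] == j) & (t["n_patients"] == n)]
        for mech in sorted(sub["mechanism"].unique()):
            for method, ls in (("unadjusted", "-"),):
                sel = sub[(sub["mechanism"] == mech) & (sub["method"] == method)]
                ax.plot(sel["icc"], sel["rate"], ls, marker="o", label=f"{mech} {method}")
            adj = sub[(sub["mechanism"] == mech) & (sub["method"] != "unadjusted")]
            ax.plot(adj["icc"], adj["rate"], "--", marker="s", label=f"{mech} adjusted")
        ax.axhline(study.alpha, color="grey", lw=0.8)
        ax.set_title(f"J={j}, N={n}")
        ax.set_xlabel("ICC")
    axes[0].set_ylabel("type I error rate")
    axes[-1].legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_power_loss(path: str | Path, target_power: float = 0.80, alpha: float = 0.05) -> None:
    """Loss in power against ICC for a trial powered at ``target_power``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .study import power_loss

    icc = np.linspace(0, 0.5, 101)
    loss = [power_loss(r, target_power, alpha) for r in icc]
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    ax.plot(icc, loss)
    ax.set_xlabel("ICC")
    ax.set_ylabel("loss in power")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
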