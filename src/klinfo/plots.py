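"""Diagnostic figures: synaptic transfer functions and architecture sketch.

These plots involve no computation beyond the logistic output function and
parameter lookup; they visualize why cells saturate (information gating,
left/right response asymmetries).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .circuit import CELLS, CircuitParams, sigmoid


def plot_transfer_functions(params: CircuitParams, path: str | Path) -> None:
    """Per-cell synaptic transfer function over the plausible input range."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.linspace(-15.0, 15.0, 400)
    fig, axes = plt.subplots(2, 4, figsize=(14, 6), sharey=True)
    for ax, cell in zip(axes.ravel(), CELLS):
        theta = getattr(params, f"theta_{cell}")
        ax.plot(x, sigmoid(x + theta))
        ax.axvline(0.0, color="k", lw=0.5, ls="--")
        ax.set_title(f"{cell} (theta={theta:.2f})")
        ax.set_xlabel("membrane potential")
    axes[0, 0].set_ylabel("synaptic output")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_architecture(arch, path: str | Path) -> None:
    """Node-and-arrow sketch of an information architecture."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pos = {
        "ASEL": (0.35, 1.0), "ASER": (0.65, 1.0),
        "AIYL": (0.35, 0.75), "AIYR": (0.65, 0.75),
        "AIZL": (0.35, 0.5), "AIZR": (0.65, 0.5),
        "SMBDL": (0.2, 0.25), "SMBVL": (0.4, 0.25),
        "SMBDR": (0.6, 0.25), "SMBVR": (0.8, 0.25),
        "neck": (0.5, 0.02),
    }
    fig, ax = plt.subplots(figsize=(7, 8))
    max_te = max((e["te"] for e in arch.edges.values()), default=1.0) or 1.0
    for key, e in arch.edges.items():
        src, dst = key.split("->")
        (x0, y0), (x1, y1) = pos[src], pos[dst]
        ax.annotate(
            "",
            xy=(x1, y1),
            xytext=(x0, y0),
            arrowprops=dict(
                arrowstyle="-|>",
                lw=0.5 + 3.0 * e["te"] / max_te,
                color="red" if e["kind"] == "gap" else "steelblue",
                alpha=0.8,
            ),
        )
    for name, n in arch.nodes.items():
        x, y = pos[name]
        ax.scatter([x], [y], s=900, c=[[n["pos"], 0.2, n["neg"]]],
                   alpha=0.3 + 0.7 * min(n["mi"], 1.0), zorder=3)
        ax.text(x, y, name, ha="center", va="center", fontsize=8, zorder=4)
    ax.set_xlim(0, 1)
    ax.set_ylim(-0.05, 1.1)
    ax.axis("off")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
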