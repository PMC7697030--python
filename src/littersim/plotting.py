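"""Map and diagnostic rendering (matplotlib)."""

from __future__ import annotations

from pathlib import Path

import numpy as np


def plot_surface(values, grid, ax=None, title="", cbar_label="", cmap="viridis"):
    """Render a flat node vector as an image in grid coordinates."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(3, 7))
    img = grid.to_image(np.asarray(values))
    extent = (
        grid.origin[0], grid.origin[0] + grid.nx * grid.cell,
        grid.origin[1], grid.origin[1] + grid.ny * grid.cell,
    )
    im = ax.imshow(img, origin="lower", extent=extent, cmap=cmap, aspect="equal")
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    ax.set_title(title)
    ax.figure.colorbar(im, ax=ax, label=cbar_label, shrink=0.7)
    return ax


def plot_accuracy(curve, ax=None, label=None):
    """Nominal probability vs observed coverage with the identity diagonal."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.plot([0, 1], [0, 1], "k--", lw=1)
    ax.plot(curve.probs, curve.coverage, "o-", label=label)
    ax.set_xlabel("probability interval p")
    ax.set_ylabel("observed coverage")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    if label:
        ax.legend()
    return ax


def save_pipeline_plots(stack, risk, validation, outdir):
    """Write the standard pipeline figures as PNGs under ``outdir``."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    grid = stack.grid
    etype = stack.etype_mean()
    fig, axes = plt.subplots(1, 2, figsize=(7, 7))
    for v, name in enumerate(stack.var_names):
        plot_surface(etype[:, v], grid, ax=axes[v], title=f"E-type {name}",
                     cbar_label="items/m$^2$")
    fig.tight_layout()
    fig.savefig(outdir / "etype.png", dpi=150)
    plt.close(fig)

    fig, axes = plt.subplots(1, 3, figsize=(10, 7))
    plot_surface(risk.butt_class_map, grid, ax=axes[0],
                 title="butt class", cmap="YlOrRd")
    plot_surface(risk.sharp_class_map, grid, ax=axes[1],
                 title="sharp-item risk", cmap="YlOrRd")
    plot_surface(risk.exceedance, grid, ax=axes[2],
                 title=f"P(sharp $\\geq$ {risk.exceedance_threshold:g}/m$^2$)",
                 cmap="magma")
    fig.tight_layout()
    fig.savefig(outdir / "risk_maps.png", dpi=150)
    plt.close(fig)

    if validation is not None and validation.coverage is not None:
        fig, ax = plt.subplots(figsize=(4, 4))
        for name, curve in zip(validation.var_names, validation.coverage):
            plot_accuracy(curve, ax=ax, label=name)
        fig.tight_layout()
        fig.savefig(outdir / "accuracy.png", dpi=150)
        plt.close(fig)
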