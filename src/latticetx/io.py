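"""Plain-text writers for lattice snapshots and run series."""

from __future__ import annotations

import numpy as np

from .lattice import Lattice


def write_snapshot_csv(lattice: Lattice, path) -> None:
    """Integer-coded occupancy matrix (0 empty, 1 sensitive, 2 resistant)."""
    np.savetxt(path, lattice.grid, fmt="%d", delimiter=",")


def read_snapshot_csv(path) -> Lattice:
    return Lattice(np.loadtxt(path, dtype=np.int8, delimiter=","))


def write_snapshot_png(lattice: Lattice, path) -> None:
    """Optional PNG rendering (empty white, sensitive blue, resistant red)."""
    import matplotlib

    matplotlib.use("Agg")
    from matplotlib import colors, pyplot as plt

    cmap = colors.ListedColormap(["white", "#4878d0", "#d65f5f"])
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(lattice.grid, cmap=cmap, vmin=0, vmax=2, interpolation="nearest")
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)
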