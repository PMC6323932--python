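"""Optional PNG rendering of fingerprint matrices and projection globes.

matplotlib is imported lazily so the core library carries no plotting
dependency.
"""

from __future__ import annotations

from .fingerprints import FingerprintMatrix
from .probabilistic import ProjectionGlobe

__all__ = ["plot_fingerprint", "plot_globe"]


def _color_map(names):
    import matplotlib.pyplot as plt

    palette = plt.get_cmap("tab10")
    ordered = sorted(set(names), key=lambda n: (n not in ("0_1", "k0.1"), n))
    return {n: ("#d9d9d9" if n in ("0_1", "k0.1") else palette(i % 10))
            for i, n in enumerate(ordered)}


def plot_fingerprint(matrix: FingerprintMatrix, path) -> None:
    """Lower-triangular heat map: x = subchain start, y = end, colour = type."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Patch

    names = [t.name for t, _ in matrix.cells.values()]
    colors = _color_map(names)
    fig, ax = plt.subplots(figsize=(6, 6))
    size = max(4, 300 // max(1, len(matrix.residue_ids) // matrix.stride))
    for (s, e), (t, _p) in matrix.cells.items():
        ax.scatter(s, e, marker="s", s=size ** 2, color=colors[t.name])
    ax.set_xlabel("subchain start (residue)")
    ax.set_ylabel("subchain end (residue)")
    ax.set_title(f"{matrix.kind} fingerprint (stride {matrix.stride})")
    handles = [Patch(color=c, label=n) for n, c in colors.items()]
    ax.legend(handles=handles, loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_globe(globe: ProjectionGlobe, path) -> None:
    """Equirectangular map of the projection sphere coloured by knotoid type."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Patch

    rows = globe.to_rows()
    colors = _color_map([name for _, _, name in rows])
    fig, ax = plt.subplots(figsize=(8, 4))
    for theta, phi, name in rows:
        ax.scatter(phi, theta, color=colors[name], s=25)
    ax.set_xlabel("azimuth phi (rad)")
    ax.set_ylabel("polar angle theta (rad)")
    ax.invert_yaxis()
    ax.set_title("projection globe: knotoid type per viewing direction")
    handles = [Patch(color=c, label=n) for n, c in colors.items()]
    ax.legend(handles=handles, loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
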