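"""Figure-style rendering of sweep results."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .errors import InvalidParameterError


def _pivot(df: pd.DataFrame, value: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    piv = df.pivot(index="g_mi_nS", columns="g_leak_nS", values=value)
    return piv.columns.to_numpy(), piv.index.to_numpy(), piv.to_numpy()


def render_sweep_maps(sweep: pd.DataFrame, out_prefix, boundary: pd.DataFrame | None = None):
    """Heatmaps of bursts and spikes per window over the (g_leak, g_MI) plane.

    Values are rendered losslessly (one raster cell per sweep record, no
    smoothing).  The optional boundary table overlays the maximum-rescuable
    I_MI curve as a white line.  Returns the two written paths.
    """
    required = {"g_leak_nS", "g_mi_nS", "n_bursts", "n_spikes"}
    missing = required - set(sweep.columns)
    if missing:
        raise InvalidParameterError(f"sweep table missing column(s) {sorted(missing)}")
    if len(sweep) == 0:
        raise InvalidParameterError("sweep table is empty")
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = []
    for value, label in (("n_bursts", "LG bursts / window"),
                         ("n_spikes", "LG spikes / window")):
        gl, gmi, z = _pivot(sweep, value)
        fig, ax = plt.subplots(figsize=(6, 4.5))
        mesh = ax.pcolormesh(gl, gmi, z, cmap="inferno", shading="nearest")
        fig.colorbar(mesh, ax=ax, label=label)
        if boundary is not None and {"g_leak_nS", "max_g_mi_nS"} <= set(boundary.columns):
            b = boundary.dropna(subset=["max_g_mi_nS"])
            ax.plot(b["g_leak_nS"], b["max_g_mi_nS"], color="white", lw=2,
                    label="max rescuable I_MI")
            ax.legend(loc="upper left", fontsize=8)
        ax.set_xlabel("LG leak conductance (nS)")
        ax.set_ylabel("LG I_MI maximal conductance (nS)")
        path = out_prefix.with_name(out_prefix.name + f"_{value}.png")
        fig.savefig(path, dpi=150)
        plt.close(fig)
        paths.append(path)
    return paths
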