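"""Non-interactive figures: group-mean normalized curves and delta-V bands."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_curves(curves, out_dir) -> list[Path]:
    """One PNG per window: mean V(t) per group plus delta-V vs control."""
    out_dir = Path(out_dir)
    paths = []
    for window, sub in curves.groupby("window"):
        fig, (ax_v, ax_d) = plt.subplots(2, 1, sharex=True, figsize=(6, 6))
        for group, g in sub.groupby("group"):
            ax_v.semilogx(g["time_ms"], g["v_mean"], label=str(group))
            ax_d.semilogx(g["time_ms"], g["delta_v_vs_control"])
        ax_v.set_ylabel(f"V ({window})")
        ax_v.legend(fontsize="small")
        ax_d.set_ylabel("delta V vs control")
        ax_d.set_xlabel("time (ms)")
        ax_d.axhline(0.0, color="k", lw=0.5)
        fig.tight_layout()
        path = out_dir / f"curves_{window.replace('-', '')}.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        paths.append(path)
    return paths
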