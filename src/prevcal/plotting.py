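"""Static metric-vs-prevalence plots (the straight line and the umbrella)."""

from __future__ import annotations

from pathlib import Path

from .calibration import SweepCurve, calibrated_metric

__all__ = ["plot_sweep"]


def plot_sweep(
    curve: SweepCurve,
    path: str | Path | None = None,
    ax=None,
    *,
    mark_balanced: bool = True,
):
    """Plot a sweep curve; a dot marks the balanced (prevalence 0.5) value.

    Returns the matplotlib Axes.  If *path* is given the figure is saved
    there (suffix selects PNG/SVG/...).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    grid, values = curve.to_arrays()
    ax.plot(grid, values, color="tab:blue", lw=1.5)
    if mark_balanced:
        balanced = calibrated_metric(curve.metric, curve.sen, curve.spe, 0.5)
        ax.plot([0.5], [balanced], "o", color="tab:red", zorder=3)
        ax.annotate(
            f"{balanced:.3f}", (0.5, balanced), textcoords="offset points", xytext=(6, 6)
        )
    ax.set_xlabel("positive prevalence")
    ax.set_ylabel(curve.metric)
    ax.set_xlim(0.0, 1.0)
    ax.set_title(f"{curve.metric} vs prevalence (sen={curve.sen:g}, spe={curve.spe:g})")
    ax.grid(True, alpha=0.3)
    if path is not None:
        ax.figure.savefig(Path(path), dpi=150, bbox_inches="tight")
    return ax
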