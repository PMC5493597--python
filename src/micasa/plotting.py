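"""Confidence-band plots on a log-frequency axis labelled in micrometres.

Curves are drawn as filled bands spanning [ci_lower, ci_upper]; plotting
two conditions together lets the reader do statistics by eye — wherever
the bands separate, the conditions differ at the bands' confidence
level.  The abscissa is logarithmic in spatial frequency but ticks are
labelled with the corresponding length scale 1/f in micrometres, so a
feature's physical scale can be read off directly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
from matplotlib.figure import Figure

from .stats import CURVE_NAMES, MiCASAResult

__all__ = ["plot_result", "length_scale_ticks"]

_NICE_SCALES_UM = (
    1, 2, 4, 8, 10, 20, 40, 80, 100, 200, 400, 800,
    1000, 2000, 4000, 8000, 10000, 20000, 40000,
)

_TITLES = {
    "log_spectrum_a": "log-spectrum (channel A)",
    "log_spectrum_b": "log-spectrum (channel B)",
    "atanh_coherence": "atanh-coherence",
    "var_log_spectrum_a": "variance of log-spectrum (A)",
    "var_log_spectrum_b": "variance of log-spectrum (B)",
    "var_atanh_coherence": "variance of atanh-coherence",
}

_COLORS = ("tab:green", "tab:gray", "tab:red", "tab:blue")


def length_scale_ticks(
    f_min: float, f_max: float
) -> tuple[list[float], list[str]]:
    """Tick frequencies and um labels covering [f_min, f_max].

    Ticks sit at frequencies ``1/s`` for round length scales ``s`` (um);
    each label is the length scale itself, e.g. the tick at frequency
    1/400 is labelled "400".
    """
    ticks, labels = [], []
    for s in _NICE_SCALES_UM:
        f = 1.0 / s
        if f_min <= f <= f_max:
            ticks.append(f)
            labels.append(str(s))
    return ticks[::-1], labels[::-1]  # increasing frequency order


def plot_result(
    results: MiCASAResult | Sequence[MiCASAResult],
    path: str | Path,
    curves: Sequence[str] = CURVE_NAMES,
) -> Path:
    """Plot one or more results as overlaid confidence bands.

    One panel per requested curve; a zero-width interval degenerates to a
    line.  The figure is written to ``path`` (PNG or PDF by suffix).
    """
    if isinstance(results, MiCASAResult):
        results = [results]
    n = len(curves)
    ncols = min(n, 3)
    nrows = int(np.ceil(n / ncols))
    fig = Figure(figsize=(4.2 * ncols, 3.2 * nrows))
    axes = fig.subplots(nrows, ncols, squeeze=False).ravel()

    for ax, name in zip(axes, curves):
        for res, color in zip(results, _COLORS):
            ci = res.curve(name)
            good = ~ci.mask
            f = ci.grid.frequencies[good]
            ax.fill_between(
                f, ci.ci_lower[good], ci.ci_upper[good],
                alpha=0.45, color=color, label=res.label, linewidth=0,
            )
            ax.plot(f, ci.estimate[good], color=color, linewidth=0.8)
        ax.set_xscale("log")
        f_min = min(r.grid.frequencies[0] for r in results)
        f_max = max(r.grid.frequencies[-1] for r in results)
        ticks, labels = length_scale_ticks(f_min, f_max)
        if ticks:
            ax.set_xticks(ticks)
            ax.set_xticklabels(labels)
            ax.minorticks_off()
        ax.set_xlabel("length scale (µm)")
        ax.set_title(_TITLES.get(name, name), fontsize=10)
    for ax in axes[n:]:
        ax.set_visible(False)
    if len(results) > 1:
        axes[0].legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    return path
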