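"""Histogram and sweep figures.

The single-cell histogram mimics the dynamic report sheet: frequency columns
labelled by class upper limit, cut-off classes highlighted, the dashed
cut-off line, the nominal value marked by a diamond, a Gaussian overlay, and
the statistics panel printed beneath (population statistics left, cut-off
statistics right).
"""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy import stats as _st

from .stats import SweepCell


def histogram_figure(cell: SweepCell, nominal: float, ax=None):
    if ax is None:
        fig, ax = plt.subplots(figsize=(7, 5))
        fig.subplots_adjust(bottom=0.32)
    else:
        fig = ax.figure
    dist, st, cut = cell.distribution, cell.stats, cell.cutoff
    width = dist.class_width
    centers = dist.class_edges[:-1] + width / 2.0
    included = dist.counts >= cut.count_threshold
    colors = np.where(included, "forestgreen", "lightsteelblue")
    ax.bar(centers, dist.counts, width=width * 0.92, color=colors, edgecolor="none")
    ax.axhline(cut.count_threshold, linestyle="--", color="dimgray", linewidth=1)
    if st.sd_population > 0:
        x = np.linspace(dist.class_edges[0], dist.class_edges[-1], 300)
        gauss = _st.norm.pdf(x, st.mean, st.sd_population) * dist.n_total * width
        ax.plot(x, gauss, color="saddlebrown", linewidth=1.5)
    ax.plot(
        [nominal], [0], marker="D", color="royalblue", markersize=9, clip_on=False
    )
    ax.set_xticks(dist.upper_limits[:: max(1, dist.n_classes // 10)])
    ax.set_xlabel("GMO % (class upper limit)")
    ax.set_ylabel("frequency")
    ax.set_title(f"{cell.setting_id}, 2x{cell.k} replicates")
    left = (
        f"Average: {st.mean:.4f}%\n"
        f"StdDevP: {st.sd_population:.4f}%  (rel. {st.rsd:.1f}%)\n"
        f"rel. |Deviation|: {st.rel_abs_deviation:.1f}%\n"
        f"SkewnessP: {st.skewness:.3f}\n"
        f"ChiSq. Norm.Distr.: {100 * st.chi_p:.1f}%"
    )
    right = (
        f"cut-off: {100 * cut.coverage_target:.0f}%"
        f" (achieved {100 * cut.achieved_coverage:.1f}%)\n"
        f"middle class: {cut.middle_class:.4f}%\n"
        f"± {cut.half_range:.4f}%\n"
        f"count threshold: {cut.count_threshold}"
    )
    fig.text(0.08, 0.02, left, fontsize=8, va="bottom", family="monospace")
    fig.text(0.60, 0.02, right, fontsize=8, va="bottom", family="monospace")
    return fig


def grid_figure(results, ks: Sequence[int] | None = None):
    """Settings left to right, increasing replicate numbers top to bottom."""
    settings = results.model.experiment.setting_ids
    if ks is None:
        ks = [k for k in (2, 4, 6, 8) if k in results.model.ks] or list(results.model.ks)[:4]
    fig, axes = plt.subplots(
        len(ks), len(settings), figsize=(3 * len(settings), 2.4 * len(ks)), squeeze=False
    )
    nominal = results.model.nominal
    for i, k in enumerate(ks):
        for j, sid in enumerate(settings):
            ax = axes[i][j]
            cell = results.grid[(sid, k)]
            dist = cell.distribution
            width = dist.class_width
            centers = dist.class_edges[:-1] + width / 2.0
            ax.bar(centers, dist.counts, width=width * 0.92, color="steelblue")
            ax.plot([nominal], [0], marker="D", color="gray", markersize=5, clip_on=False)
            ax.set_xticks([])
            ax.set_yticks([])
            if i == 0:
                ax.set_title(sid, fontsize=9)
            if j == 0:
                ax.set_ylabel(f"2x{k}", fontsize=9)
    fig.tight_layout()
    return fig


def rsd_curve_figure(results, ax=None):
    """Relative SD versus replicate number, one line per setting, with the
    RSD threshold and the minimum qualifying k marked."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 4))
    else:
        fig = ax.figure
    ks = sorted({k for _, k in results.grid})
    for sid in results.model.experiment.setting_ids:
        rsd = [results.grid[(sid, k)].stats.rsd for k in ks]
        ax.plot(ks, rsd, marker="o", markersize=3, label=sid)
    thr = results.model.rsd_threshold
    ax.axhline(thr, linestyle=":", color="gray")
    k_min = results.min_replicates()
    if k_min is not None:
        ax.plot([k_min], [thr], marker="D", color="green", markersize=9)
    ax.set_xlabel("replicates per isolation (2x k)")
    ax.set_ylabel("rel. StdDevP [%]")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig
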