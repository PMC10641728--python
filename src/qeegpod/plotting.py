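"""Mean ± SEM bar summaries of a fitted group comparison."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .stats import GroupComparisonResults

_LABELS = {
    "spectral_entropy": "SE",
    "aeeg_upper_uv": "aEEG upper (µV)",
    "aeeg_lower_uv": "aEEG lower (µV)",
    "rav_percent": "RAV (%)",
    "delta_percent": "delta (%)",
    "theta_percent": "theta (%)",
    "alpha_percent": "alpha (%)",
    "beta_percent": "beta (%)",
    "sef95_hz": "SEF95 (Hz)",
}


def plot_comparison(results: GroupComparisonResults, features=None, ax_per_row: int = 3):
    """One mean ± SEM bar panel per feature, annotated with the p value."""
    feats = list(features) if features is not None else list(results.table.index)
    n = len(feats)
    ncol = min(ax_per_row, n)
    nrow = int(np.ceil(n / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.8 * nrow), squeeze=False)
    groups = results.group_summaries
    for k, feat in enumerate(feats):
        ax = axes[k // ncol][k % ncol]
        means = [results.table.loc[feat, f"mean_{g.label}"] for g in groups]
        sems = [results.table.loc[feat, f"sem_{g.label}"] for g in groups]
        ax.bar(range(len(groups)), means, yerr=sems, capsize=4,
               color=["#4878a8", "#c44e52", "#55a868", "#8172b2"][: len(groups)])
        ax.set_xticks(range(len(groups)))
        ax.set_xticklabels([g.label for g in groups], rotation=15)
        ax.set_title(
            f"{_LABELS.get(feat, feat)}  (p={results.table.loc[feat, 'p_value']:.4f})",
            fontsize=9,
        )
    for k in range(n, nrow * ncol):
        axes[k // ncol][k % ncol].axis("off")
    fig.tight_layout()
    return fig
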