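"""Decision and survival plots (matplotlib, Agg backend)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .selection import CONFIRMED, REJECTED, TENTATIVE, BorutaResult

_DECISION_COLOURS = {CONFIRMED: "tab:green", TENTATIVE: "gold", REJECTED: "tab:red"}


def boruta_decision_plot(result: BorutaResult, path) -> None:
    """Boxplots of per-iteration feature Z-scores, coloured by decision.

    Z-scores standardise each iteration's importances against the shadow
    mean/sd; blue boxes show the min/mean/max shadow summaries.  Mirrors the
    customary all-relevant selection diagnostic.
    """
    z = result.z_scores()
    sh = result.shadow_history
    sd = sh["sd"].replace(0.0, np.nan)
    shadow_z = pd.DataFrame({
        "shadowMin": (sh["min"] - sh["mean"]) / sd,
        "shadowMean": 0.0 * sd,
        "shadowMax": (sh["max"] - sh["mean"]) / sd,
    })
    medians = z.median()
    order = list(medians.sort_values().index)
    data = [shadow_z[c].dropna().to_numpy() for c in shadow_z.columns]
    labels = list(shadow_z.columns)
    colours = ["tab:blue"] * 3
    for feat in order:
        data.append(z[feat].dropna().to_numpy())
        labels.append(feat)
        colours.append(_DECISION_COLOURS[result.decision[feat]])

    fig, ax = plt.subplots(figsize=(max(8, 0.28 * len(labels)), 5))
    bp = ax.boxplot([d if len(d) else [np.nan] for d in data], patch_artist=True,
                    showfliers=False)
    for patch, colour in zip(bp["boxes"], colours):
        patch.set_facecolor(colour)
    ax.set_xticks(range(1, len(labels) + 1))
    ax.set_xticklabels(labels, rotation=90, fontsize=6)
    ax.set_ylabel("importance Z-score")
    ax.set_title(f"Shadow-feature selection ({result.iterations_run} iterations)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def km_plot(curves: dict[str, pd.DataFrame], path, title: str = "",
            p_value: float | None = None) -> None:
    """Step plot of per-group product-limit survival curves."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for group, curve in curves.items():
        ax.step(curve["time"], curve["survival"], where="post", label=group)
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    if p_value is not None:
        ax.text(0.02, 0.05, f"log-rank p = {p_value:.3g}", transform=ax.transAxes)
    ax.legend()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
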