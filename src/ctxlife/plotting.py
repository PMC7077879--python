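"""Lightweight reporting plots: QQ, reaction norms, effect correlations."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["qq_plot", "reaction_norms", "effect_scatter"]


def qq_plot(pvalues, path=None, ax=None, title="QQ plot"):
    """Observed vs expected -log10 p under the uniform null."""
    p = np.sort(np.asarray(pvalues, float))
    p = p[np.isfinite(p) & (p > 0)]
    exp = -np.log10((np.arange(1, len(p) + 1) - 0.5) / len(p))
    obs = -np.log10(p)
    if ax is None:
        fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(exp, obs, ".", ms=3)
    lim = max(exp.max(), obs.max())
    ax.plot([0, lim], [0, lim], "k--", lw=1)
    ax.set_xlabel("expected -log10 p")
    ax.set_ylabel("observed -log10 p")
    ax.set_title(title)
    if path:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def reaction_norms(line_means: pd.DataFrame, x: str, value: str, path=None,
                   ax=None, title="Reaction norms"):
    """One line per genotype across contexts (sexes or temperatures)."""
    wide = line_means.pivot_table(index="line", columns=x, values=value, observed=True)
    if ax is None:
        fig, ax = plt.subplots(figsize=(4, 4))
    for _, row in wide.iterrows():
        ax.plot(range(wide.shape[1]), row.to_numpy(), "-", color="gray", alpha=0.3, lw=0.7)
    ax.set_xticks(range(wide.shape[1]), [str(c) for c in wide.columns])
    ax.set_xlabel(x)
    ax.set_ylabel(value)
    ax.set_title(title)
    if path:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def effect_scatter(effects_a, effects_b, labels=("context A", "context B"),
                   path=None, ax=None):
    """Per-variant effects in one context against another."""
    a = np.asarray(effects_a, float)
    b = np.asarray(effects_b, float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ax is None:
        fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(a[ok], b[ok], ".", ms=3, alpha=0.5)
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5)
    r = np.corrcoef(a[ok], b[ok])[0, 1] if ok.sum() > 2 else np.nan
    ax.set_xlabel(labels[0])
    ax.set_ylabel(labels[1])
    ax.set_title(f"r = {r:.2f}")
    if path:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
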