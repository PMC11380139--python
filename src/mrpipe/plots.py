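"""Minimal diagnostic plots: forest, funnel and scatter views of MR results.

These are deliberately plain matplotlib renderings of the same tables the
pipeline writes to disk; the TSVs are the primary output.
"""

from __future__ import annotations

import numpy as np


def _agg():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def forest_plot(results_df, path) -> None:
    """Forest plot of OR (95% CI) per exposure/outcome/method row."""
    plt = _agg()
    df = results_df.reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(7, max(2, 0.4 * len(df) + 1)))
    y = np.arange(len(df))[::-1]
    ax.errorbar(df["or"], y,
                xerr=[df["or"] - df["ci_low"], df["ci_high"] - df["or"]],
                fmt="s", color="black", ecolor="gray", capsize=3)
    ax.axvline(1.0, color="red", lw=0.8, ls="--")
    labels = [f"{r.exposure} → {r.outcome} [{r.method}]"
              for r in df.itertuples()]
    ax.set_yticks(y, labels, fontsize=8)
    ax.set_xlabel("OR (95% CI)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def funnel_plot(funnel_df, lines, path) -> None:
    """Per-SNP ratio vs precision with IVW/Egger reference lines."""
    plt = _agg()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(funnel_df["ratio"], funnel_df["precision"], s=16, alpha=0.7)
    if "ivw_beta" in lines:
        ax.axvline(lines["ivw_beta"], color="tab:blue", lw=1, label="IVW")
    if "egger_beta" in lines:
        ax.axvline(lines["egger_beta"], color="tab:orange", lw=1, label="Egger")
    ax.set_xlabel("per-SNP ratio estimate")
    ax.set_ylabel("precision (|bx| / se_out)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def scatter_plot(h, results, path) -> None:
    """SNP effect scatter (bx vs by) with fitted slopes per method."""
    plt = _agg()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(h.bx, h.by, xerr=h.sx, yerr=h.sy, fmt="o", ms=4,
                color="black", ecolor="lightgray")
    xs = np.linspace(min(0, h.bx.min()), h.bx.max() * 1.05, 50)
    for name, res in results.items():
        intercept = res.extras.get("intercept", 0.0)
        ax.plot(xs, intercept + res.beta * xs, lw=1, label=name)
    ax.set_xlabel("SNP effect on exposure")
    ax.set_ylabel("SNP effect on outcome")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
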