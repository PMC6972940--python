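"""Static plot exports (Manhattan, QQ, coverage decay)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def manhattan(table: pd.DataFrame, threshold: float, path) -> None:
    """Manhattan plot from an association table with marker ids ``chrom_pos``."""
    df = table.copy()
    parts = df["marker"].str.rsplit("_", n=1, expand=True)
    df["chrom"], df["pos"] = parts[0], parts[1].astype(int)
    df = df.sort_values(["chrom", "pos"])
    fig, ax = plt.subplots(figsize=(8, 3))
    offset = 0
    for i, (chrom, sub) in enumerate(df.groupby("chrom", sort=True)):
        ax.scatter(sub["pos"] + offset, sub["neg_log10_p"], s=8,
                   color=f"C{i % 2}", label=chrom)
        offset += sub["pos"].max() + 1
    ax.axhline(threshold, color="red", linestyle=":")
    ax.set_xlabel("position")
    ax.set_ylabel(r"$-\log_{10} p$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def qq(pvalues, path) -> None:
    p = np.sort(np.asarray(pvalues, dtype=float))
    n = p.size
    exp = -np.log10((np.arange(n) + 0.5) / n)
    obs = -np.log10(np.clip(p, 1e-300, None))
    fig, ax = plt.subplots(figsize=(3.5, 3.5))
    ax.plot(exp, obs, ".", ms=4)
    lim = max(exp.max(), obs.max())
    ax.plot([0, lim], [0, lim], "k--", lw=0.8)
    ax.set_xlabel("expected $-\\log_{10} p$")
    ax.set_ylabel("observed $-\\log_{10} p$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def decay_curve(series, fit, path) -> None:
    ks = np.array([k for k, _ in series], dtype=float)
    ys = np.array([y for _, y in series], dtype=float)
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.plot(ks, ys / 1e6, "o", label="observed")
    kk = np.linspace(ks.min(), max(ks.max(), fit.n_converge), 200)
    ax.plot(kk, fit.predict(kk) / 1e6, "-", label="fit")
    ax.axhline(fit.A / 1e6, color="gray", linestyle=":")
    ax.set_xlabel("assemblies in panel (k)")
    ax.set_ylabel("core size (Mb)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
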