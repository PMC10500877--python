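"""Manhattan and Q-Q plots for selection-scan results."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def manhattan(table, ax=None, truncate=None, threshold=0.10):
    """Manhattan plot of -log10(q) by genome position.

    ``truncate`` caps the y-axis (the polygenic, genome-wide nature of weak
    signals is easier to see with a cap of 10).
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    logq = -np.log10(np.clip(table["q"].to_numpy(), 1e-300, None))
    offset = 0.0
    ticks, labels = [], []
    for i, (chrom, grp) in enumerate(table.groupby("chrom", sort=True)):
        x = grp["pos_bp"].to_numpy() + offset
        ax.scatter(x, logq[grp.index], s=4,
                   color="C0" if i % 2 == 0 else "C1", rasterized=True)
        ticks.append(offset + grp["pos_bp"].max() / 2)
        labels.append(str(chrom))
        offset += grp["pos_bp"].max()
    ax.axhline(-np.log10(threshold), color="red", lw=0.8, ls="--")
    if truncate is not None:
        ax.set_ylim(0, truncate)
    ax.set_xticks(ticks, labels, fontsize=7)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10}(q)$")
    return ax


def qq(pvalues, ax=None):
    """Q-Q plot of observed vs expected -log10(p) under the uniform null."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    p = np.sort(np.asarray(pvalues))
    n = p.size
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    observed = -np.log10(np.clip(p, 1e-300, None))
    ax.scatter(expected, observed, s=4, rasterized=True)
    lim = max(expected.max(), observed.max())
    ax.plot([0, lim], [0, lim], color="red", lw=0.8)
    ax.set_xlabel(r"expected $-\log_{10}(p)$")
    ax.set_ylabel(r"observed $-\log_{10}(p)$")
    return ax
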