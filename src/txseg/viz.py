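"""Single-gene segment visualization.

One figure with up to five aligned panels: (A) segment x exonic-bin
membership matrix, with full-bin spanning drawn in red and partial-bin
spanning in salmon; (B) transcript x bin membership; (C) segment counts
per sample, with significantly differential segments hatched; (D) segment
length bar chart; (E) transcript abundances when provided.  Bins are laid
out in transcription order, so minus-strand genes read right to left in
genomic coordinates.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import ListedColormap

from .annotation import GeneModel
from .library import Segment
from .preprocessing import ExonicBin

__all__ = ["plot_gene", "membership_matrix"]

_CMAP = ListedColormap(["#f5f5f5", "#fa8072", "#d62728"])  # none/partial/full


def membership_matrix(
    segments: Sequence[Segment], bins: Sequence[ExonicBin]
) -> np.ndarray:
    """0 = bin untouched, 1 = partially spanned, 2 = fully spanned."""
    bin_width = {b.bin_id: b.interval.width() for b in bins}
    order = {b.bin_id: k for k, b in enumerate(bins)}
    mat = np.zeros((len(segments), len(bins)), dtype=int)
    for i, seg in enumerate(segments):
        for bin_id, left, right in seg.genomic_spans:
            full = (right - left) == bin_width[bin_id]
            mat[i, order[bin_id]] = 2 if full else 1
    return mat


def plot_gene(
    gene_id: str,
    segments: Sequence[Segment],
    bins: Sequence[ExonicBin],
    gene: GeneModel,
    scm=None,
    tx_abundances: Optional[Dict[str, Dict[str, float]]] = None,
    diff_result=None,
    out_path=None,
    dpi: int = 150,
):
    """Render the multi-panel gene view; returns the figure."""
    segs = sorted(
        [s for s in segments if s.gene_id == gene_id],
        key=lambda s: s.seg_id,
    )
    if not segs:
        raise ValueError(f"gene {gene_id!r} not present in segment library")

    have_counts = scm is not None and any(
        s.seg_id in scm.counts.index for s in segs
    )
    have_tpm = bool(tx_abundances)
    n_rows = 3 + int(have_counts) + int(have_tpm)
    fig, axes = plt.subplots(
        n_rows,
        1,
        figsize=(max(6, 0.5 * len(bins) + 2), 2.2 * n_rows),
        constrained_layout=True,
    )
    axes = np.atleast_1d(axes)
    bin_labels = [str(b.bin_id) for b in bins]
    row = 0

    # A: segment-bin membership
    ax = axes[row]
    mat = membership_matrix(segs, bins)
    ax.imshow(mat, cmap=_CMAP, vmin=0, vmax=2, aspect="auto")
    ax.set_yticks(range(len(segs)), [s.seg_id for s in segs], fontsize=7)
    ax.set_xticks(range(len(bins)), bin_labels, fontsize=7)
    ax.set_title(
        f"{gene_id} ({gene.strand}) - segment/bin membership "
        "(red=full, salmon=partial)"
    )
    row += 1

    # B: transcript-bin membership
    ax = axes[row]
    tmat = np.zeros((len(gene.transcripts), len(bins)), dtype=int)
    for i, tx in enumerate(gene.transcripts):
        for k, b in enumerate(bins):
            if tx.tx_id in b.txs:
                tmat[i, k] = 2
    ax.imshow(tmat, cmap=_CMAP, vmin=0, vmax=2, aspect="auto")
    ax.set_yticks(
        range(len(gene.transcripts)),
        [t.tx_id for t in gene.transcripts],
        fontsize=7,
    )
    ax.set_xticks(range(len(bins)), bin_labels, fontsize=7)
    ax.set_title("transcript/bin membership")
    row += 1

    # C: segment counts (optional)
    if have_counts:
        ax = axes[row]
        sig = set()
        if diff_result is not None:
            tab = diff_result.segment_table
            sig = set(
                tab.loc[tab["pvalue"] < 0.05, "seg_id"].tolist()
            )
        idx = np.arange(len(segs))
        samples = scm.sample_ids
        width = 0.8 / max(len(samples), 1)
        for k, sample in enumerate(samples):
            vals = [
                float(scm.counts.loc[s.seg_id, sample])
                if s.seg_id in scm.counts.index
                else 0.0
                for s in segs
            ]
            hatches = ["//" if s.seg_id in sig else None for s in segs]
            bars = ax.bar(
                idx + k * width, vals, width=width, label=str(sample)
            )
            for b, h in zip(bars, hatches):
                if h:
                    b.set_hatch(h)
        ax.set_xticks(idx + 0.4, [s.seg_id for s in segs], fontsize=7)
        ax.set_title("segment counts (hatched = differential)")
        ax.legend(fontsize=6)
        row += 1

    # D: segment lengths
    ax = axes[row]
    ax.bar(range(len(segs)), [s.width for s in segs], color="#4878d0")
    ax.set_xticks(range(len(segs)), [s.seg_id for s in segs], fontsize=7)
    ax.set_title("segment length (bases)")
    row += 1

    # E: transcript abundances (optional)
    if have_tpm:
        ax = axes[row]
        tx_ids = [t.tx_id for t in gene.transcripts]
        samples = sorted(tx_abundances)
        width = 0.8 / max(len(samples), 1)
        idx = np.arange(len(tx_ids))
        for k, sample in enumerate(samples):
            vals = [tx_abundances[sample].get(t, 0.0) for t in tx_ids]
            ax.bar(idx + k * width, vals, width=width, label=str(sample))
        ax.set_xticks(idx + 0.4, tx_ids, fontsize=7)
        ax.set_title("transcript abundance (TPM)")
        ax.legend(fontsize=6)
        row += 1

    if out_path is not None:
        fig.savefig(out_path, dpi=dpi)
        plt.close(fig)
    return fig
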