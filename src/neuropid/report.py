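"""Visual analyses: per-sequence basic-residue graphics and feature histograms.

``render_sequence`` draws a sequence as a scalable baseline with red
marks over di/tribasic motif spans and green marks at single basic
residues, annotated with motif counts and density — the classical
precursor "beads on a string" view.  ``feature_histogram`` compares the
positive and negative training distributions of one feature, rescaled
to standard-deviation units ("Feature Units") about the pooled mean,
with a dashed marker for a query protein.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

from .motif_scan import MotifAnnotation
from .sequence_io import ProteinSequence

_SVG_NS = "http://www.w3.org/2000/svg"


def render_sequence(
    seq: ProteinSequence,
    annotation: MotifAnnotation,
    scale: float = 2.0,
    path: str | Path | None = None,
) -> str:
    """SVG drawing of one sequence's basic-residue landscape.

    Baseline length is proportional to sequence length (``scale`` px per
    residue).  Dibasic/tribasic spans are red rectangles, single basics
    green ticks; a text line reports counts and motif density per 100
    residues.  Returns the SVG markup; optionally also writes it.
    """
    width = seq.length * scale + 40
    height = 90.0
    y = 50.0
    n_motifs = annotation.n_dibasic + annotation.n_tribasic
    density = 100.0 * n_motifs / seq.length
    parts = [
        f'<svg xmlns="{_SVG_NS}" width="{width:.0f}" height="{height:.0f}" '
        f'viewBox="0 0 {width:.0f} {height:.0f}">',
        f'<line x1="20" y1="{y}" x2="{20 + seq.length * scale:.1f}" y2="{y}" '
        'stroke="black" stroke-width="2"/>',
    ]
    for start, end, cls in annotation.spans:
        x = 20 + (start - 1) * scale
        w = (end - start + 1) * scale
        if cls == "single":
            parts.append(
                f'<rect class="single" x="{x:.1f}" y="{y - 12}" '
                f'width="{w:.1f}" height="24" fill="green"/>'
            )
        else:
            parts.append(
                f'<rect class="{cls}" x="{x:.1f}" y="{y - 16}" '
                f'width="{w:.1f}" height="32" fill="red"/>'
            )
    parts.append(
        f'<text x="20" y="20" font-size="12">{seq.id} | {seq.length} aa | '
        f'{annotation.n_dibasic} dibasic, {annotation.n_tribasic} tribasic, '
        f'{annotation.n_single} single | {density:.2f} motifs/100aa | '
        f'IS={annotation.internal_score:.2f}</text>'
    )
    parts.append("</svg>")
    svg = "\n".join(parts)
    if path is not None:
        Path(path).write_text(svg)
    return svg


def feature_units(
    pos_values, neg_values, query_value: float,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Rescale both sets to SD units about the pooled mean.

    Each set is centred on the pooled mean and divided by its *own*
    standard deviation; the query is placed on the positive set's scale.
    A zero-variance set raises ``ValueError`` naming the set.
    """
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both sets must be nonempty")
    sd_pos = pos.std(ddof=0)
    sd_neg = neg.std(ddof=0)
    if sd_pos == 0:
        raise ValueError("positive set has zero variance")
    if sd_neg == 0:
        raise ValueError("negative set has zero variance")
    mu = np.concatenate([pos, neg]).mean()
    return (pos - mu) / sd_pos, (neg - mu) / sd_neg, (query_value - mu) / sd_pos


def feature_histogram(
    feature_name: str,
    pos_values,
    neg_values,
    query_value: float,
    bins: int | None = None,
    path: str | Path | None = None,
):
    """Matplotlib histogram of one feature in Feature Units.

    Positive set green, negative red, query as a dashed vertical line.
    ``bins`` defaults to Sturges' rule on the pooled sample size.
    Returns the figure; optionally saves it (SVG or any matplotlib
    format inferred from the path suffix).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pos_u, neg_u, query_u = feature_units(pos_values, neg_values, query_value)
    if bins is None:
        bins = int(math.ceil(math.log2(pos_u.size + neg_u.size) + 1))
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(pos_u, bins=bins, color="green", alpha=0.55, label="positive set")
    ax.hist(neg_u, bins=bins, color="red", alpha=0.55, label="negative set")
    ax.axvline(query_u, color="black", linestyle="--", label="query")
    ax.set_xlabel("Feature Units (SD about pooled mean)")
    ax.set_ylabel("count")
    ax.set_title(feature_name)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig
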