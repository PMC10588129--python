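"""Demultiplexing calls, rate summaries and cross-modality concordance.

Cells in a pooled single-cell run carry a posterior over their samples of
origin plus a multiplet class. Calls are made at a probability threshold
(0.90 by default in cellranger multi, commonly relaxed to 0.85 / 0.80);
summaries report assigned / multiplet / unassigned rates at the printed
1-decimal precision, and concordance compares two modalities (antibody hash
vs genetic) on the cells both assign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import round_half_away
from .errors import MalformedTableError
from .simulate import AssignmentTable

__all__ = [
    "DemuxLabels",
    "DemuxSummary",
    "ConcordanceReport",
    "call_assignments",
    "summarize_assignments",
    "concordance",
]

MULTIPLET = "multiplet"
UNASSIGNED = "unassigned"


@dataclass
class DemuxLabels:
    """Per-cell categorical demultiplexing calls at one threshold."""

    labels: pd.Series  # barcode -> sample id | "multiplet" | "unassigned"
    threshold: float


@dataclass
class DemuxSummary:
    """Counts and 1-decimal percentages of the three call classes."""

    n_total: int
    counts: dict  # {"assigned": int, "multiplet": int, "unassigned": int}
    percents: dict  # same keys, rounded half-away-from-zero to 1 decimal
    per_sample: pd.Series  # sample -> assigned cell count


@dataclass
class ConcordanceReport:
    """Confusion matrix between two label vectors over the same barcodes."""

    confusion: pd.DataFrame  # rows: labels of a, cols: labels of b
    percent_same: float | None  # over doubly-assigned cells; None if none exist
    n_doubly_assigned: int


def call_assignments(table: AssignmentTable, threshold: float) -> DemuxLabels:
    """Call each cell at a posterior-probability threshold.

    A cell whose multiplet class holds the maximum posterior is a multiplet
    regardless of the threshold; otherwise the best sample is called when its
    posterior reaches the threshold, with lexicographically smallest sample
    id breaking exact ties; everything else is unassigned.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    P = table.posteriors
    sums = P.to_numpy().sum(axis=1)
    bad = np.flatnonzero(np.abs(sums - 1.0) > 1e-6)
    if bad.size:
        raise MalformedTableError(
            f"{bad.size} posterior rows do not sum to 1 (first: {P.index[bad[0]]!r})"
        )
    if (P.to_numpy() < 0).any():
        raise MalformedTableError("posterior table has negative entries")

    samples = sorted(table.samples)  # lexicographic tie-break order
    sample_block = P[samples].to_numpy()
    mult = P[MULTIPLET].to_numpy() if MULTIPLET in P.columns else np.zeros(len(P))
    best_idx = np.argmax(sample_block, axis=1)  # argmax takes the first = smallest id
    best_p = sample_block[np.arange(len(P)), best_idx]

    labels = np.where(
        mult >= best_p,
        MULTIPLET,
        np.where(best_p >= threshold, np.array(samples, dtype=object)[best_idx], UNASSIGNED),
    )
    return DemuxLabels(labels=pd.Series(labels, index=P.index), threshold=threshold)


def summarize_assignments(labels: DemuxLabels) -> DemuxSummary:
    """Exact counts plus percentages at the printed 1-decimal precision."""
    lab = labels.labels
    if lab.empty:
        raise ValueError("no labels to summarize")
    n = len(lab)
    n_mult = int((lab == MULTIPLET).sum())
    n_unas = int((lab == UNASSIGNED).sum())
    n_assigned = n - n_mult - n_unas
    per_sample = lab[~lab.isin([MULTIPLET, UNASSIGNED])].value_counts().sort_index()
    counts = {"assigned": n_assigned, "multiplet": n_mult, "unassigned": n_unas}
    percents = {k: round_half_away(100.0 * v / n, 1) for k, v in counts.items()}
    return DemuxSummary(n_total=n, counts=counts, percents=percents, per_sample=per_sample)


def concordance(a: DemuxLabels, b: DemuxLabels) -> ConcordanceReport:
    """Cross-tabulate two call vectors; percent-same over doubly-assigned cells."""
    la, lb = a.labels, b.labels
    if set(la.index) != set(lb.index):
        raise ValueError("label vectors cover different barcode universes")
    lb = lb.loc[la.index]
    confusion = pd.crosstab(la, lb, dropna=False)
    special = [MULTIPLET, UNASSIGNED]
    both = ~la.isin(special) & ~lb.isin(special)
    n_both = int(both.sum())
    if n_both == 0:
        percent = None
    else:
        same = int((la[both] == lb[both]).sum())
        percent = round_half_away(100.0 * same / n_both, 1)
    return ConcordanceReport(confusion=confusion, percent_same=percent,
                             n_doubly_assigned=n_both)
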