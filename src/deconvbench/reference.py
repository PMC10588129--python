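"""Reduced and perturbed single-cell reference profiles.

Two ways a reference profile shrinks in practice: deliberate downsampling to
a target cell count (mirroring the full dataset's composition, with a floor
of one cell per type), and technical attrition when only demultiplexing-
assigned cells are kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd

from ._utils import largest_remainder, stage_rng
from .errors import EmptyReferenceError, InfeasibleMinimumError, AnnotationError

__all__ = ["SizeLadder", "downsample_reference", "subset_by_labels"]


@dataclass(frozen=True)
class SizeLadder:
    """Ordered target sizes for reduced reference profiles."""

    sizes: tuple[int, ...] = (2000, 1000, 500, 200)

    def __post_init__(self) -> None:
        s = self.sizes
        if not s or any(b >= a for a, b in zip(s, s[1:])) or min(s) < 1:
            raise ValueError("sizes must be strictly decreasing positive integers")


def downsample_reference(dataset: ad.AnnData, target: int, seed: int) -> ad.AnnData:
    """Subsample the reference to roughly ``target`` cells, composition-matched.

    Per-type quotas come from largest-remainder apportionment of ``target``
    by the full dataset's cell-type proportions, then any zero quota for a
    represented type is raised to one by stealing a cell from the largest
    quota. Cells are drawn without replacement within type, so the actual
    size can differ slightly from ``target`` only through the minimum-one
    rule. Subsets at different targets are drawn independently.
    """
    ct = dataset.obs["cell_type"].astype(str)
    type_counts = ct.value_counts(sort=False)
    type_counts = type_counts[type_counts > 0]
    k = len(type_counts)
    if target < k:
        raise InfeasibleMinimumError(
            f"target {target} below the number of represented cell types ({k})"
        )
    if target > dataset.n_obs:
        raise ValueError(f"target {target} exceeds total cells ({dataset.n_obs})")

    quotas = pd.Series(
        largest_remainder(type_counts.to_numpy().astype(float), target),
        index=type_counts.index,
    )
    for cell_type in quotas.index[quotas == 0]:
        quotas[quotas.idxmax()] -= 1
        quotas[cell_type] = 1
    quotas = quotas.clip(upper=type_counts)  # cannot draw more than exist

    rng = stage_rng(seed, f"downsample:{target}")
    keep = []
    for cell_type, quota in quotas.items():
        pool = ct.index[np.asarray(ct == cell_type)].to_numpy()
        keep.append(rng.choice(pool, size=int(quota), replace=False))
    barcodes = np.concatenate(keep)
    order = dataset.obs_names.get_indexer(barcodes)
    return dataset[np.sort(order)].copy()


def subset_by_labels(dataset: ad.AnnData, labels) -> ad.AnnData:
    """Keep exactly the cells whose demultiplexing label is a sample.

    ``labels`` is a :class:`~deconvbench.demux.DemuxLabels` (or any object
    with a barcode-indexed ``labels`` Series); multiplet and unassigned
    cells are dropped, counts are untouched.
    """
    lab = labels.labels if hasattr(labels, "labels") else pd.Series(labels)
    missing = dataset.obs_names.difference(lab.index)
    if len(missing):
        raise AnnotationError(
            f"labels missing for {len(missing)} barcodes (e.g. {missing[0]!r})"
        )
    lab = lab.loc[dataset.obs_names]
    keep = ~lab.isin(["multiplet", "unassigned"])
    if not keep.any():
        raise EmptyReferenceError("no cells retained after label subsetting")
    return dataset[keep.to_numpy()].copy()
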