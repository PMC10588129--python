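"""Pseudo-bulk simulation with RNA-fraction ground truth.

Builds artificial bulk profiles by sampling annotated single cells with
replacement under four composition scenarios (realistic / even / sparse /
weighted), perturbing the target proportions with additive Gaussian noise,
apportioning them to integer cell tallies, and summing the drawn cells'
counts. The ground truth recorded for each sample is the fraction of
*transcriptional reads* contributed by each cell type — not the cell-count
fraction — because deconvolution methods estimate mRNA contributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._utils import largest_remainder, stage_rng, validate_composition
from .errors import ConfigurationError, DegenerateCompositionError, MissingCellTypeError

__all__ = [
    "ScenarioConfig",
    "PseudobulkSample",
    "scenario_proportions",
    "perturb_proportions",
    "integer_cell_counts",
    "sample_pseudobulk",
    "build_scenario_dataset",
]

SCENARIOS = ("realistic", "even", "sparse", "weighted")
DEFAULT_SPARSE_TYPES = ("epithelial", "endothelial", "fibroblast", "macrophage", "T")


@dataclass
class ScenarioConfig:
    """Parameters of one pseudo-bulk simulation scenario."""

    scenario: str = "realistic"
    n_cells: int = 2000
    n_samples: int = 50
    epithelial_weight: float = 0.70  # weighted scenario only
    epithelial_type: str = "epithelial"
    sparse_types: tuple[str, ...] = DEFAULT_SPARSE_TYPES
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ConfigurationError(f"unknown scenario {self.scenario!r}")
        if self.n_cells < 1 or self.n_samples < 1:
            raise ConfigurationError("n_cells and n_samples must be positive")
        if not (0.0 < self.epithelial_weight < 1.0):
            raise ConfigurationError("epithelial_weight must lie in (0, 1)")
        if self.scenario == "sparse" and not self.sparse_types:
            raise ConfigurationError("sparse scenario needs a non-empty sparse_types")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")


@dataclass
class PseudobulkSample:
    """One pseudo-bulk sample plus its ground truth and sampling log."""

    counts: pd.Series  # gene -> summed count over drawn cells
    truth_rna_fraction: pd.Series  # cell type -> RNA read fraction, sums to 1
    cell_tally: pd.Series  # cell type -> integer cells drawn
    source_sample: str
    scenario: str
    drawn_cells: dict[str, np.ndarray] = field(default_factory=dict)  # type -> barcode array


def scenario_proportions(
    cfg: ScenarioConfig, observed: pd.Series, seed: int
) -> pd.Series:
    """Target cell-count proportions for one pseudo-bulk draw.

    realistic -> the observed composition; even -> uniform over its support;
    sparse -> flat Dirichlet over the configured common types; weighted ->
    epithelial fixed at ``epithelial_weight`` with the remainder split
    randomly (flat Dirichlet) over the other types.
    """
    validate_composition(observed.to_numpy(), tol=1e-6, what="observed composition")
    types = observed.index
    rng = stage_rng(seed, f"scenario:{cfg.scenario}")
    if cfg.scenario == "realistic":
        return observed.astype(float).copy()
    if cfg.scenario == "even":
        k = len(types)
        return pd.Series(np.full(k, 1.0 / k), index=types)
    if cfg.scenario == "sparse":
        missing = [t for t in cfg.sparse_types if t not in types]
        if missing:
            raise ConfigurationError(f"sparse_types not in dataset: {missing}")
        out = pd.Series(0.0, index=types)
        out.loc[list(cfg.sparse_types)] = rng.dirichlet(np.ones(len(cfg.sparse_types)))
        return out
    # weighted
    if cfg.epithelial_type not in types:
        raise ConfigurationError(f"{cfg.epithelial_type!r} not among cell types")
    others = [t for t in types if t != cfg.epithelial_type]
    out = pd.Series(0.0, index=types)
    out.loc[cfg.epithelial_type] = cfg.epithelial_weight
    out.loc[others] = (1.0 - cfg.epithelial_weight) * rng.dirichlet(np.ones(len(others)))
    return out


def perturb_proportions(props: pd.Series, noise_sd: float, seed: int) -> pd.Series:
    """Add independent Gaussian noise per type, clamp at zero, renormalize."""
    p = validate_composition(props.to_numpy(), tol=1e-6, what="proportions")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be non-negative")
    if noise_sd == 0:
        return props.astype(float).copy()
    rng = stage_rng(seed, "proportion-noise")
    noisy = np.clip(p + rng.normal(0.0, noise_sd, size=p.size), 0.0, None)
    if noisy.sum() <= 0:
        raise DegenerateCompositionError("all proportions clamped to zero")
    return pd.Series(noisy / noisy.sum(), index=props.index)


def integer_cell_counts(props: pd.Series, n_cells: int) -> pd.Series:
    """Largest-remainder apportionment of ``n_cells`` to the proportions."""
    if n_cells <= 0:
        raise ConfigurationError("n_cells must be positive")
    p = validate_composition(props.to_numpy(), tol=1e-6, what="proportions")
    return pd.Series(largest_remainder(p, n_cells), index=props.index)


def _observed_cell_fractions(dataset: ad.AnnData, source_sample: str) -> pd.Series:
    mask = np.asarray(dataset.obs["sample_id"].astype(str) == source_sample)
    if not mask.any():
        raise ConfigurationError(f"sample {source_sample!r} not in dataset")
    counts = dataset.obs.loc[mask, "cell_type"].value_counts(sort=False)
    return (counts / counts.sum()).astype(float)


def sample_pseudobulk(
    dataset: ad.AnnData,
    source_sample: str,
    props: pd.Series,
    cfg: ScenarioConfig,
    seed: int,
) -> PseudobulkSample:
    """Draw cells with replacement per type and sum their counts.

    ``truth_rna_fraction[k]`` is the share of the aggregate's reads that came
    from type-k cells. No mRNA scaling factors are applied: integer counts
    are preserved and mRNA-content differences are carried by the read-share
    truth itself.
    """
    tally = integer_cell_counts(props, cfg.n_cells)
    mask = np.asarray(dataset.obs["sample_id"].astype(str) == source_sample)
    if not mask.any():
        raise ConfigurationError(f"sample {source_sample!r} not in dataset")
    obs = dataset.obs.loc[mask]
    X = dataset.X.tocsr() if sp.issparse(dataset.X) else np.asarray(dataset.X)
    row_of = pd.Series(np.flatnonzero(mask), index=obs.index)
    rng = stage_rng(seed, f"pseudobulk:{source_sample}")

    counts = np.zeros(dataset.n_vars, dtype=np.int64)
    reads_by_type = {}
    drawn = {}
    for cell_type, n_k in tally.items():
        n_k = int(n_k)
        if n_k == 0:
            reads_by_type[cell_type] = 0
            continue
        pool = obs.index[np.asarray(obs["cell_type"].astype(str) == str(cell_type))]
        if len(pool) == 0:
            raise MissingCellTypeError(
                f"cell type {cell_type!r} absent from sample {source_sample!r}"
            )
        picked = rng.choice(pool.to_numpy(), size=n_k, replace=True)
        rows = row_of.loc[picked].to_numpy()
        type_sum = np.asarray(X[rows].sum(axis=0)).ravel().astype(np.int64)
        counts += type_sum
        reads_by_type[cell_type] = int(type_sum.sum())
        drawn[str(cell_type)] = picked
    total = sum(reads_by_type.values())
    if total == 0:
        raise DegenerateCompositionError("drawn cells contributed zero reads")
    truth = pd.Series({k: v / total for k, v in reads_by_type.items()},
                      index=tally.index, dtype=float)
    return PseudobulkSample(
        counts=pd.Series(counts, index=dataset.var_names.copy()),
        truth_rna_fraction=truth,
        cell_tally=tally.astype(int),
        source_sample=source_sample,
        scenario=cfg.scenario,
        drawn_cells=drawn,
    )


def build_scenario_dataset(
    dataset: ad.AnnData, cfg: ScenarioConfig, seed: int
) -> list[PseudobulkSample]:
    """``cfg.n_samples`` pseudo-bulk samples per source sample in the dataset.

    Each sample takes a fresh scenario draw, noise perturbation, integer
    apportionment and cell sampling; the whole list is deterministic given
    (cfg, seed).
    """
    out = []
    sources = [str(s) for s in dataset.obs["sample_id"].unique()]
    for source in sources:
        observed = _observed_cell_fractions(dataset, source)
        # restrict to types present in this source: absent types get zero mass
        support = observed[observed > 0].index
        for i in range(cfg.n_samples):
            sub_seed = int(stage_rng(seed, f"scenario-draw:{source}", i).integers(2**31))
            props = scenario_proportions(cfg, observed, sub_seed)
            if cfg.scenario in ("realistic", "even"):
                props = props.where(props.index.isin(support), 0.0)
                props = props / props.sum()
            props = perturb_proportions(props, cfg.noise_sd, sub_seed)
            out.append(sample_pseudobulk(dataset, source, props, cfg, sub_seed))
    return out
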