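"""Shared numeric helpers: apportionment, rounding, seed derivation."""

from __future__ import annotations

import zlib

import numpy as np

from .errors import ConfigurationError, DegenerateCompositionError

__all__ = [
    "largest_remainder",
    "round_half_away",
    "stage_rng",
    "validate_composition",
]


def largest_remainder(proportions: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` integer units to fractions by the largest-remainder rule.

    Floors the ideal quotas, then hands the leftover units to the largest
    fractional remainders (ties broken by position). The result always sums to
    ``total`` exactly and a zero proportion always receives zero units.
    """
    p = np.asarray(proportions, dtype=float)
    if p.ndim != 1 or (p < 0).any():
        raise ConfigurationError("proportions must be a non-negative 1-d vector")
    s = p.sum()
    if s <= 0:
        raise DegenerateCompositionError("all proportions are zero")
    quota = p / s * total
    base = np.floor(quota).astype(np.int64)
    short = int(total - base.sum())
    if short > 0:
        remainder = quota - base
        # stable argsort: ties resolved by lower index
        order = np.argsort(-remainder, kind="stable")
        base[order[:short]] += 1
    return base


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention of printed percentages)."""
    factor = 10.0**decimals
    scaled = abs(x) * factor
    return float(np.sign(x) * np.floor(scaled + 0.5) / factor)


def stage_rng(seed: int, stage: str, index: int = 0) -> np.random.Generator:
    """Derive a named per-stage generator from a global seed.

    Every random draw in the pipeline traces back to (seed, stage, index); the
    stage name is folded in through a CRC so renaming a stage changes its stream
    but nothing else's.
    """
    tag = zlib.crc32(stage.encode("utf-8"))
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag, int(index)])
    return np.random.default_rng(ss)


def validate_composition(p: np.ndarray, tol: float = 1e-9, what: str = "composition") -> np.ndarray:
    """Check the simplex contract (non-negative, sums to 1 within ``tol``)."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ConfigurationError(f"{what} has negative entries")
    total = p.sum()
    if abs(total - 1.0) > tol:
        raise ConfigurationError(f"{what} sums to {total!r}, expected 1")
    return p
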