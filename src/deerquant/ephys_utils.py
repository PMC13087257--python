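"""Electrophysiology arithmetic: Nernst potentials and fold activation.

Small, exactly testable helpers for interpreting current recordings of
potassium-selective channels: the Nernst equilibrium potential for an ion
at a given transmembrane concentration ratio, and per-patch fold-change
summaries (mean +/- SEM) of stimulated over basal currents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike

__all__ = ["GAS_CONSTANT", "FARADAY", "FoldChangeSummary", "nernst_potential", "fold_activation"]

GAS_CONSTANT = 8.314462618     # J / (mol K)
FARADAY = 96485.33212          # C / mol


@dataclass(frozen=True)
class FoldChangeSummary:
    """Per-patch fold changes with mean and SEM (SEM undefined for n = 1)."""

    folds: tuple[float, ...]
    mean: float
    sem: float | None
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("need at least one patch")
        if self.sem is not None and self.sem < 0:
            raise ValueError("SEM must be non-negative")

    def __str__(self) -> str:
        if self.sem is None:
            return f"{self.mean:.2f}-fold (n = 1, SEM undefined)"
        return f"{self.mean:.2f} ± {self.sem:.2f}-fold (mean ± SEM, n = {self.n} patches)"


def nernst_potential(temperature: float, valence: int, ratio_out_over_in: float) -> float:
    """Nernst equilibrium potential E = RT/(zF) ln([out]/[in]) in mV.

    For K+ at 298.15 K with a 10-fold higher internal concentration
    (ratio 0.1) this gives -59.2 mV. The identity E(r) = -E(1/r) holds
    exactly.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if valence == 0:
        raise ValueError("valence must be non-zero")
    if ratio_out_over_in <= 0:
        raise ValueError("concentration ratio must be positive")
    volts = (GAS_CONSTANT * temperature) / (valence * FARADAY) * np.log(ratio_out_over_in)
    return float(volts * 1000.0)


def fold_activation(baseline: ArrayLike, stimulated: ArrayLike) -> FoldChangeSummary:
    """Fold change per patch (stimulated / baseline) with mean and SEM.

    The summary is invariant under a common rescaling of all currents;
    SEM = SD / sqrt(n) over patches, undefined for a single patch.
    """
    base = np.asarray(baseline, dtype=float)
    stim = np.asarray(stimulated, dtype=float)
    if base.shape != stim.shape or base.ndim != 1:
        raise ValueError("baseline and stimulated must be equal-length 1-D lists")
    zero = np.nonzero(base == 0)[0]
    if zero.size:
        raise ValueError(f"zero baseline current in patch {int(zero[0]) + 1}")
    folds = stim / base
    n = folds.size
    sem = float(np.std(folds, ddof=1) / np.sqrt(n)) if n > 1 else None
    return FoldChangeSummary(tuple(folds), float(np.mean(folds)), sem, n)
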