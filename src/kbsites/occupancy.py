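"""Equilibrium occupancy projection for a transcription-factor binding site.

Under the free-ligand approximation (site concentration ≪ free TF dimer
concentration) the fraction of time a site is bound at equilibrium is

    f = C / (C + K_D)

with C the free nuclear TF dimer concentration and K_D the equilibrium
dissociation constant, both in nM.  With the nuclear RelA concentration
reached on TNF-α stimulation (~200–250 nM) and a very weak site
(K_D ~ 3 µM), only about 6% of such sites are projected to be bound —
the puzzle that motivates looking for collective, multi-site recruitment.
No ligand-depletion quadratic or multi-site cooperativity is modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["BindingParams", "fraction_bound", "occupancy_table", "occupancy_frame"]


@dataclass(frozen=True)
class BindingParams:
    """Free nuclear TF dimer concentration and site dissociation constant, nM."""

    concentration: float
    kd: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.concentration) and self.concentration > 0):
            raise ValueError(f"concentration must be positive, got {self.concentration!r}")
        if not (math.isfinite(self.kd) and self.kd > 0):
            raise ValueError(f"kd must be positive, got {self.kd!r}")


def fraction_bound(concentration: float, kd: float) -> float:
    """Equilibrium fraction bound f = C/(C + K_D); both arguments in nM."""
    params = BindingParams(concentration, kd)
    return params.concentration / (params.concentration + params.kd)


def occupancy_table(concentrations: Sequence[float], kds: Sequence[float]) -> np.ndarray:
    """Grid of fractions bound, rows = concentrations, columns = K_D values."""
    conc = np.asarray(list(concentrations), dtype=float)
    kd = np.asarray(list(kds), dtype=float)
    if conc.size == 0 or kd.size == 0:
        return np.empty((conc.size, kd.size))
    if np.any(conc <= 0) or np.any(kd <= 0):
        raise ValueError("all concentrations and K_D values must be positive")
    return conc[:, None] / (conc[:, None] + kd[None, :])


def occupancy_frame(concentrations: Sequence[float], kds: Sequence[float]) -> pd.DataFrame:
    """Labelled occupancy grid suitable for TSV export."""
    grid = occupancy_table(concentrations, kds)
    return pd.DataFrame(
        grid,
        index=pd.Index(list(concentrations), name="concentration_nM"),
        columns=pd.Index(list(kds), name="kd_nM"),
    )
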