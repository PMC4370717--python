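"""Species-level trait indices for the farmland bird community.

Three indices characterise each species:

* **SSI** (species specialisation index): the coefficient of variation of
  the species' density across seven broad habitat classes (forest,
  heath/scrub, marshland, farmland, urban settlement, wetland/aquatic,
  rocks).  A habitat generalist has similar densities everywhere and a
  low SSI; a strict farmland specialist has a high SSI.
* **STI** (species trophic index): the diet-proportion-weighted score
  with seeds/plants = 1, invertebrates = 2, vertebrates = 3; it ranges
  from 1 (pure granivore) to 3 (pure vertebrate predator).
* **SSIg** (grassland specialisation index): the abundance-weighted mean
  over four farmland sub-habitats, weighted 4 (unimproved grassland),
  3 (improved grassland), 2 (mixed grassland/arable), 1 (arable); it
  ranges from 1 (arable specialist) to 4 (unimproved-grassland
  specialist).

The packaged 22-species reference table ships with the module and is the
authoritative source of trait values for the community analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "HABITAT_CLASSES",
    "SUBHABITATS",
    "SUBHABITAT_WEIGHTS",
    "DIET_WEIGHTS",
    "SpeciesTrait",
    "UndefinedIndexError",
    "compute_ssi",
    "compute_sti",
    "compute_ssig",
    "load_species_table",
]

#: The seven habitat classes recorded with each point count.
HABITAT_CLASSES: tuple[str, ...] = (
    "forest",
    "heath_scrub",
    "marshland",
    "farmland",
    "urban",
    "wetland_aquatic",
    "rocks",
)

#: The four farmland sub-habitats, in decreasing grassland character.
SUBHABITATS: tuple[str, ...] = (
    "unimproved_grassland",
    "improved_grassland",
    "mixed_grassland_arable",
    "arable",
)

#: SSIg weights, aligned with :data:`SUBHABITATS`.
SUBHABITAT_WEIGHTS: np.ndarray = np.array([4.0, 3.0, 2.0, 1.0])

#: STI weights for (seeds/plants, invertebrates, vertebrates).
DIET_WEIGHTS: np.ndarray = np.array([1.0, 2.0, 3.0])


class UndefinedIndexError(ValueError):
    """Raised when a trait index is undefined (e.g. all-zero abundances)."""


@dataclass(frozen=True)
class SpeciesTrait:
    """Trait values of one community species."""

    species_id: str
    ssi: float
    sti: float
    ssig: float

    def __post_init__(self) -> None:
        if self.ssi < 0:
            raise ValueError(f"{self.species_id}: ssi must be >= 0, got {self.ssi}")
        if not 1.0 <= self.sti <= 3.0:
            raise ValueError(f"{self.species_id}: sti must lie in [1, 3], got {self.sti}")
        if not 1.0 <= self.ssig <= 4.0:
            raise ValueError(f"{self.species_id}: ssig must lie in [1, 4], got {self.ssig}")


def compute_ssi(densities, *, sample_sd: bool = True) -> float:
    """Species specialisation index: CV of density across habitat classes.

    Parameters
    ----------
    densities
        Mean density (birds per point count) in each of the seven habitat
        classes, ordered as :data:`HABITAT_CLASSES`.  Classes where the
        species was never recorded contribute a density of 0.
    sample_sd
        Use the sample (n−1) standard deviation (default) or the
        population (n) one.

    Returns
    -------
    float
        sd(densities) / mean(densities); 0 iff all densities are equal.
    """
    d = np.asarray(densities, dtype=float)
    if d.ndim != 1 or d.size != len(HABITAT_CLASSES):
        raise ValueError(f"expected {len(HABITAT_CLASSES)} habitat densities, got shape {d.shape}")
    if np.any(d < 0):
        raise ValueError("habitat densities must be non-negative")
    if not np.any(d > 0):
        raise UndefinedIndexError("SSI undefined: species density is zero in every habitat class")
    return float(d.std(ddof=1 if sample_sd else 0) / d.mean())


def compute_sti(diet_proportions, *, tol: float = 1e-9) -> float:
    """Species trophic index from (seeds/plants, invertebrates, vertebrates) diet shares."""
    p = np.asarray(diet_proportions, dtype=float)
    if p.shape != (3,):
        raise ValueError(f"expected 3 diet proportions, got shape {p.shape}")
    if np.any(p < 0):
        raise ValueError("diet proportions must be non-negative")
    if abs(p.sum() - 1.0) > tol:
        raise ValueError(f"diet proportions must sum to 1, got {p.sum()!r}")
    return float(p @ DIET_WEIGHTS)


def compute_ssig(subhabitat_abundance) -> float:
    """Grassland specialisation index: abundance-weighted mean of sub-habitat weights.

    ``subhabitat_abundance`` is ordered as :data:`SUBHABITATS`
    (unimproved grassland, improved grassland, mixed, arable), weighted
    4, 3, 2, 1 respectively.
    """
    n = np.asarray(subhabitat_abundance, dtype=float)
    if n.shape != (len(SUBHABITATS),):
        raise ValueError(f"expected {len(SUBHABITATS)} sub-habitat abundances, got shape {n.shape}")
    if np.any(n < 0):
        raise ValueError("sub-habitat abundances must be non-negative")
    total = n.sum()
    if total == 0:
        raise UndefinedIndexError("SSIg undefined: total sub-habitat abundance is zero")
    return float((n / total) @ SUBHABITAT_WEIGHTS)


def load_species_table(as_frame: bool = False):
    """Load the packaged 22-species trait table.

    Returns a list of :class:`SpeciesTrait` (default) or, with
    ``as_frame=True``, a :class:`pandas.DataFrame` indexed by species.
    """
    ref = resources.files("agribirds.data") / "species_traits.tsv"
    with resources.as_file(ref) as path:
        table = pd.read_csv(path, sep="\t")
    expected = {"species_id", "ssi", "sti", "ssig"}
    if set(table.columns) != expected:
        raise ValueError(f"species fixture corrupt: columns {list(table.columns)}")
    if as_frame:
        return table.set_index("species_id")
    return [SpeciesTrait(r.species_id, r.ssi, r.sti, r.ssig) for r in table.itertuples()]
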