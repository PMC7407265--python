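"""High-level study workflows composing simulation, classification and
quantification."""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

from .classify import classify_well
from .quantify import LodResult, dropoff_maf, limit_of_blank, lod_from_dilution
from .simulate import SimulationConfig, simulate_dilution_series


def dilution_sensitivity_study(
    config: SimulationConfig | None = None,
    mutant_fractions: Sequence[float] = (0.01, 0.001),
    replicates_per_level: int = 200,
    n_blank_wells: int = 50,
    required_rate: float = 0.95,
    seed: int | None = None,
) -> LodResult:
    """Simulated dilution-series sensitivity: LoB from blank wells, then the
    limit of detection over replicate wells per mutant-fraction level.

    Every well is simulated, classified with fitted thresholds, and
    Poisson-quantified; detection is judged against the measured LoB with the
    default single-droplet minimum.
    """
    if config is None:
        config = SimulationConfig()
    master = config.seed if seed is None else seed

    blanks = simulate_dilution_series(
        replace(config, seed=master), [0.0], n_blank_wells
    )[0].wells
    lob = limit_of_blank([classify_well(w) for w in blanks])

    levels = simulate_dilution_series(
        replace(config, seed=master + 1), list(mutant_fractions), replicates_per_level
    )
    quantified = [
        (level.fraction, [dropoff_maf(classify_well(w)) for w in level.wells])
        for level in levels
    ]
    return lod_from_dilution(quantified, required_rate=required_rate, lob_droplets=lob)
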