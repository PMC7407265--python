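"""Synthetic droplet generation for a two-channel drop-off ddPCR assay.

The simulator emulates what a droplet reader exports after a drop-off
experiment on an IDH2 hotspot (R140 or R172): a table of per-droplet
fluorescence amplitudes on two channels. The generative model has three
stages:

1. **Partitioning.** A known number of wild-type and mutant template copies
   (derived from the DNA mass input) is distributed over ``n_droplets``
   droplets, each copy landing in a uniformly random droplet. This
   multinomial model conserves copies exactly and converges to the Poisson
   occupancy model the instrument software assumes.

2. **Amplitude rendering.** Each droplet's channel-1 (FAM, reference probe)
   and channel-2 (HEX, wild-type probe) amplitudes are drawn from Gaussian
   clusters according to its occupancy class. Empty droplets sit in the
   double-negative cloud; any droplet holding wild-type template is
   double-positive (the HEX probe finds its intact binding site); droplets
   holding only mutant template are FAM-only, because the hotspot mutation
   abolishes HEX probe binding — the "drop-off". Droplets co-containing
   mutant and wild-type template render double-positive, which is what makes
   the downstream Poisson correction necessary.

3. **Rain (optional).** A fraction of positive droplets is displaced halfway
   toward the negative centroid, emulating the intermediate-amplitude
   droplets that complicate thresholding on real instruments.

Every stage is deterministic given the configuration seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import yaml

from .errors import InvalidParameterError

__all__ = [
    "ClusterModel",
    "AmplitudeModel",
    "SimulationConfig",
    "DropletWell",
    "DilutionLevel",
    "copies_from_mass",
    "simulate_partition",
    "render_amplitudes",
    "simulate_well",
    "simulate_dilution_series",
]

#: Mass of one haploid human genome in picograms; one IDH2 allele per haploid genome.
PG_PER_HAPLOID_GENOME = 3.3

#: Droplet volume in nanolitres (QX200 convention).
DEFAULT_DROPLET_VOLUME_NL = 0.85


def _as_rng(seed: int | np.random.Generator | np.random.SeedSequence | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class ClusterModel:
    """Gaussian amplitude cluster: per-channel mean and SD in fluorescence a.u."""

    mean_ch1: float
    sd_ch1: float
    mean_ch2: float
    sd_ch2: float

    def __post_init__(self) -> None:
        if self.sd_ch1 < 0 or self.sd_ch2 < 0:
            raise InvalidParameterError("amplitude SDs must be >= 0")


@dataclass(frozen=True)
class AmplitudeModel:
    """Amplitude clusters for the three droplet populations of a drop-off assay."""

    negative: ClusterModel = ClusterModel(1000.0, 300.0, 1000.0, 300.0)
    double_positive: ClusterModel = ClusterModel(8000.0, 300.0, 9000.0, 300.0)
    fam_only: ClusterModel = ClusterModel(8000.0, 300.0, 1200.0, 300.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated reaction well.

    Parameters
    ----------
    n_droplets:
        Accepted droplets per well (the QX200 generates about 20,000).
    dna_input_ng:
        Template DNA mass loaded into the reaction, in nanograms.
    pg_per_haploid:
        Mass of one haploid genome in picograms; converts mass to allele copies.
    mutant_fraction:
        Fraction of template alleles carrying the hotspot mutation, in [0, 1].
    droplet_volume_nl:
        Droplet volume in nanolitres, used for copies/µL concentrations.
    amplitudes:
        Gaussian cluster model for the three droplet populations.
    rain_rate:
        Fraction of positive droplets displaced halfway toward the negative
        centroid, in [0, 1].
    seed:
        Master RNG seed; all randomness derives from it.
    assay:
        Hotspot label, ``"R140"`` or ``"R172"`` (metadata only).
    """

    n_droplets: int = 20000
    dna_input_ng: float = 16.0
    pg_per_haploid: float = PG_PER_HAPLOID_GENOME
    mutant_fraction: float = 0.0
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL
    amplitudes: AmplitudeModel = field(default_factory=AmplitudeModel)
    rain_rate: float = 0.0
    seed: int = 0
    assay: str = "R140"

    def __post_init__(self) -> None:
        if self.n_droplets < 1:
            raise InvalidParameterError("n_droplets must be >= 1")
        if not 0.0 <= self.mutant_fraction <= 1.0:
            raise InvalidParameterError("mutant_fraction must be in [0, 1]")
        if not 0.0 <= self.rain_rate <= 1.0:
            raise InvalidParameterError("rain_rate must be in [0, 1]")
        if self.droplet_volume_nl <= 0:
            raise InvalidParameterError("droplet_volume_nl must be > 0")
        if self.dna_input_ng < 0:
            raise InvalidParameterError("dna_input_ng must be >= 0")
        if self.pg_per_haploid <= 0:
            raise InvalidParameterError("pg_per_haploid must be > 0")

    def to_dict(self) -> dict:
        am = self.amplitudes
        return {
            "n_droplets": self.n_droplets,
            "dna_input_ng": self.dna_input_ng,
            "pg_per_haploid": self.pg_per_haploid,
            "mutant_fraction": self.mutant_fraction,
            "droplet_volume_nl": self.droplet_volume_nl,
            "rain_rate": self.rain_rate,
            "seed": self.seed,
            "assay": self.assay,
            "amplitudes": {
                name: {
                    "mean_ch1": c.mean_ch1,
                    "sd_ch1": c.sd_ch1,
                    "mean_ch2": c.mean_ch2,
                    "sd_ch2": c.sd_ch2,
                }
                for name, c in (
                    ("negative", am.negative),
                    ("double_positive", am.double_positive),
                    ("fam_only", am.fam_only),
                )
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        amp = d.pop("amplitudes", None)
        if amp is not None:
            d["amplitudes"] = AmplitudeModel(
                **{name: ClusterModel(**amp[name]) for name in amp}
            )
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class DropletWell:
    """Raw per-droplet two-channel amplitudes for one reaction well.

    ``amplitudes`` is an ``(n, 2)`` float array (channel 1 FAM, channel 2
    HEX). ``truth``, present only on simulated wells, is an ``(n, 2)``
    integer array of per-droplet (wild-type copies, mutant copies).
    """

    well_id: str
    assay: str
    amplitudes: np.ndarray
    truth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.ndim != 2 or self.amplitudes.shape[1] != 2:
            raise InvalidParameterError("amplitudes must be an (n, 2) array")
        if not np.all(np.isfinite(self.amplitudes)):
            raise InvalidParameterError("amplitudes must all be finite")
        if self.truth is not None:
            self.truth = np.asarray(self.truth, dtype=np.int64)
            if self.truth.shape != self.amplitudes.shape:
                raise InvalidParameterError("truth must match amplitudes shape")

    @property
    def n_droplets(self) -> int:
        return self.amplitudes.shape[0]

    def truth_counts(self) -> dict:
        """Ground-truth population counts (negative / double-positive / FAM-only)."""
        if self.truth is None:
            raise InvalidParameterError("well carries no truth labels")
        wt, mut = self.truth[:, 0], self.truth[:, 1]
        return {
            "negative": int(np.sum((wt == 0) & (mut == 0))),
            "double_positive": int(np.sum(wt >= 1)),
            "fam_only": int(np.sum((wt == 0) & (mut >= 1))),
        }


def copies_from_mass(dna_ng: float, pg_per_haploid: float = PG_PER_HAPLOID_GENOME) -> int:
    """Convert a DNA mass to target-allele copy number.

    One target allele per haploid genome is assumed, so 16 ng at 3.3 pg per
    haploid genome is 4848 copies.
    """
    if pg_per_haploid <= 0:
        raise InvalidParameterError("pg_per_haploid must be > 0")
    if dna_ng < 0:
        raise InvalidParameterError("dna_ng must be >= 0")
    return int(round(dna_ng * 1000.0 / pg_per_haploid))


def simulate_partition(
    n_wt_copies: int,
    n_mut_copies: int,
    n_droplets: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Distribute template copies over droplets, one uniform draw per copy.

    Returns an ``(n_droplets, 2)`` integer array of (wild-type, mutant)
    copies per droplet. Column sums equal the requested copy numbers exactly.
    """
    if n_droplets < 1:
        raise InvalidParameterError("n_droplets must be >= 1")
    if n_wt_copies < 0 or n_mut_copies < 0:
        raise InvalidParameterError("copy numbers must be >= 0")
    rng = _as_rng(seed)
    occ = np.zeros((n_droplets, 2), dtype=np.int64)
    if n_wt_copies:
        occ[:, 0] = np.bincount(
            rng.integers(0, n_droplets, size=n_wt_copies), minlength=n_droplets
        )
    if n_mut_copies:
        occ[:, 1] = np.bincount(
            rng.integers(0, n_droplets, size=n_mut_copies), minlength=n_droplets
        )
    return occ


def render_amplitudes(
    occupancy: np.ndarray,
    config: SimulationConfig,
    seed: int | np.random.Generator | None = None,
    well_id: str = "well-0",
) -> DropletWell:
    """Turn per-droplet occupancy into two-channel fluorescence amplitudes.

    Empty droplets draw from the negative cluster; droplets with any
    wild-type template are double-positive; droplets with mutant template
    only are FAM-only. With ``rain_rate`` > 0, that fraction of positive
    droplets is displaced halfway toward the negative centroid on both
    channels. Ground-truth occupancy is stored on the returned well.
    """
    occ = np.asarray(occupancy, dtype=np.int64)
    if occ.ndim != 2 or occ.shape[1] != 2 or np.any(occ < 0):
        raise InvalidParameterError("occupancy must be (n, 2) non-negative counts")
    rng = _as_rng(config.seed if seed is None else seed)
    am = config.amplitudes
    wt, mut = occ[:, 0], occ[:, 1]
    negative = (wt == 0) & (mut == 0)
    double_positive = wt >= 1
    fam_only = (wt == 0) & (mut >= 1)

    amps = np.empty((len(occ), 2), dtype=float)
    for mask, cluster in (
        (negative, am.negative),
        (double_positive, am.double_positive),
        (fam_only, am.fam_only),
    ):
        k = int(mask.sum())
        if k:
            amps[mask, 0] = rng.normal(cluster.mean_ch1, cluster.sd_ch1, size=k)
            amps[mask, 1] = rng.normal(cluster.mean_ch2, cluster.sd_ch2, size=k)

    if config.rain_rate > 0:
        positive_idx = np.flatnonzero(~negative)
        k = int(round(config.rain_rate * len(positive_idx)))
        if k:
            chosen = rng.choice(positive_idx, size=k, replace=False)
            amps[chosen, 0] = 0.5 * (amps[chosen, 0] + am.negative.mean_ch1)
            amps[chosen, 1] = 0.5 * (amps[chosen, 1] + am.negative.mean_ch2)

    return DropletWell(well_id=well_id, assay=config.assay, amplitudes=amps, truth=occ.copy())


def simulate_well(
    config: SimulationConfig,
    seed: int | np.random.Generator | None = None,
    well_id: str = "well-0",
) -> DropletWell:
    """Simulate one complete well from a configuration (partition + render)."""
    total = copies_from_mass(config.dna_input_ng, config.pg_per_haploid)
    n_mut = int(round(config.mutant_fraction * total))
    n_wt = total - n_mut
    rng = _as_rng(config.seed if seed is None else seed)
    occ = simulate_partition(n_wt, n_mut, config.n_droplets, rng)
    return render_amplitudes(occ, config, seed=rng, well_id=well_id)


@dataclass
class DilutionLevel:
    """Replicate wells simulated at one mutant fraction."""

    fraction: float
    wells: list


def well_id_for(fraction: float, replicate: int) -> str:
    return f"f{fraction:g}_r{replicate:03d}"


def parse_well_id(well_id: str) -> tuple[float, int]:
    """Recover (mutant fraction, replicate index) from a dilution-series well id."""
    if not well_id.startswith("f") or "_r" not in well_id:
        raise InvalidParameterError(f"not a dilution-series well id: {well_id!r}")
    frac_s, rep_s = well_id[1:].rsplit("_r", 1)
    return float(frac_s), int(rep_s)


def simulate_dilution_series(
    base_config: SimulationConfig,
    mutant_fractions: Sequence[float],
    replicates_per_level: int = 1,
    seed: int | None = None,
) -> list[DilutionLevel]:
    """Simulate replicate wells at each mutant fraction of a dilution series.

    Total copies come from the configured DNA mass; at each level
    ``round(fraction * total)`` copies are mutant and the rest wild-type.
    Each well gets its own RNG substream derived from the master seed and its
    (level, replicate) indices, so adding levels or replicates never changes
    previously generated wells. The level and replicate are recorded in the
    well id (``f0.001_r003``).
    """
    if len(mutant_fractions) == 0:
        raise InvalidParameterError("mutant_fractions must be non-empty")
    for f in mutant_fractions:
        if not 0.0 <= f <= 1.0:
            raise InvalidParameterError(f"mutant fraction {f} outside [0, 1]")
    if replicates_per_level < 1:
        raise InvalidParameterError("replicates_per_level must be >= 1")

    master = base_config.seed if seed is None else seed
    total = copies_from_mass(base_config.dna_input_ng, base_config.pg_per_haploid)
    levels: list[DilutionLevel] = []
    for li, fraction in enumerate(mutant_fractions):
        n_mut = int(round(fraction * total))
        n_wt = total - n_mut
        cfg = replace(base_config, mutant_fraction=fraction)
        wells = []
        for r in range(replicates_per_level):
            ss = np.random.SeedSequence(entropy=master, spawn_key=(li, r))
            rng = np.random.default_rng(ss)
            occ = simulate_partition(n_wt, n_mut, cfg.n_droplets, rng)
            wells.append(
                render_amplitudes(occ, cfg, seed=rng, well_id=well_id_for(fraction, r))
            )
        levels.append(DilutionLevel(fraction=fraction, wells=wells))
    return levels
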