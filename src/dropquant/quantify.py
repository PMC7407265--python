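"""Poisson quantification for drop-off ddPCR wells.

Each droplet receives template copies approximately as a Poisson draw, so
the mean copies per droplet is estimated from the fraction of droplets that
stayed negative: λ = −ln(n_negative / n_total).

The drop-off construction yields two such rates per well. The FAM reference
probe fires on *any* template, so the FAM-negative droplet count gives the
total-template rate λ_total. The HEX probe fires only on wild-type
template, so the HEX-negative count (negatives plus FAM-only droplets)
gives the wild-type rate λ_wt. Their difference is the mutant rate, and the
mutant allele fraction (MAF, "allele burden") is

    MAF = 100 · (λ_total − λ_wt) / λ_total   [percent].

This subtraction — rather than the naive droplet ratio — corrects for
droplets co-containing mutant and wild-type template, which present as
double-positive and would otherwise hide mutant copies. 95% confidence
intervals use the delta method, treating the two counts as independent
binomials (a documented approximation: the counts share droplets, which if
anything makes the interval conservative for the difference).

Assay sensitivity is characterised the standard way: the limit of blank
(LoB) is the 95th percentile of false-positive FAM-only droplets across
mutation-free wells, and the limit of detection (LoD) is the lowest mutant
fraction in a dilution series detected in at least 95% of replicate wells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

from .classify import ClassifiedWell, DEFAULT_MAX_HEX_ONLY_FRACTION
from .errors import (
    InsufficientDataError,
    InvalidCountsError,
    InvalidParameterError,
    SaturationError,
)
from .simulate import DEFAULT_DROPLET_VOLUME_NL

__all__ = [
    "PoissonEstimate",
    "DropOffResult",
    "LodResult",
    "estimate_lambda",
    "concentration",
    "dropoff_maf",
    "detect_mutation",
    "limit_of_blank",
    "lod_from_dilution",
]

_Z95 = 1.96


@dataclass(frozen=True)
class PoissonEstimate:
    """Mean copies per droplet with a 95% delta-method confidence interval."""

    lam: float
    ci_low: float
    ci_high: float
    n_droplets: int
    n_negative_for_target: int


@dataclass(frozen=True)
class DropOffResult:
    """Poisson-corrected quantification of one classified well.

    Rates are copies per droplet; ``maf`` and its CI are percentages;
    ``concentration`` is total-template copies per microlitre.
    """

    well_id: str
    lam_total: float
    lam_wt: float
    lam_mut: float
    maf: float
    maf_ci_low: float
    maf_ci_high: float
    concentration: float
    detected: bool
    n_fam_only: int
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class LodResult:
    """Dilution-series sensitivity summary.

    ``lod_pct`` is the limit of detection as a percent mutant fraction, or
    ``None`` when no tested level qualifies. ``detection_rates`` maps each
    tested mutant fraction (as a proportion) to its detection rate.
    """

    lob_droplets: int
    lod_pct: float | None
    detection_rates: dict


def estimate_lambda(n_negative: int, n_total: int) -> PoissonEstimate:
    """Estimate copies per droplet from the negative-droplet count.

    λ = −ln(n_negative / n_total); the 95% CI is λ ± 1.96·sqrt((e^λ − 1)/n),
    floored at zero. A well with no negative droplets is saturated — λ is
    unbounded and the sample must be diluted — so that raises rather than
    returning infinity.
    """
    if n_total < 1:
        raise InvalidParameterError("n_total must be >= 1")
    if n_negative < 0 or n_negative > n_total:
        raise InvalidCountsError(f"n_negative={n_negative} outside [0, {n_total}]")
    if n_negative == 0:
        raise SaturationError("no negative droplets: lambda unbounded, dilute the sample")
    lam = -math.log(n_negative / n_total)
    half = _Z95 * math.sqrt((math.exp(lam) - 1.0) / n_total)
    return PoissonEstimate(
        lam=lam,
        ci_low=max(0.0, lam - half),
        ci_high=lam + half,
        n_droplets=n_total,
        n_negative_for_target=n_negative,
    )


def concentration(lam: float, droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL) -> float:
    """Convert copies per droplet to copies per microlitre of reaction."""
    if droplet_volume_nl <= 0:
        raise InvalidParameterError("droplet_volume_nl must be > 0")
    if lam < 0:
        raise InvalidParameterError("lam must be >= 0")
    return lam / (droplet_volume_nl * 1e-3)


def _lambda_var(lam: float, n_total: int) -> float:
    return (math.exp(lam) - 1.0) / n_total


def dropoff_maf(
    cw: ClassifiedWell,
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
    max_hex_only_fraction: float = DEFAULT_MAX_HEX_ONLY_FRACTION,
) -> DropOffResult:
    """Quantify a classified well: rates, concentration and mutant fraction.

    λ_total comes from the negative-droplet count (the FAM probe fires on any
    template); λ_wt from the HEX-negative count (negatives + FAM-only).
    λ_mut = max(0, λ_total − λ_wt) and MAF = 100·λ_mut/λ_total (zero when
    λ_total is zero). ``detected`` is the default single-droplet rule
    (any FAM-only droplet); re-evaluate against a measured limit of blank
    with :func:`detect_mutation`.
    """
    est_total = estimate_lambda(cw.n_negative, cw.n_total)
    n_hex_negative = cw.n_negative + cw.n_fam_only
    est_wt = estimate_lambda(n_hex_negative, cw.n_total)

    lam_total, lam_wt = est_total.lam, est_wt.lam
    lam_mut = max(0.0, lam_total - lam_wt)
    if lam_total > 0:
        maf = 100.0 * lam_mut / lam_total
        var_f = (lam_wt / lam_total**2) ** 2 * _lambda_var(lam_total, cw.n_total) + (
            1.0 / lam_total
        ) ** 2 * _lambda_var(lam_wt, cw.n_total)
        half = 100.0 * _Z95 * math.sqrt(var_f)
        ci_low = min(100.0, max(0.0, maf - half))
        ci_high = min(100.0, max(0.0, maf + half))
    else:
        maf, ci_low, ci_high = 0.0, 0.0, 0.0

    warnings = []
    if cw.n_total > 0 and cw.n_hex_only / cw.n_total > max_hex_only_fraction:
        warnings.append(
            f"HEX-only fraction {cw.n_hex_only / cw.n_total:.4f} exceeds "
            f"{max_hex_only_fraction:g}: reference probe may be failing"
        )

    return DropOffResult(
        well_id=cw.well_id,
        lam_total=lam_total,
        lam_wt=lam_wt,
        lam_mut=lam_mut,
        maf=maf,
        maf_ci_low=ci_low,
        maf_ci_high=ci_high,
        concentration=concentration(lam_total, droplet_volume_nl),
        detected=cw.n_fam_only > 0,
        n_fam_only=cw.n_fam_only,
        warnings=tuple(warnings),
    )


def detect_mutation(
    result: DropOffResult, lob_droplets: int = 0, min_droplets_rule: int = 1
) -> bool:
    """Mutation-positivity rule: FAM-only droplets must strictly exceed the
    limit of blank and reach the minimum droplet count."""
    return result.n_fam_only > max(lob_droplets, min_droplets_rule - 1)


def limit_of_blank(blank_wells: Sequence[ClassifiedWell]) -> int:
    """Limit of blank: nearest-rank 95th percentile of FAM-only droplet
    counts across mutation-free wells."""
    if len(blank_wells) == 0:
        raise InsufficientDataError("need at least one blank well for LoB")
    values = sorted(cw.n_fam_only for cw in blank_wells)
    rank = math.ceil(0.95 * len(values))  # 1-based nearest rank
    return int(values[rank - 1])


def lod_from_dilution(
    levels: Sequence[tuple[float, Sequence]],
    required_rate: float = 0.95,
    lob_droplets: int = 0,
    min_droplets_rule: int = 1,
) -> LodResult:
    """Limit of detection from a dilution series.

    ``levels`` pairs each tested mutant fraction (a proportion) with its
    replicate :class:`DropOffResult` objects (or plain booleans). Detection
    is re-evaluated per replicate against ``lob_droplets``. The LoD is the
    smallest tested fraction whose detection rate meets ``required_rate``
    with every larger tested fraction also qualifying; blanks (fraction 0)
    are never LoD candidates. Returned as a percent, or ``None`` when no
    level qualifies.
    """
    if len(levels) == 0:
        raise InsufficientDataError("need at least one dilution level")
    rates: dict = {}
    for fraction, results in levels:
        if len(results) == 0:
            raise InsufficientDataError(f"level {fraction} has no replicates")
        flags = [
            detect_mutation(r, lob_droplets, min_droplets_rule)
            if isinstance(r, DropOffResult)
            else bool(r)
            for r in results
        ]
        rates[fraction] = sum(flags) / len(flags)

    lod = None
    for fraction in sorted(rates, reverse=True):
        if fraction == 0:
            continue
        if rates[fraction] >= required_rate:
            lod = fraction
        else:
            break
    return LodResult(
        lob_droplets=lob_droplets,
        lod_pct=None if lod is None else 100.0 * lod,
        detection_rates=rates,
    )
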