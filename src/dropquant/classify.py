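"""Droplet population assignment from two-channel amplitudes.

A drop-off assay produces up to three droplet clouds in the 2-D amplitude
plane: double-negative (empty droplets), double-positive (wild-type
template; both FAM and HEX probes fire) and FAM-only (mutant template; the
hotspot mutation abolishes HEX binding). Because those clouds sit on a
quadrant grid, the two channels are thresholded independently with a 1-D
two-means split, and droplets are assigned by the quadrant rule. HEX-only
droplets are anomalous — the FAM reference probe sits in the same amplicon
and must fire whenever any template is present — so they are counted and
surfaced through QC rather than merged into another population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, InvalidCountsError, InvalidParameterError
from .simulate import DropletWell

__all__ = [
    "ChannelThresholds",
    "ClassifiedWell",
    "QCVerdict",
    "fit_thresholds",
    "classify_droplets",
    "classify_well",
    "qc_well",
]

# two-means settings: deterministic 5th/95th-percentile initialisation,
# declared single-cluster when the means are closer than 3 pooled within-SDs
_MAX_ITER = 100
_TOL = 1e-6
_MIN_SEPARATION_SD = 3.0

DEFAULT_MIN_DROPLETS = 10000
DEFAULT_MAX_HEX_ONLY_FRACTION = 0.005


@dataclass(frozen=True)
class ChannelThresholds:
    """Per-channel amplitude cuts separating negative from positive droplets."""

    ch1_cut: float
    ch2_cut: float
    method: str = "two_means"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ch1_cut) and math.isfinite(self.ch2_cut)):
            raise InvalidParameterError("threshold cuts must be finite")
        if self.method not in ("two_means", "manual"):
            raise InvalidParameterError(f"unknown threshold method {self.method!r}")


@dataclass(frozen=True)
class ClassifiedWell:
    """Droplet counts per population for one well.

    The four populations partition the well:
    ``n_negative + n_double_positive + n_fam_only + n_hex_only == n_total``.
    """

    well_id: str
    n_total: int
    n_negative: int
    n_double_positive: int
    n_fam_only: int
    n_hex_only: int
    thresholds: ChannelThresholds | None = None

    def __post_init__(self) -> None:
        counts = (self.n_negative, self.n_double_positive, self.n_fam_only, self.n_hex_only)
        if any(c < 0 for c in counts) or self.n_total < 0:
            raise InvalidCountsError("droplet counts must be >= 0")
        if sum(counts) != self.n_total:
            raise InvalidCountsError(
                f"population counts sum to {sum(counts)}, expected n_total={self.n_total}"
            )


@dataclass(frozen=True)
class QCVerdict:
    passed: bool
    reasons: tuple[str, ...] = ()


def _two_means_cut(x: np.ndarray) -> tuple[float, bool]:
    """1-D two-means threshold; returns (cut, single_cluster_flag).

    Initialised at the 5th and 95th percentiles, iterated to convergence
    (midpoint assignment, <=100 iterations, tolerance 1e-6). If the final
    means are separated by less than 3 pooled within-cluster SDs the channel
    is declared single-cluster and the cut is placed above the maximum, so
    every droplet is negative on that channel.
    """
    x = np.asarray(x, dtype=float)
    m0, m1 = np.percentile(x, [5.0, 95.0])
    for _ in range(_MAX_ITER):
        mid = 0.5 * (m0 + m1)
        left = x <= mid
        n0 = int(left.sum())
        new0 = float(x[left].mean()) if n0 else m0
        new1 = float(x[~left].mean()) if n0 < len(x) else m1
        shift = abs(new0 - m0) + abs(new1 - m1)
        m0, m1 = new0, new1
        if shift < _TOL:
            break
    left = x <= 0.5 * (m0 + m1)
    ss = float(((x[left] - m0) ** 2).sum() + ((x[~left] - m1) ** 2).sum())
    pooled_sd = math.sqrt(ss / len(x))
    separation = m1 - m0
    if separation <= 0 or separation < _MIN_SEPARATION_SD * pooled_sd:
        return float(x.max()) + 1.0, True
    return 0.5 * (m0 + m1), False


def fit_thresholds(well: DropletWell) -> ChannelThresholds:
    """Fit per-channel amplitude cuts on one well.

    Each channel is thresholded independently; single-cluster channels (no
    positive cloud) get a cut above the channel maximum. Deterministic:
    no RNG, and droplet order does not matter.
    """
    if well.n_droplets < 2:
        raise InsufficientDataError("need at least 2 droplets to fit thresholds")
    ch1_cut, _ = _two_means_cut(well.amplitudes[:, 0])
    ch2_cut, _ = _two_means_cut(well.amplitudes[:, 1])
    return ChannelThresholds(ch1_cut=ch1_cut, ch2_cut=ch2_cut, method="two_means")


def classify_droplets(well: DropletWell, thresholds: ChannelThresholds) -> ClassifiedWell:
    """Assign each droplet to a population by the quadrant rule.

    FAM (channel 1) above its cut with HEX (channel 2) above its cut is
    double-positive (wild-type template); FAM above with HEX below is
    FAM-only (mutant template); both below is negative; HEX above with FAM
    below is the anomalous HEX-only quadrant.
    """
    ch1 = well.amplitudes[:, 0] > thresholds.ch1_cut
    ch2 = well.amplitudes[:, 1] > thresholds.ch2_cut
    n_double_positive = int(np.sum(ch1 & ch2))
    n_fam_only = int(np.sum(ch1 & ~ch2))
    n_hex_only = int(np.sum(~ch1 & ch2))
    n_negative = int(np.sum(~ch1 & ~ch2))
    return ClassifiedWell(
        well_id=well.well_id,
        n_total=well.n_droplets,
        n_negative=n_negative,
        n_double_positive=n_double_positive,
        n_fam_only=n_fam_only,
        n_hex_only=n_hex_only,
        thresholds=thresholds,
    )


def classify_well(well: DropletWell, thresholds: ChannelThresholds | None = None) -> ClassifiedWell:
    """Fit thresholds (unless given) and classify one well."""
    if thresholds is None:
        thresholds = fit_thresholds(well)
    return classify_droplets(well, thresholds)


def qc_well(
    cw: ClassifiedWell,
    min_droplets: int = DEFAULT_MIN_DROPLETS,
    max_hex_only_fraction: float = DEFAULT_MAX_HEX_ONLY_FRACTION,
) -> QCVerdict:
    """Well-level quality control: enough droplets, no anomalous population."""
    reasons = []
    if cw.n_total < min_droplets:
        reasons.append(f"too few droplets: {cw.n_total} < {min_droplets}")
    if cw.n_total > 0 and cw.n_hex_only / cw.n_total > max_hex_only_fraction:
        reasons.append(
            "anomalous HEX-only population: "
            f"{cw.n_hex_only}/{cw.n_total} > {max_hex_only_fraction:g}"
        )
    return QCVerdict(passed=not reasons, reasons=tuple(reasons))
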