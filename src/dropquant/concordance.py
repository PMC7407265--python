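"""Inter-method agreement statistics and marker-trajectory concordance.

Two mutation-calling methods applied to the same samples yield a 2×2
contingency table; agreement is summarised by the observed proportion
(a + d)/n and by Cohen's kappa, which corrects that proportion for the
agreement expected by chance from the marginals:

    κ = (p_o − p_e) / (1 − p_e),
    p_e = [(a+c)(a+b) + (b+d)(c+d)] / n².

For longitudinal monitoring, a burden trajectory is judged against the
clinical course by an explicit rule: remission timepoints must show the
marker near-negative (or collapsed relative to diagnosis) and progression
timepoints must be heralded by a rise in burden. The rule's parameters are
configurable and the defaults are illustrative, not clinically validated.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

from .errors import (
    AlignmentError,
    InsufficientDataError,
    UndefinedStatisticError,
    ValidationError,
)

__all__ = [
    "ContingencyTable",
    "MrdSeries",
    "build_contingency",
    "observed_agreement",
    "cohens_kappa",
    "prevalence",
    "recovered_positives",
    "mrd_concordance",
    "round_half_up",
]

MRD_STATUSES = ("diagnosis", "CR", "progression")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, matching how prevalences are printed."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 agreement counts: a = both positive, b = B-only positive,
    c = A-only positive, d = both negative."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency counts must be >= 0")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def transpose(self) -> "ContingencyTable":
        """Swap the roles of the two methods."""
        return ContingencyTable(a=self.a, b=self.c, c=self.b, d=self.d)


def build_contingency(
    calls_a: Mapping[str, bool], calls_b: Mapping[str, bool]
) -> ContingencyTable:
    """Cross-tabulate two per-sample boolean call sets keyed by sample id."""
    only_a = sorted(set(calls_a) - set(calls_b))
    only_b = sorted(set(calls_b) - set(calls_a))
    if only_a or only_b:
        raise AlignmentError(
            f"sample ids differ between call sets: only in A={only_a}, only in B={only_b}"
        )
    a = b = c = d = 0
    for sid, call_a in calls_a.items():
        call_b = calls_b[sid]
        if call_a and call_b:
            a += 1
        elif call_b:
            b += 1
        elif call_a:
            c += 1
        else:
            d += 1
    return ContingencyTable(a=a, b=b, c=c, d=d)


def observed_agreement(t: ContingencyTable) -> float:
    """Proportion of samples on which the two methods agree: (a + d)/n."""
    if t.n < 1:
        raise InsufficientDataError("empty contingency table")
    return (t.a + t.d) / t.n


def cohens_kappa(t: ContingencyTable) -> float:
    """Chance-corrected agreement; undefined when both marginals are degenerate."""
    if t.n < 1:
        raise InsufficientDataError("empty contingency table")
    n2 = t.n * t.n
    p_e = ((t.a + t.c) * (t.a + t.b) + (t.b + t.d) * (t.c + t.d)) / n2
    if p_e == 1.0:
        raise UndefinedStatisticError("kappa undefined: expected agreement is 1")
    p_o = observed_agreement(t)
    return (p_o - p_e) / (1.0 - p_e)


@dataclass(frozen=True)
class Prevalence:
    n_positive: int
    n: int
    percent: float
    by_subtype: dict | None = None


def prevalence(
    calls: Mapping[str, bool], subtypes: Mapping[str, str] | None = None
) -> Prevalence:
    """Positive count and percentage (one decimal, half-up), with an optional
    per-subtype breakdown (e.g. R140Q vs R172K) among the positives."""
    if len(calls) == 0:
        raise InsufficientDataError("no samples")
    n = len(calls)
    positives = [sid for sid, flag in calls.items() if flag]
    by_subtype = None
    if subtypes is not None:
        by_subtype = {}
        for sid in positives:
            label = subtypes.get(sid, "unknown")
            by_subtype[label] = by_subtype.get(label, 0) + 1
    return Prevalence(
        n_positive=len(positives),
        n=n,
        percent=round_half_up(100.0 * len(positives) / n, 1),
        by_subtype=by_subtype,
    )


def recovered_positives(t: ContingencyTable) -> tuple[int, float]:
    """Samples positive by method A but missed by method B: the count c and
    its percentage of the whole series (one decimal, half-up)."""
    if t.n < 1:
        raise InsufficientDataError("empty contingency table")
    return t.c, round_half_up(100.0 * t.c / t.n, 1)


@dataclass(frozen=True)
class MrdSeries:
    """A longitudinal allele-burden trajectory with clinical status labels.

    ``timepoints`` are months (strictly increasing), ``burden`` percent MAF
    in [0, 100], ``status`` one of diagnosis / CR / progression.
    """

    timepoints: tuple
    burden: tuple
    status: tuple

    def __post_init__(self) -> None:
        if not (len(self.timepoints) == len(self.burden) == len(self.status)):
            raise ValidationError("timepoints, burden and status must align")
        if len(self.timepoints) < 2:
            raise ValidationError("need at least two timepoints")
        if any(t2 <= t1 for t1, t2 in zip(self.timepoints, self.timepoints[1:])):
            raise ValidationError("timepoints must be strictly increasing")
        if any(not 0.0 <= b <= 100.0 for b in self.burden):
            raise ValidationError("burden values must be in [0, 100]")
        if any(s not in MRD_STATUSES for s in self.status):
            raise ValidationError(
                f"every timepoint needs a status label from {MRD_STATUSES}"
            )


def mrd_concordance(
    series: MrdSeries,
    negativity_threshold: float = 0.1,
    rise_factor: float = 2.0,
    cr_relative_fraction: float = 0.10,
) -> str:
    """Judge whether a burden trajectory tracks the clinical course.

    Concordant iff every CR timepoint has burden below
    ``negativity_threshold`` percent (or at most ``cr_relative_fraction`` of
    the diagnosis burden), and every progression timepoint is preceded by or
    coincides with a ≥ ``rise_factor``-fold increase over the preceding
    timepoint. Invariant to uniform time shifts: only order matters.
    """
    burden = series.burden
    try:
        diag_burden = burden[series.status.index("diagnosis")]
    except ValueError:
        diag_burden = burden[0]

    for i, status in enumerate(series.status):
        if status == "CR":
            if not (
                burden[i] < negativity_threshold
                or burden[i] <= cr_relative_fraction * diag_burden
            ):
                return "discordant"
        elif status == "progression":
            if not any(_rises(burden[j - 1], burden[j], rise_factor) for j in range(1, i + 1)):
                return "discordant"
    return "concordant"


def _rises(prev: float, curr: float, rise_factor: float) -> bool:
    if prev == 0.0:
        return curr > 0.0
    return curr >= rise_factor * prev
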