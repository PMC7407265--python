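"""ARMS qPCR ΔΔCt mutation calling against a healthy-donor baseline.

Allele-specific (ARMS) qPCR runs two reactions per sample: a mutant-allele
assay and a wild-type copy-number control. Calling works on cycle-threshold
(Ct) differences:

    ΔCt_sample  = Ct(mutant allele) − Ct(wild-type copy number)
    ΔCt_healthy = the same difference measured on a healthy donor
    ΔΔCt        = ΔCt_sample − ΔCt_healthy

The categorical rules: a sample is called *mutated* when ΔΔCt > 4,
*wild-type* when ΔΔCt < 3, and *borderline* in between (both endpoints
inclusive). Regardless of ΔΔCt, a mutant-allele Ct above 37 — or no
amplification at all within the 40-cycle run — forces a wild-type call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .errors import MissingDataError, InvalidParameterError, ValidationError

__all__ = ["Call", "ArmsSample", "compute_ddct", "call_sample", "call_batch"]

TOTAL_CYCLES = 40.0
CT_WT_GATE = 37.0
DDCT_MUTATED = 4.0
DDCT_WILD_TYPE = 3.0


class Call(str, Enum):
    MUTATED = "mutated"
    WILD_TYPE = "wild_type"
    BORDERLINE = "borderline"


@dataclass
class ArmsSample:
    """One sample's Ct measurements, derived ΔCt/ΔΔCt values and call."""

    sample_id: str
    assay: str
    ct_mut: float          # NaN = undetermined (no amplification in 40 cycles)
    ct_wt_copy: float
    healthy_ct_mut: float
    healthy_ct_wt_copy: float
    delta_ct_sample: float = math.nan
    delta_ct_healthy: float = math.nan
    ddct: float = math.nan
    call: Call | None = None


def _check_ct(value: float, name: str, allow_undetermined: bool = False) -> None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        if allow_undetermined:
            return
        raise MissingDataError(f"missing Ct value: {name}")
    if not (0.0 < value <= TOTAL_CYCLES):
        raise InvalidParameterError(f"{name}={value} outside (0, {TOTAL_CYCLES:g}]")


def compute_ddct(
    ct_mut: float,
    ct_wt_copy: float,
    healthy_ct_mut: float,
    healthy_ct_wt_copy: float,
) -> tuple[float, float, float]:
    """Return (ΔCt_sample, ΔCt_healthy, ΔΔCt).

    The mutant-allele Ct may be NaN (undetermined), in which case the
    sample ΔCt and ΔΔCt are NaN and the caller's Ct gate applies; any other
    missing Ct raises :class:`MissingDataError` naming the field.
    """
    _check_ct(ct_mut, "ct_mut", allow_undetermined=True)
    _check_ct(ct_wt_copy, "ct_wt_copy")
    _check_ct(healthy_ct_mut, "healthy_ct_mut")
    _check_ct(healthy_ct_wt_copy, "healthy_ct_wt_copy")
    delta_ct_sample = ct_mut - ct_wt_copy
    delta_ct_healthy = healthy_ct_mut - healthy_ct_wt_copy
    return delta_ct_sample, delta_ct_healthy, delta_ct_sample - delta_ct_healthy


def call_sample(ct_mut: float, ddct: float) -> Call:
    """Categorical call from the mutant-allele Ct and ΔΔCt.

    Precedence: the Ct gate first (Ct > 37 or undetermined → wild-type),
    then ΔΔCt > 4 → mutated, ΔΔCt < 3 → wild-type, else borderline.
    """
    if ct_mut is None or math.isnan(ct_mut) or ct_mut > CT_WT_GATE:
        return Call.WILD_TYPE
    if ddct > DDCT_MUTATED:
        return Call.MUTATED
    if ddct < DDCT_WILD_TYPE:
        return Call.WILD_TYPE
    return Call.BORDERLINE


def call_batch(table: pd.DataFrame, invert_ddct: bool = False) -> tuple[pd.DataFrame, dict]:
    """Call every sample in a Ct table.

    ``table`` needs columns ``sample_id, assay, ct_mut, ct_wt_copy,
    is_healthy_donor``; exactly one healthy-donor row per assay provides the
    baseline. Returns the completed table (delta columns and call added,
    donor rows excluded) and a count per call category. ``invert_ddct``
    flips the ΔΔCt sign before calling, for kits that define the contrast
    the other way around.
    """
    required = {"sample_id", "assay", "ct_mut", "ct_wt_copy", "is_healthy_donor"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"Ct table missing columns: {sorted(missing)}")

    out_rows = []
    counts = {c.value: 0 for c in Call}
    for assay, group in table.groupby("assay", sort=False):
        donors = group[group["is_healthy_donor"].astype(bool)]
        if len(donors) != 1:
            raise ValidationError(
                f"assay {assay!r} needs exactly one healthy-donor row, found {len(donors)}"
            )
        donor = donors.iloc[0]
        samples = group[~group["is_healthy_donor"].astype(bool)]
        dup = samples["sample_id"][samples["sample_id"].duplicated()]
        if len(dup):
            raise ValidationError(
                f"duplicated sample_id in assay {assay!r}: {sorted(set(dup))}"
            )
        for _, row in samples.iterrows():
            d_sample, d_healthy, ddct = compute_ddct(
                row["ct_mut"], row["ct_wt_copy"], donor["ct_mut"], donor["ct_wt_copy"]
            )
            if invert_ddct:
                ddct = -ddct
            call = call_sample(row["ct_mut"], ddct)
            counts[call.value] += 1
            out_rows.append(
                {
                    "sample_id": row["sample_id"],
                    "assay": assay,
                    "ct_mut": row["ct_mut"],
                    "ct_wt_copy": row["ct_wt_copy"],
                    "delta_ct_sample": d_sample,
                    "delta_ct_healthy": d_healthy,
                    "ddct": ddct,
                    "call": call.value,
                }
            )
    columns = [
        "sample_id", "assay", "ct_mut", "ct_wt_copy",
        "delta_ct_sample", "delta_ct_healthy", "ddct", "call",
    ]
    return pd.DataFrame(out_rows, columns=columns), counts
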