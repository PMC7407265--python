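"""CSV dialects for the pipeline stages.

Amplitude tables mirror a droplet-reader export: one row per droplet with
``well_id, assay, ch1_amplitude, ch2_amplitude`` and, for simulated data
written with truth, ``n_wt, n_mut``. Classification and quantification
tables carry one row per well.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classify import ChannelThresholds, ClassifiedWell, QCVerdict
from .quantify import DropOffResult
from .simulate import DropletWell

AMPLITUDE_COLUMNS = ["well_id", "assay", "ch1_amplitude", "ch2_amplitude"]


def write_amplitude_csv(wells: Iterable[DropletWell], path, with_truth: bool = False) -> None:
    frames = []
    for well in wells:
        frame = pd.DataFrame(
            {
                "well_id": well.well_id,
                "assay": well.assay,
                "ch1_amplitude": well.amplitudes[:, 0],
                "ch2_amplitude": well.amplitudes[:, 1],
            }
        )
        if with_truth:
            if well.truth is None:
                raise ValueError(f"well {well.well_id} has no truth labels")
            frame["n_wt"] = well.truth[:, 0]
            frame["n_mut"] = well.truth[:, 1]
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_amplitude_csv(path) -> list[DropletWell]:
    df = pd.read_csv(path)
    has_truth = {"n_wt", "n_mut"}.issubset(df.columns)
    wells = []
    for well_id, group in df.groupby("well_id", sort=False):
        amplitudes = group[["ch1_amplitude", "ch2_amplitude"]].to_numpy(dtype=float)
        truth = group[["n_wt", "n_mut"]].to_numpy(dtype=np.int64) if has_truth else None
        assay = str(group["assay"].iloc[0]) if "assay" in df.columns else "R140"
        wells.append(DropletWell(str(well_id), assay, amplitudes, truth=truth))
    return wells


def write_classified_csv(rows: Sequence[tuple[ClassifiedWell, QCVerdict]], path) -> None:
    records = []
    for cw, qc in rows:
        thr = cw.thresholds
        records.append(
            {
                "well_id": cw.well_id,
                "n_total": cw.n_total,
                "n_negative": cw.n_negative,
                "n_double_positive": cw.n_double_positive,
                "n_fam_only": cw.n_fam_only,
                "n_hex_only": cw.n_hex_only,
                "ch1_cut": thr.ch1_cut if thr else float("nan"),
                "ch2_cut": thr.ch2_cut if thr else float("nan"),
                "qc_pass": qc.passed,
                "qc_reasons": "; ".join(qc.reasons),
            }
        )
    pd.DataFrame.from_records(records).to_csv(path, index=False)


def read_classified_csv(path) -> list[ClassifiedWell]:
    df = pd.read_csv(path)
    wells = []
    for _, row in df.iterrows():
        thresholds = None
        if "ch1_cut" in df.columns and np.isfinite(row["ch1_cut"]):
            thresholds = ChannelThresholds(
                ch1_cut=float(row["ch1_cut"]), ch2_cut=float(row["ch2_cut"])
            )
        wells.append(
            ClassifiedWell(
                well_id=str(row["well_id"]),
                n_total=int(row["n_total"]),
                n_negative=int(row["n_negative"]),
                n_double_positive=int(row["n_double_positive"]),
                n_fam_only=int(row["n_fam_only"]),
                n_hex_only=int(row["n_hex_only"]),
                thresholds=thresholds,
            )
        )
    return wells


def write_quantified_csv(results: Sequence[DropOffResult], path) -> None:
    pd.DataFrame.from_records(
        [
            {
                "well_id": r.well_id,
                "lam_total": r.lam_total,
                "lam_wt": r.lam_wt,
                "lam_mut": r.lam_mut,
                "concentration_copies_per_ul": r.concentration,
                "maf_pct": r.maf,
                "maf_ci_low": r.maf_ci_low,
                "maf_ci_high": r.maf_ci_high,
                "detected": r.detected,
            }
            for r in results
        ]
    ).to_csv(path, index=False)
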