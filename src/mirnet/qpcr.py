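"""Relative qPCR quantification: 2^-ddCt fold changes and standard-curve efficiency.

dCt = Ct(target) - Ct(reference) within a group; ddCt = dCt(sample) -
dCt(calibrator); fold change = 2^(-ddCt) (Livak convention: positive ddCt
means down-regulation). Amplification efficiency from a standard-curve slope
(Ct per log10 dilution) is E = 10^(-1/slope) - 1, so a slope of
-1/log10(2) ~ -3.32 is 100% efficiency (one doubling per cycle).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import DataError

logger = logging.getLogger("mirnet")


@dataclass(frozen=True)
class CtRecord:
    sample_id: str
    target_id: str
    reference_id: str
    ct_target: float
    ct_reference: float
    calibrator: bool = False

    def __post_init__(self) -> None:
        for name, ct in (("target", self.ct_target), ("reference", self.ct_reference)):
            if not 0 < ct < 50:
                raise DataError(f"{self.sample_id}/{self.target_id}: {name} Ct {ct} outside (0, 50)")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


def delta_delta_ct(sample: CtRecord, calibrator: CtRecord, negate: bool = True) -> float:
    """Fold change of ``sample`` relative to ``calibrator``: 2^(-ddCt).

    ``negate=False`` gives the literal 2^(+ddCt) reading.
    """
    if sample.target_id != calibrator.target_id or sample.reference_id != calibrator.reference_id:
        raise DataError(
            f"sample ({sample.target_id}/{sample.reference_id}) and calibrator "
            f"({calibrator.target_id}/{calibrator.reference_id}) must share target and reference")
    ddct = sample.delta_ct - calibrator.delta_ct
    return 2.0 ** (-ddct if negate else ddct)


def standard_curve_efficiency(slope: float) -> float:
    """Amplification efficiency fraction from a Ct-vs-log10-dilution slope."""
    if slope >= 0:
        raise DataError(f"standard-curve slope must be negative, got {slope}")
    return 10.0 ** (-1.0 / slope) - 1.0


def slope_for_efficiency(efficiency: float) -> float:
    """Inverse of :func:`standard_curve_efficiency`."""
    if efficiency <= 0:
        raise DataError("efficiency must be positive")
    return -1.0 / math.log10(1.0 + efficiency)


def summarize_replicates(records: list[CtRecord], negate: bool = True) -> pd.DataFrame:
    """Per-(sample, target) geometric-mean fold over replicates, vs the calibrator.

    The calibrator group's ddCt baseline is the mean dCt of records flagged
    ``calibrator`` for the same target. Folds are averaged on the ddCt scale
    (arithmetic mean of ddCt = geometric mean of folds); the spread column is
    the standard deviation of the replicate log2 folds. A single replicate
    yields an undefined (NaN) sd with a warning.
    """
    by_target_cal: dict[str, list[float]] = {}
    for r in records:
        if r.calibrator:
            by_target_cal.setdefault(r.target_id, []).append(r.delta_ct)
    rows = []
    groups: dict[tuple[str, str], list[float]] = {}
    for r in records:
        if r.calibrator:
            continue
        if r.target_id not in by_target_cal:
            raise DataError(f"no calibrator records for target {r.target_id!r}")
        cal_dct = float(np.mean(by_target_cal[r.target_id]))
        ddct = r.delta_ct - cal_dct
        groups.setdefault((r.sample_id, r.target_id), []).append(-ddct if negate else ddct)
    for (sample, target), log2_folds in sorted(groups.items()):
        if len(log2_folds) < 2:
            logger.warning("%s/%s: single replicate, sd undefined", sample, target)
            sd = float("nan")
        else:
            sd = float(np.std(log2_folds, ddof=1))
        rows.append((sample, target, len(log2_folds),
                     float(2.0 ** np.mean(log2_folds)), sd))
    return pd.DataFrame(rows, columns=["sample_id", "target_id", "n_replicates",
                                       "fold_geomean", "log2_fold_sd"])
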