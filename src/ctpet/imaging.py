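"""PET/CT metabolic parameters: SUVTBR and pre/post delta tables.

SUV extraction from images is upstream of this package; metrics arrive as
numbers (SUVmax, SUVmean, MTV in ml, TLG in SUV*ml, blood-pool SUVmax) and
are validated, combined into SUVTBR, and arranged into a per-patient wide
table of pre/post values and deltas.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .quant import DataError, delta_metric

PET_METRICS = ("suvmax", "suvmean", "mtv", "tlg", "bloodpool_suvmax", "suvtbr")


class UndefinedRatioError(ValueError):
    pass


def compute_suvtbr(tumor_suvmax: float, bloodpool_suvmax: float) -> float:
    """Tumor-to-blood-pool ratio: primary-tumor SUVmax / blood-pool SUVmax."""
    if bloodpool_suvmax is None or not bloodpool_suvmax > 0:
        raise UndefinedRatioError("blood-pool SUVmax must be positive")
    if tumor_suvmax < 0:
        raise DataError("SUVmax must be nonnegative")
    return tumor_suvmax / bloodpool_suvmax


@dataclass
class PetMetrics:
    """One PET/CT reading for a sample at one timepoint."""

    sample_id: str
    timepoint: str
    suvmax: float = math.nan
    suvmean: float = math.nan
    mtv: float = math.nan
    tlg: float = math.nan
    bloodpool_suvmax: float = math.nan

    def __post_init__(self):
        for name in ("suvmax", "suvmean", "mtv", "tlg", "bloodpool_suvmax"):
            v = getattr(self, name)
            if v is not None and not math.isnan(v) and v < 0:
                raise DataError(f"{name} must be nonnegative, got {v}")

    @property
    def suvtbr(self) -> float:
        if math.isnan(self.bloodpool_suvmax) or self.bloodpool_suvmax <= 0:
            return math.nan
        if math.isnan(self.suvmax):
            return math.nan
        return compute_suvtbr(self.suvmax, self.bloodpool_suvmax)

    def check_tlg_consistency(self, rtol: float = 0.05) -> bool:
        """Warn (not fail) when TLG strays from SUVmean x MTV."""
        if any(math.isnan(v) for v in (self.tlg, self.suvmean, self.mtv)):
            return True
        expected = self.suvmean * self.mtv
        ok = math.isclose(self.tlg, expected, rel_tol=rtol, abs_tol=1e-9)
        if not ok:
            warnings.warn(
                f"{self.sample_id}/{self.timepoint}: TLG {self.tlg:.3g} "
                f"deviates from SUVmean*MTV {expected:.3g}",
                stacklevel=2,
            )
        return ok


def metric_table(records: Iterable[PetMetrics]) -> pd.DataFrame:
    """One row per patient with <metric>_pre, _post and _delta columns.

    Missing timepoints propagate as NaN; duplicate (sample, timepoint)
    readings are a data error.
    """
    records = list(records)
    seen = set()
    for r in records:
        key = (r.sample_id, r.timepoint)
        if key in seen:
            raise DataError(f"duplicate PET record for {key}")
        seen.add(key)

    patients = sorted({r.sample_id for r in records})
    by_key = {(r.sample_id, r.timepoint): r for r in records}
    rows = []
    for pid in patients:
        row: dict = {"sample_id": pid}
        for metric in PET_METRICS:
            vals = {}
            for tp in ("pre", "post"):
                rec = by_key.get((pid, tp))
                vals[tp] = getattr(rec, metric) if rec is not None else math.nan
            row[f"{metric}_pre"] = vals["pre"]
            row[f"{metric}_post"] = vals["post"]
            row[f"{metric}_delta"] = delta_metric(vals["pre"], vals["post"])
        rows.append(row)
    return pd.DataFrame(rows, columns=["sample_id"] + [
        f"{m}_{s}" for m in PET_METRICS for s in ("pre", "post", "delta")
    ])
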