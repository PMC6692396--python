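"""Delta-Ct normalization and 2^-ddCt fold change against a calibrator group.

Sign convention: delta Ct = target Ct minus the mean reference Ct, so a
HIGHER delta Ct means LOWER expression.  Averaging reference Ct values on
the cycle (log) scale is equivalent to taking the geometric mean of their
linear quantities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ct_data import CtTable

logger = logging.getLogger(__name__)


class ParameterError(ValueError):
    pass


@dataclass
class DeltaCtVector:
    """Per-sample normalized expression of one target gene."""

    target: str
    refs: tuple[str, ...]
    values: pd.Series  # indexed by sample_id

    def __post_init__(self) -> None:
        if not self.refs:
            raise ParameterError("reference gene set must be non-empty")
        self.refs = tuple(self.refs)
        self.values = self.values.astype(float)


@dataclass
class FoldChangeResult:
    """Per-sample ddCt and 2^-ddCt fold change relative to a calibrator group."""

    target: str
    calibrator: str
    table: pd.DataFrame  # columns: delta_ct, delta_delta_ct, fold_change


def delta_ct(table: CtTable, target: str, refs: list[str]) -> DeltaCtVector:
    """delta Ct = Ct(target) - mean Ct(refs), per sample.

    Samples missing the target or any reference Ct are dropped (logged).
    Duplicate reference genes are rejected rather than silently deduplicated.
    """
    refs = tuple(refs)
    if not refs:
        raise ParameterError("empty reference gene set")
    if len(set(refs)) != len(refs):
        raise ParameterError(f"duplicate reference genes in {refs}")
    if target in refs:
        raise ParameterError(f"target {target} cannot be its own reference")
    missing = [g for g in (target, *refs) if g not in table.genes]
    if missing:
        raise ParameterError(f"genes not in table: {missing}")

    sub = table.ct[[target, *refs]]
    complete = sub.dropna(axis=0)
    dropped = set(sub.index) - set(complete.index)
    if dropped:
        logger.info("delta_ct(%s|%s): dropped samples with missing Ct: %s",
                    target, ",".join(refs), sorted(dropped))
    values = complete[target] - complete[list(refs)].mean(axis=1)
    return DeltaCtVector(target=target, refs=refs, values=values)


def fold_change(
    dct: DeltaCtVector,
    calibrator: str,
    meta: pd.Series,
) -> FoldChangeResult:
    """ddCt relative to the calibrator group's mean delta Ct; FC = 2^-ddCt."""
    meta = pd.Series(meta)
    cal_samples = meta.index[meta == calibrator].intersection(dct.values.index)
    if len(cal_samples) == 0:
        raise ParameterError(
            f"calibrator group {calibrator!r} has no samples with delta Ct"
        )
    baseline = float(dct.values.loc[cal_samples].mean())
    ddct = dct.values - baseline
    table = pd.DataFrame(
        {
            "delta_ct": dct.values,
            "delta_delta_ct": ddct,
            "fold_change": np.power(2.0, -ddct),
        }
    )
    return FoldChangeResult(target=dct.target, calibrator=calibrator, table=table)
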