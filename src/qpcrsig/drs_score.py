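"""Disease Risk Scores from normalized qPCR data or log-intensity matrices.

qPCR scale (delta Ct based; higher score = viral):

* two-transcript: log(dCt_FAM89A + 10) - log(dCt_IFI44L + 10)
* one-transcript: -log(dCt_IFI44L + 10)

The +10 shift keeps log arguments positive for typical delta Ct ranges; the
published cut-points are only meaningful at shift 10 and log base 10, so
overriding the shift requires an explicit opt-in flag.  Changing the log
base rescales every score by a positive constant and therefore leaves
rankings, ROC curves and AUC untouched.

Intensity scale (log-expression based, for array/RNA-seq style matrices):

* two-transcript: expr_FAM89A - expr_IFI44L (higher score = bacterial —
  the inverse orientation of the qPCR scale, because higher expression
  means higher intensity but lower Ct)
* one-transcript: -expr_IFI44L (also higher = bacterial, consistent with
  the intensity two-transcript orientation; pick the positive class
  accordingly when computing ROC curves)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .normalization import DeltaCtVector

DRS_SHIFT = 10.0

QPCR_VARIANTS = ("two_transcript_qpcr", "one_transcript_qpcr")
INTENSITY_VARIANTS = ("two_transcript_intensity", "one_transcript_intensity")


class DomainError(ValueError):
    """A shifted delta Ct is nonpositive: the log score is undefined."""


@dataclass
class DrsResult:
    variant: str
    scores: pd.Series  # per sample, dimensionless log units
    refs: tuple[str, ...] = ()
    log_base: float = 10.0

    def __post_init__(self) -> None:
        if self.variant not in QPCR_VARIANTS + INTENSITY_VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        self.scores = self.scores.astype(float)


def _check_shift(values: pd.Series, gene: str, shift: float) -> pd.Series:
    shifted = values + shift
    bad = shifted[shifted <= 0]
    if len(bad):
        raise DomainError(
            f"{gene}: delta Ct <= {-shift:g} for sample(s) "
            f"{list(bad.index)}; shifted log argument nonpositive"
        )
    return shifted


def _resolve_shift(shift: float, allow_nonstandard_shift: bool) -> float:
    if shift != DRS_SHIFT and not allow_nonstandard_shift:
        raise ValueError(
            f"shift {shift} != {DRS_SHIFT}: published cut-points assume the "
            "standard shift; pass allow_nonstandard_shift=True to override"
        )
    return shift


def drs_two_transcript(
    dct_fam89a: DeltaCtVector,
    dct_ifi44l: DeltaCtVector,
    log_base: float = 10.0,
    shift: float = DRS_SHIFT,
    allow_nonstandard_shift: bool = False,
) -> DrsResult:
    """log(dCt_FAM89A + 10) - log(dCt_IFI44L + 10); higher = viral."""
    shift = _resolve_shift(shift, allow_nonstandard_shift)
    if dct_fam89a.refs != dct_ifi44l.refs:
        raise ValueError(
            f"delta Ct vectors use different reference sets: "
            f"{dct_fam89a.refs} vs {dct_ifi44l.refs}"
        )
    common = dct_fam89a.values.index.intersection(dct_ifi44l.values.index)
    f = _check_shift(dct_fam89a.values.loc[common], dct_fam89a.target, shift)
    i = _check_shift(dct_ifi44l.values.loc[common], dct_ifi44l.target, shift)
    scores = (np.log(f) - np.log(i)) / np.log(log_base)
    return DrsResult(
        variant="two_transcript_qpcr", scores=scores,
        refs=dct_fam89a.refs, log_base=log_base,
    )


def drs_one_transcript(
    dct_ifi44l: DeltaCtVector,
    log_base: float = 10.0,
    shift: float = DRS_SHIFT,
    allow_nonstandard_shift: bool = False,
) -> DrsResult:
    """-log(dCt_IFI44L + 10); the negative sign keeps higher = viral."""
    shift = _resolve_shift(shift, allow_nonstandard_shift)
    i = _check_shift(dct_ifi44l.values, dct_ifi44l.target, shift)
    scores = -np.log(i) / np.log(log_base)
    return DrsResult(
        variant="one_transcript_qpcr", scores=scores,
        refs=dct_ifi44l.refs, log_base=log_base,
    )


def drs_expression_matrix(
    expr_fam89a: pd.Series | None,
    expr_ifi44l: pd.Series,
    variant: str = "two_transcript",
) -> DrsResult:
    """Intensity-scale scores from already log-normalized expression values."""
    expr_ifi44l = pd.Series(expr_ifi44l).astype(float)
    if variant == "two_transcript":
        if expr_fam89a is None:
            raise ValueError("two_transcript variant needs FAM89A expression")
        expr_fam89a = pd.Series(expr_fam89a).astype(float)
        common = expr_fam89a.index.intersection(expr_ifi44l.index)
        scores = expr_fam89a.loc[common] - expr_ifi44l.loc[common]
        return DrsResult(variant="two_transcript_intensity", scores=scores)
    if variant == "one_transcript":
        return DrsResult(variant="one_transcript_intensity", scores=-expr_ifi44l)
    raise ValueError(f"unknown variant {variant!r}")
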