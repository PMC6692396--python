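"""Raw qPCR threshold-cycle (Ct) data model, CSV I/O, and replicate-level QC.

The central object is :class:`CtTable`, a sample x gene matrix of aggregated
Ct values (mean of passing technical replicates) with per-sample group labels.
Raw replicate-level observations are represented by :class:`CtMeasurement`;
:func:`qc_replicates` aggregates them while enforcing the replicate-SD rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_CYCLE_CAP = 40.0
DEFAULT_SD_THRESHOLD = 0.5
VALID_GROUPS = ("bacterial", "viral", "control")

LONG_COLUMNS = ("sample_id", "gene", "replicate", "ct")


class FormatError(ValueError):
    """Input file does not conform to the expected CSV dialect."""


class IntegrityError(ValueError):
    """Input rows are structurally inconsistent (duplicates, conflicts)."""


@dataclass(frozen=True)
class CtMeasurement:
    """All technical replicates of one gene in one sample.

    ``replicate_cts`` holds the raw per-replicate values (NaN where the
    instrument reported no amplification); ``detected_flags`` marks the
    replicates that amplified before the cycle cap.  Only detected
    replicates enter the mean and SD.
    """

    sample_id: str
    gene: str
    replicate_cts: tuple[float, ...]
    detected_flags: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.replicate_cts) == 0:
            raise ValueError(f"{self.sample_id}/{self.gene}: no replicates")
        if len(self.replicate_cts) != len(self.detected_flags):
            raise ValueError("replicate_cts and detected_flags length mismatch")
        for ct, det in zip(self.replicate_cts, self.detected_flags):
            if det and not (np.isfinite(ct) and ct > 0):
                raise ValueError(
                    f"{self.sample_id}/{self.gene}: detected replicate with "
                    f"invalid Ct {ct!r}"
                )

    @classmethod
    def from_raw(
        cls,
        sample_id: str,
        gene: str,
        cts: list[float],
        cycle_cap: float = DEFAULT_CYCLE_CAP,
    ) -> "CtMeasurement":
        """Build from raw values; NaN or Ct >= cycle cap counts as undetected."""
        vals, flags = [], []
        for ct in cts:
            ct = float(ct) if ct is not None else np.nan
            detected = bool(np.isfinite(ct) and 0.0 < ct < cycle_cap)
            vals.append(ct if detected else np.nan)
            flags.append(detected)
        return cls(str(sample_id), str(gene), tuple(vals), tuple(flags))

    @property
    def detected_cts(self) -> np.ndarray:
        return np.array(
            [ct for ct, det in zip(self.replicate_cts, self.detected_flags) if det]
        )

    @property
    def n_detected(self) -> int:
        return int(sum(self.detected_flags))

    def mean(self) -> float:
        cts = self.detected_cts
        return float(cts.mean()) if cts.size else np.nan

    def sd(self, ddof: int = 1) -> float:
        """Replicate SD over detected replicates; NaN when fewer than ddof+1."""
        cts = self.detected_cts
        if cts.size < ddof + 1:
            return np.nan
        return float(cts.std(ddof=ddof))


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    group: str

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise ValueError(
                f"group {self.group!r} not in {VALID_GROUPS} "
                f"(sample {self.sample_id})"
            )


@dataclass
class CtTable:
    """Aggregated sample x gene Ct matrix with optional group labels.

    ``ct`` is a DataFrame indexed by sample_id with gene columns; missing
    entries are NaN.  ``meta`` maps sample_id -> group ('bacterial', 'viral'
    or 'control') and may be None when labels are unknown.
    """

    ct: pd.DataFrame
    meta: pd.Series | None = None
    cycle_cap: float = DEFAULT_CYCLE_CAP

    def __post_init__(self) -> None:
        self.ct = self.ct.astype(float)
        vals = self.ct.to_numpy()
        bad = np.isfinite(vals) & ((vals <= 0) | (vals > self.cycle_cap))
        if bad.any():
            raise ValueError("Ct entries outside (0, cycle_cap]")
        if self.meta is not None:
            self.meta = pd.Series(self.meta).reindex(self.ct.index)
            unknown = set(self.meta.dropna()) - set(VALID_GROUPS)
            if unknown:
                raise ValueError(f"unknown group labels: {sorted(unknown)}")

    @property
    def samples(self) -> list[str]:
        return list(self.ct.index)

    @property
    def genes(self) -> list[str]:
        return list(self.ct.columns)

    def to_csv(self, path) -> None:
        df = self.ct.copy()
        if self.meta is not None:
            df.insert(0, "group", self.meta)
        df.to_csv(path, index_label="sample_id")

    @classmethod
    def from_csv(cls, path, cycle_cap: float = DEFAULT_CYCLE_CAP) -> "CtTable":
        df = pd.read_csv(path, index_col="sample_id")
        df.index = df.index.astype(str)
        meta = None
        if "group" in df.columns:
            meta = df.pop("group")
        return cls(ct=df, meta=meta, cycle_cap=cycle_cap)


@dataclass
class QCReport:
    """Per (sample, gene) replicate-level QC outcome."""

    table: pd.DataFrame  # sample_id, gene, n_detected, replicate_sd, passed
    sd_threshold: float = DEFAULT_SD_THRESHOLD

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path) -> None:
        self.table.to_json(path, orient="records", indent=2)

    @property
    def n_failed(self) -> int:
        return int((~self.table["passed"]).sum())


def _parse_ct_cell(value) -> float:
    """Numeric Ct or NaN for non-numeric cells such as 'Undetermined'."""
    out = pd.to_numeric(pd.Series([value]), errors="coerce").iloc[0]
    return float(out) if pd.notna(out) else np.nan


def read_sample_meta(path) -> list[SampleMeta]:
    df = pd.read_csv(path)
    required = {"sample_id", "group"}
    if not required.issubset(df.columns):
        raise FormatError(f"metadata file must have columns {sorted(required)}")
    if df["sample_id"].duplicated().any():
        raise IntegrityError("duplicate sample_id in metadata")
    return [SampleMeta(str(r.sample_id), str(r.group)) for r in df.itertuples()]


def read_ct_table(
    path,
    format: str = "long",
    cycle_cap: float = DEFAULT_CYCLE_CAP,
) -> tuple[list[CtMeasurement], list[SampleMeta]]:
    """Parse a long- or wide-format replicate-level Ct CSV.

    Long format: columns sample_id, gene, replicate, ct and optionally group.
    Wide format: one row per (sample, replicate); columns sample_id,
    replicate, optionally group, and one column per gene.

    Returns the replicate measurements plus any sample metadata found in the
    file (empty list when no group column is present).
    """
    df = pd.read_csv(path)
    if format == "long":
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"long format requires columns {missing}")
        key = ["sample_id", "gene", "replicate"]
        if df.duplicated(subset=key).any():
            dup = df[df.duplicated(subset=key, keep=False)][key].iloc[0]
            raise IntegrityError(f"duplicate (sample, gene, replicate) key: {tuple(dup)}")
        long = df
    elif format == "wide":
        fixed = [c for c in ("sample_id", "replicate", "group") if c in df.columns]
        if "sample_id" not in fixed or "replicate" not in fixed:
            raise FormatError("wide format requires sample_id and replicate columns")
        if df.duplicated(subset=["sample_id", "replicate"]).any():
            raise IntegrityError("duplicate (sample, replicate) rows in wide input")
        genes = [c for c in df.columns if c not in fixed]
        if not genes:
            raise FormatError("wide format has no gene columns")
        long = df.melt(
            id_vars=fixed, value_vars=genes, var_name="gene", value_name="ct"
        )
    else:
        raise ValueError(f"unknown format {format!r}")

    long = long.copy()
    long["sample_id"] = long["sample_id"].astype(str)
    long["ct"] = [_parse_ct_cell(v) for v in long["ct"]]

    measurements = []
    for (sid, gene), grp in long.groupby(["sample_id", "gene"], sort=False):
        measurements.append(
            CtMeasurement.from_raw(sid, gene, list(grp["ct"]), cycle_cap=cycle_cap)
        )

    meta: list[SampleMeta] = []
    if "group" in long.columns:
        by_sample = long.dropna(subset=["group"]).groupby("sample_id")["group"]
        for sid, vals in by_sample:
            labels = set(vals.astype(str))
            if len(labels) > 1:
                raise IntegrityError(f"sample {sid} has conflicting group labels")
            meta.append(SampleMeta(sid, labels.pop()))
    return measurements, meta


def qc_replicates(
    measurements: list[CtMeasurement],
    meta: list[SampleMeta] | None = None,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
    on_fail: str = "mask",
    cycle_cap: float = DEFAULT_CYCLE_CAP,
) -> tuple[CtTable, QCReport]:
    """Aggregate replicates into a CtTable, applying the replicate-SD rule.

    An entry fails QC when the sample SD (ddof=1) of its detected replicates
    exceeds ``sd_threshold``.  Failing entries are masked as missing by
    default (``on_fail='mask'``); ``on_fail='keep'`` retains the mean with a
    warning.  Entries with zero detected replicates are always missing.
    """
    if sd_threshold <= 0:
        raise ValueError("sd_threshold must be positive")
    if on_fail not in ("mask", "keep"):
        raise ValueError("on_fail must be 'mask' or 'keep'")

    rows = []
    agg: dict[tuple[str, str], float] = {}
    sample_order: list[str] = []
    gene_order: list[str] = []
    for m in measurements:
        if m.sample_id not in sample_order:
            sample_order.append(m.sample_id)
        if m.gene not in gene_order:
            gene_order.append(m.gene)
        sd = m.sd()
        mean = m.mean()
        if m.n_detected == 0:
            logger.warning("%s/%s: no detected replicates, entry missing",
                           m.sample_id, m.gene)
            passed = False
            value = np.nan
        else:
            # SD undefined for a single replicate: cannot fail the rule
            passed = bool(np.isnan(sd) or sd <= sd_threshold)
            value = mean
            if not passed:
                if on_fail == "mask":
                    value = np.nan
                else:
                    logger.warning(
                        "%s/%s: replicate SD %.3f > %.3f, keeping mean",
                        m.sample_id, m.gene, sd, sd_threshold,
                    )
        agg[(m.sample_id, m.gene)] = value
        rows.append(
            {
                "sample_id": m.sample_id,
                "gene": m.gene,
                "n_detected": m.n_detected,
                "replicate_sd": sd,
                "passed": passed,
            }
        )

    ct = pd.DataFrame(
        [[agg.get((s, g), np.nan) for g in gene_order] for s in sample_order],
        index=pd.Index(sample_order, name="sample_id"),
        columns=gene_order,
    )
    meta_series = None
    if meta:
        meta_series = pd.Series(
            {m.sample_id: m.group for m in meta}, name="group"
        ).reindex(sample_order)
    table = CtTable(ct=ct, meta=meta_series, cycle_cap=cycle_cap)
    report = QCReport(table=pd.DataFrame(rows), sd_threshold=sd_threshold)
    return table, report
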