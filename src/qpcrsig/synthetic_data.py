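"""Synthetic qPCR cohorts and intensity matrices with known ground truth.

The generative model for a replicate Ct value is

    Ct = group mean  +  biological noise (per sample x gene)
       + global sample offset (RNA-input variation, shared by all genes)
       + technical replicate noise,

censored at the cycle cap (values at or above the cap are undetected).
Delta-Ct normalization removes the global offset exactly, which is what the
property tests exploit.

``default_cohort_spec`` is calibrated to the published cohort structure:
35 samples (14 bacterial / 11 viral / 10 control); five reference genes
whose between-sample SDs follow the printed ladder 0.843 (PGK1), 0.907
(GUSB), 0.997 (TBP), 1.200 (GAPDH), 1.483 (ACTB) with mean Ct between 21.6
(ACTB, highest expression) and 29.7 (TBP, lowest); a low-expressed FAM89A
target (overall mean Ct ~33.1, mildly up in bacterial samples) and a
high-expressed IFI44L target (overall mean Ct ~27.7, strongly up in viral
samples).  The per-group target means are free parameters calibrated once
so that the two-transcript score medians land near 0.10 (bacterial) and
0.31 (viral) under the standard three-reference normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ct_data import CtMeasurement, SampleMeta, VALID_GROUPS

REFERENCE_GENES = ("PGK1", "GUSB", "TBP", "GAPDH", "ACTB")
TARGET_GENES = ("FAM89A", "IFI44L")


@dataclass(frozen=True)
class GeneSpec:
    """Per-group mean Ct and biological (between-sample) SD for one gene."""

    means: dict[str, float]  # group -> mean Ct
    bio_sd: float

    def __post_init__(self) -> None:
        if self.bio_sd < 0:
            raise ValueError("bio_sd must be >= 0")
        unknown = set(self.means) - set(VALID_GROUPS)
        if unknown:
            raise ValueError(f"unknown groups {sorted(unknown)}")

    @classmethod
    def flat(cls, mean: float, bio_sd: float) -> "GeneSpec":
        return cls({g: mean for g in VALID_GROUPS}, bio_sd)


@dataclass
class CohortSpec:
    group_sizes: dict[str, int]
    genes: dict[str, GeneSpec]
    technical_sd: float = 0.15
    offset_sd: float = 0.5
    n_replicates: int = 3
    cycle_cap: float = 40.0
    reference_genes: tuple[str, ...] = REFERENCE_GENES
    target_genes: tuple[str, ...] = TARGET_GENES

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 0")
        if self.technical_sd < 0 or self.offset_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("need >= 1 replicate")
        refs = [g for g in self.reference_genes if g in self.genes]
        if len(refs) < 2:
            raise ValueError("need >= 2 reference genes in the panel")
        for name, gene in self.genes.items():
            for group, mu in gene.means.items():
                if not (0.0 < mu < self.cycle_cap):
                    raise ValueError(
                        f"{name}/{group}: mean Ct {mu} outside (0, cycle_cap)"
                    )


def default_cohort_spec() -> CohortSpec:
    """Calibrated defaults mirroring the published cohort structure."""
    genes = {
        "PGK1": GeneSpec.flat(25.0, 0.843),
        "GUSB": GeneSpec.flat(27.0, 0.907),
        "TBP": GeneSpec.flat(29.7, 0.997),
        "GAPDH": GeneSpec.flat(22.5, 1.200),
        "ACTB": GeneSpec.flat(21.6, 1.483),
        "FAM89A": GeneSpec(
            {"bacterial": 32.9, "viral": 33.4, "control": 33.2}, 1.8
        ),
        "IFI44L": GeneSpec(
            {"bacterial": 29.0, "viral": 24.9, "control": 28.8}, 1.5
        ),
    }
    return CohortSpec(
        group_sizes={"bacterial": 14, "viral": 11, "control": 10},
        genes=genes,
    )


def _sample_ids(group_sizes: dict[str, int]) -> list[tuple[str, str]]:
    prefix = {"bacterial": "B", "viral": "V", "control": "C"}
    out = []
    for group, n in group_sizes.items():
        for i in range(1, n + 1):
            out.append((f"{prefix.get(group, group[0].upper())}{i:02d}", group))
    return out


def generate_cohort(
    spec: CohortSpec, seed: int | np.random.Generator = 0
) -> tuple[list[CtMeasurement], list[SampleMeta], dict]:
    """Draw a replicate-level synthetic cohort plus its latent truth record.

    The truth record stores the per-sample offsets and latent (pre-technical
    -noise, uncensored) Ct values so tests can verify parameter recovery.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    measurements: list[CtMeasurement] = []
    meta: list[SampleMeta] = []
    offsets: dict[str, float] = {}
    latent: dict[str, dict[str, float]] = {}

    for sample_id, group in _sample_ids(spec.group_sizes):
        meta.append(SampleMeta(sample_id, group))
        # standard-normal draws scaled afterwards: the random stream is
        # independent of the SD settings, so cohorts generated from the same
        # seed with different SDs are sample-wise paired
        offset = rng.normal() * spec.offset_sd
        offsets[sample_id] = offset
        latent[sample_id] = {}
        for gene, gspec in spec.genes.items():
            mu = gspec.means.get(group)
            if mu is None:
                continue
            value = mu + rng.normal() * gspec.bio_sd + offset
            latent[sample_id][gene] = value
            reps = value + rng.normal(size=spec.n_replicates) * spec.technical_sd
            measurements.append(
                CtMeasurement.from_raw(
                    sample_id, gene, list(reps), cycle_cap=spec.cycle_cap
                )
            )
    truth = {"offsets": offsets, "latent_ct": latent}
    return measurements, meta, truth


def cohort_to_long_frame(measurements: list[CtMeasurement],
                         meta: list[SampleMeta]) -> pd.DataFrame:
    """Long-format replicate table as consumed by ct_data.read_ct_table."""
    groups = {m.sample_id: m.group for m in meta}
    rows = []
    for m in measurements:
        for rep, (ct, det) in enumerate(
            zip(m.replicate_cts, m.detected_flags), start=1
        ):
            rows.append(
                {
                    "sample_id": m.sample_id,
                    "gene": m.gene,
                    "replicate": rep,
                    "ct": ct if det else "Undetermined",
                    "group": groups.get(m.sample_id, ""),
                }
            )
    return pd.DataFrame(rows)


def generate_expression_matrix(
    group_sizes: dict[str, int],
    effects: dict[str, dict[str, float]],
    noise_sd: float = 1.0,
    baselines: dict[str, float] | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Log-intensity matrix with additive per-group shifts per gene.

    ``effects[gene][group]`` is the shift (in log-intensity units) added to
    that gene's baseline in that group; unspecified groups get no shift.
    Returns (samples x genes matrix, per-sample group labels).
    """
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    baselines = baselines or {}
    ids = _sample_ids(group_sizes)
    genes = list(effects)
    data = np.empty((len(ids), len(genes)))
    for gi, gene in enumerate(genes):
        base = baselines.get(gene, 10.0)
        for si, (_, group) in enumerate(ids):
            mu = base + effects[gene].get(group, 0.0)
            data[si, gi] = mu + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
    index = pd.Index([sid for sid, _ in ids], name="sample_id")
    expr = pd.DataFrame(data, index=index, columns=genes)
    labels = pd.Series([g for _, g in ids], index=index, name="group")
    return expr, labels
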