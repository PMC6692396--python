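"""Reference-gene stability scoring and comprehensive ranking.

Four classic candidate-selection algorithms are implemented on a common
sample x gene matrix:

* pairwise-ratio variation with iterative exclusion (geNorm-style M values),
* model-based intra/intergroup variance decomposition (NormFinder-style),
* descriptive Ct dispersion plus a geometric-mean index (BestKeeper-style),
* mean SD of per-sample pairwise Ct differences (comparative delta-Ct).

Their per-method ranks are combined by a geometric mean of ranks into a
comprehensive ranking (RefFinder-style).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ct_data import CtTable

METHODS = ("genorm", "normfinder", "bestkeeper", "delta_ct", "comprehensive")


class AlgorithmError(ValueError):
    """Preconditions of a stability algorithm are not met."""


@dataclass
class StabilityReport:
    """Per-gene stability scores and ranks for one method (1 = most stable)."""

    method: str
    scores: pd.Series
    ranks: pd.Series
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = self.scores.astype(float)
        self.ranks = self.ranks.astype(float).reindex(self.scores.index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"method": self.method, "score": self.scores, "rank": self.ranks}
        ).rename_axis("gene").reset_index()

    def ordered_genes(self) -> list[str]:
        """Genes from most to least stable; ties broken by gene name."""
        order = sorted(self.ranks.index, key=lambda g: (self.ranks[g], g))
        return list(order)


def rank_ascending(scores: pd.Series) -> pd.Series:
    """Rank with 1 = smallest score; exact ties get the average rank."""
    return pd.Series(
        stats.rankdata(scores.to_numpy()), index=scores.index, dtype=float
    )


def _ct_frame(ct) -> pd.DataFrame:
    if isinstance(ct, CtTable):
        return ct.ct
    return pd.DataFrame(ct).astype(float)


def relative_quantities(ct, efficiency: float = 2.0) -> pd.DataFrame:
    """Per-gene relative quantities Q = E**(min Ct - Ct), in (0, 1].

    The best-expressed (lowest-Ct) sample of each gene gets Q = 1.  Missing
    Ct entries propagate as NaN.
    """
    if not (1.0 < efficiency <= 2.0):
        raise ValueError("efficiency must lie in (1, 2]")
    frame = _ct_frame(ct)
    if frame.isna().all(axis=0).any():
        raise ValueError("gene column with no observed Ct values")
    return efficiency ** (frame.min(axis=0) - frame)


def genorm_stability(q: pd.DataFrame, efficiency_log_base: float = 2.0) -> StabilityReport:
    """Pairwise-variation M values with iterative-exclusion ranking.

    M_j is the mean over all other genes k of the SD across samples of
    log2(Q_j / Q_k).  Ranking repeatedly removes the highest-M gene and
    recomputes M on the survivors until two genes remain; those two share
    the top rank (reported as the average 1.5).
    Reported scores are the M values on the full panel.
    """
    q = pd.DataFrame(q).astype(float)
    genes = list(q.columns)
    if len(genes) < 3:
        raise AlgorithmError("pairwise-variation ranking needs >= 3 genes")

    logq = np.log2(q)

    def m_values(cols: list[str]) -> pd.Series:
        out = {}
        for j in cols:
            sds = []
            for k in cols:
                if k == j:
                    continue
                ratio = (logq[j] - logq[k]).dropna()
                if len(ratio) < 2:
                    raise AlgorithmError(
                        f"genes {j}/{k}: fewer than 2 complete sample pairs"
                    )
                sds.append(ratio.std(ddof=1))
            out[j] = float(np.mean(sds))
        return pd.Series(out)

    full_m = m_values(genes)

    survivors = list(genes)
    exclusion_order: list[str] = []
    while len(survivors) > 2:
        m = m_values(survivors)
        worst = max(survivors, key=lambda g: (m[g], g))
        exclusion_order.append(worst)
        survivors.remove(worst)

    ranks = pd.Series(index=genes, dtype=float)
    for g in survivors:
        ranks[g] = 1.5
    for pos, g in enumerate(reversed(exclusion_order)):
        ranks[g] = 3.0 + pos

    return StabilityReport(
        method="genorm",
        scores=full_m,
        ranks=ranks,
        extras={"final_pair": tuple(sorted(survivors)),
                "exclusion_order": exclusion_order},
    )


def genorm_pairwise_variation(q: pd.DataFrame) -> pd.Series:
    """V(n/n+1) values for deciding how many reference genes to use.

    V(n/n+1) is the SD across samples of log2(NF_n / NF_{n+1}) where NF_n is
    the geometric mean of the n most stable genes under the iterative
    ranking.  Provided for completeness; not used by the default pipeline,
    which fixes the reference count.
    """
    q = pd.DataFrame(q).astype(float)
    report = genorm_stability(q)
    order = report.ordered_genes()
    logq = np.log2(q)
    out = {}
    for n in range(2, len(order)):
        nf_n = logq[order[:n]].mean(axis=1)
        nf_n1 = logq[order[: n + 1]].mean(axis=1)
        out[f"V{n}/{n + 1}"] = float((nf_n - nf_n1).std(ddof=1))
    return pd.Series(out)


def normfinder_stability(
    q: pd.DataFrame,
    groups: pd.Series | None = None,
) -> StabilityReport:
    """Model-based stability from intragroup variance and intergroup bias.

    Operates on log2 relative quantities.  The grouped variant decomposes
    each group's matrix into gene and sample effects, estimates a
    bias-corrected intragroup variance per (gene, group) and a shrunken
    gene x group interaction ("intergroup bias"); the stability value is the
    group average of |bias| + sqrt(variance / n_group).  With no groups the
    stability value is the corrected within-set SD.  Smaller = more stable.
    """
    q = pd.DataFrame(q).astype(float)
    genes = list(q.columns)
    k = len(genes)
    if k < 3:
        raise AlgorithmError("variance decomposition needs >= 3 genes")
    if q.isna().any().any():
        raise AlgorithmError("missing entries not supported; drop samples first")
    x = np.log2(q.to_numpy()).T  # genes x samples

    def group_var(xg: np.ndarray) -> np.ndarray:
        """Bias-corrected per-gene variance after removing gene/sample effects."""
        n = xg.shape[1]
        if n < 2:
            raise AlgorithmError("each group needs >= 2 samples")
        r = xg - xg.mean(axis=1, keepdims=True)
        r = r - r.mean(axis=0, keepdims=True)
        z = (r**2).sum(axis=1) / (n - 1)
        sig = (z - z.sum() / (k * (k - 1))) / (1.0 - 2.0 / k)
        return np.maximum(sig, 0.0)

    if groups is None:
        var = group_var(x)
        scores = pd.Series(np.sqrt(var), index=genes)
        return StabilityReport(
            method="normfinder", scores=scores, ranks=rank_ascending(scores),
            extras={"grouped": False},
        )

    groups = pd.Series(groups).reindex(q.index)
    if groups.isna().any():
        raise AlgorithmError("every sample needs a group label")
    labels = list(dict.fromkeys(groups))
    if len(labels) < 2:
        raise AlgorithmError("grouped variant needs >= 2 groups")
    gcount = len(labels)

    var = np.zeros((k, gcount))
    gene_mean = np.zeros((k, gcount))
    n_g = np.zeros(gcount)
    for gi, lab in enumerate(labels):
        xg = x[:, (groups == lab).to_numpy()]
        n_g[gi] = xg.shape[1]
        var[:, gi] = group_var(xg)
        gene_mean[:, gi] = xg.mean(axis=1)

    # gene x group interaction: double-center gene means across groups/genes
    d = gene_mean - gene_mean.mean(axis=1, keepdims=True)
    d = d - d.mean(axis=0, keepdims=True)

    samp_var = var / n_g  # sampling variance of each d entry (approx.)
    gamma2 = max(
        0.0, (d**2).sum() / ((k - 1) * (gcount - 1)) - samp_var.mean()
    )
    denom = gamma2 + samp_var
    with np.errstate(invalid="ignore"):
        shrunk = np.where(denom > 0, d * gamma2 / np.where(denom > 0, denom, 1.0), 0.0)

    stab_per_group = np.abs(shrunk) + np.sqrt(samp_var)
    scores = pd.Series(stab_per_group.mean(axis=1), index=genes)
    return StabilityReport(
        method="normfinder", scores=scores, ranks=rank_ascending(scores),
        extras={"grouped": True, "groups": labels,
                "intergroup_bias": pd.DataFrame(shrunk, index=genes, columns=labels),
                "intragroup_var": pd.DataFrame(var, index=genes, columns=labels)},
    )


def bestkeeper_stats(ct, sd_mode: str = "mad") -> StabilityReport:
    """Descriptive Ct dispersion plus correlation with a geometric-mean index.

    The primary stability score is the per-gene dispersion of raw Ct values:
    the mean absolute deviation from the arithmetic mean by default
    (``sd_mode='mad'``, as in the original descriptive tool), or the classic
    sample SD (``sd_mode='sample'``).  Also reports per-gene descriptive
    statistics and the Pearson r of each gene against the per-sample
    geometric mean of all candidates (the BestKeeper index).
    """
    if sd_mode not in ("mad", "sample"):
        raise ValueError("sd_mode must be 'mad' or 'sample'")
    frame = _ct_frame(ct)
    if len(frame) < 2:
        raise AlgorithmError("need >= 2 samples")
    if (frame <= 0).any().any():
        raise ValueError("nonpositive Ct: geometric mean undefined")

    desc_rows = {}
    for gene in frame.columns:
        col = frame[gene].dropna()
        mean = col.mean()
        if sd_mode == "mad":
            disp = float((col - mean).abs().mean())
        else:
            disp = float(col.std(ddof=1))
        desc_rows[gene] = {
            "n": int(len(col)),
            "geo_mean": float(stats.gmean(col)),
            "mean": float(mean),
            "min": float(col.min()),
            "max": float(col.max()),
            "sd": disp,
            "cv_pct": 100.0 * disp / float(mean),
        }
    desc = pd.DataFrame(desc_rows).T

    index = pd.Series(stats.gmean(frame, axis=1), index=frame.index)
    corr = {}
    for gene in frame.columns:
        both = pd.concat([frame[gene], index], axis=1).dropna()
        if len(both) >= 3 and both.iloc[:, 0].std() > 0 and both.iloc[:, 1].std() > 0:
            corr[gene] = float(stats.pearsonr(both.iloc[:, 0], both.iloc[:, 1])[0])
        else:
            corr[gene] = np.nan

    scores = desc["sd"].astype(float)
    return StabilityReport(
        method="bestkeeper",
        scores=scores,
        ranks=rank_ascending(scores),
        extras={"descriptives": desc, "index": index,
                "index_correlation": pd.Series(corr)},
    )


def delta_ct_stability(ct) -> StabilityReport:
    """Comparative delta-Ct stability: mean SD of pairwise Ct differences.

    For every gene pair (j, k) the SD across samples of Ct_j - Ct_k is
    computed; gene j's score is the mean over all pairs involving j.
    A per-sample global offset cancels in every difference.
    """
    frame = _ct_frame(ct)
    genes = list(frame.columns)
    if len(genes) < 2 or len(frame) < 2:
        raise AlgorithmError("need >= 2 genes and >= 2 samples")
    scores = {}
    for j in genes:
        sds = []
        for k_ in genes:
            if k_ == j:
                continue
            diff = (frame[j] - frame[k_]).dropna()
            if len(diff) < 2:
                raise AlgorithmError(f"genes {j}/{k_}: < 2 complete samples")
            sds.append(diff.std(ddof=1))
        scores[j] = float(np.mean(sds))
    scores = pd.Series(scores)
    return StabilityReport(
        method="delta_ct", scores=scores, ranks=rank_ascending(scores)
    )


def comprehensive_ranking(
    per_method_ranks: dict[str, pd.Series] | list[pd.Series],
) -> StabilityReport:
    """Geometric mean of per-method ranks; ascending = most stable first."""
    if isinstance(per_method_ranks, dict):
        vectors = list(per_method_ranks.values())
    else:
        vectors = list(per_method_ranks)
    if not vectors:
        raise ValueError("no rank vectors supplied")
    genes = set(vectors[0].index)
    for v in vectors[1:]:
        if set(v.index) != genes:
            raise ValueError("rank vectors cover different gene sets")
    mat = pd.concat([v.reindex(sorted(genes)) for v in vectors], axis=1)
    scores = pd.Series(
        stats.gmean(mat.to_numpy(), axis=1), index=mat.index, name="score"
    )
    return StabilityReport(
        method="comprehensive", scores=scores, ranks=rank_ascending(scores)
    )


def ranking_correlation(
    vectors: dict[str, pd.Series] | pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and r^2 matrices between rank/score vectors.

    Zero-variance vectors yield NaN (undefined correlation) off-diagonal.
    """
    df = pd.DataFrame(vectors).astype(float)
    if len(df) < 3:
        raise ValueError("need >= 3 genes for a meaningful correlation")
    names = list(df.columns)
    r = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            both = df[[a, b]].dropna()
            if both[a].std() == 0 or both[b].std() == 0:
                val = np.nan
            else:
                val = float(stats.pearsonr(both[a], both[b])[0])
            r.loc[a, b] = r.loc[b, a] = val
    return r, r**2


def run_all_methods(
    table: CtTable,
    candidates: list[str] | None = None,
    efficiency: float = 2.0,
    grouped: bool = True,
    sd_mode: str = "mad",
) -> dict[str, StabilityReport]:
    """Run the four stability methods plus the comprehensive ranking.

    Samples with any missing candidate Ct are dropped (all methods need a
    complete matrix to see the same data).
    """
    ct = table.ct if candidates is None else table.ct[list(candidates)]
    complete = ct.dropna(axis=0)
    groups = None
    if grouped and table.meta is not None:
        groups = table.meta.reindex(complete.index)
        if groups.isna().any():
            groups = None
    q = relative_quantities(complete, efficiency=efficiency)

    reports = {
        "genorm": genorm_stability(q),
        "normfinder": normfinder_stability(q, groups=groups),
        "bestkeeper": bestkeeper_stats(complete, sd_mode=sd_mode),
        "delta_ct": delta_ct_stability(complete),
    }
    reports["comprehensive"] = comprehensive_ranking(
        {name: rep.ranks for name, rep in reports.items()}
    )
    return reports
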