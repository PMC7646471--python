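"""Transcription-factor regulon construction, validation and activity.

A regulon is seeded by two anchors — the factor itself (AHR) and its
prototypical target (CYP1A1).  Candidate members are the genes whose
expression correlates (Spearman) with BOTH anchors at least as strongly
as the anchors correlate with each other, after discarding the
lowest-variance 20% of genes.  Candidates are validated against a
knockdown experiment: genes significantly downregulated on factor
knockdown form the final regulon.  Per-sample activity is a rank-based
single-sample enrichment score (ssGSEA-style running sum), which
depends only on within-sample ranks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix

logger = logging.getLogger("apohot")


@dataclass
class RegulonModel:
    tf: str
    prototype: str
    rho_threshold: float
    anchor_p: float
    candidates: list[str] = field(default_factory=list)
    validated_set: list[str] = field(default_factory=list)
    de_table: pd.DataFrame | None = None
    randomisation_p: float | None = None

    def to_dict(self) -> dict:
        return {
            "tf": self.tf,
            "prototype": self.prototype,
            "rho_threshold": self.rho_threshold,
            "anchor_p": self.anchor_p,
            "candidates": list(self.candidates),
            "validated_set": list(self.validated_set),
            "randomisation_p": self.randomisation_p,
        }


def select_regulon_candidates(
    expr: ExpressionMatrix,
    tf: str = "AHR",
    prototype: str = "CYP1A1",
    variance_quantile: float = 0.20,
) -> RegulonModel:
    """Co-expression candidate selection for a factor's regulon.

    Drops the bottom ``variance_quantile`` of genes by variance, sets
    the correlation threshold to Spearman(tf, prototype), and keeps the
    genes (anchors excluded) correlating at or above that threshold
    with both anchors.
    """
    values = expr.values
    for g in (tf, prototype):
        if g not in values.index:
            raise ValueError(f"anchor gene {g!r} absent from matrix")
    variances = values.var(axis=1)
    cut = variances.quantile(variance_quantile)
    kept = values.loc[(variances > cut) | values.index.isin([tf, prototype])]
    if tf not in kept.index or prototype not in kept.index:
        raise ValueError("anchor genes removed by the variance filter")

    rho, p = stats.spearmanr(kept.loc[tf], kept.loc[prototype])
    ranks = kept.rank(axis=1)  # Spearman = Pearson on ranks, vectorised
    ranks = ranks.sub(ranks.mean(axis=1), axis=0)
    norms = np.sqrt((ranks**2).sum(axis=1))
    rho_tf = (ranks @ ranks.loc[tf]) / (norms * norms[tf])
    rho_proto = (ranks @ ranks.loc[prototype]) / (norms * norms[prototype])
    mask = (rho_tf >= rho) & (rho_proto >= rho)
    candidates = [g for g in kept.index[mask] if g not in (tf, prototype)]
    return RegulonModel(
        tf=tf,
        prototype=prototype,
        rho_threshold=float(rho),
        anchor_p=float(p),
        candidates=candidates,
    )


# ---------------------------------------------------------------------------
# knockdown differential expression
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors (samples in columns)."""
    logc = np.log(counts.replace(0, np.nan))
    ref = logc.mean(axis=1)
    usable = ref.notna()
    sf = np.exp((logc[usable.to_numpy()].sub(ref[usable], axis=0)).median(axis=0))
    return sf.rename("size_factor")


def nb_differential_expression(
    counts: ExpressionMatrix | pd.DataFrame,
    condition: pd.Series,
    reference_level: str = "control",
) -> pd.DataFrame:
    """Negative-binomial Wald differential expression (DESeq2 model).

    ``counts`` holds raw integer counts (genes x samples); ``condition``
    maps each sample to one of two levels, ``reference_level`` being the
    baseline.  All-zero genes are excluded.  Returns a per-gene table
    with log2FC (unshrunk), Wald p and BH FDR.
    """
    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    values = counts.values if isinstance(counts, ExpressionMatrix) else counts
    condition = pd.Series(condition)
    levels = [lv for lv in pd.unique(condition) if lv != reference_level]
    if len(levels) != 1:
        raise ValueError("condition must have exactly two levels")
    if (condition.value_counts() < 2).any():
        raise ValueError("need >= 2 replicates per group")
    mat = values.T  # samples x genes for pydeseq2
    keep = (mat.sum(axis=0) > 0).to_numpy()
    mat = mat.loc[:, keep].astype(int)
    meta = pd.DataFrame({"condition": condition.reindex(mat.index)})
    meta["condition"] = pd.Categorical(
        meta["condition"], categories=[reference_level, levels[0]]
    )
    dds = DeseqDataSet(counts=mat, metadata=meta, design="~condition", quiet=True)
    dds.deseq2()
    ds = DeseqStats(
        dds, contrast=["condition", levels[0], reference_level], quiet=True
    )
    ds.summary()
    res = ds.results_df
    table = pd.DataFrame(
        {
            "log2FC": res["log2FoldChange"],
            "p": res["pvalue"],
            "FDR": res["padj"],
        }
    )
    table.index.name = "gene"
    return table


def de_ranking(de_table: pd.DataFrame) -> pd.Series:
    """Rank genes with significant downregulation on top.

    The ranking key is descending (-log2FC) x (-log10 FDR) restricted to
    downregulated genes; upregulated or non-scored genes sort last.
    Returns integer ranks (1 = top).
    """
    lfc = de_table["log2FC"]
    fdr = de_table["FDR"].fillna(1.0).clip(lower=1e-300)
    key = np.where(lfc < 0, (-lfc) * (-np.log10(fdr)), -np.inf)
    order = pd.Series(-key, index=de_table.index)
    ranks = order.rank(method="average")
    return ranks.rename("rank")


def ranksum_randomisation_test(
    ranking: pd.Series,
    candidates,
    n_rand: int = 1_000_000,
    seed=None,
    chunk: int = 100_000,
) -> float:
    """Randomisation p-value for candidate enrichment at the top ranks.

    p = (1 + #{random same-size gene sets with rank sum <= observed})
    / (n_rand + 1); the add-one estimator never returns 0.
    """
    rng = np.random.default_rng(seed)
    present = [g for g in candidates if g in ranking.index]
    dropped = len(list(candidates)) - len(present)
    if dropped:
        logger.warning("%d candidate genes absent from ranking; dropped", dropped)
    if not present:
        raise ValueError("no candidates present in the ranking")
    ranks = ranking.to_numpy(dtype=float)
    m, N = len(present), len(ranks)
    observed = float(ranking[present].sum())
    hits = 0
    done = 0
    while done < n_rand:
        size = min(chunk, n_rand - done)
        idx = rng.integers(0, N, size=(size, m))
        # resample rows with duplicate indices (rare for m << N)
        bad = np.array([len(np.unique(row)) != m for row in idx])
        while bad.any():
            idx[bad] = rng.integers(0, N, size=(int(bad.sum()), m))
            bad = np.array([len(np.unique(row)) != m for row in idx])
        sums = ranks[idx].sum(axis=1)
        hits += int((sums <= observed).sum())
        done += size
    return (1 + hits) / (n_rand + 1)


def finalise_regulon(
    model: RegulonModel,
    de_table: pd.DataFrame,
    fdr_cut: float = 0.05,
) -> RegulonModel:
    """Validated regulon: candidates downregulated at FDR < cut."""
    sig = de_table[(de_table["log2FC"] < 0) & (de_table["FDR"] < fdr_cut)]
    model.validated_set = [g for g in model.candidates if g in sig.index]
    model.de_table = de_table
    if not model.validated_set:
        logger.warning("no candidate passed knockdown validation; empty regulon")
    return model


# ---------------------------------------------------------------------------
# activity scores
# ---------------------------------------------------------------------------

def regulon_activity_score(
    expr: ExpressionMatrix,
    gene_set,
    weight: float = 0.25,
) -> pd.Series:
    """Rank-based single-sample enrichment score of a gene set.

    ssGSEA-style weighted Kolmogorov-Smirnov running sum on each
    sample's expression ranks (weight exponent on the normalised rank).
    Depends only on within-sample ranks, hence invariant to any
    strictly monotone transform of a sample's expression vector.
    """
    gene_set = list(dict.fromkeys(gene_set))
    if len(gene_set) < 5:
        raise ValueError("need >= 5 regulon genes")
    missing = [g for g in gene_set if g not in expr.values.index]
    if missing:
        raise ValueError(f"regulon genes absent from matrix: {missing}")
    values = expr.values
    in_set = values.index.isin(gene_set).astype(float)
    n_genes = len(values.index)
    scores = {}
    for sample in values.columns:
        ranks = stats.rankdata(values[sample].to_numpy(), method="average")
        order = np.argsort(-ranks, kind="stable")  # descending expression
        hit = in_set[order]
        w = (ranks[order] / n_genes) ** weight * hit
        p_hit = np.cumsum(w) / w.sum()
        p_miss = np.cumsum(1 - hit) / (n_genes - hit.sum())
        scores[sample] = float(np.sum(p_hit - p_miss) / n_genes)
    return pd.Series(scores, name="activity")


def dunn_posthoc(values: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Pairwise Dunn tests on ranks with BH adjustment."""
    values = pd.Series(values)
    groups = pd.Series(groups).reindex(values.index)
    ranks = stats.rankdata(values.to_numpy())
    N = len(values)
    ties = pd.Series(values).value_counts().to_numpy()
    tie_term = (ties**3 - ties).sum() / (12 * (N - 1))
    var_base = N * (N + 1) / 12 - tie_term
    names = list(pd.unique(groups))
    rows = []
    for i, ga in enumerate(names):
        for gb in names[i + 1 :]:
            ra = ranks[(groups == ga).to_numpy()]
            rb = ranks[(groups == gb).to_numpy()]
            z = (ra.mean() - rb.mean()) / np.sqrt(
                var_base * (1 / len(ra) + 1 / len(rb))
            )
            rows.append({"group_a": ga, "group_b": gb, "z": z,
                         "p": 2 * stats.norm.sf(abs(z))})
    table = pd.DataFrame(rows)
    table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    return table


def activity_group_tests(scores: pd.Series, groups: pd.Series) -> dict:
    """Kruskal-Wallis across groups plus pairwise Dunn with BH."""
    groups = pd.Series(groups).reindex(scores.index)
    samples = [scores[groups == g].to_numpy() for g in pd.unique(groups)]
    if len(samples) < 2:
        raise ValueError("need >= 2 groups")
    h, p = stats.kruskal(*samples)
    out = {"kruskal_h": float(h), "kruskal_p": float(p)}
    if len(samples) == 2:
        _, wp = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
        out["wilcoxon_p"] = float(wp)
    out["dunn"] = dunn_posthoc(scores, groups)
    return out


# ---------------------------------------------------------------------------
# dependency comparison
# ---------------------------------------------------------------------------

def dependency_quantile_comparison(
    scores_a,
    scores_b,
    alternative: str = "less",
) -> dict:
    """Quantile-matched paired comparison of two dependency score groups.

    For each score in group A (e.g. luminal lines), its quantile within
    A is computed and group B's empirical quantile function is read at
    the same quantile by local linear interpolation; the paired deltas
    (A minus matched B) feed a Wilcoxon signed-rank test.  With CERES
    scores lower means more dependent, so ``alternative='less'`` asks
    whether A is more dependent than B.
    """
    a = np.sort(np.asarray(scores_a, dtype=float))
    b = np.sort(np.asarray(scores_b, dtype=float))
    if len(b) < 2:
        raise ValueError("group B needs >= 2 members for interpolation")
    if len(a) == 0:
        raise ValueError("group A is empty")
    qa = (np.arange(1, len(a) + 1) - 0.5) / len(a)
    qb = (np.arange(1, len(b) + 1) - 0.5) / len(b)
    matched = np.interp(qa, qb, b)
    deltas = a - matched
    if np.allclose(deltas, 0):
        return {"deltas": deltas, "p": 1.0, "statistic": float("nan")}
    w, p = stats.wilcoxon(deltas, alternative=alternative, zero_method="wilcox")
    return {"deltas": deltas, "p": float(p), "statistic": float(w)}
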