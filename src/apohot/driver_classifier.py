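"""Driver/passenger inference in the (loop stability, expression rank) plane.

Known driver and passenger hotspot mutations seed an iterative
similarity classifier: each unresolved mutation's Euclidean distances
to the current driver and passenger reference sets are compared with a
Welch two-sided t-test, significant points join the closer class, and
newly labelled points extend the reference sets for the next sweep.
Confidence comes from a label-permutation null over the seed points
(full combinatorial enumeration of driver-subset relabelings) with
Benjamini-Hochberg control across predictions.

Also here: the two-step logistic (GLR) alternative, clonality tests, a
mutability-adjusted recurrence surrogate for selection intensity, and
exact 1-D two-cluster weighted k-means.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("apohot")

DRIVER, PASSENGER, UNDETERMINED = "driver", "passenger", "undetermined"


def _distances(points: np.ndarray, refs: np.ndarray) -> np.ndarray:
    return np.sqrt(((points[:, None, :] - refs[None, :, :]) ** 2).sum(axis=2))


class IterativeSimilarityClassifier(BaseEstimator, ClassifierMixin):
    """Iterative similarity-based driver/passenger classifier.

    Parameters
    ----------
    alpha:
        Welch-test significance level for assigning a point per sweep.
    max_iter:
        Safety cap on sweeps (the iteration stops naturally when a sweep
        assigns nothing or everything is assigned).

    Both features are expected on the [0, 1] scale so the two axes are
    weighted equally in the Euclidean distance.
    """

    def __init__(self, alpha: float = 0.05, max_iter: int = 100):
        self.alpha = alpha
        self.max_iter = max_iter

    def fit(self, X, y):
        """Record the seed points. ``y`` holds 'driver' / 'passenger'."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_seeds, 2)")
        if not np.isfinite(X).all():
            raise ValueError("seed coordinates must be finite")
        bad = set(y) - {DRIVER, PASSENGER}
        if bad:
            raise ValueError(f"seed labels must be driver/passenger, got {bad}")
        if (y == DRIVER).sum() < 2 or (y == PASSENGER).sum() < 2:
            raise ValueError("need >= 2 known drivers and >= 2 known passengers")
        self.X_seed_ = X
        self.y_seed_ = y
        self.classes_ = np.array([DRIVER, PASSENGER])
        return self

    def classify(self, X) -> pd.DataFrame:
        """Label unknown points; returns a per-point result table.

        Columns: label, iteration (sweep of assignment, 0 when
        undetermined), mdod (mean distance to the seed passengers minus
        mean distance to the seed drivers; positive = driver-like),
        t_p (Welch p at assignment, or at the final sweep for
        undetermined points).
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_points, 2)")
        n = len(X)
        ref_d = [row for row, lab in zip(self.X_seed_, self.y_seed_) if lab == DRIVER]
        ref_p = [row for row, lab in zip(self.X_seed_, self.y_seed_) if lab == PASSENGER]
        labels = np.array([UNDETERMINED] * n, dtype=object)
        iteration = np.zeros(n, dtype=int)
        t_p = np.full(n, np.nan)

        unresolved = list(range(n))
        for sweep in range(1, self.max_iter + 1):
            if not unresolved:
                break
            Dd = _distances(X[unresolved], np.asarray(ref_d))
            Dp = _distances(X[unresolved], np.asarray(ref_p))
            assigned_d, assigned_p, still = [], [], []
            for row, idx in enumerate(unresolved):
                dd, dp = Dd[row], Dp[row]
                _, p = stats.ttest_ind(dd, dp, equal_var=False)
                p = float(p) if np.isfinite(p) else 1.0
                t_p[idx] = p
                if p < self.alpha:
                    if dd.mean() < dp.mean():
                        labels[idx] = DRIVER
                        assigned_d.append(idx)
                    else:
                        labels[idx] = PASSENGER
                        assigned_p.append(idx)
                    iteration[idx] = sweep
                else:
                    still.append(idx)
            if not assigned_d and not assigned_p:
                break
            ref_d.extend(X[assigned_d])
            ref_p.extend(X[assigned_p])
            unresolved = still

        seed_d = self.X_seed_[self.y_seed_ == DRIVER]
        seed_p = self.X_seed_[self.y_seed_ == PASSENGER]
        mdod = _distances(X, seed_p).mean(axis=1) - _distances(X, seed_d).mean(axis=1)
        return pd.DataFrame(
            {
                "x1": X[:, 0],
                "x2": X[:, 1],
                "label": labels,
                "iteration": iteration,
                "mdod": mdod,
                "t_p": t_p,
            }
        )

    def predict(self, X):
        return self.classify(X)["label"].to_numpy()


def iterative_similarity_classify(points: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Functional wrapper over :class:`IterativeSimilarityClassifier`.

    ``points`` needs columns x1, x2, seed_label (known_driver /
    known_passenger / unknown).  Returns the result table for the
    unknown rows, indexed like their rows in ``points``.
    """
    seeds = points[points["seed_label"] != "unknown"]
    unknown = points[points["seed_label"] == "unknown"]
    est = IterativeSimilarityClassifier(alpha=alpha)
    est.fit(
        seeds[["x1", "x2"]].to_numpy(),
        seeds["seed_label"].map(
            {"known_driver": DRIVER, "known_passenger": PASSENGER}
        ).to_numpy(),
    )
    result = est.classify(unknown[["x1", "x2"]].to_numpy())
    result.index = unknown.index
    return result


# ---------------------------------------------------------------------------
# permutation FDR
# ---------------------------------------------------------------------------

from functools import lru_cache


@lru_cache(maxsize=8)
def _exact_masks(n: int, k: int) -> np.ndarray:
    rows = [np.isin(np.arange(n), combo) for combo in combinations(range(n), k)]
    return np.asarray(rows)


def _relabeling_masks(n: int, k: int, max_exact: int, n_mc: int, rng) -> np.ndarray:
    """Boolean (m, n) matrix: rows mark the 'driver' subset of size k."""
    from math import comb

    if comb(n, k) <= max_exact:
        return _exact_masks(n, k)
    logger.warning(
        "C(%d,%d) exceeds %d; falling back to %d Monte-Carlo relabelings",
        n, k, max_exact, n_mc,
    )
    rows = np.zeros((n_mc, n), dtype=bool)
    for r in range(n_mc):
        rows[r, rng.choice(n, size=k, replace=False)] = True
    return rows


def permutation_fdr(
    result: pd.DataFrame,
    X_seed,
    y_seed,
    max_exact: int = 200_000,
    n_mc: int = 100_000,
    seed=None,
) -> pd.DataFrame:
    """Permutation p-values and BH FDR for classifier predictions.

    For every predicted point, all relabelings of the seed coordinates
    that keep the driver-set size (C(n, k) subsets, e.g. C(16,9) =
    11,440 for 9 drivers and 7 passengers) are enumerated; the p-value
    is the fraction of relabelings whose mean-difference-of-distance
    (MDoD) is at least as extreme in the prediction's direction as the
    observed one.  Undetermined points receive no p/FDR.
    """
    X_seed = np.asarray(X_seed, dtype=float)
    y_seed = np.asarray(y_seed, dtype=object)
    n_seed = len(X_seed)
    k = int((y_seed == DRIVER).sum())
    rng = np.random.default_rng(seed)
    masks = _relabeling_masks(n_seed, k, max_exact, n_mc, rng)
    n_pass = n_seed - k

    out = result.copy()
    out["p_perm"] = np.nan
    out["fdr"] = np.nan
    predicted = out.index[out["label"].isin([DRIVER, PASSENGER])]
    if len(predicted) == 0:
        return out

    pvals = []
    for idx in predicted:
        pt = out.loc[idx, ["x1", "x2"]].to_numpy(dtype=float)
        d = np.sqrt(((X_seed - pt) ** 2).sum(axis=1))  # (n_seed,)
        perm_mdod = (d @ (~masks).T) / n_pass - (d @ masks.T) / k
        obs = (
            d[y_seed == PASSENGER].mean() - d[y_seed == DRIVER].mean()
        )
        # tolerance keeps the observed labeling counted despite float noise
        if out.loc[idx, "label"] == DRIVER:
            p = float(np.mean(perm_mdod >= obs - 1e-9))
        else:
            p = float(np.mean(perm_mdod <= obs + 1e-9))
        pvals.append(p)
    _, fdrs, _, _ = multipletests(pvals, method="fdr_bh")
    out.loc[predicted, "p_perm"] = pvals
    out.loc[predicted, "fdr"] = fdrs
    return out


# ---------------------------------------------------------------------------
# two-step GLR alternative
# ---------------------------------------------------------------------------

class TwoStepGLRClassifier(BaseEstimator):
    """Driverness as a product of two logistic probabilities.

    Model 1: P(functional gene | expression rank), trained on known
    OG/TSG vs unknown genes.  Model 2: P(driver | loop score), trained
    on known drivers vs passengers.  Driverness = P1 x P2 in [0, 1].
    Perfect separation triggers a penalised (ridge) fit, flagged in
    ``penalised_``.
    """

    def fit(self, ranks, y_gene, loop_scores, y_mut):
        self.model1_, pen1 = _logistic_fit(ranks, y_gene)
        self.model2_, pen2 = _logistic_fit(loop_scores, y_mut)
        self.penalised_ = (pen1, pen2)
        return self

    def predict_proba(self, ranks, loop_scores) -> np.ndarray:
        p1 = _logistic_predict(self.model1_, ranks)
        p2 = _logistic_predict(self.model2_, loop_scores)
        return p1 * p2


def _logistic_fit(x, y):
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float).reshape(-1, 1)
    y = np.asarray(y, dtype=float)
    X = sm.add_constant(x)
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not np.isfinite(res.params).all() or np.abs(res.params).max() > 1e3:
            raise np.linalg.LinAlgError("separation")
        return ("sm", res), False
    except Exception:
        from sklearn.linear_model import LogisticRegression

        logger.warning("logistic fit separated; using penalised fallback")
        clf = LogisticRegression(C=1.0, max_iter=1000).fit(x, y)
        return ("sk", clf), True


def _logistic_predict(model, x):
    kind, m = model
    x = np.asarray(x, dtype=float).reshape(-1, 1)
    if kind == "sm":
        import statsmodels.api as sm

        return np.asarray(m.predict(sm.add_constant(x, has_constant="add")))
    return m.predict_proba(x)[:, 1]


# ---------------------------------------------------------------------------
# clonality
# ---------------------------------------------------------------------------

def clonality_tests(cohort, panel) -> dict:
    """Clonality enrichment of hotspots within APOBEC-target genes.

    Fisher's exact test on the (hotspot vs other) x (clonal vs
    subclonal) 2x2 table over mutation events in the panel's genes, and
    a logistic mixed model clonal ~ hotspot + mutation_count with a
    per-gene random intercept (variational Bayes estimator).  With a
    degenerate 2x2 margin only Fisher's test is reported.
    """
    from .hotspots import tally_recurrence

    panel_keys = {h.key for h in panel.hotspots}
    panel_genes = {h.gene for h in panel.hotspots}
    table = tally_recurrence(cohort)

    rows = []
    for rec in cohort.records:
        if rec.gene not in panel_genes:
            continue
        if rec.clonality not in ("clonal", "subclonal"):
            continue
        rows.append(
            {
                "clonal": 1 if rec.clonality == "clonal" else 0,
                "hotspot": 1 if rec.key in panel_keys else 0,
                "count": table.entries[rec.key].count,
                "gene": rec.gene,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty or df["clonal"].nunique() < 2:
        raise ValueError("need both clonal and subclonal events in scope")

    a = int(((df.hotspot == 1) & (df.clonal == 1)).sum())
    b = int(((df.hotspot == 1) & (df.clonal == 0)).sum())
    c = int(((df.hotspot == 0) & (df.clonal == 1)).sum())
    d = int(((df.hotspot == 0) & (df.clonal == 0)).sum())
    fisher_or, fisher_p = stats.fisher_exact([[a, b], [c, d]])
    out = {
        "table": (a, b, c, d),
        "fisher_or": float(fisher_or),
        "fisher_p": float(fisher_p),
        "glmm_or": None,
        "glmm_ci": None,
        "glmm_p": None,
    }
    if min(a + b, c + d, a + c, b + d) == 0 or df["hotspot"].nunique() < 2:
        logger.warning("degenerate 2x2 margin; GLMM skipped")
        return out

    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    df["log_count"] = np.log(df["count"])
    model = BinomialBayesMixedGLM.from_formula(
        "clonal ~ hotspot + log_count", {"gene": "0 + C(gene)"}, df
    )
    fit = model.fit_vb()
    i = list(fit.model.exog_names).index("hotspot")
    beta, sd = float(fit.fe_mean[i]), float(fit.fe_sd[i])
    z = beta / sd
    out["glmm_or"] = float(np.exp(beta))
    out["glmm_ci"] = (float(np.exp(beta - 1.96 * sd)), float(np.exp(beta + 1.96 * sd)))
    out["glmm_p"] = float(2 * stats.norm.sf(abs(z)))
    return out


# ---------------------------------------------------------------------------
# selection-intensity surrogate + exact 1-D two-cluster split
# ---------------------------------------------------------------------------

def mutability_adjusted_recurrence(gene_records, exposures, reference) -> pd.DataFrame:
    """Observed/expected recurrence per site of a gene.

    The expected mass of a site is the cohort mutability of its channel:
    sum over samples and signatures of exposure x profile intensity at
    the site's channel.  The enrichment ratio is a simplified surrogate
    for selection intensity, used for relative ranking and clustering
    of the sites within a gene.  Sites with zero expected mass are
    excluded (flagged in the log).
    """
    from .signatures import channel_of_record

    E = exposures.exposures.to_numpy()  # (n_samples, K)
    S = reference.profiles.to_numpy()  # (K, 96)
    cohort_channel_mass = E.sum(axis=0) @ S  # (96,)
    chan_index = {c: i for i, c in enumerate(reference.profiles.columns)}

    sites: dict[tuple, dict] = {}
    for rec in gene_records:
        ch = channel_of_record(rec)
        if ch is None:
            continue
        entry = sites.setdefault(
            rec.key,
            {"channel": ch, "observed": 0, "protein_change": rec.protein_change},
        )
        entry["observed"] += 1
    rows = []
    for key, entry in sites.items():
        expected = float(cohort_channel_mass[chan_index[entry["channel"]]])
        if expected <= 0:
            logger.warning("site %s has zero expected mass; excluded", key)
            continue
        rows.append(
            {
                "chrom": key[0],
                "pos": key[1],
                "ref": key[2],
                "alt": key[3],
                "protein_change": entry["protein_change"],
                "observed": entry["observed"],
                "expected": expected,
                "enrichment": entry["observed"] / expected,
            }
        )
    return pd.DataFrame(rows)


class WeightedKMeans1D(BaseEstimator):
    """Exact two-cluster weighted k-means on a line.

    Minimises the weighted within-cluster sum of squares over all
    threshold splits of the sorted values (optimal clusters on a line
    are contiguous).  ``labels_`` holds 'low' / 'high'.
    """

    def __init__(self, n_clusters: int = 2):
        if n_clusters != 2:
            raise ValueError("only the two-cluster split is supported")
        self.n_clusters = n_clusters

    def fit(self, values, weights=None):
        x = np.asarray(values, dtype=float)
        if x.ndim != 1 or len(x) < 2:
            raise ValueError("need >= 2 one-dimensional values")
        w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
        order = np.argsort(x, kind="stable")
        xs, ws = x[order], w[order]
        cw = np.cumsum(ws)
        cwx = np.cumsum(ws * xs)
        cwx2 = np.cumsum(ws * xs**2)
        total_w, total_wx, total_wx2 = cw[-1], cwx[-1], cwx2[-1]
        best, best_split = np.inf, 1
        for s in range(1, len(xs)):
            wl, wxl, wx2l = cw[s - 1], cwx[s - 1], cwx2[s - 1]
            wr, wxr, wx2r = total_w - wl, total_wx - wxl, total_wx2 - wx2l
            wcss = (wx2l - wxl**2 / wl) + (wx2r - wxr**2 / wr)
            if wcss < best - 1e-12:
                best, best_split = wcss, s
        labels = np.empty(len(x), dtype=object)
        labels[order[:best_split]] = "low"
        labels[order[best_split:]] = "high"
        self.labels_ = labels
        self.inertia_ = float(best)
        self.threshold_ = float((xs[best_split - 1] + xs[best_split]) / 2)
        return self

    def fit_predict(self, values, weights=None):
        return self.fit(values, weights).labels_


def univariate_two_cluster(values, weights=None) -> np.ndarray:
    """Functional wrapper over :class:`WeightedKMeans1D`."""
    return WeightedKMeans1D().fit_predict(values, weights)
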