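"""96-channel catalogs, fixed-profile signature refitting and attribution.

The refit treats each sample's trinucleotide catalog as draws from a
mixture of fixed reference profiles and estimates the mixing fractions
(exposures) by EM for the multinomial mixture — the profiles are inputs,
never learned.  The APOBEC score of a sample is the summed exposure of
the two APOBEC-attributed signatures (slots 2 and 13 of the COSMIC v2
catalogue).  Carrier association compares APOBEC scores of hotspot
carriers against tumours free of every APOBEC-type candidate hotspot
(one-sided Wilcoxon rank-sum, Benjamini-Hochberg across candidates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

from .io_formats import CHANNELS_96, CohortTable, SignatureMatrix, SnvRecord, revcomp
from .hotspots import HotspotPanel

logger = logging.getLogger("apohot")

_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS_96)}

DEFAULT_APOBEC_SIGNATURES = ("Signature.2", "Signature.13")


def channel_of(ref: str, alt: str, five: str, three: str) -> str:
    """Map a substitution with +/-1 plus-strand context to its channel.

    Purine references are reverse-complemented onto the pyrimidine
    strand first (COSMIC convention).
    """
    if ref in ("G", "A"):
        ref, alt = revcomp(ref), revcomp(alt)
        five, three = revcomp(three), revcomp(five)
    return f"{five}[{ref}>{alt}]{three}"


def channel_of_record(record: SnvRecord) -> str | None:
    ctx = record.central_context(1)
    if ctx is None:
        return None
    return channel_of(record.ref, record.alt, ctx[0], ctx[2])


@dataclass
class MutationCatalog96:
    """Per-sample 96-channel mutation counts (samples x channels)."""

    counts: pd.DataFrame
    n_excluded: int = 0

    def __post_init__(self) -> None:
        assert tuple(self.counts.columns) == CHANNELS_96
        assert (self.counts.to_numpy() >= 0).all()


@dataclass
class ExposureMatrix:
    """Fitted per-sample signature fractions and the derived APOBEC score."""

    exposures: pd.DataFrame  # samples x signatures, rows sum to 1 (or 0)
    apobec_score: pd.Series
    undefined: pd.Series  # True for samples with zero usable mutations


@dataclass
class ProcessAttribution:
    """Posterior probability of each signature having caused one mutation."""

    key: tuple
    sample_id: str
    channel: str
    probabilities: pd.Series
    flagged: bool = False

    @property
    def dominant(self) -> str:
        return str(self.probabilities.idxmax())


def build_96_catalog(cohort: CohortTable) -> MutationCatalog96:
    """Tally each sample's mutations into the canonical 96 channels.

    Records lacking a usable +/-1 context are excluded and counted.
    """
    samples = cohort.sample_ids
    mat = np.zeros((len(samples), 96), dtype=int)
    sample_index = {s: i for i, s in enumerate(samples)}
    n_excluded = 0
    for rec in cohort.records:
        ch = channel_of_record(rec)
        if ch is None:
            n_excluded += 1
            continue
        mat[sample_index[rec.sample_id], _CHANNEL_INDEX[ch]] += 1
    counts = pd.DataFrame(mat, index=samples, columns=list(CHANNELS_96))
    return MutationCatalog96(counts=counts, n_excluded=n_excluded)


class SignatureRefitter(BaseEstimator, TransformerMixin):
    """Refit fixed signature profiles to 96-channel catalogs.

    EM for the multinomial mixture: exposures are the per-sample
    non-negative fractions minimising the multinomial negative
    log-likelihood of the catalog under sum_k E[k] * S_k.

    Parameters
    ----------
    reference:
        SignatureMatrix of fixed profiles (rows sum to one).
    max_iter, tol:
        EM stops when the per-sample log-likelihood gain drops below
        ``tol * (1 + |loglik|)`` or after ``max_iter`` sweeps.
    apobec_signatures:
        Signature ids whose exposures sum to the APOBEC score.
    """

    def __init__(
        self,
        reference: SignatureMatrix | None = None,
        max_iter: int = 1000,
        tol: float = 1e-8,
        apobec_signatures: tuple[str, str] = DEFAULT_APOBEC_SIGNATURES,
    ):
        self.reference = reference
        self.max_iter = max_iter
        self.tol = tol
        self.apobec_signatures = apobec_signatures

    def fit(self, X, y=None):
        """Fit exposures for catalog ``X`` (n_samples x 96 counts)."""
        if self.reference is None:
            raise ValueError("a SignatureMatrix reference is required")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 96:
            raise ValueError("X must be (n_samples, 96)")
        S = self.reference.profiles.to_numpy(dtype=float)  # (K, 96)
        K = S.shape[0]
        n = X.shape[0]
        totals = X.sum(axis=1)
        E = np.full((n, K), 1.0 / K)
        loglik = np.full(n, -np.inf)
        converged = np.zeros(n, dtype=bool)
        undefined = totals == 0
        converged |= undefined
        path = []
        for it in range(self.max_iter):
            P = E @ S  # (n, 96) mixture channel probabilities
            with np.errstate(divide="ignore", invalid="ignore"):
                ll = np.where(
                    totals > 0,
                    np.sum(np.where(X > 0, X * np.log(np.where(P > 0, P, 1.0)), 0.0), axis=1),
                    0.0,
                )
                ratio = np.where(P > 0, X / np.where(P > 0, P, 1.0), 0.0)
            E_new = E * (ratio @ S.T)
            row = E_new.sum(axis=1, keepdims=True)
            np.divide(E_new, row, out=E_new, where=row > 0)
            gain = ll - loglik
            loglik = ll
            path.append(ll.sum())
            # relative criterion: log-likelihoods scale with mutation load
            newly = (~converged) & (np.abs(gain) < self.tol * (1.0 + np.abs(ll)))
            converged |= newly
            active = ~converged
            E[active] = E_new[active]
            if not active.any():
                break
        else:
            logger.warning(
                "EM did not converge for %d samples after %d iterations; "
                "best iterate returned", int((~converged).sum()), self.max_iter,
            )
        E[undefined] = 0.0
        self.exposures_ = E
        self.undefined_ = undefined
        self.loglik_ = loglik
        self.loglik_path_ = np.asarray(path)
        self.n_iter_ = it + 1
        return self

    def transform(self, X):
        self.fit(X)
        return self.exposures_


def fit_signature_exposures(
    catalog: MutationCatalog96,
    reference: SignatureMatrix,
    apobec_signatures: tuple[str, str] = DEFAULT_APOBEC_SIGNATURES,
    **kwargs,
) -> ExposureMatrix:
    """Convenience wrapper returning a labelled :class:`ExposureMatrix`."""
    est = SignatureRefitter(
        reference=reference, apobec_signatures=apobec_signatures, **kwargs
    )
    est.fit(catalog.counts.to_numpy())
    exposures = pd.DataFrame(
        est.exposures_, index=catalog.counts.index, columns=reference.signature_ids
    )
    present = [s for s in apobec_signatures if s in exposures.columns]
    apobec = exposures[present].sum(axis=1) if present else pd.Series(0.0, index=exposures.index)
    return ExposureMatrix(
        exposures=exposures,
        apobec_score=apobec.rename("apobec_score"),
        undefined=pd.Series(est.undefined_, index=exposures.index, name="undefined"),
    )


def hotspot_association_test(
    panel: HotspotPanel,
    exposures: ExposureMatrix,
    cohort: CohortTable,
    alpha: float = 0.05,
    adjust: bool = True,
) -> HotspotPanel:
    """Flag APOBEC-associated hotspots by carrier APOBEC scores.

    For each APOBEC-type candidate hotspot, carriers' APOBEC scores are
    compared against tumours carrying none of the candidates (one-sided
    Wilcoxon rank-sum, 'greater').  P-values are BH-adjusted across the
    candidates unless ``adjust`` is False; non-candidates are marked not
    associated by definition.
    """
    candidates = panel.candidates
    carrier_union: set[str] = set()
    for h in candidates:
        carrier_union.update(h.samples)
    scores = exposures.apobec_score[~exposures.undefined]
    background = scores[~scores.index.isin(carrier_union)]
    if len(background) == 0:
        raise ValueError("no candidate-free background samples")

    pvals = []
    tested = []
    for h in candidates:
        carriers = scores[scores.index.isin(h.samples)]
        if len(carriers) == 0:
            h.apobec_associated = None
            h.association_p = None
            continue
        _, p = stats.mannwhitneyu(carriers, background, alternative="greater")
        h.association_p = float(p)
        pvals.append(p)
        tested.append(h)

    if tested:
        if adjust:
            _, fdrs, _, _ = multipletests(pvals, method="fdr_bh")
        else:
            fdrs = pvals
        for h, q in zip(tested, fdrs):
            h.association_fdr = float(q)
            h.apobec_associated = bool(q < alpha)
    for h in panel.hotspots:
        if h.motif_class != "APOBEC_TCN":
            h.apobec_associated = False
    return panel


def per_mutation_process_probability(
    exposures: ExposureMatrix,
    reference: SignatureMatrix,
    record: SnvRecord,
) -> ProcessAttribution:
    """Posterior signature attribution for one mutation.

    p[k] = E[s,k] * S_k[c] / sum_j E[s,j] * S_j[c] for the record's
    channel c in its sample s.  A zero denominator falls back to a
    uniform distribution over the signatures with non-zero exposure
    (flagged).
    """
    ch = channel_of_record(record)
    if ch is None:
        raise ValueError("record has no usable +/-1 context")
    sid = record.sample_id
    if sid not in exposures.exposures.index:
        raise KeyError(f"sample {sid} has no fitted exposures")
    if bool(exposures.undefined.loc[sid]):
        raise ValueError(f"sample {sid} exposures are undefined")
    e = exposures.exposures.loc[sid].to_numpy()
    s_col = reference.profiles[ch].to_numpy()
    weights = e * s_col
    total = weights.sum()
    flagged = False
    if total <= 0:
        flagged = True
        support = e > 0
        weights = support / max(support.sum(), 1)
        total = weights.sum()
    probs = pd.Series(weights / total, index=reference.signature_ids)
    return ProcessAttribution(
        key=record.key, sample_id=sid, channel=ch, probabilities=probs, flagged=flagged
    )
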