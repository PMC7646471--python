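"""Synthetic cohorts with the statistical structure every stage assumes.

The generator emulates an exome-sequenced tumour cohort shaped like a
bladder-cancer series: per-sample mutation catalogs drawn from a
mixture of reference signature profiles (APOBEC-like activity varying
between samples), planted recurrent APOBEC-motif sites whose carrier
probability scales with the sample's APOBEC activity, mutation-centred
sequence windows with hairpins of tunable stability, log-normal
expression with a highly expressed functional-gene stratum and a
housekeeping anchor, piecewise-linear replication-fork-directionality
tracks, negative-binomial knockdown counts with a planted downregulated
regulon, and clonality labels enriched among hotspots.

Contexts are synthesised, never taken from a real genome; hairpin tiers
are realised by embedding reverse-complement arms of tunable length and
composition around the mutated base.  Every draw flows from the config
seed, so identical configs reproduce identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import (
    CHANNELS_96,
    CohortTable,
    ExpressionMatrix,
    RfdTrack,
    SignatureMatrix,
    SnvRecord,
    revcomp,
)

_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS_96)}


def _parse_channel(channel: str) -> tuple[str, str, str, str]:
    """five, ref, alt, three of a '<5>[R>A]<3>' channel string."""
    return channel[0], channel[2], channel[4], channel[6]


# ---------------------------------------------------------------------------
# synthetic signature reference
# ---------------------------------------------------------------------------

def synthetic_signature_reference(n_signatures: int = 30, seed: int = 715) -> SignatureMatrix:
    """A synthetic stand-in for the 30-profile COSMIC v2 catalogue.

    Synthetic profiles, not the published ones: slot 1 is
    deamination/ageing-like (C>T at NpCpG), slots 2 and 13 are
    APOBEC-like (C>T and C>G at TpCpN respectively), slot 5 is flat,
    and the remaining slots are random sparse profiles.  Rows sum to 1.
    """
    rng = np.random.default_rng(seed)
    profiles = np.zeros((n_signatures, 96))

    def mass(sub: str, five: str | None = None, three: str | None = None):
        idx = []
        for c in CHANNELS_96:
            f, r, a, t = _parse_channel(c)
            if f"{r}>{a}" != sub:
                continue
            if five is not None and f != five:
                continue
            if three is not None and t != three:
                continue
            idx.append(_CHANNEL_INDEX[c])
        return np.array(idx)

    flat = np.full(96, 1.0 / 96)
    # slot 1: ageing-like
    i = mass("C>T", three="G")
    profiles[0, i] = 0.8 / len(i)
    profiles[0] += 0.2 * flat
    # slot 2: APOBEC C>T at TCN
    i = mass("C>T", five="T")
    profiles[1, i] = np.array([0.30, 0.12, 0.05, 0.38])  # TCA, TCC, TCG, TCT
    profiles[1] += 0.15 * flat
    # slot 13: APOBEC C>G at TCN
    i = mass("C>G", five="T")
    profiles[12, i] = np.array([0.32, 0.10, 0.05, 0.38])
    profiles[12] += 0.15 * flat
    # slot 5: flat
    profiles[4] = flat + rng.dirichlet(np.full(96, 50.0)) * 0.2
    for k in range(n_signatures):
        if profiles[k].sum() == 0:
            profiles[k] = rng.dirichlet(np.full(96, 0.1))
    profiles /= profiles.sum(axis=1, keepdims=True)
    ids = [f"Signature.{k + 1}" for k in range(n_signatures)]
    return SignatureMatrix(
        profiles=pd.DataFrame(profiles, index=ids, columns=list(CHANNELS_96))
    )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedSite:
    """One recurrent site planted into the cohort.

    ``ref``, ``alt`` and ``context31`` are plus-strand; the hairpin tier
    controls the reverse-complement arms embedded around the centre
    (strong: long GC stem; weak: short mixed stem; none: unstructurable
    flanks).  Carrier probability per sample is
    baseline_rate * (1 + (apobec_multiplier - 1) * apobec_score).
    """

    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    context31: str
    motif_class: str
    hairpin_tier: str
    role: str  # driver | passenger | none
    seed_label: str = "unknown"  # known_driver | known_passenger | unknown
    baseline_rate: float = 0.02
    apobec_multiplier: float = 8.0

    @property
    def context25(self) -> str:
        return self.context31[3:28]

    @property
    def key(self):
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def channel(self) -> str:
        from .signatures import channel_of

        c = self.context31
        mid = len(c) // 2
        return channel_of(self.ref, self.alt, c[mid - 1], c[mid + 1])


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe a scaled-down exome cohort: 200 tumours, ~150
    usable SNVs each, bimodal APOBEC activity concentrated on the
    APOBEC-like signature slots, 28 planted APOBEC-motif recurrent
    sites (16 of known role seeding the classifier, 12 of hidden role)
    plus 2 non-APOBEC recurrent sites, clonality enriched among
    hotspots, and a 25-gene planted regulon in the knockdown design.
    """

    n_samples: int = 200
    mutations_mean: float = 150.0
    mutations_shape: float = 5.0  # negative-binomial shape (n)
    genome_span: int = 50_000_000
    clonal_p_hotspot: float = 0.8
    clonal_p_other: float = 0.5
    planted: tuple[PlantedSite, ...] = ()
    n_background_genes: int = 500
    n_cell_lines: int = 9
    rfd_bin: int = 10_000
    rfd_origin_spacing: int = 1_500_000
    rfd_noise: float = 0.05
    kd_n_genes: int = 2000
    kd_replicates: int = 4
    kd_fold_change: float = 0.25
    kd_dispersion: float = 0.05
    n_regulon_genes: int = 25
    seed: int = 0

    def rng(self, stage: str) -> np.random.Generator:
        """Named per-stage substream of the master seed."""
        stage_key = int.from_bytes(stage.encode()[:8].ljust(8, b"\0"), "big")
        return np.random.default_rng(np.random.SeedSequence((self.seed, stage_key)))


# ---------------------------------------------------------------------------
# context construction
# ---------------------------------------------------------------------------

_SAFE = np.array(list("AC"))  # bases that cannot Watson-Crick pair together


def _safe_fill(rng, n: int) -> str:
    return "".join(rng.choice(_SAFE, size=n))


def make_context31(
    rng: np.random.Generator,
    tier: str = "none",
    apobec_motif: bool = True,
    strand_flip: bool | None = None,
) -> tuple[str, str, str]:
    """Build a 31-nt plus-strand context with a mutable centre.

    Returns (context31, ref, alt).  The pyrimidine-strand centre is a C
    in a TCN context when ``apobec_motif`` (alt C>T), otherwise a C in
    an ApCpA context (non-APOBEC).  Tiers embed reverse-complement arms
    so the centre sits in a terminal loop of tunable stability.
    """
    if strand_flip is None:
        strand_flip = bool(rng.random() < 0.5)
    left2 = str(rng.choice(_SAFE))
    minus1 = "T" if apobec_motif else "A"
    plus1 = str(rng.choice(_SAFE)) if apobec_motif else "A"
    plus2 = str(rng.choice(_SAFE))
    loop = left2 + minus1 + "C" + plus1 + plus2  # centre at loop[2]
    if tier == "strong":
        arm = "".join(rng.choice(np.array(list("GC")), size=9))
        ctx = _safe_fill(rng, 4) + arm + loop[:2] + "C" + loop[3:] + revcomp(arm) + _safe_fill(rng, 4)
        # arms at 4..12 / 18..26; loop occupies 13..17 with centre 15
    elif tier == "weak":
        arm = "".join(rng.choice(np.array(list("ATGC")), size=4, p=[0.35, 0.35, 0.15, 0.15]))
        ctx = _safe_fill(rng, 9) + arm + loop + revcomp(arm) + _safe_fill(rng, 9)
    elif tier == "none":
        ctx = _safe_fill(rng, 13) + loop + _safe_fill(rng, 13)
    else:
        raise ValueError(f"unknown hairpin tier {tier!r}")
    ctx = ctx[:13] + loop + ctx[18:]  # enforce loop at 13..17, centre 15
    assert len(ctx) == 31 and ctx[15] == "C"
    ref, alt = "C", "T"
    if strand_flip:
        ctx, ref, alt = revcomp(ctx), "G", "A"
    return ctx, ref, alt


def default_planted_sites(seed: int = 91) -> tuple[PlantedSite, ...]:
    """The default planted-site panel.

    9 known drivers, 7 known passengers (the classifier seeds), 12
    hidden-role sites (7 drivers, 5 passengers) and 2 non-APOBEC
    recurrent sites.  Drivers sit outside stable loops (tier none or
    weak) in functional genes; passengers sit in strong hairpin loops.
    """
    rng = np.random.default_rng(seed)
    sites = []
    spec = (
        [("driver", "known_driver")] * 9
        + [("passenger", "known_passenger")] * 7
        + [("driver", "unknown")] * 7
        + [("passenger", "unknown")] * 5
    )
    for i, (role, seed_label) in enumerate(spec):
        tier = ("none" if i % 2 else "weak") if role == "driver" else "strong"
        ctx, ref, alt = make_context31(rng, tier=tier, apobec_motif=True)
        sites.append(
            PlantedSite(
                gene=f"PL{i:02d}",
                chrom="chr1",
                pos=1_000_000 * (i + 1) + int(rng.integers(0, 500_000)),
                ref=ref,
                alt=alt,
                context31=ctx,
                motif_class="APOBEC_TCN",
                hairpin_tier=tier,
                role=role,
                seed_label=seed_label,
            )
        )
    for j in range(2):
        ctx, ref, alt = make_context31(rng, tier="none", apobec_motif=False)
        sites.append(
            PlantedSite(
                gene=f"NA{j:02d}",
                chrom="chr1",
                pos=31_000_000 + 1_000_000 * j + int(rng.integers(0, 500_000)),
                ref=ref,
                alt=alt,
                context31=ctx,
                motif_class="other",
                hairpin_tier="none",
                role="none",
                seed_label="unknown",
                baseline_rate=0.05,
                apobec_multiplier=1.0,
            )
        )
    return tuple(sites)


def default_config(seed: int = 0) -> SimConfig:
    return SimConfig(planted=default_planted_sites(), seed=seed)


# ---------------------------------------------------------------------------
# truth manifest
# ---------------------------------------------------------------------------

@dataclass
class TruthManifest:
    sites: list[dict]
    exposures: pd.DataFrame  # samples x signatures (true fractions)
    apobec_score: pd.Series
    emission_tally: pd.DataFrame  # samples x 96 channels
    expression_strata: dict[str, str] = field(default_factory=dict)
    regulon_genes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _draw_exposures(config: SimConfig, reference: SignatureMatrix, rng) -> pd.DataFrame:
    ids = reference.signature_ids
    n = config.n_samples
    E = np.zeros((n, len(ids)))
    apobec = rng.beta(0.6, 0.6, size=n)
    split2 = rng.beta(2.0, 2.0, size=n)
    split1 = rng.beta(2.0, 2.0, size=n)
    E[:, ids.index("Signature.2")] = apobec * split2
    E[:, ids.index("Signature.13")] = apobec * (1 - split2)
    E[:, ids.index("Signature.1")] = (1 - apobec) * split1
    E[:, ids.index("Signature.5")] = (1 - apobec) * (1 - split1)
    samples = [f"S{i:04d}" for i in range(n)]
    return pd.DataFrame(E, index=samples, columns=ids)


def simulate_cohort(
    config: SimConfig,
    reference: SignatureMatrix | None = None,
) -> tuple[CohortTable, TruthManifest]:
    """Draw a full cohort and its ground-truth manifest."""
    for site in config.planted:
        mid = site.context31[len(site.context31) // 2]
        if mid != site.ref:
            raise ValueError(f"planted context centre != ref for {site.gene}")
    if reference is None:
        reference = synthetic_signature_reference()
    rng = config.rng("cohort")
    exposures = _draw_exposures(config, reference, rng)
    samples = list(exposures.index)
    S = reference.profiles.to_numpy()
    channel_probs = exposures.to_numpy() @ S  # per-sample channel mixture
    apobec_ids = [c for c in ("Signature.2", "Signature.13") if c in exposures.columns]
    apobec_score = exposures[apobec_ids].sum(axis=1)

    p_nb = config.mutations_shape / (config.mutations_shape + config.mutations_mean)
    n_mut = rng.negative_binomial(config.mutations_shape, p_nb, size=len(samples))
    n_mut = np.maximum(n_mut, 30)

    tally = np.zeros((len(samples), 96), dtype=int)
    records: list[SnvRecord] = []
    site_carriers: dict[tuple, list[str]] = {s.key: [] for s in config.planted}

    bases = np.array(list("ACGT"))
    for si, sample in enumerate(samples):
        m = int(n_mut[si])
        chans = rng.choice(96, size=m, p=channel_probs[si] / channel_probs[si].sum())
        positions = rng.integers(1, config.genome_span, size=m)
        flips = rng.random(m) < 0.5
        flanks = rng.choice(bases, size=(m, 22))
        clonal = rng.random(m) < config.clonal_p_other
        for mi in range(m):
            ch = CHANNELS_96[chans[mi]]
            five, ref, alt, three = _parse_channel(ch)
            ctx = "".join(flanks[mi][:11]) + five + ref + three + "".join(flanks[mi][11:])
            if flips[mi]:
                ctx, ref, alt = revcomp(ctx), revcomp(ref), revcomp(alt)
            pos = int(positions[mi])
            gene = f"G{pos * config.n_background_genes // config.genome_span:04d}"
            records.append(
                SnvRecord(
                    patient_id=sample,
                    sample_id=sample,
                    chrom="chr1",
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    gene=gene,
                    context25=ctx,
                    clonality="clonal" if clonal[mi] else "subclonal",
                )
            )
            tally[si, chans[mi]] += 1

    for site in config.planted:
        p_carry = np.minimum(
            site.baseline_rate
            * (1 + (site.apobec_multiplier - 1) * apobec_score.to_numpy()),
            0.95,
        )
        carried = rng.random(len(samples)) < p_carry
        clonal = rng.random(len(samples)) < config.clonal_p_hotspot
        ch_idx = _CHANNEL_INDEX[site.channel]
        for si, sample in enumerate(samples):
            if not carried[si]:
                continue
            site_carriers[site.key].append(sample)
            records.append(
                SnvRecord(
                    patient_id=sample,
                    sample_id=sample,
                    chrom=site.chrom,
                    pos=site.pos,
                    ref=site.ref,
                    alt=site.alt,
                    gene=site.gene,
                    protein_change=None,
                    context25=site.context25,
                    clonality="clonal" if clonal[si] else "subclonal",
                )
            )
            tally[si, ch_idx] += 1

    manifest = TruthManifest(
        sites=[
            {
                "gene": s.gene,
                "key": s.key,
                "role": s.role,
                "seed_label": s.seed_label,
                "motif_class": s.motif_class,
                "hairpin_tier": s.hairpin_tier,
                "context31": s.context31,
                "channel": s.channel,
                "carriers": tuple(site_carriers[s.key]),
            }
            for s in config.planted
        ],
        exposures=exposures,
        apobec_score=apobec_score.rename("apobec_score"),
        emission_tally=pd.DataFrame(tally, index=samples, columns=list(CHANNELS_96)),
    )
    return CohortTable(records=records, metadata={"synthetic": True}), manifest


# ---------------------------------------------------------------------------
# expression / knockdown / RFD
# ---------------------------------------------------------------------------

_STRATA = {
    # log-normal location/scale per gene stratum (arbitrary RSEM-like units)
    "functional": (2.0, 0.5),
    "unknown_high": (1.5, 0.8),
    "unknown_low": (-1.0, 1.0),
    "background": (0.5, 1.2),
    "anchor": (4.0, 0.1),
}


def simulate_expression(
    config: SimConfig,
    manifest: TruthManifest,
    anchor: str = "GAPDH",
) -> ExpressionMatrix:
    """Log-normal expression for every cohort gene plus the anchor.

    Planted driver genes fall in the highly expressed functional
    stratum, planted passenger genes in the low/heterogeneous unknown
    stratum, background genes in a broad middle stratum; the anchor is
    uniformly high with small variance.
    """
    rng = config.rng("expression")
    strata: dict[str, str] = {anchor: "anchor"}
    for site in manifest.sites:
        if site["role"] == "driver":
            strata[site["gene"]] = "functional"
        elif site["role"] == "passenger":
            strata[site["gene"]] = "unknown_low"
        else:
            strata[site["gene"]] = "background"
    for g in range(config.n_background_genes):
        strata.setdefault(f"G{g:04d}", "background")
    genes = sorted(strata)
    samples = list(manifest.exposures.index)
    mat = np.empty((len(genes), len(samples)))
    for gi, gene in enumerate(genes):
        mu, sigma = _STRATA[strata[gene]]
        mat[gi] = rng.lognormal(mu, sigma, size=len(samples))
    manifest.expression_strata = strata
    return ExpressionMatrix(
        values=pd.DataFrame(mat, index=genes, columns=samples), units="normalised"
    )


def simulate_knockdown(
    config: SimConfig,
    manifest: TruthManifest,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Raw NB counts for a knockdown-vs-control design with a planted regulon.

    Returns (counts, condition).  The first ``n_regulon_genes`` genes
    (named REG####) are downregulated by ``kd_fold_change`` in the
    knockdown arm; dispersion is gamma-Poisson with the configured
    coefficient.
    """
    rng = config.rng("knockdown")
    n_genes = config.kd_n_genes
    reg = [f"REG{i:04d}" for i in range(config.n_regulon_genes)]
    other = [f"KD{i:04d}" for i in range(n_genes - len(reg))]
    genes = reg + other
    base_mean = rng.lognormal(4.0, 1.0, size=n_genes)
    r = config.kd_replicates
    cols = [f"ctrl_{i}" for i in range(r)] + [f"kd_{i}" for i in range(r)]
    condition = pd.Series(
        ["control"] * r + ["knockdown"] * r, index=cols, name="condition"
    )
    mat = np.empty((n_genes, 2 * r))
    shape = 1.0 / config.kd_dispersion
    for ci, col in enumerate(cols):
        mean = base_mean.copy()
        if condition[col] == "knockdown":
            mean[: len(reg)] = mean[: len(reg)] * config.kd_fold_change
        lam = rng.gamma(shape, mean / shape)
        mat[:, ci] = rng.poisson(lam)
    manifest.regulon_genes = reg
    counts = ExpressionMatrix(
        values=pd.DataFrame(mat, index=genes, columns=cols), units="counts"
    )
    return counts, condition


def simulate_rfd(config: SimConfig) -> list[RfdTrack]:
    """Sawtooth RFD tracks: linear between replication origins, noisy, clipped."""
    rng = config.rng("rfd")
    tracks = []
    span, binsize = config.genome_span, config.rfd_bin
    edges = np.arange(0, span + binsize, binsize)
    for cl in range(config.n_cell_lines):
        origins = [0]
        while origins[-1] < span:
            origins.append(
                origins[-1]
                + int(config.rfd_origin_spacing * (0.5 + rng.random()))
            )
        origins = np.asarray(origins, dtype=float)
        mids = (edges[:-1] + edges[1:]) / 2
        seg = np.searchsorted(origins, mids) - 1
        left, right = origins[seg], origins[seg + 1]
        base = -1 + 2 * (mids - left) / (right - left)
        values = np.clip(base + rng.normal(0, config.rfd_noise, size=len(mids)), -1, 1)
        intervals = [
            ("chr1", int(edges[i]), int(edges[i + 1]), float(values[i]))
            for i in range(len(mids))
        ]
        tracks.append(RfdTrack(cell_line=f"CL{cl + 1}", intervals=intervals))
    return tracks


def simulate_all(config: SimConfig, reference: SignatureMatrix | None = None) -> dict:
    """Every pipeline input for one config, with its truth manifest."""
    if reference is None:
        reference = synthetic_signature_reference()
    cohort, manifest = simulate_cohort(config, reference)
    expr = simulate_expression(config, manifest)
    kd_counts, kd_condition = simulate_knockdown(config, manifest)
    tracks = simulate_rfd(config)
    return {
        "config": config,
        "reference": reference,
        "cohort": cohort,
        "manifest": manifest,
        "expression": expr,
        "kd_counts": kd_counts,
        "kd_condition": kd_condition,
        "rfd_tracks": tracks,
    }
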