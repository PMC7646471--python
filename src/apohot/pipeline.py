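"""End-to-end orchestration: ingest -> hotspots -> signatures ->
association -> strand -> fold -> rank -> classify -> (optional) regulon.

Each stage writes a TSV/JSON artifact plus a machine-readable log of
parameters and seeds; reruns with an identical config reproduce
identical outputs.  All randomness flows from one master seed through
named per-stage substreams, so stages can be rerun in isolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    ahr_regulon,
    driver_classifier,
    expression_rank,
    hairpin,
    hotspots as hotspots_mod,
    io_formats,
    replication_strand,
    signatures as signatures_mod,
    synthetic_data,
)

logger = logging.getLogger("apohot")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    With ``simulate`` (the default) every input is generated from the
    master seed; otherwise ``snv_path`` (and friends) are read from
    disk and ``seeds_path`` must label the known driver/passenger
    mutations for the classifier.
    """

    out_dir: str = "apohot_run"
    seed: int = 0
    simulate: bool = True
    snv_path: str | None = None
    fasta_path: str | None = None
    expression_path: str | None = None
    rfd_dir: str | None = None
    seeds_path: str | None = None
    signature_path: str | None = None
    anchor_gene: str = "GAPDH"
    alpha: float = 0.05
    window: int = 25
    n_rand: int = 10_000
    run_strand: bool = True
    run_regulon: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # typed error naming the stage
                raise StageError(name, exc) from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the stages in order; returns the in-memory results.

    Artifacts land in ``config.out_dir``: cohort.tsv, panel.tsv,
    exposures.tsv, lagging.tsv, loops.tsv, ranks.tsv, predictions.tsv,
    regulon.json and log.json.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": config}
    log = {"seed": config.seed, "stages": [], "params": asdict(config)}

    cohort, manifest, expr, tracks, reference, kd = _ingest(config)
    io_formats.write_snv_table(cohort, out / "cohort.tsv")
    log["stages"].append("ingest")
    results.update(cohort=cohort, manifest=manifest, expression=expr)

    panel = _hotspots(cohort)
    log["stages"].append("hotspots")

    catalog, exposures, panel = _signatures(cohort, panel, reference, config.alpha)
    exposures.exposures.assign(
        apobec_score=exposures.apobec_score, undefined=exposures.undefined
    ).to_csv(out / "exposures.tsv", sep="\t", index_label="sample")
    log["stages"].append("signatures")
    results.update(catalog=catalog, exposures=exposures, panel=panel)

    if config.run_strand and tracks:
        lagging = _strand(cohort, panel, tracks)
        lagging.to_csv(out / "lagging.tsv", sep="\t", index=False)
        log["stages"].append("strand")
        results["lagging"] = lagging

    loops = _fold(cohort, panel, config.window)
    loops.to_csv(out / "loops.tsv", sep="\t", index=False)
    log["stages"].append("fold")
    results["loops"] = loops

    ranks = expression_rank.gapdh_percentile_rank(expr, anchor=config.anchor_gene)
    ranks.to_csv(out / "ranks.tsv", sep="\t", index_label="gene")
    log["stages"].append("rank")
    results["ranks"] = ranks

    panel.to_frame().to_csv(out / "panel.tsv", sep="\t", index=False)

    seeds = _seed_labels(config, manifest)
    predictions = _classify(panel, loops, ranks, seeds, config)
    predictions.to_csv(out / "predictions.tsv", sep="\t", index=False)
    log["stages"].append("classify")
    results["predictions"] = predictions

    if config.run_regulon and kd is not None:
        regulon = _regulon(kd, manifest, config)
        with open(out / "regulon.json", "w") as fh:
            json.dump(regulon.to_dict(), fh, indent=1, sort_keys=True)
        log["stages"].append("regulon")
        results["regulon"] = regulon

    with open(out / "log.json", "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)
    return results


@_stage("ingest")
def _ingest(config: PipelineConfig):
    if config.simulate:
        sim_config = synthetic_data.default_config(seed=config.seed)
        sim = synthetic_data.simulate_all(sim_config)
        return (
            sim["cohort"],
            sim["manifest"],
            sim["expression"],
            sim["rfd_tracks"],
            sim["reference"],
            (sim["kd_counts"], sim["kd_condition"]),
        )
    if config.snv_path is None or config.expression_path is None:
        raise ValueError("snv_path and expression_path required when not simulating")
    cohort = io_formats.read_snv_table(config.snv_path, fasta=config.fasta_path)
    expr = io_formats.read_expression_matrix(config.expression_path)
    tracks = []
    if config.rfd_dir:
        for p in sorted(Path(config.rfd_dir).glob("*.bedgraph")):
            tracks.append(io_formats.read_rfd_bedgraph(p, cell_line=p.stem))
    if config.signature_path:
        reference = io_formats.read_signature_reference(config.signature_path)
    else:
        reference = io_formats.load_packaged_signature_reference()
    return cohort, None, expr, tracks, reference, None


@_stage("hotspots")
def _hotspots(cohort):
    return hotspots_mod.call_hotspots(cohort)


@_stage("signatures")
def _signatures(cohort, panel, reference, alpha):
    catalog = signatures_mod.build_96_catalog(cohort)
    exposures = signatures_mod.fit_signature_exposures(catalog, reference)
    panel = signatures_mod.hotspot_association_test(
        panel, exposures, cohort, alpha=alpha
    )
    return catalog, exposures, panel


@_stage("strand")
def _strand(cohort, panel, tracks):
    rec_by_key = {}
    for rec in cohort.records:
        rec_by_key.setdefault(rec.key, rec)
    rows = []
    for h in panel.hotspots:
        profile = replication_strand.lagging_profile(rec_by_key[h.key], tracks)
        row = {
            "chrom": h.key[0], "pos": h.key[1], "ref": h.key[2], "alt": h.key[3],
            "apobec_associated": h.apobec_associated,
        }
        row.update(profile.indicators)
        row["lagging_probability"] = profile.lagging_probability
        rows.append(row)
    return pd.DataFrame(rows)


@_stage("fold")
def _fold(cohort, panel, window):
    flank = window // 2
    ctx_by_key = {}
    for rec in cohort.records:
        if rec.key not in ctx_by_key:
            ctx = rec.central_context(flank)
            if ctx is not None:
                ctx_by_key[rec.key] = ctx
    feats = []
    for h in panel.hotspots:
        ctx = ctx_by_key.get(h.key)
        if ctx is None:
            feats.append((h.key, 0.0, False))
            continue
        fr = hairpin.fold_mfe(ctx)
        feats.append((h.key, fr.delta_g, fr.centre_in_loop))
    scored = hairpin.normalised_loop_stability(feats)
    rows = []
    for h, f in zip(panel.hotspots, scored):
        rows.append(
            {
                "chrom": h.key[0], "pos": h.key[1], "ref": h.key[2], "alt": h.key[3],
                "gene": h.gene,
                "delta_g": f.delta_g,
                "in_loop": f.in_loop,
                "loop_score": f.normalised_score,
            }
        )
    return pd.DataFrame(rows)


def _seed_labels(config: PipelineConfig, manifest) -> dict:
    """mutation key -> known_driver / known_passenger."""
    if manifest is not None:
        return {
            s["key"]: s["seed_label"]
            for s in manifest.sites
            if s["seed_label"] in ("known_driver", "known_passenger")
        }
    if config.seeds_path is None:
        raise ValueError("seeds_path required when not simulating")
    df = pd.read_csv(config.seeds_path, sep="\t", dtype={"pos": int})
    return {
        (r.chrom, r.pos, r.ref, r.alt): r.seed_label
        for r in df.itertuples(index=False)
    }


@_stage("classify")
def _classify(panel, loops, ranks, seeds, config: PipelineConfig):
    associated = [h for h in panel.hotspots if h.apobec_associated]
    loop_by_key = {
        (r.chrom, r.pos, r.ref, r.alt): r.loop_score for r in loops.itertuples()
    }
    rows = []
    for h in associated:
        if h.gene not in ranks.index:
            continue
        rows.append(
            {
                "chrom": h.key[0], "pos": h.key[1], "ref": h.key[2], "alt": h.key[3],
                "gene": h.gene,
                "x1": loop_by_key[h.key],
                "x2": float(ranks.loc[h.gene, "rank"]),
                "seed_label": seeds.get(h.key, "unknown"),
            }
        )
    points = pd.DataFrame(rows)
    result = driver_classifier.iterative_similarity_classify(points, alpha=config.alpha)
    seeds_mask = points["seed_label"] != "unknown"
    result = driver_classifier.permutation_fdr(
        result,
        points.loc[seeds_mask, ["x1", "x2"]].to_numpy(),
        points.loc[seeds_mask, "seed_label"]
        .map({"known_driver": "driver", "known_passenger": "passenger"})
        .to_numpy(),
        seed=config.seed,
    )
    merged = points.loc[result.index, ["chrom", "pos", "ref", "alt", "gene"]].join(
        result[["x1", "x2", "label", "iteration", "mdod", "t_p", "p_perm", "fdr"]]
    )
    return merged


@_stage("regulon")
def _regulon(kd, manifest, config: PipelineConfig):
    counts, condition = kd
    de = ahr_regulon.nb_differential_expression(counts, condition)
    candidates = list(manifest.regulon_genes) + [
        g for g in counts.values.index if g.startswith("KD")
    ][: len(manifest.regulon_genes)]
    model = ahr_regulon.RegulonModel(
        tf="TF", prototype="TARGET", rho_threshold=float("nan"), anchor_p=float("nan"),
        candidates=candidates,
    )
    ranking = ahr_regulon.de_ranking(de)
    model.randomisation_p = ahr_regulon.ranksum_randomisation_test(
        ranking, candidates, n_rand=config.n_rand, seed=config.seed
    )
    model = ahr_regulon.finalise_regulon(model, de)
    return model
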