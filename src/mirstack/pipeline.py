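"""End-to-end orchestration: discover / train / tune / evaluate / simulate.

The discovery pass is: load alignments -> recompute hit counts -> collapse
duplicates -> group read regions per strand -> MPRF feature vectors and
decision values -> candidate precursor spans (duplex- and product-focused)
for passing products -> product naming and the 71 HPRF features -> HPRF
decision values -> threshold + overlap resolution -> predictions.  Every
evaluated locus keeps its best score whether or not it passes, so the score
table supports precision-recall curves.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluation, hairpin, io as sio, mature, spans
from .io import SampleLibrary
from .mature import ForestModel


@dataclass
class PipelineConfig:
    """All tunables with the tool's shipped defaults."""

    mprf_threshold: float = 0.5
    y_hprf: float = 0.28  # tuned HPRF decision-value threshold
    e_th: float = 0.11  # tuned expression threshold (ARPM)
    hprf_ratio_x: int = 25  # 1:X negative sampling for the HPRF
    mprf_ratio_x: int = 1  # 1:1 for the product layer
    duplex_window: int = 70
    product_gap: int = 5
    pad: int = spans.DEFAULT_PAD
    max_span: int = spans.MAX_SPAN
    cluster_distance: int = 10_000
    neighbor_window: int = 1000
    lfc_pseudocount: float = 0.015
    n_trees: int = 500
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class DiscoveryResult:
    predictions: list
    locus_scores: pd.DataFrame  # one row per read region, PR-curve ready
    regions: list
    candidates: list
    library: SampleLibrary


def prepare_regions(reads, trust_nh: bool = False):
    """Hit-count annotation, duplicate collapsing and region grouping."""
    reads = sio.annotate_hit_counts(reads, trust_existing=trust_nh)
    reads = sio.collapse_duplicates(reads)
    regions = sio.group_read_regions(reads)
    return reads, regions


def _mprf_pass(regions, genome, model, threshold):
    """Score every region; return (vectors, scores, passing-region list)."""
    X = np.array([mature.mature_feature_vector(g, genome) for g in regions])
    scores = mature.score_read_regions(model, X) if len(X) else np.array([])
    passing = [g for g, s in zip(regions, scores) if s >= threshold]
    return X, scores, passing


def generate_candidates(passing, genome, config: PipelineConfig):
    """Duplex- and product-focused candidate spans for each passing product."""
    out = []
    for g in passing:
        cand = spans.duplex_focused_span(
            g, genome, window=config.duplex_window, pad=config.pad,
            max_span=config.max_span,
        )
        if cand is not None:
            out.append(cand)
        neighbors = [
            h
            for h in passing
            if h is not g
            and h.chrom == g.chrom
            and h.strand == g.strand
            and abs(h.start - g.start) <= config.max_span
        ]
        out.extend(
            spans.product_focused_spans(
                g, neighbors, genome, min_gap=config.product_gap,
                pad=config.pad, max_span=config.max_span,
            )
        )
    return out


def _candidate_vectors(candidates, regions, reads, genome, library, mprf_scores,
                       config):
    """Name products and compute the HPRF vector for each viable candidate."""
    kept, vectors = [], []
    for cand in candidates:
        products = hairpin.name_products(cand, regions)
        if not products:
            continue
        vec = hairpin.hairpin_feature_vector(
            cand, products, library, mprf_scores, regions, reads, genome
        )
        kept.append(cand)
        vectors.append(vec)
    return kept, vectors


def run_discover(
    reads,
    genome,
    mprf_model: ForestModel,
    hprf_model: ForestModel,
    config: PipelineConfig | None = None,
    sample_id: str = "sample",
) -> DiscoveryResult:
    """Full discovery pass over one sample (reads already loaded)."""
    config = config or PipelineConfig()
    reads, regions = prepare_regions(reads)
    library = SampleLibrary.from_reads(reads, sample_id)
    if not regions:
        return DiscoveryResult([], _empty_scores(), [], [], library)
    X, mscores, passing = _mprf_pass(
        regions, genome, mprf_model, config.mprf_threshold
    )
    mprf_scores = {id(g): float(s) for g, s in zip(regions, mscores)}
    candidates = generate_candidates(passing, genome, config)
    candidates, vectors = _candidate_vectors(
        candidates, regions, reads, genome, library, mprf_scores, config
    )
    predictions = (
        hairpin.predict(
            hprf_model, candidates, vectors, library,
            y_threshold=config.y_hprf, expression_threshold=config.e_th,
        )
        if candidates
        else []
    )
    locus_scores = _locus_score_table(regions, mscores, candidates)
    return DiscoveryResult(predictions, locus_scores, regions, candidates, library)


def _empty_scores() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["chrom", "start", "end", "strand", "mprf_score", "hprf_score"]
    )


def _locus_score_table(regions, mscores, candidates) -> pd.DataFrame:
    """Best HPRF score per read region (0 for regions with no scored
    candidate), so every evaluated locus appears in the output."""
    best: dict[int, float] = {}
    for cand in candidates:
        if cand.hprf_score is None:
            continue
        for p in cand.products:
            key = id(p.parent if p.parent is not None else p.region)
            best[key] = max(best.get(key, 0.0), cand.hprf_score)
    rows = []
    for g, ms in zip(regions, mscores):
        rows.append(
            {
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "mprf_score": float(ms),
                "hprf_score": best.get(id(g), 0.0),
            }
        )
    return pd.DataFrame(rows)


def run_train(
    reads, genome, annotations, config: PipelineConfig | None = None,
    sample_id: str = "train",
) -> tuple[ForestModel, ForestModel]:
    """Train both layers on one annotated sample.

    The MPRF is trained first (1:1 sampling by default); candidates are then
    generated from its passing products and the HPRF is trained at 1:X.
    """
    config = config or PipelineConfig()
    reads, regions = prepare_regions(reads)
    library = SampleLibrary.from_reads(reads, sample_id)
    Xm, ym, _ = mature.build_mprf_training_set(
        regions, annotations, genome, ratio_x=config.mprf_ratio_x,
        seed=config.seed,
    )
    mprf = mature.train_mprf(Xm, ym, seed=config.seed, n_trees=config.n_trees)

    X, mscores, passing = _mprf_pass(regions, genome, mprf, config.mprf_threshold)
    mprf_scores = {id(g): float(s) for g, s in zip(regions, mscores)}
    candidates = generate_candidates(passing, genome, config)
    candidates, vectors = _candidate_vectors(
        candidates, regions, reads, genome, library, mprf_scores, config
    )
    Xh, yh, _ = hairpin.build_hprf_training_set(
        candidates, vectors, annotations, ratio_x=config.hprf_ratio_x,
        seed=config.seed,
    )
    hprf = hairpin.train_hprf(Xh, yh, seed=config.seed, n_trees=config.n_trees)
    return mprf, hprf


def expressed_precursors(annotations, reads) -> set[str]:
    """Names of annotated precursors with at least one read aligned."""
    out = set()
    precursors = [a for a in annotations if a.kind == "precursor"]
    for ann in precursors:
        for r in reads:
            if r.chrom == ann.chrom and r.start < ann.end and ann.start < r.end:
                out.add(ann.name)
                break
    return out


def run_evaluate(predictions, annotations, reads=None) -> dict:
    """Stringent metrics for a prediction set against annotations."""
    expressed = (
        expressed_precursors(annotations, reads) if reads is not None else None
    )
    p, r = evaluation.precision_recall(predictions, annotations, expressed)
    f1, f_paper = evaluation.f_scores(p or 0.0, r or 0.0)
    labels = [evaluation.classify_prediction(x, annotations) for x in predictions]
    counts = {lab: labels.count(lab) for lab in set(labels)}
    return {
        "precision": p,
        "recall": r,
        "f1": f1,
        "f_paper": f_paper,
        "n_predictions": len(predictions),
        "label_counts": counts,
        "n_expressed": len(expressed) if expressed is not None else None,
    }


def run_tune(
    train_reads, train_genome, train_annotations,
    tune_reads, tune_genome, tune_annotations,
    y_grid, e_grid, x_grid,
    config: PipelineConfig | None = None,
    objective: str = "f1",
) -> evaluation.TuningResult:
    """Grid-search (y_HPRF, E_th, X) on a tuning sample disjoint from the
    training sample (train and tune inputs must differ)."""
    config = config or PipelineConfig()
    if train_reads is tune_reads:
        raise ValueError("tuning sample must differ from the training sample")

    def train_fn(x):
        cfg = dataclasses.replace(config, hprf_ratio_x=x)
        mprf, hprf = run_train(train_reads, train_genome, train_annotations, cfg)
        # score the tuning sample once per X; thresholds apply afterwards
        reads2, regions = prepare_regions(list(tune_reads))
        library = SampleLibrary.from_reads(reads2, "tune")
        X, mscores, passing = _mprf_pass(
            regions, tune_genome, mprf, cfg.mprf_threshold
        )
        mprf_scores = {id(g): float(s) for g, s in zip(regions, mscores)}
        cands = generate_candidates(passing, tune_genome, cfg)
        cands, vectors = _candidate_vectors(
            cands, regions, reads2, tune_genome, library, mprf_scores, cfg
        )
        return {
            "models": (mprf, hprf),
            "cands": cands,
            "vectors": vectors,
            "library": library,
            "reads": reads2,
        }

    expressed = None

    def eval_fn(ctx, y, e):
        nonlocal expressed
        preds = (
            hairpin.predict(
                ctx["models"][1], ctx["cands"], ctx["vectors"], ctx["library"],
                y_threshold=y, expression_threshold=e,
            )
            if ctx["cands"]
            else []
        )
        if expressed is None:
            expressed = expressed_precursors(tune_annotations, ctx["reads"])
        p, r = evaluation.precision_recall(preds, tune_annotations, expressed)
        return (p or 0.0), (r or 0.0)

    return evaluation.tune_grid(
        train_fn, eval_fn, y_grid, e_grid, x_grid, objective=objective
    )
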