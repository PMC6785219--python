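"""Second classifier layer: product naming, the 71 hairpin features, and HPRF.

Read stacks inside a candidate span are named as the products expected from
Drosha/Dicer processing — miR-5p/miR-3p (the duplex pair), moRs immediately
outside the miRs on the same arm, loop products, and out/other stacks.  The
71-feature vector combines sequence composition of the precursor, fold and
duplex structure, the spatial arrangement and abundance distribution of the
named products, read-count/start-position variances, neighborhood density,
and the first layer's decision values.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

import numpy as np

from . import io as sio
from .folding import duplex, fold_duplex_agreement, parse_hairpin, structural_features
from .io import ReadRegion, SampleLibrary, adjusted_count, arpm
from .mature import (
    DINUCS,
    ForestModel,
    dinucleotide_frequencies,
    five_prime_heterogeneity,
    gc_content,
)
from .spans import HairpinCandidate, resolve_overlapping_hairpins

PRODUCT_LABELS = [
    "miR-5p",
    "miR-3p",
    "moR-5p",
    "moR-3p",
    "loop",
    "out-5p",
    "out-3p",
    "other",
]

#: the 11 product-pair overlap features (fixed convention, see manifest)
OVERLAP_PAIRS = [
    ("miR-5p", "moR-5p"),
    ("miR-5p", "loop"),
    ("miR-5p", "miR-3p"),
    ("miR-3p", "moR-3p"),
    ("miR-3p", "loop"),
    ("moR-5p", "loop"),
    ("moR-3p", "loop"),
    ("miR-5p", "out-5p"),
    ("miR-3p", "out-3p"),
    ("moR-5p", "out-5p"),
    ("moR-3p", "out-3p"),
]


def _overlap_name(pair) -> str:
    a, b = (p.replace("-", "") for p in pair)
    return f"{a}{b}Overlap"


#: fixed 71-feature order shared by training and scoring
HPRF_FEATURES: list[str] = (
    [
        "mfe",
        "pbp",
        "urf",
        "gcContent",
        "totalSenseRPM",
        "loopSize",
        "maxBulge",
        "tapd",
        "aapd",
        "ahc",
        "afh",
        "sameShift",
        "bothShift",
    ]
    + DINUCS
    + [
        "maxInteriorLoop",
        "intLoopSideDiff",
        "OPA",
        "duplexEnergy",
        "foldDupCmp",
        "dupPBP",
        "dupLoopLength",
        "APV",
        "wAPV",
        "ARV",
        "wARV",
        "mpLoopDistance",
        "dupLoopDistance",
        "totalOverlap",
        "totalRelativeOverlapAmount",
        "averageOverlapAmount",
        "innerLoopGapCount",
        "totalAntisenseRPM",
        "maxUnboundOverhang",
        "numOffshoots",
        "dupSize",
        "neighborCount",
        "RFProductAvg",
    ]
    + [label.replace("-", "") + "Frac" for label in PRODUCT_LABELS]
    + [_overlap_name(p) for p in OVERLAP_PAIRS]
)
assert len(HPRF_FEATURES) == 71

#: neighbor-count window around the precursor (nt)
NEIGHBOR_WINDOW = 1000
#: tolerance when matching a stack to the miR* duplex register (nt)
REGISTER_TOLERANCE = 2
#: reads whose 5' ends lie within this of a product's modal cut belong to it
CUT_TOLERANCE = 3


@dataclass
class Product:
    """A named cut product within a hairpin candidate."""

    label: str
    region: ReadRegion  # the cut-product stack (possibly a sub-stack)
    arm: str  # '5p' | '3p' | 'loop'
    is_major: bool = False
    local_span: tuple[int, int] = (0, 0)  # precursor-local coordinates
    parent: ReadRegion | None = None  # the enclosing maximal read region

    @property
    def dup_total(self) -> int:
        return self.region.dup_total


def split_cut_products(region: ReadRegion, tolerance: int = CUT_TOLERANCE):
    """Decompose a read region into cut products.

    Drosha/Dicer cuts are precise, so each real product is a group of reads
    sharing (nearly) one 5' end; a maximal read region can fuse several such
    products — miR with an abutting moR, or both arms bridged by loop
    fragments.  Groups are seeded greedily by the most abundant remaining
    read; reads with 5' ends within ``tolerance`` nt of the seed join it.
    Unlike maximal regions, the resulting product spans may overlap.
    """
    remaining = sorted(
        region.reads, key=lambda r: (-r.dup_count, r.start, r.end, r.seq)
    )
    out = []
    while remaining:
        seed = remaining[0]
        members = [
            r
            for r in remaining
            if abs(r.five_prime - seed.five_prime) <= tolerance
        ]
        member_ids = {id(r) for r in members}
        remaining = [r for r in remaining if id(r) not in member_ids]
        out.append(
            ReadRegion(
                region.chrom,
                region.strand,
                min(r.start for r in members),
                max(r.end for r in members),
                members,
            )
        )
    out.sort(key=lambda g: (g.start, g.end))
    return out


@dataclass
class Prediction:
    """A final scored precursor call with its mature products."""

    chrom: str
    strand: str
    start: int
    end: int
    hprf_score: float
    total_sense_rpm: float
    origin: str
    fold_structure: str
    mfe: float
    loop_span: tuple[int, int] | None  # precursor-local main loop
    mature_5p: str | None
    mature_3p: str | None
    products: list = field(default_factory=list)
    name: str = ""

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


# ---------------------------------------------------------------------------
# product naming


def _compute_candidate_duplex(candidate: HairpinCandidate, genome) -> None:
    """Duplex the major product's most frequent read against the precursor
    sequence with the product's own span masked (so the optimum is the
    partner arm, not the product pairing with itself)."""
    seq = candidate.local_seq(genome)
    lo, hi = candidate.major.major_read_span()
    mloc = candidate.to_local(lo, hi)
    masked = list(seq)
    for k in range(max(0, mloc[0]), min(len(seq), mloc[1])):
        masked[k] = "N"
    candidate.duplex = duplex(candidate.major.most_frequent_seq(), "".join(masked))


def name_products(
    candidate: HairpinCandidate, regions, register_tol: int = REGISTER_TOLERANCE
) -> list[Product]:
    """Name the cut products in a candidate after expected Drosha/Dicer
    products.

    Member read regions are first decomposed into cut products (see
    :func:`split_cut_products`).  The most abundant product is the major and
    is labeled miR on its arm; the product on the opposite arm overlapping
    the major's duplex register (+- tolerance) is the partner miR; products
    outside a miR on the same arm are moRs; products over the main loop are
    loop products; anything else is out-5p/out-3p/other.
    """
    parents = [
        g
        for g in regions
        if g.chrom == candidate.chrom
        and g.strand == candidate.strand
        and g.overlaps(candidate.start, candidate.end)
    ]
    members, parent_of = [], {}
    for g in parents:
        for sub in split_cut_products(g):
            members.append(sub)
            parent_of[id(sub)] = g
    if not members:
        return []
    n = len(candidate.fold)
    anatomy = parse_hairpin(
        candidate.fold, candidate.to_local(*candidate.major.major_read_span())
    )
    loop = anatomy.main_loop

    def arm_of(local_span: tuple[int, int]) -> str:
        center = (local_span[0] + local_span[1]) / 2
        if loop is not None:
            # a stack overlapping the loop with its center inside it is a
            # loop product; otherwise the center decides the arm
            if local_span[1] > loop[0] and local_span[0] < loop[1] and (
                loop[0] <= center < loop[1]
            ):
                return "loop"
            if center < (loop[0] + loop[1]) / 2:
                return "5p"
            return "3p"
        return "5p" if center < n / 2 else "3p"

    products: list[Product] = []
    major = max(members, key=lambda g: (g.dup_total, -g.start))
    major_local = candidate.to_local(major.start, major.end)
    major_arm = arm_of(major_local)
    if major_arm == "loop":  # degenerate: a loop-spanning major still anchors
        major_arm = "5p" if (major_local[0] + major_local[1]) / 2 < n / 2 else "3p"
    products.append(
        Product("miR-" + major_arm, major, major_arm, True, major_local,
                parent_of[id(major)])
    )

    register = candidate.duplex.target_span if candidate.duplex else None
    star_arm = "3p" if major_arm == "5p" else "5p"
    star = None
    if register is not None:
        opposite = [
            g
            for g in members
            if g is not major
            and arm_of(candidate.to_local(g.start, g.end)) == star_arm
        ]
        matching = [
            g
            for g in opposite
            if _loc_overlap(
                candidate.to_local(g.start, g.end),
                (register[0] - register_tol, register[1] + register_tol),
            )
            > 0
        ]
        if matching:
            star = max(matching, key=lambda g: (g.dup_total, -g.start))
            products.append(
                Product(
                    "miR-" + star_arm,
                    star,
                    star_arm,
                    False,
                    candidate.to_local(star.start, star.end),
                    parent_of[id(star)],
                )
            )

    mir_spans = {p.arm: p.local_span for p in products if p.label.startswith("miR")}
    for g in members:
        if g is major or g is star:
            continue
        local = candidate.to_local(g.start, g.end)
        arm = arm_of(local)
        if arm == "loop":
            products.append(
                Product("loop", g, "loop", False, local, parent_of[id(g)])
            )
            continue
        mir_span = mir_spans.get(arm)
        if arm == "5p":
            if mir_span is not None and local[0] < mir_span[0]:
                label = "moR-5p"
            elif mir_span is not None:
                label = "out-5p"
            else:
                label = "out-5p"
        else:
            if mir_span is not None and local[1] > mir_span[1]:
                label = "moR-3p"
            elif mir_span is not None:
                label = "out-3p"
            else:
                label = "out-3p"
        products.append(Product(label, g, arm, False, local, parent_of[id(g)]))
    candidate.products = products
    return products


def _loc_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


# ---------------------------------------------------------------------------
# feature blocks


def distribution_features(products, candidate, library, antisense_reads) -> dict:
    """Abundance/mapping features: unique-read fraction, hit counts, per-strand
    ARPM, per-label product fractions, and the most abundant overlapper."""
    sense_reads = [r for p in products for r in p.region.reads]
    locus_adj = adjusted_count(sense_reads)
    dup_total = sum(r.dup_count for r in sense_reads)
    major = next(p for p in products if p.is_major)

    uniq_dups = sum(r.dup_count for r in sense_reads if r.hit_count == 1)
    urf = uniq_dups / locus_adj if locus_adj else 0.0

    mj_reads = major.region.reads
    mj_dups = sum(r.dup_count for r in mj_reads)
    ahc = sum(r.dup_count * r.hit_count for r in mj_reads) / mj_dups

    anti = [
        r
        for r in antisense_reads
        if r.chrom == candidate.chrom
        and r.strand != candidate.strand
        and r.start < candidate.end
        and candidate.start < r.end
    ]
    feats = {
        "urf": urf,
        "ahc": ahc,
        "afh": five_prime_heterogeneity(major.region),
        "totalSenseRPM": arpm(locus_adj, library),
        "totalAntisenseRPM": arpm(adjusted_count(anti), library) if anti else 0.0,
    }
    # per-label dup-count fractions (8 classes); multiple stacks per label sum
    for label in PRODUCT_LABELS:
        w = sum(p.dup_total for p in products if p.label == label)
        feats[label.replace("-", "") + "Frac"] = w / dup_total if dup_total else 0.0
    # OPA: dup-count frequency of the most abundant product that overlaps
    # another product (0 when all products are disjoint)
    opa = 0.0
    for p in products:
        if any(
            q is not p and _loc_overlap(p.local_span, q.local_span) > 0
            for q in products
        ):
            opa = max(opa, p.dup_total / dup_total)
    feats["OPA"] = opa
    return feats


def overlap_shift_features(products, candidate, antisense_reads) -> dict:
    """Pairwise product overlaps, register shifts, and sense/antisense
    displacement summaries."""
    dup_total = sum(p.dup_total for p in products)
    # representative product per label = most abundant stack of that label
    rep: dict[str, Product] = {}
    for p in products:
        if p.label not in rep or p.dup_total > rep[p.label].dup_total:
            rep[p.label] = p

    feats = {}
    for pair in OVERLAP_PAIRS:
        a, b = rep.get(pair[0]), rep.get(pair[1])
        feats[_overlap_name(pair)] = (
            float(_loc_overlap(a.local_span, b.local_span)) if a and b else 0.0
        )

    total = rel = avg = 0.0
    for i, p in enumerate(products):
        for q in products[i + 1 :]:
            ov = _loc_overlap(p.local_span, q.local_span)
            if not ov:
                continue
            small, big = sorted((p.dup_total, q.dup_total))
            total += ov
            rel += ov * (small / big if big else 0.0)
            avg += ov * (small / dup_total if dup_total else 0.0)
    feats["totalOverlap"] = total
    feats["totalRelativeOverlapAmount"] = rel
    feats["averageOverlapAmount"] = avg

    # sameShift: largest |modal 5' offset| between overlapping same-arm stacks
    same = 0
    for i, p in enumerate(products):
        for q in products[i + 1 :]:
            if p.arm == q.arm and _loc_overlap(p.local_span, q.local_span):
                same = max(
                    same, abs(p.region.modal_start - q.region.modal_start)
                )
    feats["sameShift"] = float(same)

    # bothShift: deviation of opposite-arm stacks from the miR:miR* register
    both = 0
    register = candidate.duplex.target_span if candidate.duplex else None
    major = next(p for p in products if p.is_major)
    if register is not None:
        for p in products:
            if p.arm in ("5p", "3p") and p.arm != major.arm:
                both = max(both, abs(p.local_span[0] - register[0]))
    feats["bothShift"] = float(both)

    # tapd/aapd: displacement of antisense read stacks' 5' ends from the
    # nearest sense product 5' end (0 when no antisense reads)
    anti = [
        r
        for r in antisense_reads
        if r.chrom == candidate.chrom
        and r.strand != candidate.strand
        and r.start < candidate.end
        and candidate.start < r.end
    ]
    if anti:
        anti_regions = sio.group_read_regions(anti)
        sense_fps = [p.region.modal_start for p in products]
        disps = [
            min(abs(g.modal_start - fp) for fp in sense_fps) for g in anti_regions
        ]
        feats["tapd"] = float(sum(disps))
        feats["aapd"] = float(statistics.fmean(disps))
    else:
        feats["tapd"] = 0.0
        feats["aapd"] = 0.0
    return feats


def _pop_variance(values, weights=None) -> float:
    v = np.asarray(values, dtype=float)
    if len(v) == 0:
        return 0.0
    if weights is None:
        return float(np.var(v))
    w = np.asarray(weights, dtype=float)
    mean = np.average(v, weights=w)
    return float(np.average((v - mean) ** 2, weights=w))


def variance_features(products) -> dict:
    """Read-count and start-position variances per product, plain and weighted.

    Population variance throughout.  APV averages, over products, the
    variance of dup-counts across a product's distinct reads; ARV the
    dup-weighted variance of 5' start positions.  wAPV weights products by
    read abundance, wARV by product length.
    """
    locus_dups = sum(p.dup_total for p in products)
    count_vars, start_vars, abunds, lengths = [], [], [], []
    for p in products:
        counts = list(p.region.distinct_seqs().values())
        count_vars.append(_pop_variance(counts))
        starts = [r.five_prime for r in p.region.reads]
        weights = [r.dup_count for r in p.region.reads]
        start_vars.append(_pop_variance(starts, weights))
        abunds.append(p.dup_total)
        lengths.append(p.local_span[1] - p.local_span[0])
    apv = statistics.fmean(count_vars)
    arv = statistics.fmean(start_vars)
    wapv = (
        sum(v * a for v, a in zip(count_vars, abunds)) / locus_dups
        if locus_dups
        else 0.0
    )
    total_len = sum(lengths)
    warv = (
        sum(v * ln for v, ln in zip(start_vars, lengths)) / total_len
        if total_len
        else 0.0
    )
    return {"APV": apv, "wAPV": wapv, "ARV": arv, "wARV": warv}


def neighbor_count(
    candidate, all_regions, window: int = NEIGHBOR_WINDOW
) -> int:
    """Distinct read loci (any strand) within ``window`` nt of the candidate
    span, excluding loci overlapping the candidate itself."""
    n = 0
    for g in all_regions:
        if g.chrom != candidate.chrom:
            continue
        if g.overlaps(candidate.start, candidate.end) and g.strand == candidate.strand:
            continue
        if g.start < candidate.end and candidate.start < g.end:
            continue  # inside/overlapping on either strand: not a neighbor
        gap = max(g.start - candidate.end, candidate.start - g.end)
        if gap <= window:
            n += 1
    return n


def hairpin_feature_vector(
    candidate: HairpinCandidate,
    products,
    library: SampleLibrary,
    mprf_scores: dict,
    all_regions,
    antisense_reads,
    genome,
) -> np.ndarray:
    """All 71 HPRF features in :data:`HPRF_FEATURES` order.

    ``mprf_scores`` maps id(region) -> MPRF decision value; RFProductAvg is
    the mean over the candidate's scored products.
    """
    seq = candidate.local_seq(genome)
    if candidate.duplex is None:
        _compute_candidate_duplex(candidate, genome)
    major = next(p for p in products if p.is_major)
    anatomy = parse_hairpin(candidate.fold, major.local_span)
    star = candidate.duplex.target_span if candidate.duplex else None
    feats: dict[str, float] = {
        "mfe": candidate.fold.mfe,
        "gcContent": gc_content(seq),
        "duplexEnergy": candidate.duplex.energy if candidate.duplex else 0.0,
        "foldDupCmp": fold_duplex_agreement(
            candidate.fold, candidate.duplex, (0, len(seq)), major.local_span
        ),
        "neighborCount": float(neighbor_count(candidate, all_regions)),
    }
    feats.update(dinucleotide_frequencies(seq))
    feats.update(structural_features(anatomy, candidate.fold, major.local_span, star))
    feats.update(distribution_features(products, candidate, library, antisense_reads))
    feats.update(overlap_shift_features(products, candidate, antisense_reads))
    feats.update(variance_features(products))
    scored = [
        mprf_scores[key]
        for p in products
        for key in (id(p.parent if p.parent is not None else p.region),)
        if key in mprf_scores
    ]
    feats["RFProductAvg"] = float(statistics.fmean(scored)) if scored else 0.0
    vec = np.array([feats[name] for name in HPRF_FEATURES], dtype=float)
    if not np.all(np.isfinite(vec)):
        bad = [HPRF_FEATURES[i] for i in np.where(~np.isfinite(vec))[0]]
        raise ValueError(f"non-finite hairpin features: {bad}")
    return vec


# ---------------------------------------------------------------------------
# training / prediction


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    ov = _loc_overlap(a, b)
    if not ov:
        return 0.0
    return min(ov / (a[1] - a[0]), ov / (b[1] - b[0]))


def build_hprf_training_set(
    candidates, vectors, annotations, ratio_x: int = 25, seed: int = 0
):
    """Labeled HPRF vectors.

    Positives: for each annotated precursor, the same-strand candidate with
    the greatest reciprocal overlap.  Negatives: candidates overlapping no
    annotation on either strand, sampled at 1:X (all if fewer exist).
    """
    precursors = [a for a in annotations if a.kind == "precursor"]
    pos_idx: set[int] = set()
    for ann in precursors:
        best, best_ro = None, 0.0
        for i, c in enumerate(candidates):
            if c.chrom != ann.chrom or c.strand != ann.strand:
                continue
            ro = _reciprocal_overlap(c.span, (ann.start, ann.end))
            if ro > best_ro:
                best, best_ro = i, ro
        if best is not None:
            pos_idx.add(best)
    if not pos_idx:
        raise ValueError("no candidate overlaps an annotated precursor")
    neg_pool = [
        i
        for i, c in enumerate(candidates)
        if i not in pos_idx
        and not any(
            a.chrom == c.chrom and a.overlaps(c.start, c.end) for a in annotations
        )
    ]
    rng = np.random.default_rng(seed)
    n_neg = min(ratio_x * len(pos_idx), len(neg_pool))
    chosen = (
        sorted(rng.choice(len(neg_pool), size=n_neg, replace=False))
        if n_neg
        else []
    )
    neg_idx = [neg_pool[i] for i in chosen]
    order = sorted(pos_idx) + neg_idx
    X = np.array([vectors[i] for i in order])
    y = np.array([1] * len(pos_idx) + [0] * len(neg_idx))
    return X, y, order


def train_hprf(X, y, seed: int = 0, n_trees: int = 500) -> ForestModel:
    from sklearn.ensemble import RandomForestClassifier

    forest = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1
    )
    forest.fit(X, y)
    return ForestModel(
        forest,
        list(HPRF_FEATURES),
        metadata={"layer": "HPRF", "seed": seed, "n_trees": n_trees},
    )


def predict(
    model: ForestModel,
    candidates,
    vectors,
    library: SampleLibrary,
    y_threshold: float = 0.28,
    expression_threshold: float = 0.11,
) -> list[Prediction]:
    """Final predictions: score >= y_threshold AND locus sense ARPM >=
    expression_threshold, then greedy overlap resolution.  There is no read
    count floor: a single-read locus passing both thresholds is kept."""
    scores = model.score(np.asarray(vectors), feature_names=list(HPRF_FEATURES))
    rpm_idx = HPRF_FEATURES.index("totalSenseRPM")
    passing = []
    for cand, vec, s in zip(candidates, vectors, scores):
        cand.hprf_score = float(s)
        if s >= y_threshold and vec[rpm_idx] >= expression_threshold:
            passing.append(cand)
    kept = resolve_overlapping_hairpins(passing)
    out = []
    for i, cand in enumerate(kept):
        anatomy = parse_hairpin(
            cand.fold, cand.to_local(cand.major.start, cand.major.end)
        )
        matures = {"5p": None, "3p": None}
        for p in cand.products:
            if p.label.startswith("miR"):
                matures[p.arm] = p.region.most_frequent_seq()
        out.append(
            Prediction(
                chrom=cand.chrom,
                strand=cand.strand,
                start=cand.start,
                end=cand.end,
                hprf_score=cand.hprf_score,
                total_sense_rpm=float(
                    arpm(
                        adjusted_count(
                            [r for p in cand.products for r in p.region.reads]
                        ),
                        library,
                    )
                ),
                origin=cand.origin,
                fold_structure=cand.fold.structure,
                mfe=cand.fold.mfe,
                loop_span=anatomy.main_loop,
                mature_5p=matures["5p"],
                mature_3p=matures["3p"],
                products=cand.products,
                name=f"Novel-{i + 1}",
            )
        )
    return out


def write_predictions_gff3(predictions, path) -> None:
    """Final calls as miRBase-dialect GFF3 (precursor + mature children)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for pred in predictions:
            fh.write(
                f"{pred.chrom}\tmirstack\tmiRNA_primary_transcript\t"
                f"{pred.start + 1}\t{pred.end}\t{pred.hprf_score:.3f}\t"
                f"{pred.strand}\t.\tID={pred.name};Name={pred.name}\n"
            )
            for p in pred.products:
                if not p.label.startswith("miR"):
                    continue
                fh.write(
                    f"{pred.chrom}\tmirstack\tmiRNA\t{p.region.start + 1}\t"
                    f"{p.region.end}\t.\t{pred.strand}\t.\t"
                    f"ID={pred.name}-{p.arm};Name={pred.name}-{p.arm};"
                    f"Derives_from={pred.name}\n"
                )
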