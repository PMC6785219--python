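"""First classifier layer: mature-product features and random forest (MPRF).

Every read region — including single-read regions, which are never
pre-filtered by abundance — is summarized as a 36-feature vector describing
its sequence (GC, dinucleotides, Wootton-Federhen complexity), its read
geometry (5'-heterogeneity, the +-7 nt offset profile of 5' ends around the
modal start, median read length) and the minimum duplex energy between the
stack's most frequent read sequence and the surrounding genomic region.
The duplex-energy feature is the discriminative heart of the layer: a true
mature product has a near-complementary partner arm within ~70 nt, an
arbitrary degradation stack does not.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .folding import duplex
from .io import AlignedRead, ReadRegion, fetch_seq, revcomp

DINUCS = [a + b for a in "acgt" for b in "acgt"]

#: fixed feature order shared by training and scoring
MPRF_FEATURES: list[str] = (
    ["fivePrimeHet", "medianLength", "gcContent"]
    + DINUCS
    + [f"r{k}" for k in range(7, 0, -1)]
    + ["s0"]
    + [f"f{k}" for k in range(1, 8)]
    + ["wfc", "duplexEnergy"]
)

#: duplex search window on each side of the product (nt)
DUPLEX_WINDOW = 70


def wootton_federhen_complexity(seq: str) -> float:
    """Wootton-Federhen local compositional complexity in [0, 1].

    (1/N) * log_4( N! / prod_i n_i! ) over A/C/G/T counts; 0 for
    homopolymers, approaching 1 for maximally mixed composition.  Non-ACGT
    symbols are excluded from the counts.
    """
    counts = Counter(c for c in seq.upper().replace("U", "T") if c in "ACGT")
    n = sum(counts.values())
    if n == 0:
        return 0.0
    log_multinom = math.lgamma(n + 1) - sum(
        math.lgamma(c + 1) for c in counts.values()
    )
    return log_multinom / (n * math.log(4))


def gc_content(seq: str) -> float:
    s = seq.upper().replace("U", "T")
    acgt = sum(s.count(c) for c in "ACGT")
    if acgt == 0:
        return 0.0
    return (s.count("G") + s.count("C")) / acgt


def dinucleotide_frequencies(seq: str) -> dict[str, float]:
    """Overlapping dinucleotide frequencies; ambiguous pairs are dropped from
    both numerator and denominator."""
    s = seq.upper().replace("U", "T")
    counts = Counter(
        s[i : i + 2] for i in range(len(s) - 1) if set(s[i : i + 2]) <= set("ACGT")
    )
    total = sum(counts.values())
    return {
        d: (counts[d.upper()] / total if total else 0.0) for d in DINUCS
    }


def five_prime_heterogeneity(region: ReadRegion) -> float:
    """1 - (dup-weighted fraction of reads starting at the modal 5' position)."""
    total = region.dup_total
    modal = region.modal_start
    at_modal = sum(r.dup_count for r in region.reads if r.five_prime == modal)
    return 1.0 - at_modal / total


def read_offset_profile(region: ReadRegion) -> dict[str, float]:
    """Dup-weighted fraction of 5' ends at each offset in -7..+7 from the modal
    start, strand-aware (f1 is one position downstream in the 5'->3' sense)."""
    total = region.dup_total
    modal = region.modal_start
    sign = 1 if region.strand == "+" else -1
    tally: Counter = Counter()
    for r in region.reads:
        d = sign * (r.five_prime - modal)
        tally[d] += r.dup_count
    out = {}
    for k in range(7, 0, -1):
        out[f"r{k}"] = tally[-k] / total
    out["s0"] = tally[0] / total
    for k in range(1, 8):
        out[f"f{k}"] = tally[k] / total
    return out


def weighted_median(values, weights) -> float:
    order = np.argsort(values, kind="stable")
    v = np.asarray(values, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    cum = np.cumsum(w)
    half = cum[-1] / 2.0
    idx = int(np.searchsorted(cum, half))
    if cum[idx] == half and idx + 1 < len(v):
        return (v[idx] + v[idx + 1]) / 2.0
    return float(v[idx])


def _flanks(region: ReadRegion, genome, window: int = DUPLEX_WINDOW):
    """Strand-aware (upstream, downstream) flank sequences surrounding the
    region's most abundant read, each up to ``window`` nt, in read
    orientation.  The window is anchored on the major read's span rather
    than the whole region so that a stack broadened by bridging fragments
    still searches the sequence next to its defining product."""
    lo, hi = region.major_read_span()
    left = fetch_seq(genome, region.chrom, lo - window, lo)
    right = fetch_seq(genome, region.chrom, hi, hi + window)
    if region.strand == "+":
        return left, right
    return revcomp(right), revcomp(left)


def stack_duplex_energy(region: ReadRegion, genome, window: int = DUPLEX_WINDOW) -> float:
    """Minimum duplex energy of the most frequent read sequence against either
    70 nt flank (kcal/mol; 0.0 when no flank supports a stabilizing duplex)."""
    query = region.most_frequent_seq()
    best = 0.0
    for flank in _flanks(region, genome, window):
        if len(flank) < 10:
            continue
        d = duplex(query, flank)
        if d is not None and d.energy < best:
            best = d.energy
    return best


def mature_feature_vector(region: ReadRegion, genome) -> np.ndarray:
    """The 36 MPRF features, in :data:`MPRF_FEATURES` order.

    Sequence features are computed on the region's most frequent read
    sequence; the median length is dup-count weighted.
    """
    seq = region.most_frequent_seq()
    feats = {
        "fivePrimeHet": five_prime_heterogeneity(region),
        "medianLength": weighted_median(
            [len(r.seq) for r in region.reads],
            [r.dup_count for r in region.reads],
        ),
        "gcContent": gc_content(seq),
        "wfc": wootton_federhen_complexity(seq),
        "duplexEnergy": stack_duplex_energy(region, genome),
    }
    feats.update(dinucleotide_frequencies(seq))
    feats.update(read_offset_profile(region))
    return np.array([feats[name] for name in MPRF_FEATURES], dtype=float)


# ---------------------------------------------------------------------------
# training / scoring


@dataclass
class ForestModel:
    """A trained forest plus the feature-order manifest it was fit with."""

    forest: RandomForestClassifier
    feature_names: list[str]
    metadata: dict = field(default_factory=dict)

    def score(self, X: np.ndarray, feature_names: list[str] | None = None) -> np.ndarray:
        """Positive-class vote fraction for each row (decision values)."""
        if feature_names is not None and list(feature_names) != self.feature_names:
            raise ValueError("feature order mismatch between model and vectors")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        proba = self.forest.predict_proba(X)
        pos_col = list(self.forest.classes_).index(1)
        return proba[:, pos_col]

    def save(self, path) -> None:
        joblib.dump(
            {
                "forest": self.forest,
                "feature_names": self.feature_names,
                "metadata": self.metadata,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "ForestModel":
        blob = joblib.load(path)
        return cls(blob["forest"], blob["feature_names"], blob.get("metadata", {}))


def _region_overlaps_any(region: ReadRegion, annotations, kinds, same_strand: bool):
    for ann in annotations:
        if kinds is not None and ann.kind not in kinds:
            continue
        if ann.chrom != region.chrom:
            continue
        if same_strand and ann.strand != region.strand:
            continue
        if ann.overlaps(region.start, region.end):
            return True
    return False


def build_mprf_training_set(
    regions, annotations, genome, ratio_x: int = 1, seed: int = 0
):
    """Labeled MPRF vectors: positives overlap an annotated mature on the same
    strand; negatives overlap no annotation on either strand, stratified-
    sampled at ratio 1:X (all available if fewer exist).
    """
    positives, candidates = [], []
    for g in regions:
        if _region_overlaps_any(g, annotations, {"mature"}, same_strand=True):
            positives.append(g)
        elif not _region_overlaps_any(g, annotations, None, same_strand=False):
            candidates.append(g)
    if not positives:
        raise ValueError("no positive training regions overlap annotated matures")
    rng = np.random.default_rng(seed)
    n_neg = min(ratio_x * len(positives), len(candidates))
    idx = rng.choice(len(candidates), size=n_neg, replace=False) if n_neg else []
    negatives = [candidates[i] for i in sorted(idx)]
    X = np.array(
        [mature_feature_vector(g, genome) for g in positives + negatives]
    )
    y = np.array([1] * len(positives) + [0] * len(negatives))
    return X, y, positives + negatives


def train_mprf(
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    n_trees: int = 500,
) -> ForestModel:
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return ForestModel(
        forest,
        list(MPRF_FEATURES),
        metadata={"layer": "MPRF", "seed": seed, "n_trees": n_trees},
    )


def score_read_regions(model: ForestModel, vectors: np.ndarray) -> np.ndarray:
    """Decision values (positive vote fraction) for precomputed MPRF vectors."""
    return model.score(vectors, feature_names=list(MPRF_FEATURES))
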