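"""Post-processing of predictions: homology, genomic clusters, novel families.

Homology calls use a local-alignment search of each predicted mature against
a database of known matures.  The built-in engine is a deterministic
Smith-Waterman (blastn-like scoring 2/-3, gap 5/2) with a Karlin-Altschul
E-value; any engine with the same call signature can be plugged in (e.g. a
BLAST wrapper) and the engine identity is recorded on every call.  A hit is
a *homolog* only if its seed (mature positions 2-8) matches exactly and
E < 0.05.  Novel-family search relaxes E to <= 0.5 but additionally requires
the same arm, and excludes hits antisense to the query's own locus and
identical mature sequences (repeat-region guards).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio import Align, SeqIO

# Karlin-Altschul parameters for match +2 / mismatch -3, gap open 5 extend 2
_KA_LAMBDA = 0.625
_KA_K = 0.41

SEED_START, SEED_END = 1, 8  # python slice of mature positions 2-8 (1-based)

CLUSTER_DISTANCE = 10_000  # nt, inclusive


def seed_of(mature: str) -> str:
    return mature.upper().replace("T", "U")[SEED_START:SEED_END]


@dataclass
class Hit:
    name: str
    seq: str
    score: float
    e_value: float


@dataclass
class HomologyCall:
    query: str
    best_hit: str | None
    e_value: float
    seed_match: bool
    verdict: str  # 'known' | 'homolog' | 'novel'
    engine: str = "smith-waterman"


class SmithWatermanEngine:
    """Deterministic local aligner with an approximate Karlin-Altschul E-value."""

    name = "smith-waterman"

    def __init__(self):
        self.aligner = Align.PairwiseAligner(
            mode="local",
            match_score=2,
            mismatch_score=-3,
            open_gap_score=-5,
            extend_gap_score=-2,
        )

    def search(self, query: str, database: list[tuple[str, str]]) -> list[Hit]:
        q = query.upper().replace("T", "U")
        total_db = sum(len(s) for _, s in database)
        hits = []
        for name, seq in database:
            s = seq.upper().replace("T", "U")
            score = float(self.aligner.score(q, s))
            e = _KA_K * len(q) * total_db * math.exp(-_KA_LAMBDA * score)
            hits.append(Hit(name=name, seq=s, score=score, e_value=e))
        hits.sort(key=lambda h: (h.e_value, h.name))
        return hits


def load_mature_fasta(path) -> list[tuple[str, str]]:
    """(name, sequence) pairs from a miRBase-style mature FASTA (U tolerated)."""
    return [
        (rec.id, str(rec.seq).upper().replace("T", "U"))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def assign_homology(
    mature_seq: str, known_matures, engine: SmithWatermanEngine | None = None
) -> HomologyCall:
    """Classify a predicted mature as known / homolog / novel.

    known: identical sequence in the database.  homolog: best hit with an
    identical seed (positions 2-8) and E < 0.05.  Otherwise novel.  An empty
    database yields novel.
    """
    engine = engine or SmithWatermanEngine()
    if isinstance(known_matures, (str,)) or hasattr(known_matures, "read"):
        known_matures = load_mature_fasta(known_matures)
    q = mature_seq.upper().replace("T", "U")
    if not known_matures:
        import warnings

        warnings.warn("empty known-mature database; everything is novel")
        return HomologyCall(q, None, math.inf, False, "novel", engine.name)
    for name, seq in known_matures:
        if seq == q:
            return HomologyCall(q, name, 0.0, True, "known", engine.name)
    hits = engine.search(q, known_matures)
    best = hits[0]
    seed_match = seed_of(best.seq) == seed_of(q)
    verdict = "homolog" if (seed_match and best.e_value < 0.05) else "novel"
    return HomologyCall(q, best.name, best.e_value, seed_match, verdict, engine.name)


# ---------------------------------------------------------------------------
# clusters


@dataclass
class Cluster:
    id: int
    members: list = field(default_factory=list)  # (name, chrom, start, end, is_annotated)
    source: str = "novel"  # 'annotated' | 'novel'


def _chain(loci, distance):
    """Single-linkage chains of loci whose span edges are <= distance apart
    (inclusive), per chromosome.  Loci are (name, chrom, start, end, flag)."""
    chains = []
    for locus in sorted(loci, key=lambda t: (t[1], t[2], t[3], t[0])):
        if (
            chains
            and chains[-1][-1][1] == locus[1]
            and locus[2] - max(m[3] for m in chains[-1]) <= distance
        ):
            chains[-1].append(locus)
        else:
            chains.append([locus])
    return chains


def identify_clusters(
    annotated_loci, novel_loci, distance: int = CLUSTER_DISTANCE
) -> list[Cluster]:
    """Genomic clusters of precursors within ``distance`` nt, annotated-first.

    Annotated loci are chained first; a chain of >= 2 annotated members fixes
    the cluster source as 'annotated'.  Novel loci then join existing chains
    or form new ones.  Singletons are not clusters.  Loci are
    (name, chrom, start, end) tuples.
    """
    ann = [(n, c, s, e, True) for (n, c, s, e) in annotated_loci]
    nov = [(n, c, s, e, False) for (n, c, s, e) in novel_loci]
    ann_chains = _chain(ann, distance)
    # the annotated/novel source label is decided before novels join
    sourced = [(ch, len(ch) >= 2) for ch in ann_chains]
    combined = _chain(ann + nov, distance)

    clusters = []
    for ch in combined:
        if len(ch) < 2:
            continue
        members = set((m[0], m[1], m[2], m[3]) for m in ch)
        # the cluster is annotated-sourced iff it contains an annotated-only
        # chain of >= 2 members
        source = "novel"
        for ann_ch, is_src in sourced:
            if is_src and all(
                (m[0], m[1], m[2], m[3]) in members for m in ann_ch
            ):
                source = "annotated"
                break
        clusters.append(
            Cluster(id=len(clusters) + 1, members=sorted(members), source=source)
        )
    return clusters


# ---------------------------------------------------------------------------
# novel families


@dataclass
class NovelMature:
    """A novel predicted mature with the locus context the family rules need."""

    name: str
    seq: str
    arm: str  # '5p' | '3p'
    chrom: str
    start: int
    end: int
    strand: str


def identify_novel_families(
    novel_matures: list[NovelMature],
    database: list[tuple[str, str, str]],  # (name, seq, arm)
    locus_of: dict[str, tuple[str, int, int, str]] | None = None,
    engine: SmithWatermanEngine | None = None,
) -> list[dict]:
    """Candidate families: a novel mature plus hits with a perfect seed match,
    the same arm, and E <= 0.5; excluding hits antisense to the query's own
    locus and hits with an identical mature sequence.

    ``locus_of`` maps database names to (chrom, start, end, strand) for the
    antisense-to-self exclusion; entries without coordinates skip that check.
    """
    engine = engine or SmithWatermanEngine()
    families = []
    seen = set()
    for q in novel_matures:
        db_pairs = [(n, s) for n, s, _ in database if n != q.name]
        if not db_pairs:
            continue
        arms = {n: a for n, s, a in database}
        hits = engine.search(q.seq, db_pairs)
        members = []
        for h in hits:
            if h.e_value > 0.5:
                break  # sorted by E-value
            if seed_of(h.seq) != seed_of(q.seq):
                continue
            if arms.get(h.name) != q.arm:
                continue
            if h.seq == q.seq.upper().replace("T", "U"):
                continue  # identical matures: repeat-region guard
            if locus_of and h.name in locus_of:
                c, s, e, st = locus_of[h.name]
                if (
                    c == q.chrom
                    and s < q.end
                    and q.start < e
                    and st != q.strand
                ):
                    continue  # antisense to the query's own locus
            members.append(h.name)
        if members:
            key = frozenset([q.name, *members])
            if key not in seen:
                seen.add(key)
                families.append({"query": q.name, "members": members})
    return families
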