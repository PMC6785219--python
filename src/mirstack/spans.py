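"""Candidate hairpin precursor spans for each MPRF-passing product.

Two span-generation strategies co-exist and compete only through the
downstream hairpin classifier:

* *duplex-focused*: the optimal RNA:RNA duplex between the product's most
  frequent read and each 70 nt flank locates the partner arm; the span runs
  from product to duplexed subsequence.  This sidesteps the sensitive
  dependence of whole-window secondary structure on the chosen window.
* *product-focused*: the span between the product and any other passing
  product >= 5 nt away.

Overlapping scored candidates are resolved greedily by decision value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .folding import DotBracket, DuplexResult, duplex, fold
from .io import ReadRegion, fetch_seq, revcomp
from .mature import DUPLEX_WINDOW, _flanks

#: extension beyond product/duplex boundaries before folding (nt each side)
DEFAULT_PAD = 5
#: candidate spans larger than this are rejected (precursors are ~70 nt)
MAX_SPAN = 250
#: minimum gap between products for a product-focused span (nt)
MIN_PRODUCT_GAP = 5


@dataclass
class HairpinCandidate:
    """A putative precursor span with its fold and provenance."""

    chrom: str
    strand: str
    start: int
    end: int
    origin: str  # 'duplex_focused' | 'product_focused'
    fold: DotBracket
    major: ReadRegion
    duplex: DuplexResult | None = None  # in precursor-local coordinates
    hprf_score: float | None = None
    products: list = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def __len__(self) -> int:
        return self.end - self.start

    def to_local(self, start: int, end: int) -> tuple[int, int]:
        """Map a genomic interval into precursor-local (5'->3') coordinates."""
        if self.strand == "+":
            return (start - self.start, end - self.start)
        return (self.end - end, self.end - start)

    def local_seq(self, genome) -> str:
        s = fetch_seq(genome, self.chrom, self.start, self.end)
        return s if self.strand == "+" else revcomp(s)

    def overlaps(self, other: "HairpinCandidate") -> bool:
        return (
            self.chrom == other.chrom
            and self.strand == other.strand
            and self.start < other.end
            and other.start < self.end
        )


def _build_candidate(
    major: ReadRegion, genome, start: int, end: int, origin: str,
    pad: int, max_span: int,
) -> HairpinCandidate | None:
    start = max(0, start - pad)
    end = min(len(genome[major.chrom]), end + pad)
    if end - start > max_span or end - start < 10:
        return None
    seq = fetch_seq(genome, major.chrom, start, end)
    if major.strand == "-":
        seq = revcomp(seq)
    return HairpinCandidate(
        chrom=major.chrom,
        strand=major.strand,
        start=start,
        end=end,
        origin=origin,
        fold=fold(seq),
        major=major,
    )


def duplex_focused_span(
    major: ReadRegion,
    genome,
    window: int = DUPLEX_WINDOW,
    pad: int = DEFAULT_PAD,
    max_span: int = MAX_SPAN,
) -> HairpinCandidate | None:
    """Span from the product to its optimal duplex partner in either flank.

    The most frequent read is duplexed against the upstream and downstream
    70 nt flanks (product span excluded); the lower-energy side wins and its
    duplexed target interval, mapped back to the genome, bounds the candidate
    together with the product span.  Returns None when neither flank yields a
    stabilizing duplex.
    """
    query = major.most_frequent_seq()
    lo, hi = major.major_read_span()
    up, down = _flanks(major, genome, window)
    best = None  # (energy, genomic target span)
    for side, flank in (("up", up), ("down", down)):
        if len(flank) < 10:
            continue
        d = duplex(query, flank)
        if d is None:
            continue
        t0, t1 = d.target_span
        # map flank-local (read-orientation) coords to genomic; the flanks
        # surround the major read's span [lo, hi)
        if major.strand == "+":
            if side == "up":
                g = (lo - len(flank) + t0, lo - len(flank) + t1)
            else:
                g = (hi + t0, hi + t1)
        else:
            if side == "up":  # genomically right of the major read, revcomp'd
                g = (hi + len(flank) - t1, hi + len(flank) - t0)
            else:  # genomically left
                g = (lo - t1, lo - t0)
        if best is None or d.energy < best[0]:
            best = (d.energy, g)
    if best is None:
        return None
    tgt = best[1]
    return _build_candidate(
        major,
        genome,
        min(lo, tgt[0]),
        max(hi, tgt[1]),
        "duplex_focused",
        pad,
        max_span,
    )


def product_focused_spans(
    major: ReadRegion,
    others,
    genome,
    min_gap: int = MIN_PRODUCT_GAP,
    pad: int = DEFAULT_PAD,
    max_span: int = MAX_SPAN,
) -> list[HairpinCandidate]:
    """Candidate spans between the major product and each other product
    separated by at least ``min_gap`` nt (same chrom and strand)."""
    out = []
    for other in others:
        if other is major:
            continue
        if other.chrom != major.chrom or other.strand != major.strand:
            continue
        gap = max(other.start - major.end, major.start - other.end)
        if gap < min_gap:
            continue
        cand = _build_candidate(
            major,
            genome,
            min(major.start, other.start),
            max(major.end, other.end),
            "product_focused",
            pad,
            max_span,
        )
        if cand is not None:
            out.append(cand)
    return out


def resolve_overlapping_hairpins(candidates) -> list[HairpinCandidate]:
    """Greedy non-overlap resolution by descending decision value.

    Ties break toward duplex-focused origin (the duplex span localizes the
    partner arm and orients the fold more reliably than a product-pair
    window), then toward the smaller genomic start.  Kept candidates are
    pairwise non-overlapping per chrom+strand.
    """
    scored = [c for c in candidates if c.hprf_score is not None]
    if len(scored) != len(list(candidates)):
        raise ValueError("all candidates must be HPRF-scored before resolution")
    kept: list[HairpinCandidate] = []
    for cand in sorted(
        scored,
        key=lambda c: (-c.hprf_score, c.origin != "duplex_focused", c.start),
    ):
        if not any(cand.overlaps(k) for k in kept):
            kept.append(cand)
    kept.sort(key=lambda c: (c.chrom, c.start))
    return kept
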