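"""Small RNA-seq I/O: alignments, read regions, annotations, ARPM normalization.

All internal coordinates are 0-based, half-open intervals on the forward
genomic strand.  SAM/BAM (1-based via pysam's 0-based API) and GFF3 (1-based,
closed) are converted at the boundary.  Read sequences are stored in *read*
orientation: for a minus-strand alignment the reference-oriented SAM SEQ is
reverse-complemented back.

Multi-mapping is handled by fractional counting, never by filtering: a read
aligned to ``n_r`` genomic loci contributes ``dup_count / n_r`` to each locus
(its *adjusted count*), and per-sample totals of adjusted counts define the
adjusted-reads-per-million (ARPM) normalization::

    ARPM(L) = 1e6 * (sum_{r in L} dup_r / n_r) / (sum_{r in S} dup_r / n_r)

When every read is unique (n_r == 1 everywhere) ARPM reduces to plain
reads-per-million.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace

import pysam

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")

# collapsed-FASTA convention: read names like "seq1234_x57" carry the number
# of identical raw reads collapsed into one record
_DUP_RE = re.compile(r"_x(\d+)$")


def revcomp(seq: str) -> str:
    """Reverse complement (DNA alphabet; U treated as T's complement source)."""
    return seq.translate(_COMPLEMENT)[::-1]


def fetch_seq(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome[chrom][start:end) uppercased, clamped at contig ends.

    ``genome`` may be a plain ``{chrom: sequence}`` mapping or a
    ``pyfaidx.Fasta`` handle; both support ``len`` and slicing.
    """
    n = len(genome[chrom])
    start = max(0, start)
    end = min(n, end)
    if end <= start:
        return ""
    return str(genome[chrom][start:end]).upper()


@dataclass
class AlignedRead:
    """One genome-mapped small RNA read (possibly a collapsed duplicate set)."""

    read_id: str
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str  # '+' or '-'
    seq: str  # read orientation
    dup_count: int = 1
    hit_count: int | None = None  # n_r: alignments of this read in the genome

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"empty interval for read {self.read_id}")
        if len(self.seq) != self.end - self.start:
            raise ValueError(
                f"read {self.read_id}: seq length {len(self.seq)} != span "
                f"{self.end - self.start}"
            )
        if self.dup_count < 1:
            raise ValueError("dup_count must be >= 1")

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the 5' end (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def adjusted(self) -> float:
        if self.hit_count is None:
            raise ValueError(f"read {self.read_id} has no hit_count")
        return self.dup_count / self.hit_count


@dataclass
class ReadRegion:
    """A read stack: maximal set of overlapping same-strand reads."""

    chrom: str
    strand: str
    start: int
    end: int
    reads: list = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def dup_total(self) -> int:
        return sum(r.dup_count for r in self.reads)

    def distinct_seqs(self) -> dict[str, int]:
        """Map read sequence -> summed dup_count."""
        out: Counter = Counter()
        for r in self.reads:
            out[r.seq] += r.dup_count
        return dict(out)

    def most_frequent_seq(self) -> str:
        """Most abundant read sequence (ties: lexicographically first)."""
        seqs = self.distinct_seqs()
        return max(sorted(seqs), key=lambda s: seqs[s])

    def major_read_span(self) -> tuple[int, int]:
        """Genomic span of the most abundant distinct read.

        A region can be broader than its defining product (e.g. when loop
        fragments bridge the two arms of a hairpin into one stack); duplex
        windows are anchored on this span, not the full region span.
        """
        tally: Counter = Counter()
        for r in self.reads:
            tally[(r.start, r.end, r.seq)] += r.dup_count
        start, end, _ = min(tally, key=lambda k: (-tally[k], k))
        return (start, end)

    @property
    def modal_start(self) -> int:
        """Most frequent 5' position, dup-count weighted.

        Ties are broken toward the smaller genomic coordinate so the value is
        deterministic regardless of read order.
        """
        tally: Counter = Counter()
        for r in self.reads:
            tally[r.five_prime] += r.dup_count
        return min(tally, key=lambda p: (-tally[p], p))

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass
class AnnotationRecord:
    """A miRBase-style annotation: hairpin precursor or mature product."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str
    kind: str  # 'precursor' | 'mature'
    arm: str = "unknown"  # '5p' | '3p' | 'unknown'
    parent: str | None = None

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class SampleLibrary:
    """Per-sample normalization constant: total adjusted read count."""

    sample_id: str
    total_adjusted_reads: float

    @classmethod
    def from_reads(cls, reads, sample_id: str = "sample") -> "SampleLibrary":
        return cls(sample_id, adjusted_count(reads))


# ---------------------------------------------------------------------------
# alignment loading


def load_alignments(path, min_mapq: int = 0) -> list[AlignedRead]:
    """Load mapped records from a SAM/BAM file as :class:`AlignedRead`.

    Unmapped records are skipped.  ``dup_count`` is recovered from the
    collapsed-read naming convention ``*_x<count>`` when present, else 1.
    A pre-existing NH tag is stored as ``hit_count``; use
    :func:`annotate_hit_counts` to (re)compute it from read-id multiplicity.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    reads: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for i, rec in enumerate(fh):
            if rec.is_unmapped:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            seq = rec.query_sequence
            if seq is None or rec.reference_name is None:
                raise ValueError(f"malformed alignment record at index {i}")
            strand = "-" if rec.is_reverse else "+"
            if strand == "-":
                seq = revcomp(seq)
            m = _DUP_RE.search(rec.query_name)
            dup = int(m.group(1)) if m else 1
            nh = rec.get_tag("NH") if rec.has_tag("NH") else None
            reads.append(
                AlignedRead(
                    read_id=rec.query_name,
                    chrom=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand=strand,
                    seq=seq.upper(),
                    dup_count=dup,
                    hit_count=nh,
                )
            )
    return reads


def annotate_hit_counts(reads, trust_existing: bool = False) -> list[AlignedRead]:
    """Set each read's ``hit_count`` (n_r) to its read_id's record multiplicity.

    With ``trust_existing=True``, records that already carry a hit count (e.g.
    an NH tag from the aligner) keep it.  Distinct sequences sharing a read_id
    are tallied together, with a warning, as stated.
    """
    tally: Counter = Counter(r.read_id for r in reads)
    by_id_seqs = defaultdict(set)
    for r in reads:
        by_id_seqs[r.read_id].add(r.seq)
    for rid, seqs in by_id_seqs.items():
        if len(seqs) > 1:
            warnings.warn(f"read_id {rid} maps with {len(seqs)} distinct sequences")
    out = []
    for r in reads:
        if trust_existing and r.hit_count is not None:
            out.append(r)
        else:
            out.append(replace(r, hit_count=tally[r.read_id]))
    return out


def collapse_duplicates(reads) -> list[AlignedRead]:
    """Merge reads identical in (chrom, start, end, strand, seq), summing dup_count.

    The surviving record keeps the read_id of the most duplicated member.
    hit_count must agree across merged members (it is per-sequence).
    """
    groups: dict = {}
    for r in reads:
        key = (r.chrom, r.start, r.end, r.strand, r.seq)
        groups.setdefault(key, []).append(r)
    out = []
    for key in sorted(groups):
        members = groups[key]
        if len(members) == 1:
            out.append(members[0])
            continue
        best = max(members, key=lambda m: (m.dup_count, m.read_id))
        out.append(
            replace(best, dup_count=sum(m.dup_count for m in members))
        )
    return out


def group_read_regions(reads) -> list[ReadRegion]:
    """Group reads into maximal overlapping same-strand stacks (read regions).

    Regions are the connected components of the interval-overlap graph per
    (chrom, strand); abutting half-open intervals do not overlap.  The result
    is sorted by (chrom, start, strand) and independent of input order.
    """
    regions: list[ReadRegion] = []
    for r in sorted(reads, key=lambda r: (r.chrom, r.strand, r.start, r.end, r.seq)):
        cur = regions[-1] if regions else None
        if (
            cur is not None
            and cur.chrom == r.chrom
            and cur.strand == r.strand
            and r.start < cur.end
        ):
            cur.reads.append(r)
            cur.end = max(cur.end, r.end)
        else:
            regions.append(
                ReadRegion(r.chrom, r.strand, r.start, r.end, [r])
            )
    regions.sort(key=lambda g: (g.chrom, g.start, g.strand))
    return regions


# ---------------------------------------------------------------------------
# normalization


def adjusted_count(reads) -> float:
    """Sum of dup_count / n_r over the given reads (fractional multi-mapper counts)."""
    return float(sum(r.adjusted for r in reads))


def arpm(locus_adjusted: float, library: SampleLibrary) -> float:
    """Adjusted reads per million for a locus within a sample library."""
    if library.total_adjusted_reads <= 0:
        raise ValueError("library total_adjusted_reads must be positive")
    return 1e6 * locus_adjusted / library.total_adjusted_reads


# ---------------------------------------------------------------------------
# annotations (miRBase GFF3 dialect)

_ARM_RE = re.compile(r"-(5p|3p)\b", re.IGNORECASE)


def load_annotations(path) -> list[AnnotationRecord]:
    """Parse a miRBase-dialect GFF3 into precursor/mature records.

    Matures (`miRNA` features) are linked to their parent precursors
    (`miRNA_primary_transcript`) via Derives_from/Parent attributes.  Arm is
    taken from a ``-5p``/``-3p`` name suffix when present; otherwise inferred
    from the mature's position within the parent (5' half -> 5p,
    strand-aware).  Orphan matures are kept with ``parent=None``.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    precursors: dict[str, AnnotationRecord] = {}
    out: list[AnnotationRecord] = []
    for feat in db.features_of_type("miRNA_primary_transcript"):
        name = feat.attributes.get("Name", feat.attributes.get("ID", [feat.id]))[0]
        rec = AnnotationRecord(
            name=name,
            chrom=feat.seqid,
            start=feat.start - 1,
            end=feat.end,
            strand=feat.strand,
            kind="precursor",
        )
        precursors[name] = rec
        for key in feat.attributes.get("ID", [feat.id]):
            precursors[key] = rec
        out.append(rec)
    for feat in db.features_of_type("miRNA"):
        name = feat.attributes.get("Name", feat.attributes.get("ID", [feat.id]))[0]
        parent_keys = feat.attributes.get(
            "Derives_from", feat.attributes.get("Parent", [])
        )
        parent = None
        for key in parent_keys:
            if key in precursors:
                parent = precursors[key]
                break
        if parent_keys and parent is None:
            warnings.warn(f"mature {name}: unresolvable parent {parent_keys}")
        start, end = feat.start - 1, feat.end
        m = _ARM_RE.search(name)
        if m:
            arm = m.group(1).lower()
        elif parent is not None:
            mid = (start + end) / 2
            pmid = (parent.start + parent.end) / 2
            if parent.strand == "+":
                arm = "5p" if mid < pmid else "3p"
            else:
                arm = "5p" if mid > pmid else "3p"
        else:
            arm = "unknown"
        out.append(
            AnnotationRecord(
                name=name,
                chrom=feat.seqid,
                start=start,
                end=end,
                strand=feat.strand,
                kind="mature",
                arm=arm,
                parent=parent.name if parent is not None else None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# exports


def write_regions_bed(regions, path) -> None:
    """Export read regions as BED6 (score column = total dup count)."""
    with open(path, "w") as fh:
        for i, g in enumerate(regions):
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\tregion_{i}\t"
                f"{g.dup_total}\t{g.strand}\n"
            )


def write_annotations_gff3(records, path) -> None:
    """Write annotation records back to miRBase-dialect GFF3 (round-trip exact)."""
    type_of = {"precursor": "miRNA_primary_transcript", "mature": "miRNA"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            attrs = [f"ID={rec.name}", f"Name={rec.name}"]
            if rec.kind == "mature" and rec.parent:
                attrs.append(f"Derives_from={rec.parent}")
            fh.write(
                f"{rec.chrom}\t.\t{type_of[rec.kind]}\t{rec.start + 1}\t{rec.end}"
                f"\t.\t{rec.strand}\t.\t{';'.join(attrs)}\n"
            )
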