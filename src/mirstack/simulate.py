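"""Synthetic small RNA-seq fixtures: genome, planted hairpins, read stacks.

The generator emulates the read anatomy a Drosha/Dicer-processed locus
leaves in aligned small RNA-seq data: a tight stack of ~22 nt reads on the
mature arm with a well-defined modal 5' end, a weaker stack on the star arm
at the duplex register, occasional moR and loop fragments, and — crucially
for the classifiers — background noise stacks drawn from unstructured
genomic sequence, whose flanks carry no planted reverse complement and hence
no strong product:flank duplex.  Multi-mapping is realized by physically
duplicating a locus's sequence at a decoy position and emitting each read at
both loci, which keeps hit counts consistent without an aligner.

All randomness flows from one seed; outputs are byte-identical across runs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .io import AlignedRead, AnnotationRecord, revcomp

BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic library.

    Defaults describe a clean, well-expressed small RNA library: 50 planted
    hairpins at 5-50x depth with 90% 5'-precise mature reads, ~70 nt
    precursors (21-23 nt matures, 8-20 nt loops, 2 nt 3' overhang at the
    base), star reads at a quarter of mature depth, minor moR/loop products,
    and 500 unstructured noise stacks of 1-10 reads with ragged 5' ends.
    """

    rng_seed: int
    genome_length: int = 300_000
    chrom: str = "chrSim"
    gc: float = 0.42
    n_hairpins: int = 50
    mir_length: tuple[int, int] = (21, 23)
    loop_length: tuple[int, int] = (8, 20)
    star_mismatch_rate: float = 0.0
    overhang: int = 2
    depth_range: tuple[int, int] = (5, 50)
    five_prime_precision: float = 0.9
    star_fraction: float = 0.25
    moR_fraction: float = 0.10
    loop_fraction: float = 0.05
    n_noise_loci: int = 500
    noise_depth_range: tuple[int, int] = (1, 10)
    noise_precision: float = 0.4
    multimap_fraction: float = 0.05
    n_single_read_hairpins: int = 0  # extra clean depth-1 hairpins

    def validate(self) -> None:
        problems = []
        for name in (
            "gc",
            "star_mismatch_rate",
            "five_prime_precision",
            "star_fraction",
            "moR_fraction",
            "loop_fraction",
            "noise_precision",
            "multimap_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                problems.append(f"{name}={v} not in [0,1]")
        for name in ("genome_length", "overhang"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be non-negative")
        if problems:
            raise ValueError("invalid simulation config: " + "; ".join(problems))


@dataclass
class TruthRecord:
    """Ground truth for one planted locus."""

    name: str
    chrom: str
    start: int  # precursor span
    end: int
    strand: str
    mir5p_span: tuple[int, int]
    mir3p_span: tuple[int, int]
    mir5p_seq: str
    mir3p_seq: str
    depth: int
    is_noise: bool = False


def _random_seq(rng, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=n, p=p)])


def _mutate(rng, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = str(rng.choice([b for b in "ACGT" if b != out[i]]))
    return "".join(out)


def plant_hairpin(
    genome: list, position: int, config: SimulationConfig, rng, name: str,
    strand: str, depth: int,
) -> TruthRecord:
    """Write miR + loop + star (revcomp with mismatches) into the genome at
    ``position`` and return the truth record.

    The star arm is the reverse complement of the mature arm (mutated at
    ``star_mismatch_rate``); ``overhang`` extra nucleotides after the star
    extend the precursor span, mimicking the 2 nt 3' overhang Drosha leaves
    at the base of the hairpin.
    """
    mir_len = int(rng.integers(config.mir_length[0], config.mir_length[1] + 1))
    loop_len = int(rng.integers(config.loop_length[0], config.loop_length[1] + 1))
    mir = _random_seq(rng, mir_len, config.gc)
    loop = _random_seq(rng, loop_len, config.gc)
    star = _mutate(rng, revcomp(mir), config.star_mismatch_rate)
    tail = _random_seq(rng, config.overhang, config.gc)
    construct = mir + loop + star + tail
    end = position + len(construct)
    if end > len(genome):
        raise ValueError("hairpin does not fit at position")
    genome[position:end] = list(construct)
    span_5p = (position, position + mir_len)
    span_3p = (position + mir_len + loop_len, position + mir_len + loop_len + len(star))
    if strand == "+":
        mir5p_span, mir3p_span = span_5p, span_3p
        mir5p_seq, mir3p_seq = mir, star
    else:
        # on the minus strand the genomically-right arm is read first
        mir5p_span, mir3p_span = span_3p, span_5p
        mir5p_seq, mir3p_seq = revcomp(star), revcomp(mir)
    return TruthRecord(
        name=name,
        chrom=config.chrom,
        start=position,
        end=end,
        strand=strand,
        mir5p_span=mir5p_span,
        mir3p_span=mir3p_span,
        mir5p_seq=mir5p_seq,
        mir3p_seq=mir3p_seq,
        depth=depth,
    )


def _stack_reads(
    rng, genome_str, chrom, span, strand, depth, precision, name_prefix,
    jitter_window=2, len_jitter=1,
):
    """Emit a read stack over ``span``: ``precision`` of reads start at the
    modal 5' cut, the rest within +-jitter_window; lengths jitter +-1."""
    counts = {}
    lo, hi = span
    base_len = hi - lo
    for _ in range(depth):
        if rng.random() < precision:
            off = 0
        else:
            off = int(rng.integers(-jitter_window, jitter_window + 1))
        dl = int(rng.integers(-len_jitter, len_jitter + 1))
        length = max(16, base_len + dl)
        if strand == "+":
            s = lo + off
            e = s + length
        else:
            e = hi - off
            s = e - length
        s = max(0, s)
        e = min(len(genome_str), e)
        if e - s < 16:
            continue
        counts[(s, e)] = counts.get((s, e), 0) + 1
    reads = []
    for i, ((s, e), dup) in enumerate(sorted(counts.items())):
        seq = genome_str[s:e]
        if strand == "-":
            seq = revcomp(seq)
        reads.append(
            AlignedRead(
                read_id=f"{name_prefix}.{i}_x{dup}",
                chrom=chrom,
                start=s,
                end=e,
                strand=strand,
                seq=seq,
                dup_count=dup,
            )
        )
    return reads


def simulate_reads(truth, genome_str: str, config: SimulationConfig, rng):
    """Simulated aligned reads for every planted hairpin and noise locus."""
    reads = []
    for rec in truth:
        if rec.is_noise:
            reads += _stack_reads(
                rng,
                genome_str,
                rec.chrom,
                rec.mir5p_span,
                rec.strand,
                rec.depth,
                config.noise_precision,
                rec.name,
                jitter_window=5,
                len_jitter=4,
            )
            continue
        reads += _stack_reads(
            rng, genome_str, rec.chrom, rec.mir5p_span, rec.strand,
            rec.depth, config.five_prime_precision, rec.name + ".5p",
        )
        n_star = int(round(rec.depth * config.star_fraction))
        if n_star:
            reads += _stack_reads(
                rng, genome_str, rec.chrom, rec.mir3p_span, rec.strand,
                n_star, config.five_prime_precision, rec.name + ".3p",
            )
        n_mor = int(round(rec.depth * config.moR_fraction))
        if n_mor:
            # moR sits immediately 5' of the 5p mature on the same arm
            lo, hi = rec.mir5p_span
            if rec.strand == "+":
                span = (max(0, lo - 20), lo)
            else:
                span = (hi, min(len(genome_str), hi + 20))
            reads += _stack_reads(
                rng, genome_str, rec.chrom, span, rec.strand, n_mor,
                config.five_prime_precision, rec.name + ".mor",
            )
        n_loop = int(round(rec.depth * config.loop_fraction))
        if n_loop:
            inner = (
                min(rec.mir5p_span[1], rec.mir3p_span[1]),
                max(rec.mir5p_span[0], rec.mir3p_span[0]),
            )
            if inner[1] - inner[0] >= 16:
                reads += _stack_reads(
                    rng, genome_str, rec.chrom, inner, rec.strand, n_loop,
                    config.noise_precision, rec.name + ".loop",
                )
    return reads


@dataclass
class Fixture:
    """An in-memory simulated library plus its ground truth."""

    config: SimulationConfig
    genome: dict  # {chrom: sequence string}
    reads: list
    truth: list
    annotations: list = field(default_factory=list)


def simulate(config: SimulationConfig) -> Fixture:
    """Generate a complete in-memory fixture (genome, reads, truth, GFF-style
    annotation records) under one seed."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    genome = list(_random_seq(rng, config.genome_length, config.gc))

    # lay out loci left to right with randomized spacing so nothing overlaps
    n_loci = config.n_hairpins + config.n_single_read_hairpins + config.n_noise_loci
    margin = 200
    usable = config.genome_length - 2 * margin
    slot = usable // max(1, n_loci)
    if slot < 160:
        raise ValueError(
            "genome too short for requested loci (needs ~160 nt per locus)"
        )
    positions = [
        margin + i * slot + int(rng.integers(0, max(1, slot - 130)))
        for i in range(n_loci)
    ]
    order = rng.permutation(n_loci)
    kinds = (
        ["hairpin"] * config.n_hairpins
        + ["single"] * config.n_single_read_hairpins
        + ["noise"] * config.n_noise_loci
    )
    truth = []
    n_hp = n_noise = 0
    for idx in order:
        kind = kinds[idx]
        pos = positions[idx]
        strand = "+" if rng.random() < 0.5 else "-"
        if kind in ("hairpin", "single"):
            n_hp += 1
            depth = (
                1
                if kind == "single"
                else int(rng.integers(config.depth_range[0], config.depth_range[1] + 1))
            )
            truth.append(
                plant_hairpin(
                    genome, pos, config, rng, f"sim-mir-{n_hp}", strand, depth
                )
            )
        else:
            n_noise += 1
            length = int(rng.integers(18, 29))
            depth = int(
                rng.integers(
                    config.noise_depth_range[0], config.noise_depth_range[1] + 1
                )
            )
            truth.append(
                TruthRecord(
                    name=f"noise-{n_noise}",
                    chrom=config.chrom,
                    start=pos,
                    end=pos + length,
                    strand=strand,
                    mir5p_span=(pos, pos + length),
                    mir3p_span=(pos, pos + length),
                    mir5p_seq="",
                    mir3p_seq="",
                    depth=depth,
                    is_noise=True,
                )
            )
    truth.sort(key=lambda t: t.start)
    genome_str = "".join(genome)
    reads = simulate_reads(truth, genome_str, config, rng)

    # decoy multi-mapping: duplicate a fraction of loci elsewhere in the genome
    if config.multimap_fraction > 0:
        genome_str, reads = _add_multimappers(
            genome_str, reads, truth, config, rng
        )

    annotations = []
    for rec in truth:
        if rec.is_noise:
            continue
        annotations.append(
            AnnotationRecord(
                name=rec.name, chrom=rec.chrom, start=rec.start, end=rec.end,
                strand=rec.strand, kind="precursor",
            )
        )
        for arm, span in (("5p", rec.mir5p_span), ("3p", rec.mir3p_span)):
            annotations.append(
                AnnotationRecord(
                    name=f"{rec.name}-{arm}", chrom=rec.chrom,
                    start=span[0], end=span[1], strand=rec.strand,
                    kind="mature", arm=arm, parent=rec.name,
                )
            )
    reads.sort(key=lambda r: (r.chrom, r.start, r.end, r.strand, r.read_id))
    return Fixture(
        config=config,
        genome={config.chrom: genome_str},
        reads=reads,
        truth=truth,
        annotations=annotations,
    )


def _add_multimappers(genome_str, reads, truth, config, rng):
    """Duplicate a seeded subset of noise loci at a decoy position appended to
    the genome, emitting each of their reads at both loci."""
    noise = [t for t in truth if t.is_noise]
    n_dup = int(round(config.multimap_fraction * len(noise)))
    if n_dup == 0:
        return genome_str, reads
    chosen = [noise[i] for i in rng.choice(len(noise), size=n_dup, replace=False)]
    chosen_names = {t.name for t in chosen}
    genome = genome_str
    extra = []
    spacer = "".join("T" for _ in range(100))
    for rec in sorted(chosen, key=lambda t: t.start):
        src_reads = [r for r in reads if r.read_id.startswith(rec.name + ".")]
        lo = min((r.start for r in src_reads), default=rec.start) - 10
        hi = max((r.end for r in src_reads), default=rec.end) + 10
        lo = max(0, lo)
        offset = len(genome) + len(spacer)
        genome = genome + spacer + genome_str[lo:hi]
        for r in src_reads:
            extra.append(
                AlignedRead(
                    read_id=r.read_id,
                    chrom=r.chrom,
                    start=offset + (r.start - lo),
                    end=offset + (r.end - lo),
                    strand=r.strand,
                    seq=r.seq,
                    dup_count=r.dup_count,
                )
            )
    return genome, reads + extra


# ---------------------------------------------------------------------------
# file output


def generate_fixture(config: SimulationConfig, outdir) -> dict:
    """Write genome FASTA, reads SAM, truth GFF3, mature FASTA, truth TSV and
    a manifest JSON with config + SHA256 hashes.  Byte-identical per seed."""
    import pysam

    fx = simulate(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chrom = config.chrom
    genome_seq = fx.genome[chrom]

    paths = {
        "genome": outdir / "genome.fa",
        "reads": outdir / "reads.sam",
        "truth_gff3": outdir / "truth.gff3",
        "matures": outdir / "matures.fa",
        "truth_tsv": outdir / "truth.tsv",
    }
    with open(paths["genome"], "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(genome_seq), 70):
            fh.write(genome_seq[i : i + 70] + "\n")

    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": chrom, "LN": len(genome_seq)}]}
    with pysam.AlignmentFile(str(paths["reads"]), "wh", header=header) as fh:
        for r in fx.reads:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = r.read_id
            a.reference_id = 0
            a.reference_start = r.start
            a.mapping_quality = 255
            a.cigarstring = f"{r.end - r.start}M"
            a.flag = 16 if r.strand == "-" else 0
            a.query_sequence = r.seq if r.strand == "+" else revcomp(r.seq)
            fh.write(a)

    from .io import write_annotations_gff3

    write_annotations_gff3(fx.annotations, paths["truth_gff3"])
    with open(paths["matures"], "w") as fh:
        for rec in fx.truth:
            if rec.is_noise:
                continue
            fh.write(f">{rec.name}-5p\n{rec.mir5p_seq.replace('T', 'U')}\n")
            fh.write(f">{rec.name}-3p\n{rec.mir3p_seq.replace('T', 'U')}\n")
    with open(paths["truth_tsv"], "w") as fh:
        fh.write("name\tchrom\tstart\tend\tstrand\tdepth\tis_noise\n")
        for rec in fx.truth:
            fh.write(
                f"{rec.name}\t{rec.chrom}\t{rec.start}\t{rec.end}\t"
                f"{rec.strand}\t{rec.depth}\t{int(rec.is_noise)}\n"
            )

    manifest = {"config": asdict(config), "hashes": {}}
    for key, p in paths.items():
        manifest["hashes"][key] = hashlib.sha256(p.read_bytes()).hexdigest()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {k: str(p) for k, p in paths.items()}
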