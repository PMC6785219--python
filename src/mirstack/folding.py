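"""RNA secondary structure: MFE folding, two-sequence duplexes, hairpin anatomy.

Thermodynamic prediction is delegated to the ViennaRNA engine (RNAfold /
RNAduplex equivalents through its Python bindings) at 37 degC with default
parameters.  Everything downstream of the dot-bracket string — pair tables,
loop decomposition, the main-stem walk that defines "the loop", bulge and
interior-loop bookkeeping — is implemented here, because those structural
summaries are the classifier's raw material.

Conventions (frozen; see docs/methods.md):

* The *main stem* of a fold, relative to an anchor interval (the major
  product), is found by taking the outermost base pair that encloses or
  touches the anchor and walking inward.  The walk passes through bulges and
  interior loops (they belong to the stem); at a multibranch loop it descends
  into the child branch containing the anchor if any, otherwise the branch
  with the most base pairs in its subtree (ties toward the 5'-most branch).
* The *main loop* is the hairpin loop the walk terminates in.  *Offshoots*
  are hairpin loops other than the main loop located under the anchor's
  enclosing stem.
* ``innerLoopGapCount`` counts maximal runs of >= 3 unpaired positions lying
  directly in the loop closed by the innermost main-stem pair (for a clean
  hairpin that is the hairpin loop itself, count 1; a multibranch loop
  typically yields > 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

try:
    import RNA as _RNA
except ImportError as _e:  # pragma: no cover - environment guard
    _RNA = None
    _RNA_ERR = _e


class FoldingEngineError(RuntimeError):
    """The thermodynamic folding engine is unavailable or failed."""


def _engine():
    if _RNA is None:  # pragma: no cover
        raise FoldingEngineError(
            f"ViennaRNA Python bindings are required but not importable: {_RNA_ERR}"
        )
    return _RNA


def engine_version() -> str:
    return getattr(_engine(), "__version__", "unknown")


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass
class DotBracket:
    """A sequence with its MFE structure and energy (kcal/mol)."""

    seq: str
    structure: str
    mfe: float

    def __post_init__(self):
        if len(self.seq) != len(self.structure):
            raise ValueError("structure/sequence length mismatch")

    def pair_table(self) -> list[int]:
        """p[i] = partner of i, or -1 if unpaired (0-based)."""
        return pair_table(self.structure)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class DuplexResult:
    """Optimal inter-molecular duplex between a query and a target sequence.

    Spans are 0-based half-open on their respective sequences, trimmed to the
    paired extent (terminal unpaired positions of the engine's interval are
    dropped).
    """

    query_span: tuple[int, int]
    target_span: tuple[int, int]
    structure: str  # "...((((&))))..." with '&' separating the molecules
    energy: float

    def target_paired(self, target_len: int) -> list[bool]:
        """Paired/unpaired state over the full target, from the duplex."""
        part2 = self.structure.split("&")[1]
        state = [False] * target_len
        for off, ch in enumerate(part2):
            pos = self._raw_target_start + off
            if ch != "." and 0 <= pos < target_len:
                state[pos] = True
        return state

    # start of the engine's (untrimmed) target interval; set by duplex()
    _raw_target_start: int = 0


def pair_table(structure: str) -> list[int]:
    """Parse a dot-bracket string into a partner table (raises on imbalance)."""
    stack: list[int] = []
    pt = [-1] * len(structure)
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pt[i], pt[j] = j, i
        elif ch != ".":
            raise ValueError(f"illegal structure character {ch!r}")
    if stack:
        raise ValueError("unbalanced '(' in structure")
    return pt


def fold(seq: str) -> DotBracket:
    """MFE fold of a single sequence (T mapped to U; 37 degC defaults)."""
    if len(seq) < 10:
        raise ValueError("sequence too short to fold (< 10 nt)")
    rna = _to_rna(seq)
    structure, mfe = _engine().fold(rna)
    return DotBracket(seq=rna, structure=structure, mfe=float(mfe))


def duplex(query: str, target: str) -> DuplexResult | None:
    """Optimal inter-molecular duplex; None if no stabilizing duplex exists.

    Engine interval convention (verified against the bindings): the part
    before '&' covers query positions [i - len1, i) and the part after covers
    target positions [j - 1, j - 1 + len2), with i and j 1-based.  Reported
    spans are additionally trimmed to the outermost paired positions.
    """
    if not query or not target:
        raise ValueError("both sequences must be non-empty")
    d = _engine().duplexfold(_to_rna(query), _to_rna(target))
    if d is None or "&" not in d.structure or d.energy >= 0:
        return None
    part1, part2 = d.structure.split("&")
    if "(" not in part1:
        return None
    q_start = d.i - len(part1)
    t_start = d.j - 1
    # trim to paired extent
    q_l = part1.index("(")
    q_r = part1.rindex("(")
    t_l = part2.index(")")
    t_r = part2.rindex(")")
    res = DuplexResult(
        query_span=(q_start + q_l, q_start + q_r + 1),
        target_span=(t_start + t_l, t_start + t_r + 1),
        structure=d.structure,
        energy=float(d.energy),
    )
    res._raw_target_start = t_start
    return res


# ---------------------------------------------------------------------------
# anatomy

#: position classes for the partition invariant
PAIRED, LOOP, BULGE, INTERIOR, EXTERIOR = "paired", "loop", "bulge", "interior", "exterior"


@dataclass
class HairpinAnatomy:
    """Structural decomposition of a fold around an anchor (major product).

    ``classes`` partitions every position into paired / loop / bulge /
    interior / exterior (hairpin and multibranch loop positions both count as
    ``loop``).  Stem-local records (``bulges``, ``interior_loops``) list the
    destabilizing elements met while walking the main stem, with their spans.
    """

    classes: list[str]
    main_loop: tuple[int, int] | None  # hairpin loop of the anchor's stem
    enclosing_pair: tuple[int, int] | None  # outermost pair of the main stem
    inner_pair: tuple[int, int] | None  # innermost pair (closes main/multi loop)
    bulges: list = field(default_factory=list)  # (side, (start, end)); side '5p'|'3p'
    interior_loops: list = field(default_factory=list)  # ((s1,e1), (s2,e2))
    offshoot_spans: list = field(default_factory=list)  # other hairpin loops

    @property
    def no_hairpin(self) -> bool:
        return self.main_loop is None

    @property
    def loop_size(self) -> int:
        return 0 if self.main_loop is None else self.main_loop[1] - self.main_loop[0]

    @property
    def num_offshoots(self) -> int:
        return len(self.offshoot_spans)

    def paired(self, i: int) -> bool:
        return self.classes[i] == PAIRED


def _children(pt: list[int], i: int, j: int) -> list[tuple[int, int]]:
    """Direct child pairs inside pair (i, j), left to right."""
    out = []
    k = i + 1
    while k < j:
        if pt[k] > k:
            out.append((k, pt[k]))
            k = pt[k] + 1
        else:
            k += 1
    return out


def _top_level_pairs(pt: list[int]) -> list[tuple[int, int]]:
    out = []
    k = 0
    while k < len(pt):
        if pt[k] > k:
            out.append((k, pt[k]))
            k = pt[k] + 1
        else:
            k += 1
    return out


def _classify_positions(pt: list[int]) -> list[str]:
    """Partition every position: paired / loop / bulge / interior / exterior."""
    n = len(pt)
    classes = [EXTERIOR] * n
    for i, j in enumerate(pt):
        if j != -1:
            classes[i] = PAIRED

    def visit(i: int, j: int) -> None:
        kids = _children(pt, i, j)
        unpaired = [k for k in range(i + 1, j) if pt[k] == -1 and not any(
            a < k < b for a, b in kids
        )]
        if not kids:
            for k in unpaired:
                classes[k] = LOOP
        elif len(kids) == 1:
            (a, b) = kids[0]
            left = [k for k in unpaired if k < a]
            right = [k for k in unpaired if k > b]
            if left and right:
                lab = INTERIOR
            else:
                lab = BULGE
            for k in left + right:
                classes[k] = lab
        else:
            for k in unpaired:
                classes[k] = LOOP  # multibranch loop positions
        for a, b in kids:
            visit(a, b)

    for i, j in _top_level_pairs(pt):
        visit(i, j)
    return classes


def _subtree_pair_count(pt: list[int], i: int, j: int) -> int:
    return sum(1 for k in range(i, j + 1) if i <= pt[k] <= j and pt[k] > k)


def _hairpin_loops_under(pt: list[int], i: int, j: int) -> list[tuple[int, int]]:
    """All hairpin-loop spans in the subtree of pair (i, j)."""
    loops = []

    def visit(a: int, b: int) -> None:
        kids = _children(pt, a, b)
        if not kids:
            loops.append((a + 1, b))
        for c, d in kids:
            visit(c, d)

    visit(i, j)
    return loops


def parse_hairpin(db: DotBracket, anchor: tuple[int, int]) -> HairpinAnatomy:
    """Decompose a fold around an anchor interval (the major product span).

    Returns a no-hairpin anatomy (main_loop=None) when the anchor is entirely
    unpaired with no enclosing stem.
    """
    pt = db.pair_table()
    n = len(pt)
    a, b = anchor
    a = max(0, a)
    b = min(n, b)
    if b <= a:
        raise ValueError("anchor outside fold")
    classes = _classify_positions(pt)

    # outermost pair enclosing or touching the anchor: among all pairs that
    # involve an anchor position or fully enclose the anchor, take the one
    # contained in no other candidate (5'-most on ties)
    candidates = [
        (i, j)
        for i, j in enumerate(pt)
        if j > i and ((a <= i < b) or (a <= j < b) or (i < a and j >= b - 1))
    ]
    outer = None
    for i, j in sorted(candidates, key=lambda p: (p[0], -p[1])):
        if not any(ci < i and j < cj for ci, cj in candidates):
            outer = (i, j)
            break
    if outer is None:
        return HairpinAnatomy(classes=classes, main_loop=None,
                              enclosing_pair=None, inner_pair=None)

    bulges: list = []
    interiors: list = []
    i, j = outer
    branch_pair = None  # first multiloop-closing pair met on the walk
    while True:
        kids = _children(pt, i, j)
        if not kids:
            main_loop = (i + 1, j)
            inner = branch_pair or (i, j)
            break
        if len(kids) == 1:
            (c, d) = kids[0]
            left = (i + 1, c)  # 5' side gap span
            right = (d + 1, j)  # 3' side gap span
            nl, nr = left[1] - left[0], right[1] - right[0]
            if nl and nr:
                interiors.append((left, right))
            elif nl:
                bulges.append(("5p", left))
            elif nr:
                bulges.append(("3p", right))
            i, j = c, d
            continue
        # multibranch: the main stem ends here (the innermost pair closes
        # this loop); continue into the child holding the anchor, else the
        # child with the most pairs in its subtree (ties -> 5'-most)
        if branch_pair is None:
            branch_pair = (i, j)
        holder = [k for k in kids if k[0] <= a and k[1] >= b - 1]
        if holder:
            i, j = holder[0]
            continue
        i, j = max(kids, key=lambda p: (_subtree_pair_count(pt, *p), -p[0]))

    all_loops = _hairpin_loops_under(pt, outer[0], outer[1])
    offshoots = [lp for lp in all_loops if lp != main_loop]
    return HairpinAnatomy(
        classes=classes,
        main_loop=main_loop,
        enclosing_pair=outer,
        inner_pair=inner,
        bulges=bulges,
        interior_loops=interiors,
        offshoot_spans=offshoots,
    )


def inner_loop_gap_count(db: DotBracket, anatomy: HairpinAnatomy) -> int:
    """Maximal runs of >= 3 unpaired positions directly in the innermost loop.

    The loop considered is the one closed by the innermost main-stem pair:
    positions strictly inside it that are not covered by child branches.
    More than one such run indicates a multibranched loop.
    """
    if anatomy.inner_pair is None:
        return 0
    pt = db.pair_table()
    i, j = anatomy.inner_pair
    kids = _children(pt, i, j)
    in_loop = [
        k
        for k in range(i + 1, j)
        if pt[k] == -1 and not any(a < k < b for a, b in kids)
    ]
    count, run, prev = 0, 0, None
    for k in in_loop:
        run = run + 1 if prev is not None and k == prev + 1 else 1
        if run == 3:
            count += 1
        prev = k
    return count


def _longest_unpaired_run(pt: list[int], span: tuple[int, int]) -> int:
    best = run = 0
    for k in range(span[0], span[1]):
        if pt[k] == -1:
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best


def _gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Non-negative gap between two intervals (0 when overlapping/abutting)."""
    return max(0, max(a[0], b[0]) - min(a[1], b[1]))


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def structural_features(
    anatomy: HairpinAnatomy,
    db: DotBracket,
    mir: tuple[int, int],
    star: tuple[int, int] | None,
) -> dict[str, float]:
    """The hairpin-structure feature block around the miR and its duplex partner.

    All intervals are fold-local.  With no duplex partner (``star=None``) the
    duplex-derived features are 0 and ``dup_missing`` is flagged (the flag is
    bookkeeping, not part of the feature vector).
    """
    pt = db.pair_table()
    n = len(pt)
    mir = (max(0, mir[0]), min(n, mir[1]))
    # the stem region spanning miR and its partner: positions between the
    # 5'-most and 3'-most ends of the two intervals (inclusive convention)
    if star is not None:
        region = (min(mir[0], star[0]), max(mir[1], star[1]))
    else:
        region = mir

    max_bulge = 0
    for _side, span in anatomy.bulges:
        if _overlap(span, region):
            max_bulge = max(max_bulge, span[1] - span[0])
    max_int = 0
    int_diff = 0
    for left, right in anatomy.interior_loops:
        if _overlap(left, region) or _overlap(right, region):
            nl, nr = left[1] - left[0], right[1] - right[0]
            if nl + nr > max_int:
                max_int = nl + nr
            int_diff = max(int_diff, abs(nl - nr))

    # unpaired overhang at either end of the miR span
    left_run = 0
    for k in range(mir[0], mir[1]):
        if pt[k] == -1:
            left_run += 1
        else:
            break
    right_run = 0
    for k in range(mir[1] - 1, mir[0] - 1, -1):
        if pt[k] == -1:
            right_run += 1
        else:
            break
    max_overhang = max(left_run, right_run)

    loop = anatomy.main_loop
    mp_loop = _gap(mir, loop) if loop is not None else 0
    dup_loop_dist = _gap(star, loop) if (loop is not None and star) else 0

    mir_len = mir[1] - mir[0]
    pbp = (
        sum(1 for k in range(mir[0], mir[1]) if pt[k] != -1) / mir_len
        if mir_len
        else 0.0
    )
    if star is not None and star[1] > star[0]:
        s0, s1 = max(0, star[0]), min(n, star[1])
        dup_pbp = (
            sum(1 for k in range(s0, s1) if pt[k] != -1) / (s1 - s0)
            if s1 > s0
            else 0.0
        )
        dup_loop_len = _longest_unpaired_run(pt, (s0, s1))
        dup_size = star[1] - star[0]
    else:
        dup_pbp = 0.0
        dup_loop_len = 0
        dup_size = 0

    return {
        "loopSize": float(anatomy.loop_size),
        "maxBulge": float(max_bulge),
        "maxInteriorLoop": float(max_int),
        "intLoopSideDiff": float(int_diff),
        "maxUnboundOverhang": float(max_overhang),
        "innerLoopGapCount": float(inner_loop_gap_count(db, anatomy)),
        "numOffshoots": float(anatomy.num_offshoots),
        "mpLoopDistance": float(mp_loop),
        "dupLoopDistance": float(dup_loop_dist),
        "pbp": float(pbp),
        "dupPBP": float(dup_pbp),
        "dupLoopLength": float(dup_loop_len),
        "dupSize": float(dup_size),
        "dup_missing": 0.0 if star is not None else 1.0,
    }


def fold_duplex_agreement(
    db: DotBracket,
    dup: DuplexResult | None,
    span: tuple[int, int],
    query_span_on_target: tuple[int, int] | None = None,
) -> float:
    """Fraction of positions in ``span`` whose paired state agrees between the
    full fold and the duplex prediction.

    The duplex marks its target-side paired positions; if the query also lies
    on the target sequence (as it does when duplexing a product against its
    own precursor), pass its location so its paired positions count too.
    Empty span -> 1.0 by convention; missing duplex compares against
    all-unpaired.
    """
    s, e = max(0, span[0]), min(len(db), span[1])
    if e <= s:
        return 1.0
    pt = db.pair_table()
    dup_state = [False] * len(db)
    if dup is not None:
        dup_state = dup.target_paired(len(db))
        if query_span_on_target is not None:
            part1 = dup.structure.split("&")[0]
            q0 = dup.query_span[0]
            off = part1.index("(")
            for k, ch in enumerate(part1[off:]):
                pos = query_span_on_target[0] + q0 + off + k
                if ch != "." and 0 <= pos < len(db):
                    dup_state[pos] = True
    agree = sum(1 for k in range(s, e) if (pt[k] != -1) == dup_state[k])
    return agree / (e - s)
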