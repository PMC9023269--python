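"""Semiglobal read-to-amplicon alignment and normalized variant extraction.

Reads are aligned to the amplicon reference with an affine-gap scheme and
free end gaps on the reference, so a read may cover any sub-interval of the
amplicon.  Alignment itself is performed by :class:`Bio.Align.PairwiseAligner`;
this module owns the variant model: each insertion/deletion is reported
left-aligned (smallest reference start yielding the identical edited
sequence) together with its full equivalence interval -- the half-open range
of reference placements over which the call can slide.  Downstream logic
(editing-window overlap, TIS calling, microhomology) is written against
equivalence intervals, so it is invariant to where inside a repeat the
aligner happened to place an indel.

The gap convention is Biopython's: a gap of length L scores
``gap_open + (L - 1) * gap_extend``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .refmodel import reverse_complement

__all__ = [
    "Scoring",
    "Alignment",
    "IndelCall",
    "align_semiglobal",
    "align_best_orientation",
    "extract_variants",
    "apply_variants",
    "normalize_indel",
]

DEFAULT_SCORING = {"match": 2, "mismatch": -4, "gap_open": -10, "gap_extend": -1}


@dataclass(frozen=True)
class Scoring:
    match: float = 2
    mismatch: float = -4
    gap_open: float = -10
    gap_extend: float = -1


@dataclass
class Alignment:
    """One read-vs-reference alignment as an ordered list of operations.

    ``ops`` entries are ``(op, length, ref_pos, read_pos)`` with op in
    {match, mismatch, ins, del}; ``ref_span`` is the half-open reference
    interval covered by the read (free end gaps excluded).
    """

    read_id: str
    ops: list = field(default_factory=list)
    score: float = 0.0
    ref_span: tuple = (0, 0)

    def has_op(self, kind: str) -> bool:
        return any(op == kind for op, *_ in self.ops)


@dataclass
class IndelCall:
    """One normalized variant on reference coordinates.

    ``ref_start`` is the left-aligned position (a junction for insertions);
    ``equivalence_interval`` is the half-open range of equivalent
    ``ref_start`` placements (width 1 when the context is non-repetitive).
    """

    kind: str          # 'deletion' | 'insertion' | 'substitution'
    ref_start: int
    length: int
    seq: str           # inserted/substituted bases; '' for deletions
    equivalence_interval: tuple

    @property
    def ref_span(self) -> tuple:
        """Reference interval touched under any equivalent placement."""
        lo, hi = self.equivalence_interval
        if self.kind == "deletion":
            return (lo, hi - 1 + self.length)
        return (lo, hi)


def _make_aligner(scoring: Scoring) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = scoring.match
    a.mismatch_score = scoring.mismatch
    a.open_gap_score = scoring.gap_open
    a.extend_gap_score = scoring.gap_extend
    # free end gaps on the reference: reads may cover a sub-interval
    a.end_deletion_score = 0
    return a


def align_semiglobal(
    read: str,
    reference_seq: str,
    scoring: Scoring | None = None,
    read_id: str = "read",
) -> Alignment:
    """Optimal affine-gap alignment of ``read`` against ``reference_seq``.

    End gaps on the reference are free.  Among equal-score alignments the
    aligner's first traceback is kept (deterministic); indel placement is
    canonicalized later by :func:`extract_variants`.
    """
    if not read or not reference_seq:
        raise ValueError("empty sequence")
    if len(read) > 2 * len(reference_seq):
        raise ValueError("read more than twice the reference length")
    scoring = scoring or Scoring()
    aligner = _make_aligner(scoring)
    result = aligner.align(reference_seq, read)
    aln = result[0]
    return _from_biopython(aln, result.score, read, reference_seq, read_id)


def align_best_orientation(
    read: str,
    reference_seq: str,
    scoring: Scoring | None = None,
    read_id: str = "read",
) -> tuple[Alignment, str]:
    """Align the read as given and reverse-complemented; keep the higher score.

    Returns ``(alignment, orientation)`` with orientation ``'forward'`` or
    ``'reverse-complement'``.  Ties keep the forward orientation.
    """
    fwd = align_semiglobal(read, reference_seq, scoring, read_id)
    rev = align_semiglobal(reverse_complement(read), reference_seq, scoring, read_id)
    if rev.score > fwd.score:
        return rev, "reverse-complement"
    return fwd, "forward"


def _from_biopython(aln, score, read, ref, read_id) -> Alignment:
    coords = aln.coordinates  # 2 x (n+1): target (ref) and query (read) block bounds
    blocks = [
        (int(coords[0, i]), int(coords[0, i + 1]), int(coords[1, i]), int(coords[1, i + 1]))
        for i in range(coords.shape[1] - 1)
    ]
    # leading/trailing reference-only blocks are free end gaps, not deletions
    while blocks and blocks[0][2] == blocks[0][3] == 0 and blocks[0][1] > blocks[0][0]:
        blocks.pop(0)
    while (
        blocks
        and blocks[-1][2] == blocks[-1][3] == len(read)
        and blocks[-1][1] > blocks[-1][0]
    ):
        blocks.pop()

    ops = []
    for t0, t1, q0, q1 in blocks:
        if t1 > t0 and q1 > q0:  # diagonal: split into match/mismatch runs
            i = 0
            n = t1 - t0
            while i < n:
                is_mm = ref[t0 + i] != read[q0 + i]
                j = i
                while j < n and (ref[t0 + j] != read[q0 + j]) == is_mm:
                    j += 1
                ops.append(("mismatch" if is_mm else "match", j - i, t0 + i, q0 + i))
                i = j
        elif t1 > t0:
            ops.append(("del", t1 - t0, int(t0), int(q0)))
        elif q1 > q0:
            ops.append(("ins", q1 - q0, int(t0), int(q0)))

    if ops:
        ref_span = (ops[0][2], ops[-1][2] + (ops[-1][1] if ops[-1][0] != "ins" else 0))
    else:
        ref_span = (0, 0)
    return Alignment(read_id=read_id, ops=ops, score=float(score), ref_span=ref_span)


def _slide_range_deletion(ref: str, start: int, length: int) -> tuple[int, int]:
    """Smallest and largest start of an equivalent placement of a deletion."""
    lo = start
    while lo > 0 and ref[lo - 1] == ref[lo - 1 + length]:
        lo -= 1
    hi = start
    while hi + length < len(ref) and ref[hi] == ref[hi + length]:
        hi += 1
    return lo, hi


def _slide_insertion_left(ref: str, pos: int, seq: str) -> tuple[int, str]:
    while pos > 0 and seq and ref[pos - 1] == seq[-1]:
        pos -= 1
        seq = ref[pos] + seq[:-1]
    return pos, seq


def _insertion_slide_max(ref: str, pos: int, seq: str) -> int:
    hi, s = pos, seq
    while hi < len(ref) and s and ref[hi] == s[0]:
        s = s[1:] + ref[hi]
        hi += 1
    return hi


def normalize_indel(ref: str, call: IndelCall) -> IndelCall:
    """Left-align an indel and record its full equivalence interval.

    Idempotent: normalizing a normalized call returns an equal call.
    Substitutions are returned with a width-1 equivalence interval.
    """
    if call.kind == "deletion":
        lo, hi = _slide_range_deletion(ref, call.ref_start, call.length)
        return IndelCall("deletion", lo, call.length, "", (lo, hi + 1))
    if call.kind == "insertion":
        lo, seq = _slide_insertion_left(ref, call.ref_start, call.seq)
        hi = _insertion_slide_max(ref, lo, seq)
        return IndelCall("insertion", lo, len(seq), seq, (lo, hi + 1))
    return IndelCall(
        call.kind, call.ref_start, call.length, call.seq,
        (call.ref_start, call.ref_start + 1),
    )


def extract_variants(aln: Alignment, reference_seq: str, read: str | None = None) -> list[IndelCall]:
    """One left-normalized :class:`IndelCall` per indel op and mismatch run.

    ``read`` is needed to recover inserted/substituted bases; if omitted it
    is reconstructed from the ops, which requires a full Alignment produced
    by :func:`align_semiglobal` (mismatch runs then carry no sequence).
    """
    calls = []
    for op, length, ref_pos, read_pos in aln.ops:
        if op == "match":
            continue
        if op == "del":
            raw = IndelCall("deletion", ref_pos, length, "", (ref_pos, ref_pos + 1))
        elif op == "ins":
            seq = read[read_pos : read_pos + length] if read is not None else "N" * length
            raw = IndelCall("insertion", ref_pos, length, seq, (ref_pos, ref_pos + 1))
        else:  # mismatch run
            seq = read[read_pos : read_pos + length] if read is not None else "N" * length
            raw = IndelCall("substitution", ref_pos, length, seq, (ref_pos, ref_pos + 1))
        calls.append(normalize_indel(reference_seq, raw))
    return calls


def apply_variants(reference_seq: str, variants: list[IndelCall], ref_span: tuple) -> str:
    """Rebuild the read over ``ref_span`` by applying variants to the reference.

    Used for round-trip verification: the result must equal the aligned read.
    """
    lo, hi = ref_span
    out = []
    pos = lo
    for v in sorted(variants, key=lambda c: (c.ref_start, 0 if c.kind == "insertion" else 1)):
        if v.ref_start < pos and v.kind != "insertion":
            raise ValueError("overlapping variants")
        out.append(reference_seq[pos : v.ref_start])
        if v.kind == "deletion":
            pos = v.ref_start + v.length
        elif v.kind == "insertion":
            out.append(v.seq)
            pos = v.ref_start
        else:
            out.append(v.seq)
            pos = v.ref_start + v.length
    out.append(reference_seq[pos:hi])
    return "".join(out)
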