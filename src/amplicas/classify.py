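"""Per-read editing-outcome classification and per-sample mutation profiles.

Each aligned read is reduced to an :class:`OutcomeRecord`: its class
(unedited, 1-bp deletion, >1-bp deletion, insertion, mixed, or
substitution-only), indel sizes, whether an insertion is a templated
insertion (TIS), and -- for >1-bp deletions -- a microhomology annotation.
Only variants overlapping an editing window around the predicted cut
(default +/-10 nt) count as editing; distal variants are treated as noise.

A templated insertion duplicates the bases immediately 5' of the blunt cut
(the base 4 nt upstream of the PAM for a 1-bp TIS), the product of
polymerase fill-in of a staggered-cut 5' overhang.  The TIS test is string
based and therefore placement invariant: an insertion is a k-bp TIS iff
applying it to the reference yields exactly the sequence obtained by
inserting the k-nt template at the cut junction.

Per-sample profiles mirror standard amplicon-editing reporting: deletion /
insertion class percentages among all INDEL reads, 1-bp TIS as a percentage
of all insertion reads, deletion-size spectra, and the fraction of reads
carrying substitutions in a window around the cut (default +/-20 nt),
counted per read over all reads.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .align import Alignment, IndelCall, Scoring, align_best_orientation, extract_variants
from .microhomology import MicrohomologyAnnotation, classify_mh_position, find_microhomology
from .refmodel import TargetSite, tis_template

__all__ = [
    "OutcomeRecord",
    "MutationProfile",
    "classify_read",
    "classify_sample",
    "profile_sample",
    "substitution_rate",
    "deletion_size_spectrum",
]

DEFAULT_EDIT_WINDOW = 10   # nt half-width around the cut for indel counting
DEFAULT_SUB_WINDOW = 20    # nt half-width for substitution-rate measurement

INDEL_CLASSES = ("del_1bp", "del_gt1bp", "insertion", "mixed")


@dataclass
class OutcomeRecord:
    read_id: str
    klass: str                 # unedited | del_1bp | del_gt1bp | insertion | mixed | substitution_only
    del_size: int = 0
    ins_size: int = 0
    ins_seq: str = ""
    is_TIS: bool | None = None  # defined only for insertions of 1-3 nt
    mh: MicrohomologyAnnotation | None = None

    @property
    def is_indel(self) -> bool:
        return self.klass in INDEL_CLASSES


@dataclass
class MutationProfile:
    sample_id: str
    n_reads_total: int
    n_reads_edited: int        # reads with >=1 indel in the editing window
    indel_rate: float          # % of all reads
    pct_del_1bp: float | None
    pct_del_gt1bp: float | None
    pct_insertion: float | None
    pct_mixed: float | None
    pct_TIS_1bp_of_insertions: float | None
    size_histogram: dict = field(default_factory=dict)           # deletion size -> count
    insertion_size_histogram: dict = field(default_factory=dict)


def _overlaps_window(call: IndelCall, lo: int, hi: int) -> bool:
    a, b = call.ref_span
    if call.kind == "insertion":
        # junction positions; a junction equal to hi is outside [lo, hi)
        return a < hi and b > lo
    return a < hi and b > lo


def _is_tis(ins: IndelCall, site: TargetSite) -> bool:
    if not 1 <= ins.length <= 3:
        return False
    ref = site.working_seq
    template = tis_template(site, ins.length)
    templated = ref[: site.cut_pos] + template + ref[site.cut_pos :]
    observed = ref[: ins.ref_start] + ins.seq + ref[ins.ref_start :]
    return observed == templated


def classify_read(
    variants: list[IndelCall],
    site: TargetSite,
    window: int = DEFAULT_EDIT_WINDOW,
    read_id: str = "read",
) -> OutcomeRecord:
    """Classify one read's variants into an editing-outcome record.

    Precedence: deletion + insertion in the window -> ``mixed``; a single
    1-bp deletion -> ``del_1bp``; deletions totalling >1 bp -> ``del_gt1bp``;
    insertions only -> ``insertion``; mismatches only -> ``substitution_only``;
    nothing in the window -> ``unedited``.
    """
    lo, hi = site.cut_pos - window, site.cut_pos + window
    dels = [v for v in variants if v.kind == "deletion" and _overlaps_window(v, lo, hi)]
    inss = [v for v in variants if v.kind == "insertion" and _overlaps_window(v, lo, hi)]
    subs = [v for v in variants if v.kind == "substitution" and _overlaps_window(v, lo, hi)]

    del_size = sum(v.length for v in dels)
    ins_size = sum(v.length for v in inss)
    ins_seq = inss[0].seq if len(inss) == 1 else "".join(v.seq for v in inss)

    if dels and inss:
        klass = "mixed"
    elif dels:
        klass = "del_1bp" if len(dels) == 1 and del_size == 1 else "del_gt1bp"
    elif inss:
        klass = "insertion"
    elif subs:
        klass = "substitution_only"
    else:
        klass = "unedited"

    is_tis = None
    if klass == "insertion" and len(inss) == 1 and 1 <= ins_size <= 3:
        is_tis = _is_tis(inss[0], site)

    mh = None
    if klass == "del_gt1bp" and len(dels) == 1 and dels[0].length >= 2:
        mh = find_microhomology(site.working_seq, dels[0])
        classify_mh_position(mh, dels[0], site)

    return OutcomeRecord(
        read_id=read_id,
        klass=klass,
        del_size=del_size,
        ins_size=ins_size,
        ins_seq=ins_seq if inss else "",
        is_TIS=is_tis,
        mh=mh,
    )


def profile_sample(
    records: list[OutcomeRecord],
    n_reads_total: int,
    sample_id: str = "sample",
) -> MutationProfile:
    """Aggregate outcome records into a per-sample mutation profile.

    Class percentages are expressed over all INDEL reads; 1-bp TIS over all
    insertion reads.  Percentages are reported as ``None`` (missing) when
    their denominator is zero.
    """
    if n_reads_total == 0:
        raise ValueError("empty sample: n_reads_total is 0")
    edited = [r for r in records if r.is_indel]
    n_edited = len(edited)
    tally = Counter(r.klass for r in edited)

    def pct(k):
        return 100.0 * tally[k] / n_edited if n_edited else None

    n_ins = tally["insertion"]
    n_tis1 = sum(
        1 for r in edited if r.klass == "insertion" and r.ins_size == 1 and r.is_TIS
    )
    return MutationProfile(
        sample_id=sample_id,
        n_reads_total=n_reads_total,
        n_reads_edited=n_edited,
        indel_rate=100.0 * n_edited / n_reads_total,
        pct_del_1bp=pct("del_1bp"),
        pct_del_gt1bp=pct("del_gt1bp"),
        pct_insertion=pct("insertion"),
        pct_mixed=pct("mixed"),
        pct_TIS_1bp_of_insertions=(100.0 * n_tis1 / n_ins if n_ins else None),
        size_histogram=deletion_size_spectrum(edited),
        insertion_size_histogram=dict(
            Counter(r.ins_size for r in edited if r.klass == "insertion")
        ),
    )


def substitution_rate(
    aligned: list[tuple[Alignment, list[IndelCall]]],
    site: TargetSite,
    half_window: int = DEFAULT_SUB_WINDOW,
) -> float:
    """Percent of reads with >=1 substitution within ``cut +/- half_window``.

    Counted per read, over all reads covering the window; reads with indels
    in the window remain in the denominator.  Raises ``ValueError`` if no
    read covers the window.
    """
    lo, hi = site.cut_pos - half_window, site.cut_pos + half_window
    n_cov = 0
    n_sub = 0
    for aln, variants in aligned:
        a, b = aln.ref_span
        if not (a <= lo and b >= hi):
            continue
        n_cov += 1
        if any(
            v.kind == "substitution" and _overlaps_window(v, lo, hi) for v in variants
        ):
            n_sub += 1
    if n_cov == 0:
        raise ValueError("window uncovered: no read spans the substitution window")
    return 100.0 * n_sub / n_cov


def classify_sample(
    reads: list[tuple[str, str]],
    site: TargetSite,
    window: int = DEFAULT_EDIT_WINDOW,
    scoring: Scoring | None = None,
) -> tuple[list[OutcomeRecord], list[tuple[Alignment, list[IndelCall]]]]:
    """Align and classify every read of a sample against the site's reference.

    Each read is aligned in both orientations against the working reference
    (protospacer strand on top); the higher-scoring orientation is kept.
    Returns the outcome records and the (alignment, variants) pairs, the
    latter reusable for :func:`substitution_rate`.
    """
    ref = site.working_seq
    records, aligned = [], []
    for rid, seq in reads:
        aln, orientation = align_best_orientation(seq, ref, scoring, read_id=rid)
        oriented = seq if orientation == "forward" else _revcomp(seq)
        variants = extract_variants(aln, ref, oriented)
        records.append(classify_read(variants, site, window, read_id=rid))
        aligned.append((aln, variants))
    return records, aligned


def _revcomp(seq: str) -> str:
    from .refmodel import reverse_complement

    return reverse_complement(seq)


def deletion_size_spectrum(records: list[OutcomeRecord], max_size: int = 30) -> dict:
    """Deletion-size histogram over deletion-class reads (sizes 1..max, + overflow)."""
    hist: dict = {}
    for r in records:
        if r.klass in ("del_1bp", "del_gt1bp"):
            key = r.del_size if r.del_size <= max_size else f"gt{max_size}"
            hist[key] = hist.get(key, 0) + 1
    return hist
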