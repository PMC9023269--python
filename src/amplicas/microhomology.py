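"""Flanking-microhomology annotation of deletions and cut-relative classes.

Microhomology-mediated end joining (MMEJ) leaves a signature: the deleted
interval is flanked by a short (2-5 nt) repeat of which one copy survives
the deletion.  Both copies are present in the unedited reference, so the
annotation is computed from the reference alone: with the deletion
left-aligned at ``[d, d+L)``, the microhomology length is the longest common
suffix of ``ref[:d]`` and ``ref[:d+L]`` (zero once left-aligned) plus the
longest common prefix of ``ref[d:]`` and ``ref[d+L:]``, capped at ``L - 1``
so that deletions inside a perfect repeat are not degenerately annotated.

The position classes mirror the deletion taxonomy used for Cas9 outcome
spectra: microhomology abutting the predicted cut junction (``mh_at_cut``),
microhomology elsewhere (``mh_away``), no microhomology but a deletion
boundary placeable at the cut (``no_mh_end_at_cut``), and neither
(``no_mh``).  "At the cut" is evaluated over the deletion's whole
equivalence interval, so it does not depend on the aligner's placement.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import IndelCall, _slide_range_deletion
from .refmodel import TargetSite

__all__ = ["MicrohomologyAnnotation", "find_microhomology", "classify_mh_position"]

MIN_MH_LEN = 2  # MMEJ operates on 2-5 nt homologies; <2 is treated as no MH


@dataclass
class MicrohomologyAnnotation:
    mh_len: int
    mh_seq: str
    left_copy: tuple   # half-open ref interval of the 5' repeat copy
    right_copy: tuple  # half-open ref interval of the 3' repeat copy
    position_class: str | None = None  # set by classify_mh_position


def _common_prefix(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def find_microhomology(reference_seq: str, deletion: IndelCall) -> MicrohomologyAnnotation:
    """Maximal flanking repeat consistent with the deletion's equivalence interval.

    Requires a deletion of length >= 2 (1-bp deletions are never
    MH-classified).  Raises ``ValueError`` for out-of-bounds intervals.
    """
    if deletion.kind != "deletion" or deletion.length < 2:
        raise ValueError("microhomology is defined for deletions of length >= 2")
    L = deletion.length
    if deletion.ref_start < 0 or deletion.ref_start + L > len(reference_seq):
        raise ValueError("invalid deletion: interval out of bounds")
    d0, _ = _slide_range_deletion(reference_seq, deletion.ref_start, L)
    suffix = 0  # zero by construction at the left-aligned placement
    prefix = _common_prefix(reference_seq[d0:], reference_seq[d0 + L :])
    mh_len = min(suffix + prefix, L - 1)
    return MicrohomologyAnnotation(
        mh_len=mh_len,
        mh_seq=reference_seq[d0 : d0 + mh_len],
        left_copy=(d0, d0 + mh_len),
        right_copy=(d0 + L, d0 + L + mh_len),
    )


def _boundary_at_cut(deletion: IndelCall, reference_seq: str, cut_pos: int) -> bool:
    """Can some equivalent placement put a deletion boundary at the cut junction?"""
    lo, hi = _slide_range_deletion(reference_seq, deletion.ref_start, deletion.length)
    L = deletion.length
    return lo <= cut_pos <= hi or lo + L <= cut_pos <= hi + L


def classify_mh_position(
    ann: MicrohomologyAnnotation,
    deletion: IndelCall,
    site: TargetSite,
) -> str:
    """Assign mh_at_cut / mh_away / no_mh_end_at_cut / no_mh.

    A retained microhomology copy abuts the cut when some placement within
    the equivalence interval puts a deletion boundary exactly at ``cut_pos``
    (the surviving copy then sits immediately against the junction).
    """
    ref = site.working_seq
    at_cut = _boundary_at_cut(deletion, ref, site.cut_pos)
    if ann.mh_len >= MIN_MH_LEN:
        cls = "mh_at_cut" if at_cut else "mh_away"
    else:
        cls = "no_mh_end_at_cut" if at_cut else "no_mh"
    ann.position_class = cls
    return cls
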