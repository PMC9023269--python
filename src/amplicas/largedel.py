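"""Anchored large-deletion detection in long (CCS) amplicon reads.

Long on-target deletions (>0.5 kb) escape short-amplicon sequencing, so they
are detected in long-read circular consensus sequences (CCS) of a kb-scale
amplicon.  The detector locates two fixed 25-nt anchor sequences -- taken
from the 5' and 3' ends of the amplicon -- in each read, each tolerating 2
mismatches (92% identity) to absorb sequencing error, and compares the
anchor-to-anchor distance in the read with the distance in the reference.
A read whose distance is shortened and which no longer contains an intact
sgRNA target site (exact 23-nt protospacer+PAM by default) is called as
carrying a deletion; calls are binned cumulatively at >0.5, >1 and >2 kb.

Only reads in which both anchors are found enter the analyzed denominator.
Anchor matching is Hamming (substitutions only): the tolerance is defined
on a fixed-length 25-nt window.  The 5' anchor takes the leftmost and the
3' anchor the rightmost among minimal-mismatch hits, so the enclosed
distance is maximal and deletions are never inflated by a spurious inner
match.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .refmodel import TargetSite, reverse_complement

__all__ = [
    "AnchorSpec",
    "AnchorHit",
    "LargeDeletionCall",
    "anchors_from_reference",
    "find_anchor",
    "orient_read",
    "contains_intact_target",
    "detect_large_deletion",
    "tally_deletion_bins",
]

ANCHOR_LEN = 25
DEFAULT_MAX_MISMATCH = 2      # 2/25 = 92% identity
BIN_THRESHOLDS = {"gt500": 500, "gt1000": 1000, "gt2000": 2000}


@dataclass(frozen=True)
class AnchorSpec:
    anchor5: str
    anchor3: str
    ref_distance: int          # start-of-anchor5 to start-of-anchor3 in the reference
    max_mismatch: int = DEFAULT_MAX_MISMATCH

    def __post_init__(self):
        if len(self.anchor5) != ANCHOR_LEN or len(self.anchor3) != ANCHOR_LEN:
            raise ValueError(f"anchors must be {ANCHOR_LEN} nt")
        if self.ref_distance <= 0:
            raise ValueError("ref_distance must be positive")


@dataclass(frozen=True)
class AnchorHit:
    read_pos: int
    mismatches: int


@dataclass
class LargeDeletionCall:
    read_id: str
    orientation: str           # 'forward' | 'reverse-complement'
    read_distance: int
    delta: int                 # ref_distance - read_distance; positive = deletion
    target_intact: bool
    bins: frozenset = field(default_factory=frozenset)


def anchors_from_reference(reference_seq: str, max_mismatch: int = DEFAULT_MAX_MISMATCH) -> AnchorSpec:
    """Anchor spec from the amplicon ends: first and last 25 nt."""
    if len(reference_seq) < 2 * ANCHOR_LEN:
        raise ValueError("reference too short for end anchors")
    return AnchorSpec(
        anchor5=reference_seq[:ANCHOR_LEN],
        anchor3=reference_seq[-ANCHOR_LEN:],
        ref_distance=len(reference_seq) - ANCHOR_LEN,
        max_mismatch=max_mismatch,
    )


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _hamming_profile(read: str, anchor: str) -> np.ndarray:
    """Mismatch count of the anchor at every read offset (sliding Hamming scan)."""
    r = _encode(read)
    a = _encode(anchor)
    if len(r) < len(a):
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(r, len(a))
    return (windows != a).sum(axis=1)


def find_anchor(
    read: str,
    anchor: str,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    tie: str = "leftmost",
) -> AnchorHit | None:
    """Best anchor placement in the read, or ``None`` if none qualifies.

    Returns the offset with the fewest mismatches ``<= max_mismatch``; among
    ties, the smallest offset (``tie='leftmost'``, default) or largest
    (``tie='rightmost'``).
    """
    profile = _hamming_profile(read, anchor)
    if profile.size == 0:
        return None
    best = int(profile.min())
    if best > max_mismatch:
        return None
    hits = np.flatnonzero(profile == best)
    pos = int(hits[0] if tie == "leftmost" else hits[-1])
    return AnchorHit(read_pos=pos, mismatches=best)


def orient_read(read: str, spec: AnchorSpec) -> tuple[str, str] | None:
    """Orientation (as-is or reverse complement) in which anchor5 is found.

    If both orientations contain anchor5, the one with fewer total anchor
    mismatches (anchor5 + anchor3 where found) wins; ``None`` if neither
    orientation contains anchor5.
    """
    candidates = []
    for orientation, seq in (("forward", read), ("reverse-complement", reverse_complement(read))):
        h5 = find_anchor(seq, spec.anchor5, spec.max_mismatch)
        if h5 is None:
            continue
        h3 = find_anchor(seq, spec.anchor3, spec.max_mismatch, tie="rightmost")
        total_mm = h5.mismatches + (h3.mismatches if h3 else 0)
        candidates.append((total_mm, orientation, seq))
    if not candidates:
        return None
    candidates.sort(key=lambda c: c[0])
    _, orientation, seq = candidates[0]
    return seq, orientation


def contains_intact_target(
    oriented_read: str,
    site: TargetSite,
    allowed_mismatches: int = 0,
) -> bool:
    """Does the 23-nt protospacer+PAM occur in the read within the tolerance?"""
    target = site.target_with_pam
    if allowed_mismatches == 0:
        return target in oriented_read
    profile = _hamming_profile(oriented_read, target)
    return profile.size > 0 and int(profile.min()) <= allowed_mismatches


def detect_large_deletion(
    read: str,
    spec: AnchorSpec,
    site: TargetSite,
    min_delta: int = 1,
    read_id: str = "read",
    intact_mismatches: int = 0,
) -> LargeDeletionCall | str:
    """Anchor-distance deletion call for one CCS read.

    Returns a :class:`LargeDeletionCall`, or a status string:
    ``'no_anchors'`` (read excluded from the analyzed denominator),
    ``'intact'`` (sgRNA target still present), ``'unchanged'`` (distance
    within ``min_delta`` of the reference and target absent), or
    ``'anchor_order_violation'`` (anchor3 not downstream of anchor5).
    """
    oriented = orient_read(read, spec)
    if oriented is None:
        return "no_anchors"
    seq, orientation = oriented
    h5 = find_anchor(seq, spec.anchor5, spec.max_mismatch, tie="leftmost")
    h3 = find_anchor(seq, spec.anchor3, spec.max_mismatch, tie="rightmost")
    if h3 is None:
        return "no_anchors"
    if h3.read_pos <= h5.read_pos:
        return "anchor_order_violation"
    read_distance = h3.read_pos - h5.read_pos
    delta = spec.ref_distance - read_distance
    intact = contains_intact_target(seq, site, intact_mismatches)
    if intact:
        return "intact"
    if delta < min_delta:
        return "unchanged"
    bins = frozenset(
        name for name, thr in BIN_THRESHOLDS.items() if delta > thr
    )
    return LargeDeletionCall(
        read_id=read_id,
        orientation=orientation,
        read_distance=read_distance,
        delta=delta,
        target_intact=intact,
        bins=bins,
    )


def tally_deletion_bins(calls: list[LargeDeletionCall], n_analyzed: int) -> dict:
    """Cumulative bin counts over calls (denominator: reads with both anchors)."""
    return {
        "total_ccs": n_analyzed,
        "n_deletion_calls": len(calls),
        "n_gt500": sum(1 for c in calls if "gt500" in c.bins),
        "n_gt1000": sum(1 for c in calls if "gt1000" in c.bins),
        "n_gt2000": sum(1 for c in calls if "gt2000" in c.bins),
    }
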