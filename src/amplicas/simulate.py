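"""Synthetic amplicon reads with planted Cas9 editing outcomes.

The generator emulates the statistical structure of targeted amplicon
sequencing after Cas9 (or Cas9-polymerase fusion) treatment so that every
pipeline stage is exercisable with known ground truth:

* short reads carrying no edit, a 1-bp deletion at the cut, an MMEJ deletion
  between planted flanking microhomologies (2-5 nt; default deletion sizes
  8 and 11 nt with the microhomology at the cut, mirroring the dominant
  deletion peaks of Cas9 outcome spectra), a 1-3-nt templated insertion
  (duplication of the bases 5' of the cut), or a 1-3-nt non-templated
  insertion;
* long CCS-like reads from a kb-scale amplicon (default 4862 nt) with
  kb-scale deletions spanning the cut;
* i.i.d. per-base substitution sequencing error on top of either.

Outcome probabilities default to a mixture exercising all classes
(10% unedited, 20% 1-bp deletion, 30% MMEJ, 25% TIS, 15% random insertion);
short-read error defaults to 0.1% per base and CCS error to 0.5%.  Every
read carries a :class:`TruthRecord`, and identical seeds give identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .refmodel import TargetSite, locate_protospacer, tis_template

__all__ = [
    "MMEJPair",
    "OutcomeMix",
    "TruthRecord",
    "make_reference",
    "simulate_short_reads",
    "simulate_ccs_reads",
    "apply_sequencing_errors",
]

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
DEFAULT_SHORT_LENGTH = 240
DEFAULT_SITE_OFFSET = 100
DEFAULT_CCS_LENGTH = 4862
CCS_END_MARGIN = 75  # 25-nt anchor + 50 nt that deletions must not erode
AWAY_PAIR_OFFSET = 8  # start of away-from-cut MMEJ deletions, 3' of the cut


@dataclass(frozen=True)
class MMEJPair:
    """A planted flanking-repeat deletion: mh_len in 2..5, at-cut by default."""

    mh_len: int
    del_size: int
    at_cut: bool = True

    def __post_init__(self):
        if not 2 <= self.mh_len <= 5:
            raise ValueError("microhomology length must be 2..5 nt")
        if self.del_size <= self.mh_len:
            raise ValueError("deletion must be longer than the microhomology")


DEFAULT_MMEJ_PAIRS = (MMEJPair(2, 8), MMEJPair(3, 11))


@dataclass(frozen=True)
class OutcomeMix:
    """Per-read outcome probabilities and error model for short-read simulation."""

    p_unedited: float = 0.10
    p_del1: float = 0.20
    p_mmej: float = 0.30
    p_tis: float = 0.25
    p_ins_random: float = 0.15
    p_large_del: float = 0.0
    p_compound: float = 0.0    # mixed del+ins reads; off by default
    tis_k_weights: tuple = ((1, 0.90), (2, 0.06), (3, 0.04))
    mmej_pairs: tuple = DEFAULT_MMEJ_PAIRS
    large_del_size_range: tuple = (501, 3000)
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self):
        probs = self.class_probs
        if any(p < 0 for p in probs.values()):
            raise ValueError("probabilities must be non-negative")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError("outcome probabilities must sum to 1")
        lo, hi = self.large_del_size_range
        if self.p_large_del > 0 and lo <= 500:
            raise ValueError("large deletions must exceed 500 nt")

    @property
    def class_probs(self) -> dict:
        return {
            "unedited": self.p_unedited,
            "del1": self.p_del1,
            "mmej": self.p_mmej,
            "tis": self.p_tis,
            "ins_random": self.p_ins_random,
            "large_del": self.p_large_del,
            "compound": self.p_compound,
        }


@dataclass
class TruthRecord:
    read_id: str
    true_class: str
    true_del_size: int = 0
    true_ins_seq: str = ""
    true_is_TIS: bool = False
    true_mh_len: int = 0


class LayoutInfeasibleError(ValueError):
    """Planted reference elements collide and cannot coexist."""


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.choice(BASES, size=n)


def _decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def make_reference(
    length: int = DEFAULT_SHORT_LENGTH,
    site_offset: int = DEFAULT_SITE_OFFSET,
    protospacer: str = "random",
    mmej_pairs: tuple = DEFAULT_MMEJ_PAIRS,
    seed: int = 0,
    reference_id: str = "amplicon",
) -> tuple[str, TargetSite]:
    """Random amplicon with a planted protospacer+NGG and exact repeat pairs.

    The protospacer starts at ``site_offset`` (cut at ``site_offset + 17``).
    For each at-cut :class:`MMEJPair` ``(m, L)`` the bases at
    ``[cut+L, cut+L+m)`` are made to duplicate ``[cut, cut+m)`` and the
    flanking bases are set so the repeat length is exactly ``m``; deleting
    ``[cut, cut+L)`` then leaves one repeat copy abutting the cut junction.
    Deterministic under ``seed``; colliding elements raise
    :class:`LayoutInfeasibleError`.
    """
    if length < 30 or site_offset < 1 or site_offset + 23 > length:
        raise ValueError("reference too short for the requested site")
    rng = np.random.default_rng(seed)

    for _attempt in range(20):
        ref = _random_seq(rng, length)
        if protospacer == "random":
            proto = _decode(_random_seq(rng, 20))
        else:
            proto = protospacer.upper()
        pam = _decode(rng.choice(BASES, size=1)) + "GG"
        ref[site_offset : site_offset + 23] = np.frombuffer(
            (proto + pam).encode(), dtype=np.uint8
        )
        fixed = set(range(site_offset, site_offset + 23))
        cut = site_offset + 17

        assigned: dict[int, int] = {}
        forbidden: dict[int, set] = {}

        def fix(pos: int, base: int):
            if pos in fixed or (pos in assigned and assigned[pos] != base):
                raise LayoutInfeasibleError("layout infeasible: planted elements collide")
            assigned[pos] = base

        def forbid(pos: int, base: int):
            forbidden.setdefault(pos, set()).add(base)

        for pair in mmej_pairs:
            m, L = pair.mh_len, pair.del_size
            # away pairs start 8 nt 3' of the cut (past the PAM, in free
            # sequence): inside the editing window yet not slidable to the cut
            d = cut if pair.at_cut else cut + AWAY_PAIR_OFFSET
            if d < 1 or d + L + m + 1 > length:
                raise LayoutInfeasibleError("layout infeasible: repeat outside reference")
            for i in range(m):
                src = ref[d + i] if (d + i) in fixed or (d + i) not in assigned else assigned[d + i]
                fix(d + L + i, int(src))
            # terminators: pin the left-aligned placement and the exact mh length
            forbid(d + L - 1, int(ref[d - 1]))
            src_end = ref[d + m] if (d + m) not in assigned else assigned[d + m]
            forbid(d + L + m, int(src_end))

        try:
            for pos, base in assigned.items():
                if base in forbidden.get(pos, ()):
                    raise LayoutInfeasibleError("layout infeasible: conflicting constraints")
                ref[pos] = base
            for pos, banned in forbidden.items():
                if pos in assigned or pos in fixed:
                    if int(ref[pos]) in banned:
                        raise LayoutInfeasibleError("layout infeasible: conflicting constraints")
                    continue
                options = [b for b in BASES.tolist() if b not in banned]
                if not options:
                    raise LayoutInfeasibleError("layout infeasible: no base satisfies constraints")
                ref[pos] = options[int(rng.integers(len(options)))]
        except LayoutInfeasibleError:
            if protospacer != "random":
                raise
            continue

        ref_str = _decode(ref)
        try:
            site = locate_protospacer(ref_str, proto, reference_id=reference_id)
        except ValueError:
            if protospacer != "random":
                raise
            continue  # accidental second hit: redraw
        if site.strand == "+":
            return ref_str, site
    raise LayoutInfeasibleError("layout infeasible: could not place a unique site")


def apply_sequencing_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    """Independently substitute each base to a uniform different base."""
    if not 0.0 <= error_rate < 1.0 + 1e-12:
        raise ValueError("error rate must be in [0, 1]")
    if error_rate == 0.0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    mask = rng.random(arr.size) < error_rate
    n = int(mask.sum())
    if n:
        # shift by 1-3 positions in base order: always a different base
        idx = np.searchsorted(BASES, arr[mask])
        arr[mask] = BASES[(idx + rng.integers(1, 4, size=n)) % 4]
    return _decode(arr)


def _sample_tis_k(mix: OutcomeMix, rng: np.random.Generator) -> int:
    ks, ws = zip(*mix.tis_k_weights)
    w = np.asarray(ws, dtype=float)
    return int(rng.choice(ks, p=w / w.sum()))


def simulate_short_reads(
    site: TargetSite,
    mix: OutcomeMix | None = None,
    n: int = 1000,
    seed: int | None = None,
) -> tuple[list[tuple[str, str]], list[TruthRecord]]:
    """Simulate ``n`` full-amplicon short reads from the outcome mixture.

    Returns ``(reads, truths)`` where reads are ``(read_id, sequence)``.
    The seed defaults to ``mix.seed``; identical seeds give byte-identical
    output.
    """
    mix = mix or OutcomeMix()
    if mix.p_large_del > 0:
        raise ValueError("large deletions belong to simulate_ccs_reads")
    rng = np.random.default_rng(mix.seed if seed is None else seed)
    ref = site.working_seq
    cut = site.cut_pos

    labels = [k for k, p in mix.class_probs.items() if p > 0]
    probs = np.array([mix.class_probs[k] for k in labels])
    classes = rng.choice(labels, size=n, p=probs / probs.sum())

    tis_products = {
        k: ref[:cut] + tis_template(site, k) + ref[cut:] for k in (1, 2, 3)
    }

    reads, truths = [], []
    for i, klass in enumerate(classes):
        rid = f"read_{i:06d}"
        truth = TruthRecord(read_id=rid, true_class=str(klass))
        if klass == "unedited":
            seq = ref
        elif klass == "del1":
            seq = ref[: cut - 1] + ref[cut:]
            truth.true_del_size = 1
        elif klass == "mmej":
            pair = mix.mmej_pairs[int(rng.integers(len(mix.mmej_pairs)))]
            d = cut if pair.at_cut else cut + AWAY_PAIR_OFFSET
            seq = ref[:d] + ref[d + pair.del_size :]
            truth.true_del_size = pair.del_size
            truth.true_mh_len = pair.mh_len
        elif klass == "tis":
            k = _sample_tis_k(mix, rng)
            seq = tis_products[k]
            truth.true_ins_seq = tis_template(site, k)
            truth.true_is_TIS = True
        elif klass == "ins_random":
            k = _sample_tis_k(mix, rng)
            while True:
                ins = _decode(_random_seq(rng, k))
                seq = ref[:cut] + ins + ref[cut:]
                if seq != tis_products[k]:
                    break
            truth.true_ins_seq = ins
        elif klass == "compound":
            # 1-bp deletion at the cut plus a 3-bp insertion 8 nt downstream;
            # inserted bases avoid the junction neighbours so the two events
            # cannot collapse into a gap-free or single-gap alignment
            pool = [b for b in "ACGT" if b not in (ref[cut + 7], ref[cut + 8])]
            ins = "".join(rng.choice(pool, size=3))
            seq = ref[: cut - 1] + ref[cut : cut + 8] + ins + ref[cut + 8 :]
            truth.true_del_size = 1
            truth.true_ins_seq = ins
        else:  # pragma: no cover
            raise AssertionError(klass)
        seq = apply_sequencing_errors(seq, mix.error_rate, rng)
        reads.append((rid, seq))
        truths.append(truth)
    return reads, truths


def simulate_ccs_reads(
    reference_seq: str,
    site: TargetSite,
    p_large_del: float = 0.10,
    size_range: tuple = (501, 3000),
    n: int = 1000,
    error_rate: float = 0.005,
    seed: int = 0,
    random_orientation: bool = True,
) -> tuple[list[tuple[str, str]], list[TruthRecord]]:
    """Simulate CCS-like long reads with kb-scale deletions spanning the cut.

    With probability ``p_large_del`` a uniform-size segment from
    ``size_range`` is deleted, positioned uniformly among the placements
    that involve the cut and keep at least 50 nt beyond each 25-nt end
    anchor.  Substitution errors are applied at ``error_rate``; half of the
    reads are emitted reverse-complemented when ``random_orientation``.
    """
    from .refmodel import reverse_complement

    rng = np.random.default_rng(seed)
    cut = site.cut_pos
    lo_size, hi_size = size_range
    max_start_limit = len(reference_seq) - CCS_END_MARGIN
    if hi_size > len(reference_seq) - 2 * CCS_END_MARGIN:
        raise ValueError("infeasible deletion: size range exceeds the amplicon span")

    reads, truths = [], []
    for i in range(n):
        rid = f"ccs_{i:06d}"
        truth = TruthRecord(read_id=rid, true_class="unedited")
        seq = reference_seq
        if rng.random() < p_large_del:
            size = int(rng.integers(lo_size, hi_size + 1))
            start_lo = max(CCS_END_MARGIN, cut - size)
            start_hi = min(cut, max_start_limit - size)
            if start_hi < start_lo:
                raise ValueError("infeasible deletion: cannot span the cut")
            start = int(rng.integers(start_lo, start_hi + 1))
            seq = reference_seq[:start] + reference_seq[start + size :]
            truth.true_class = "large_del"
            truth.true_del_size = size
        seq = apply_sequencing_errors(seq, error_rate, rng)
        if random_orientation and rng.random() < 0.5:
            seq = reverse_complement(seq)
        reads.append((rid, seq))
        truths.append(truth)
    return reads, truths
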