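"""Amplicon reference model: protospacer/PAM geometry, cut sites and TIS templates.

SpCas9 cleaves 3 nt upstream of the NGG PAM, producing a blunt end or a
staggered end with a 1-3 nt 5' overhang (non-target strand cut 4, 5 or 6 nt
upstream of the PAM).  Fill-in of such an overhang duplicates the base(s)
immediately 5' of the blunt cut -- the templated-insertion (TIS) signature.

Coordinates are 0-based, half-open, on the top strand of the supplied
reference.  Cut positions denote junctions: the double-strand break falls
between ``cut_pos - 1`` and ``cut_pos``.  For a protospacer found on the
minus strand, analysis operates on the reverse-complemented reference so the
protospacer strand is always the working top strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "TargetSite",
    "TargetNotFoundError",
    "AmbiguousTargetError",
    "reverse_complement",
    "locate_protospacer",
    "tis_template",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# IUPAC nucleotide codes -> regex character class
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]",
    "B": "[CGT]", "D": "[AGT]", "H": "[ACT]", "V": "[ACG]",
    "N": "[ACGT]",
}


class TargetNotFoundError(ValueError):
    """Protospacer + PAM not present on either strand of the reference."""


class AmbiguousTargetError(ValueError):
    """Protospacer + PAM occurs more than once; the site cannot be resolved."""

    def __init__(self, hits):
        self.hits = list(hits)
        super().__init__(
            "ambiguous target: protospacer+PAM found at "
            + ", ".join(f"{strand}{pos}" for strand, pos in self.hits)
        )


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (alphabet A/C/G/T/N, case kept)."""
    if re.search("[^ACGTNacgtn]", seq):
        bad = re.search("[^ACGTNacgtn]", seq).group()
        raise ValueError(f"invalid base {bad!r} in sequence")
    return seq.translate(_COMPLEMENT)[::-1]


def _iupac_regex(pattern: str) -> re.Pattern:
    try:
        return re.compile("".join(_IUPAC[c] for c in pattern.upper()))
    except KeyError as e:
        raise ValueError(f"invalid IUPAC code {e.args[0]!r} in PAM pattern") from None


@dataclass(frozen=True)
class TargetSite:
    """One sgRNA target site on an amplicon reference.

    ``pam_start`` and ``cut_pos`` are top-strand coordinates of the working
    reference: for a minus-strand site they refer to the reverse-complemented
    reference (``working_seq``), so that the protospacer strand is always the
    top strand and a single geometry code path serves both orientations.
    """

    reference_id: str
    reference_seq: str    # reference as supplied
    protospacer: str      # 20 nt, protospacer strand
    pam: str              # 3 nt observed PAM on the protospacer strand
    strand: str           # '+' or '-': orientation of protospacer on the input
    pam_start: int        # 0-based start of PAM on the working (protospacer) strand
    cut_pos: int          # blunt DSB junction: between cut_pos-1 and cut_pos

    @property
    def working_seq(self) -> str:
        """Reference with the protospacer strand as top strand."""
        if self.strand == "+":
            return self.reference_seq
        return reverse_complement(self.reference_seq)

    @property
    def target_with_pam(self) -> str:
        """23-nt protospacer + PAM on the protospacer strand."""
        return self.protospacer + self.pam

    def __post_init__(self):
        seq = self.working_seq
        if seq[self.pam_start : self.pam_start + 3] != self.pam:
            raise ValueError("pam_start inconsistent with reference")
        if seq[self.pam_start - 20 : self.pam_start] != self.protospacer:
            raise ValueError("protospacer not immediately 5' of PAM")
        if self.cut_pos != self.pam_start - 3:
            raise ValueError("cut_pos must lie 3 nt upstream of the PAM")
        if not 0 <= self.cut_pos <= len(seq):
            raise ValueError("cut_pos outside reference")


def locate_protospacer(
    reference_seq: str,
    protospacer: str,
    pam_pattern: str = "NGG",
    reference_id: str = "ref",
) -> TargetSite:
    """Find the unique protospacer + PAM occurrence on either strand.

    Raises :class:`TargetNotFoundError` if absent and
    :class:`AmbiguousTargetError` if the 23-mer occurs more than once
    (hit coordinates are reported on the top strand of the input).
    """
    reference_seq = reference_seq.upper()
    protospacer = protospacer.upper()
    if len(protospacer) != 20:
        raise ValueError("protospacer must be 20 nt")
    if len(reference_seq) < 30:
        raise ValueError("reference too short")
    pam_re = _iupac_regex(pam_pattern)
    plen = len(pam_pattern)

    hits = []  # (strand, protospacer start on that strand's coordinates)
    for strand, seq in (("+", reference_seq), ("-", reverse_complement(reference_seq))):
        start = 0
        while (i := seq.find(protospacer, start)) != -1:
            pam_obs = seq[i + 20 : i + 20 + plen]
            if len(pam_obs) == plen and pam_re.fullmatch(pam_obs):
                hits.append((strand, i, pam_obs))
            start = i + 1

    if not hits:
        raise TargetNotFoundError("target not found: no protospacer+PAM match")
    if len(hits) > 1:
        raise AmbiguousTargetError((s, i) for s, i, _ in hits)

    strand, i, pam_obs = hits[0]
    return TargetSite(
        reference_id=reference_id,
        reference_seq=reference_seq,
        protospacer=protospacer,
        pam=pam_obs,
        strand=strand,
        pam_start=i + 20,
        cut_pos=i + 20 - 3,
    )


def tis_template(site: TargetSite, k: int) -> str:
    """Sequence duplicated by fill-in of a k-nt 5' overhang (k = 1..3).

    Returns the k bases immediately 5' of the blunt cut on the protospacer
    strand; for k=1 this is the single base 4 nt upstream of the PAM.
    """
    if not 1 <= k <= 3:
        raise ValueError("unsupported overhang length: k must be 1..3")
    return site.working_seq[site.cut_pos - k : site.cut_pos]
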