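# Methods

## Coordinate conventions and site geometry

All coordinates are 0-based, half-open, on the top strand of the working
reference; cut positions denote junctions between bases. When the
protospacer is found on the minus strand of the supplied amplicon, the
whole analysis runs on the reverse-complemented reference so that the
protospacer strand is always the working top strand; outputs record the
flip. This keeps a single geometry code path: the blunt SpCas9 cut is
always `cut = pam_start − 3`, and the k-nt TIS template is always
`ref[cut−k : cut]` (for k=1, the base 4 nt upstream of the PAM). The PAM
pattern is configurable IUPAC (default NGG); generality beyond SpCas9 is
cheap and changes nothing downstream.

## Alignment and variant normalization

Reads are aligned to the amplicon with an affine-gap semiglobal scheme
(free end gaps on the reference, so a read may cover any sub-interval of
the amplicon), delegated to Biopython's `PairwiseAligner`. Default scoring
is match +2, mismatch −4, gap open −10, gap extend −1, with the Biopython
gap convention (a length-L gap scores `open + (L−1)·extend`). These values
keep true 1–3-bp indels as gaps while leaving isolated sequencing errors
as mismatches rather than spurious indel pairs; they are configurable.
Each read is tried in both orientations and the higher-scoring one kept
(ties keep forward).

Among equal-score alignments the aligner's first traceback is accepted;
determinism and placement-independence come from the variant layer rather
than from tie-break rules inside the DP: every indel is reported
left-aligned together with its *equivalence interval*, the half-open range
of reference placements that yield the identical edited sequence
(insertions rotate their sequence as they slide). All downstream decisions
— editing-window overlap, TIS identity, microhomology, cut-abutment — are
made over equivalence intervals or by direct edited-string comparison, so
they cannot depend on where inside a repeat the aligner happened to put a
gap. The test suite checks alignment scores against an independent
three-state dynamic program and verifies round-trip reconstruction of
every read from its extracted variants.

## Outcome classification

Variants count as editing only if they overlap the window `cut ± 10` nt
(configurable). The window default is a compromise: it encloses the
deletion sizes that dominate Cas9 spectra at these loci (1, 8 and 11 nt at
the cut) while excluding distal PCR/sequencing artefacts. Class precedence
is: deletion + insertion → `mixed`; single 1-bp deletion → `del_1bp`;
deletions totalling >1 bp → `del_gt1bp`; insertion(s) only → `insertion`;
mismatches only → `substitution_only`; otherwise `unedited`. `mixed` is
tallied as its own class and included in the INDEL denominator, making
explicit a case that per-read outcome tools leave undocumented.

TIS calling is exact: a k-bp insertion (k ≤ 3) is TIS iff applying it to
the reference reproduces the string obtained by inserting the full k-nt
template at the cut junction. Partial template matches are non-TIS.
Profiles report class percentages over all INDEL reads and 1-bp TIS as a
percentage of all insertion reads (the convention used when fusions shift
total insertion frequencies); percentages with zero denominators are
reported as missing, not zero.

The substitution rate is read-based, not base-based: the percentage of
reads with ≥1 mismatch inside `cut ± 20` nt, over all reads covering that
window — reads with indels stay in the denominator. This follows the
reported convention of substitution percentages "over total reads".

## Microhomology

For a left-aligned deletion `[d, d+L)` the annotation is the longest
common prefix of `ref[d:]` and `ref[d+L:]` (the common suffix term is zero
once left-aligned), capped at `L−1` to avoid degenerate annotation of
deletions inside perfect repeats. This equals the size of the deletion's
sliding range, so it is invariant to placement; the suite verifies it
exhaustively against a brute-force placement scan. Position classes use a
2-nt minimum (the MMEJ-relevant homology range being 2–5 nt): `mh_at_cut`
when some equivalent placement puts a deletion boundary exactly at the cut
junction (the retained repeat copy then abuts the junction), `mh_away`
otherwise; deletions without microhomology split into `no_mh_end_at_cut` /
`no_mh` by the same boundary test. 1-bp deletions are never MH-classified.

## Anchored large-deletion detection

Each CCS read is oriented by searching for the 25-nt 5′ anchor in both
strands, then both anchors are located by a sliding Hamming scan
(vectorized over all offsets), each tolerating 2 mismatches — i.e. 92%
identity on a fixed 25-nt window. Matching is substitution-only by design:
the tolerance is defined on a fixed-length window, and at CCS-like error
rates (0.5% per base) the chance of ≥3 errors in a 25-mer is ≈2×10⁻⁵, so
anchor loss is negligible. The 5′ anchor takes the leftmost and the 3′
anchor the rightmost minimal-mismatch hit, maximizing the enclosed
distance so spurious inner matches can never inflate a deletion. A read is
called deleted iff its anchor distance shrank by ≥ `min_delta` (default
1 nt, the literal "distance differed" rule) *and* it lacks an intact
target site — by default an exact 23-nt protospacer+PAM match, the
strictest reading of "intact" (configurable). Reads missing either anchor
are excluded from the analyzed denominator. Bins at >0.5/>1/>2 kb are
cumulative; sub-0.5-kb calls remain in the per-read table so either
reading of "reads with deletions" is recoverable.

## Statistics

Chi-square tests are Pearson without Yates correction by default (a
`--yates` flag applies it); for large-deletion tables the 2×2
deletion-vs-no-deletion per treatment arm is the canonical comparison.
The t-test reconstructs group variances from SEMs (`s² = n·sem²`) and uses
the pooled-variance statistic with `n_a + n_b − 2` df. Both p-values are
computed by in-package special functions — the regularized incomplete
gamma Q(df/2, x/2) via series/continued fraction and the regularized
incomplete beta via the Lentz continued fraction — validated against
scipy to 1e-8 relative in the suite. Degenerate inputs are handled
explicitly: zero marginals raise; two zero-SEM groups give p=1 (equal
means) or p=0 with a warning (unequal).

## Synthetic data

The generator plants a protospacer+NGG in a random amplicon (240 nt for
short-read mode, 4862 nt for CCS mode, cut near the middle) and constructs
reads by applying exactly one event per read: nothing; deletion of the
base 5′ of the cut; an MMEJ deletion that removes `[cut, cut+L)` between a
planted exact repeat (defaults: mh 2 with L=8 and mh 3 with L=11, the
repeat copy abutting the cut — mirroring the dominant 8/11-nt at-cut
deletion peaks of Cas9 spectra); insertion of the k-nt TIS template at the
cut (k weighted 90/6/4% for 1/2/3 bp, since multi-bp TIS are rare); or
insertion of k random bases resampled until the product differs from the
TIS product. Flanking bases around planted repeats are constrained so the
microhomology length is exact and the deletion's left-aligned placement is
at the cut; infeasible layouts raise rather than silently overlap. An
optional compound class (off by default) adds del+ins reads to exercise
the `mixed` classification. Substitution errors are i.i.d. uniform-base
(default 0.1% short reads, 0.5% CCS); CCS deletions are uniform in size
(default 501–3000 nt), positioned uniformly among placements that involve
the cut and keep ≥50 nt beyond each anchor, and reads are emitted in
random orientation.

What the generator does *not* emulate: indel sequencing errors (available
behind the substitution-only default as a deliberate omission — they are
the known failure mode of Hamming anchors), PCR chimeras and amplification
bias, base-quality structure, paired-end artefacts, and multi-event
alleles beyond the compound flag. Passing closed-loop tests therefore
demonstrates correctness of the classification and detection logic under
a clean error model, not robustness to every real-data artefact.

## Problem sizes and numerical choices

Closed-loop classification is checked at 5000 reads (zero error, exact
label match required), mixture recovery at 10 000 reads and 0.1% error
(tolerance 3 binomial SE per class), large-deletion detection at 1000
CCS reads (exact tally at zero error; anchor retention and zero false
calls at 0.5%), alignment against the DP oracle at 200 pairs ≤80 nt, and
special functions at 1000 random inputs (1e-8 relative). These sizes give
comfortable statistical power while keeping the whole suite around a
minute of compute. Percentage invariants (class percentages summing to
100) are asserted to ±0.01 to absorb float rounding.

## Known limitations

Anchor matching cannot compensate indel sequencing errors between anchors
(delta would shift by the net indel length); an edit-distance mode would
lift this at some cost. The `mixed` class depends on the aligner calling
both events as gaps, which for closely spaced, length-compensating
del+ins pairs can legitimately collapse into substitutions. Insertions are
only detected as large events through target-site loss, not anchor
distance growth (distance-increased reads are tabulated but not analyzed).
Quality scores are ignored throughout; inputs are assumed to be
pre-trimmed amplicon reads.
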