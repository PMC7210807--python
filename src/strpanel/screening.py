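"""Candidate-STR screening filters and fragment-size to allele-name conversion.

Panel candidates are drawn from a genome-wide STR annotation (locus id,
scaffold, position, motif, reference repeat count) joined with diploid repeat
calls from a handful of re-sequenced individuals.  A candidate is retained
when

1. the motif is a tetra- or pentanucleotide (longer repeat units type more
   cleanly on capillary electrophoresis and stutter less),
2. the reference genome carries 10 to 20 repeat units (inclusive; long enough
   to be polymorphic, short enough to amplify reliably), and
3. the call set shows 3 to 6 distinct alleles across the re-sequenced
   individuals (polymorphic but not hypermutable).

Rejections carry the first failed criterion as a reason code, in the order
``motif``, ``repeat_count``, ``allele_count``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .genotypes import AlleleName, Locus, StrPanelError

REASON_MOTIF = "motif"
REASON_REPEATS = "repeat_count"
REASON_ALLELES = "allele_count"


class OrphanCallsError(StrPanelError):
    """Call records referencing loci absent from the annotation table."""


class OffLadderError(StrPanelError):
    """A fragment size matching no allele on the locus ladder."""


@dataclass(frozen=True)
class StrAnnotation:
    """One reference-genome STR annotation row (1-based start position).

    ``ref_repeat_count`` may be fractional (e.g. 12.2 copies), as repeat
    finders report partial trailing units.
    """

    locus_id: str
    scaffold: str
    position: int
    motif: str
    ref_repeat_count: float

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"{self.locus_id}: position must be 1-based, got {self.position}")
        if len(self.motif) < 1:
            raise ValueError(f"{self.locus_id}: empty motif")


@dataclass
class MultiSampleCalls:
    """Diploid repeat-number calls at one locus across re-sequenced samples."""

    locus_id: str
    calls: dict[str, tuple[float, float]] = field(default_factory=dict)

    def distinct_alleles(self) -> set[float]:
        out: set[float] = set()
        for a, b in self.calls.values():
            out.add(a)
            out.add(b)
        return out


@dataclass
class ScreeningOutcome:
    retained: list[str]
    rejected: dict[str, str]  # locus_id -> first failed criterion

    def reason_counts(self) -> Counter:
        return Counter(self.rejected.values())


def filter_candidates(
    annotations: Sequence[StrAnnotation],
    calls: Sequence[MultiSampleCalls],
    motif_lengths: tuple[int, ...] = (4, 5),
    repeat_range: tuple[float, float] = (10.0, 20.0),
    allele_range: tuple[int, int] = (3, 6),
) -> ScreeningOutcome:
    """Apply the three screening criteria; order-independent and idempotent.

    Both repeat-range bounds are inclusive; fractional reference repeat counts
    are compared by numeric value.  Loci with no call record count zero
    alleles and fail the allele-count criterion.
    """
    ann_by_id = {a.locus_id: a for a in annotations}
    calls_by_id = {c.locus_id: c for c in calls}
    orphans = sorted(set(calls_by_id) - set(ann_by_id))
    if orphans:
        raise OrphanCallsError(f"calls without annotation: {', '.join(orphans)}")
    retained: list[str] = []
    rejected: dict[str, str] = {}
    for locus_id in sorted(ann_by_id):
        ann = ann_by_id[locus_id]
        if len(ann.motif) not in motif_lengths:
            rejected[locus_id] = REASON_MOTIF
            continue
        if not repeat_range[0] <= ann.ref_repeat_count <= repeat_range[1]:
            rejected[locus_id] = REASON_REPEATS
            continue
        call = calls_by_id.get(locus_id)
        n_alleles = len(call.distinct_alleles()) if call else 0
        if not allele_range[0] <= n_alleles <= allele_range[1]:
            rejected[locus_id] = REASON_ALLELES
            continue
        retained.append(locus_id)
    return ScreeningOutcome(retained, rejected)


def allele_number_histogram(calls: Sequence[MultiSampleCalls]) -> dict[int, float]:
    """Proportion of loci by distinct-allele count; proportions sum to 1."""
    if not calls:
        raise ValueError("no call records")
    counts = Counter(len(c.distinct_alleles()) for c in calls)
    total = sum(counts.values())
    return {k: counts[k] / total for k in sorted(counts)}


@dataclass
class SizeLadder:
    """Maps fragment sizes (bp) to repeat-based allele names for one locus.

    The ladder is anchored at one sequenced allele of known size; every other
    allele sits at ``anchor_size + (repeats - anchor.repeats) * step +
    (microvariant - anchor.microvariant)`` bp, where ``step`` is the motif
    length.  ``size_range`` (defaulting to the locus's) bounds the callable
    window; sizes outside it are off-ladder.
    """

    locus: Locus
    anchor: AlleleName
    anchor_size_bp: float
    step_bp: Optional[int] = None
    size_range: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.step_bp is None:
            if self.locus.motif_length is None:
                raise ValueError(f"{self.locus.name}: ladder needs step_bp or a locus motif")
            self.step_bp = self.locus.motif_length
        if self.size_range is None:
            self.size_range = self.locus.size_range

    def size_of(self, allele: AlleleName) -> float:
        d_bp = (allele.repeats * self.step_bp + allele.microvariant) - (
            self.anchor.repeats * self.step_bp + self.anchor.microvariant
        )
        return self.anchor_size_bp + d_bp


def size_to_allele(
    fragment_bp: float, ladder: SizeLadder, tol_bp: float = 0.5
) -> AlleleName:
    """Name a fragment by its position on the ladder.

    The fragment is snapped to the nearest 1-bp grid point of the ladder;
    offsets that are not whole motif steps become microvariant names (e.g.
    one step plus 2 bp on a tetranucleotide ladder is ``.2``).  A residual
    above ``tol_bp`` or a size outside the ladder window raises
    :class:`OffLadderError` (the "off-range peak" situation).
    """
    step = ladder.step_bp
    lo, hi = ladder.size_range if ladder.size_range else (None, None)
    if lo is not None and not (lo - tol_bp <= fragment_bp <= hi + tol_bp):
        raise OffLadderError(
            f"{ladder.locus.name}: fragment {fragment_bp} bp outside ladder "
            f"window [{lo}, {hi}]"
        )
    anchor_bp = ladder.anchor.repeats * step + ladder.anchor.microvariant
    target = anchor_bp + (fragment_bp - ladder.anchor_size_bp)
    nearest = round(target)
    if abs(target - nearest) > tol_bp:
        raise OffLadderError(
            f"{ladder.locus.name}: fragment {fragment_bp} bp is {abs(target - nearest):.2f} bp "
            f"off the allelic grid (tolerance {tol_bp})"
        )
    if nearest < 0:
        raise OffLadderError(f"{ladder.locus.name}: fragment below ladder origin")
    repeats, microvariant = divmod(int(nearest), step)
    allele = AlleleName(repeats, microvariant)
    ladder.locus.validate_allele(allele)
    return allele
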