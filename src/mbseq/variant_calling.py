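"""Allele frequencies, variant calls and artifact filtering.

Calls are made from a :class:`~mbseq.barcode_consensus.Pileup` of either
arm. The MBS arm counts consensus families, the raw arm counts reads; in
both arms the allele frequency (percent) of an alternate allele at a
position is ``100 * alt_support / depth`` with the same unit in numerator
and denominator. The detection threshold for low-frequency variants is a
0.5% allele frequency, with a minimum alternate support of 3 units so a
bare percentage at low depth cannot call single-molecule noise.

Classification follows the clinical PCR-clamp assay: exon 19 deletions,
L858R, L861Q, T790M and G719A/S/C are the *common* EGFR mutations the
clamp detects; every other coding call in the panel footprint is
*uncommon*. A sample carrying at least one common and one uncommon call is
a *compound* sample. Recurrent cross-sample calls — present in strictly
more than half of a cohort's call sets — are treated as systematic
sequencing artifacts and removed before any comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .barcode_consensus import BASE_CODES, GAP, Pileup
from .synthetic_data import PanelDesign, Variant

__all__ = [
    "VariantCall",
    "CallSet",
    "COMMON_MUTATIONS",
    "allele_frequency",
    "call_variants",
    "classify",
    "filter_systematic",
    "compound_status",
    "af_difference",
    "write_callset_tsv",
    "read_callset_tsv",
    "write_vcf",
]

#: labels detectable by the clinical PCR-clamp assay
COMMON_MUTATIONS = frozenset(
    {"exon19del", "L858R", "L861Q", "T790M", "G719A", "G719S", "G719C"}
)

VariantKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class VariantCall:
    variant: Variant
    alt_support: int
    depth: int
    allele_frequency: float  # percent, one decimal
    arm: str  # "MBS" | "raw"
    classification: str  # "common" | "uncommon" | "artifact-filtered"

    def __post_init__(self) -> None:
        if not 0 <= self.alt_support <= self.depth:
            raise ValueError("alt_support must lie in [0, depth]")

    @property
    def key(self) -> VariantKey:
        return self.variant.key


@dataclass
class CallSet:
    """All calls for one sample on one arm, with bookkeeping tallies."""

    sample_id: str
    arm: str
    calls: dict[VariantKey, VariantCall] = field(default_factory=dict)
    unassigned_reads: int = 0
    rejected_families: int = 0

    def add(self, call: VariantCall) -> None:
        if call.key in self.calls:
            raise ValueError(f"duplicate call for {call.key}")
        self.calls[call.key] = call

    def keys(self) -> set[VariantKey]:
        return set(self.calls)

    def labels(self) -> set[str]:
        return {c.variant.label for c in self.calls.values() if c.variant.label}


def allele_frequency(alt_support: int, depth: int) -> float:
    """Percent allele frequency ``100 * alt_support / depth``, one decimal.

    Zero depth is a no-coverage signal and raises ``ValueError``.
    """
    if depth <= 0:
        raise ValueError("no coverage: depth must be positive")
    if not 0 <= alt_support <= depth:
        raise ValueError("alt_support must lie in [0, depth]")
    return round(100.0 * alt_support / depth, 1)


def classify(variant: Variant, panel: PanelDesign) -> str:
    """``common`` iff the call matches the clamp-detectable hotspot list.

    Exon 19 deletions are matched as a class: any catalogued in-frame
    deletion overlapping the exon-19 hotspot window counts. Variants
    outside the panel footprint raise ``ValueError``.
    """
    if panel.amplicon_at(variant.contig, variant.pos) is None:
        raise ValueError(f"variant at {variant.contig}:{variant.pos} outside panel footprint")
    label = variant.label or panel.label_of(variant.key)
    if label in COMMON_MUTATIONS:
        return "common"
    if variant.is_deletion:
        for cat_label, cat in panel.catalog.items():
            if cat_label in COMMON_MUTATIONS and cat.is_deletion:
                cat_span = range(cat.pos, cat.pos + len(cat.ref))
                span = range(variant.pos, variant.pos + len(variant.ref))
                if set(cat_span) & set(span):
                    return "common"
    return "uncommon"


def call_variants(
    pileup: Pileup,
    panel: PanelDesign,
    sample_id: str = "sample",
    min_af: float = 0.5,
    min_alt_support: int = 3,
    unassigned_reads: int = 0,
    rejected_families: int = 0,
) -> CallSet:
    """Call every non-reference allele at or above the detection threshold.

    A call requires allele frequency >= ``min_af`` percent (boundary
    inclusive) *and* alternate support >= ``min_alt_support`` units.
    Deleted-base counts at a catalogued deletion hotspot are aggregated
    into that catalogued deletion; stray deleted bases become single-base
    anchored deletions. The arm is taken from the pileup unit.
    """
    arm = "MBS" if pileup.unit == "family" else "raw"
    callset = CallSet(
        sample_id=sample_id,
        arm=arm,
        unassigned_reads=unassigned_reads,
        rejected_families=rejected_families,
    )
    gap_row = int(np.nonzero(BASE_CODES == GAP)[0][0])

    for amplicon_name, counts in pileup.counts.items():
        amplicon = panel.amplicon(amplicon_name)
        ref_arr = np.frombuffer(amplicon.sequence.encode(), dtype=np.uint8)
        depth = counts.sum(axis=0)

        # catalogued deletions first: uniform '-' support across the window
        deletion_cols: set[int] = set()
        for hotspot in panel.deletion_hotspots(amplicon):
            anchor = hotspot.pos - amplicon.start
            dlen = len(hotspot.ref) - len(hotspot.alt)
            window = counts[gap_row, anchor + 1 : anchor + 1 + dlen]
            support = int(window.min()) if window.size else 0
            if support == 0:
                continue
            deletion_cols.update(range(anchor + 1, anchor + 1 + dlen))
            d = int(depth[anchor + 1])
            if d > 0 and support >= min_alt_support and 100.0 * support / d >= min_af - 1e-12:
                callset.add(
                    VariantCall(
                        variant=hotspot,
                        alt_support=support,
                        depth=d,
                        allele_frequency=allele_frequency(support, d),
                        arm=arm,
                        classification=classify(hotspot, panel),
                    )
                )

        for row, code in enumerate(BASE_CODES):
            is_gap = code == GAP
            alt_cols = np.nonzero(
                (counts[row] >= min_alt_support)
                & (counts[row] * 100.0 >= (min_af - 1e-12) * depth)
                & (depth > 0)
                & (ref_arr != code)
            )[0]
            for col in alt_cols:
                if is_gap and int(col) in deletion_cols:
                    continue  # already aggregated into the catalogued deletion
                pos = amplicon.start + int(col)
                if is_gap:
                    if col == 0:
                        continue  # cannot anchor a deletion at the amplicon edge
                    variant = Variant(
                        amplicon.contig,
                        pos - 1,
                        amplicon.sequence[col - 1 : col + 1],
                        amplicon.sequence[col - 1],
                        None,
                    )
                else:
                    key = (amplicon.contig, pos, chr(ref_arr[col]), chr(code))
                    variant = Variant(
                        amplicon.contig,
                        pos,
                        chr(ref_arr[col]),
                        chr(code),
                        panel.label_of(key),
                    )
                support = int(counts[row, col])
                d = int(depth[col])
                callset.add(
                    VariantCall(
                        variant=variant,
                        alt_support=support,
                        depth=d,
                        allele_frequency=allele_frequency(support, d),
                        arm=arm,
                        classification=classify(variant, panel),
                    )
                )
    return callset


def filter_systematic(
    callsets: list[CallSet],
) -> tuple[list[CallSet], list[VariantKey]]:
    """Remove systematic artifacts shared by more than half of the cohort.

    A variant key present in *strictly* more than half of the call sets is
    removed from all of them and reported; the filter runs before any
    cross-arm or replicate comparison. Applying it twice is a no-op.
    """
    if len(callsets) < 2:
        raise ValueError("systematic filtering needs at least 2 call sets")
    n = len(callsets)
    counts: dict[VariantKey, int] = {}
    for cs in callsets:
        for key in cs.calls:
            counts[key] = counts.get(key, 0) + 1
    artifacts = sorted(key for key, c in counts.items() if c * 2 > n)
    filtered = [
        CallSet(
            sample_id=cs.sample_id,
            arm=cs.arm,
            calls={k: v for k, v in cs.calls.items() if k not in set(artifacts)},
            unassigned_reads=cs.unassigned_reads,
            rejected_families=cs.rejected_families,
        )
        for cs in callsets
    ]
    return filtered, artifacts


def compound_status(callset: CallSet) -> str:
    """``compound`` iff the sample keeps >=1 common and >=1 uncommon call."""
    classes = {c.classification for c in callset.calls.values()}
    return "compound" if {"common", "uncommon"} <= classes else "single"


def af_difference(common_af: float, uncommon_af: float) -> float:
    """Absolute difference of the two allele frequencies (percent).

    Rounded to two decimals so sub-percent differences between almost
    identical common/uncommon pairs (e.g. 6.56 vs 6.8) stay visible.
    """
    for af in (common_af, uncommon_af):
        if not 0.0 <= af <= 100.0:
            raise ValueError("allele frequencies must lie in [0, 100]")
    return round(abs(uncommon_af - common_af), 2)


# ---------------------------------------------------------------------------
# Report output
# ---------------------------------------------------------------------------

_TSV_HEADER = (
    "sample_id\tarm\tcontig\tpos\tref\talt\tlabel\talt_support\tdepth"
    "\taf_percent\tclass\tflags\n"
)


def write_callset_tsv(callset: CallSet, path: str | Path) -> None:
    """Per-sample variant TSV; positions are 1-based in this report."""
    with open(path, "w") as out:
        out.write(_TSV_HEADER)
        for call in sorted(callset.calls.values(), key=lambda c: c.key):
            v = call.variant
            out.write(
                f"{callset.sample_id}\t{call.arm}\t{v.contig}\t{v.pos + 1}\t{v.ref}"
                f"\t{v.alt}\t{v.label or '.'}\t{call.alt_support}\t{call.depth}"
                f"\t{call.allele_frequency:.1f}\t{call.classification}\t.\n"
            )


def read_callset_tsv(path: str | Path) -> CallSet:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != _TSV_HEADER.rstrip("\n"):
        raise ValueError(f"{path}: not a call-set TSV")
    callset: CallSet | None = None
    for line in lines[1:]:
        (sample_id, arm, contig, pos, ref, alt, label, alt_support, depth,
         af, cls, _flags) = line.split("\t")
        if callset is None:
            callset = CallSet(sample_id=sample_id, arm=arm)
        callset.add(
            VariantCall(
                variant=Variant(contig, int(pos) - 1, ref, alt,
                                None if label == "." else label),
                alt_support=int(alt_support),
                depth=int(depth),
                allele_frequency=float(af),
                arm=arm,
                classification=cls,
            )
        )
    if callset is None:
        raise ValueError(f"{path}: empty call-set TSV")
    return callset


def write_vcf(callset: CallSet, path: str | Path, panel: PanelDesign) -> None:
    """Minimal VCF-dialect output (fixed columns; INFO keys AF/DP/ARM)."""
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write(f"##source=mbseq\n")
        for a in panel.amplicons:
            out.write(f"##amplicon=<ID={a.name},start={a.start + 1},end={a.end}>\n")
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for call in sorted(callset.calls.values(), key=lambda c: c.key):
            v = call.variant
            out.write(
                f"{v.contig}\t{v.pos + 1}\t{v.label or '.'}\t{v.ref}\t{v.alt}\t.\t"
                f"PASS\tAF={call.allele_frequency:.1f};DP={call.depth};ARM={call.arm}\n"
            )
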