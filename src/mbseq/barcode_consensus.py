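"""Molecular-barcode (UMI) consensus calling for amplicon reads.

The four-step barcode analysis: reads are (1) tagged with molecular
barcodes at library preparation (simulated upstream), (2) aligned to
amplicon coordinates, (3) grouped into molecular families by identical
barcode, and (4) consolidated to one consensus read per barcode, which
removes PCR and sequencing errors private to a minority of the family.
The "without MBS" comparison arm is a plain read pileup that skips steps
3-4 and therefore retains those errors.

Aligned reads are represented as reference-projected base vectors over the
amplicon: one ``uint8`` per reference position holding the read base,
``-`` for a base deleted relative to the reference, ``N`` for an ambiguous
position (mate disagreement or failed consensus vote), and 0 where the
read does not cover the position. This representation makes family
consensus a column-wise majority vote and lets whole libraries be
consolidated with a handful of vectorised scatter-adds.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .synthetic_data import PanelDesign, TaggedReadPair, revcomp

__all__ = [
    "AlignedRead",
    "MolecularFamily",
    "ConsensusSequence",
    "AssignmentResult",
    "Pileup",
    "assign_reads",
    "group_families",
    "consensus",
    "consensus_families",
    "raw_pileup",
    "consensus_pileup",
    "write_family_table",
]

# base codes used in projected read vectors; voting alphabet is ACGT-
BASE_CODES = np.frombuffer(b"ACGT-", dtype=np.uint8)
GAP = ord("-")
AMBIGUOUS = ord("N")
UNCOVERED = 0

_ANCHOR_K = 16  # seed length for amplicon assignment


@dataclass
class AlignedRead:
    """A merged read pair projected onto its amplicon's coordinates."""

    read_id: str
    barcode: str
    amplicon: str
    bases: np.ndarray  # uint8, length == amplicon length
    mismatches: int
    aligned_length: int

    @property
    def offset(self) -> int:
        """0-based start of the covered span within the amplicon."""
        covered = np.nonzero(self.bases != UNCOVERED)[0]
        return int(covered[0]) if covered.size else 0


@dataclass
class MolecularFamily:
    """All reads sharing one (barcode, amplicon): the consensus unit."""

    barcode: str
    amplicon: str
    members: list[AlignedRead]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ConsensusSequence:
    """One consensus read per retained molecular family."""

    barcode: str
    amplicon: str
    bases: np.ndarray  # uint8; N where the vote failed, 0 where uncovered
    family_size: int
    agreement: np.ndarray  # winning-base fraction per covered position


@dataclass
class AssignmentResult:
    reads: list[AlignedRead]
    unassigned: int


@dataclass
class Pileup:
    """Per-amplicon base counts: rows follow ``BASE_CODES`` (A, C, G, T, -).

    ``unit`` records what one count means: a consensus family for the MBS
    arm, a raw read for the comparison arm.
    """

    counts: dict[str, np.ndarray]
    unit: str

    def depth(self, amplicon: str) -> np.ndarray:
        return self.counts[amplicon].sum(axis=0)


# ---------------------------------------------------------------------------
# Step 2: alignment (anchor-verify with sliding fallback)
# ---------------------------------------------------------------------------


class _PanelIndex:
    """Precomputed per-amplicon arrays and k-mer anchors for assignment."""

    def __init__(self, panel: PanelDesign):
        if not panel.amplicons:
            raise ValueError("panel has no amplicons")
        self.panel = panel
        self.seq: dict[str, np.ndarray] = {}
        self.prefix: dict[str, list[str]] = defaultdict(list)
        self.suffix: dict[str, list[str]] = defaultdict(list)
        # deletion hotspots: (anchor offset, deleted length, alt-seq array)
        self.hotspots: dict[str, list[tuple[int, int, np.ndarray]]] = {}
        for a in panel.amplicons:
            arr = np.frombuffer(a.sequence.encode(), dtype=np.uint8)
            self.seq[a.name] = arr
            self.prefix[a.sequence[:_ANCHOR_K]].append(a.name)
            self.suffix[a.sequence[-_ANCHOR_K:]].append(a.name)
            spots = []
            for v in panel.deletion_hotspots(a):
                anchor = v.pos - a.start
                dlen = len(v.ref) - len(v.alt)
                alt = np.concatenate([arr[: anchor + 1], arr[anchor + 1 + dlen :]])
                spots.append((anchor, dlen, alt))
            self.hotspots[a.name] = spots


def _mm(read: np.ndarray, ref: np.ndarray, offset: int) -> int:
    """Mismatches of ``read`` placed at ``offset`` (inf if it overhangs)."""
    if offset < 0 or offset + read.size > ref.size:
        return 10**9
    return int((read != ref[offset : offset + read.size]).sum())


def _best_sliding(read: np.ndarray, ref: np.ndarray) -> tuple[int, int]:
    """Exhaustive ungapped placement: (best mismatches, best offset)."""
    best = (10**9, 0)
    for offset in range(ref.size - read.size + 1):
        mm = _mm(read, ref, offset)
        if mm < best[0]:
            best = (mm, offset)
            if mm == 0:
                break
    return best


def _project_gapless(length: int, a1, o1, a2, o2) -> np.ndarray:
    """Merge two gapless mates into one reference-projected vector."""
    p1 = np.full(length, UNCOVERED, dtype=np.uint8)
    p1[o1 : o1 + a1.size] = a1
    p2 = np.full(length, UNCOVERED, dtype=np.uint8)
    p2[o2 : o2 + a2.size] = a2
    return _merge(p1, p2)


def _merge(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    out = np.where(p1 == UNCOVERED, p2, p1)
    both = (p1 != UNCOVERED) & (p2 != UNCOVERED)
    out[both & (p1 != p2)] = AMBIGUOUS
    return out


def _project_gapped(
    length: int, anchor: int, dlen: int, mate: np.ndarray, alt_offset: int
) -> np.ndarray:
    """Project a mate aligned to the deletion haplotype onto ref coords.

    Alt coordinate j maps to reference j for j <= anchor and j + dlen
    beyond; the deleted reference window is marked ``-`` when the mate
    spans the junction with at least one base on each side.
    """
    proj = np.full(length, UNCOVERED, dtype=np.uint8)
    start, stop = alt_offset, alt_offset + mate.size
    left = min(stop, anchor + 1) - start
    if left > 0:
        proj[start : start + left] = mate[:left]
    right = stop - max(start, anchor + 1)
    if right > 0:
        ref_from = max(start, anchor + 1) + dlen
        proj[ref_from : ref_from + right] = mate[mate.size - right :]
    if start <= anchor and stop > anchor + 1:  # spans the junction
        proj[anchor + 1 : anchor + 1 + dlen] = GAP
    return proj


def assign_reads(
    pairs: list[TaggedReadPair],
    panel: PanelDesign,
    max_mismatch_frac: float = 0.2,
) -> AssignmentResult:
    """Assign read pairs to amplicons and merge mates into aligned records.

    Amplicon reads are primer-anchored, so mate 1 is verified at the
    amplicon start and mate 2 at the amplicon end; candidate amplicons
    come from exact ``16``-mer anchors with an exhaustive sliding-placement
    fallback when no anchor matches. A gapped second pass at catalogued
    deletion hotspots (the exon-19 deletion) rescues reads the ungapped
    placement cannot explain. Pairs whose best placement still mismatches
    more than ``max_mismatch_frac`` of aligned bases are dropped and
    counted. Overlapping mate positions that disagree become ``N``.
    """
    index = _PanelIndex(panel)
    all_names = [a.name for a in panel.amplicons]
    aligned: list[AlignedRead] = []
    unassigned = 0

    for pair in pairs:
        m1 = pair.mate1
        m2 = revcomp(pair.mate2)
        a1 = np.frombuffer(m1.encode(), dtype=np.uint8)
        a2 = np.frombuffer(m2.encode(), dtype=np.uint8)
        total_bases = a1.size + a2.size

        candidates = list(
            dict.fromkeys(
                index.prefix.get(m1[:_ANCHOR_K], []) + index.suffix.get(m2[-_ANCHOR_K:], [])
            )
        )
        if not candidates:
            candidates = all_names

        # (mismatches, amplicon, kind, payload)
        best: tuple[int, str, str, tuple] | None = None
        for name in candidates:
            ref = index.seq[name]
            o2 = ref.size - a2.size
            mm = _mm(a1, ref, 0) + _mm(a2, ref, o2)
            if best is None or mm < best[0]:
                best = (mm, name, "gapless", (0, o2))
            for anchor, dlen, alt in index.hotspots[name]:
                go2 = alt.size - a2.size
                gmm = _mm(a1, alt, 0) + _mm(a2, alt, go2)
                if gmm < best[0]:
                    best = (gmm, name, "gapped", (anchor, dlen, 0, go2))

        if best is None or best[0] > max_mismatch_frac * total_bases:
            # rare slow path: exhaustive sliding placement over every amplicon
            for name in all_names:
                ref = index.seq[name]
                mm1, o1 = _best_sliding(a1, ref)
                mm2, o2 = _best_sliding(a2, ref)
                mm = mm1 + mm2
                if best is None or mm < best[0]:
                    best = (mm, name, "gapless", (o1, o2))

        if best is None or best[0] > max_mismatch_frac * total_bases:
            unassigned += 1
            continue

        mm, name, kind, payload = best
        length = index.seq[name].size
        if kind == "gapless":
            o1, o2 = payload
            bases = _project_gapless(length, a1, o1, a2, o2)
        else:
            anchor, dlen, o1, o2 = payload
            bases = _merge(
                _project_gapped(length, anchor, dlen, a1, o1),
                _project_gapped(length, anchor, dlen, a2, o2),
            )
        aligned.append(
            AlignedRead(
                read_id=pair.read_id,
                barcode=pair.barcode,
                amplicon=name,
                bases=bases,
                mismatches=mm,
                aligned_length=total_bases,
            )
        )
    return AssignmentResult(aligned, unassigned)


# ---------------------------------------------------------------------------
# Step 3: family grouping
# ---------------------------------------------------------------------------


def group_families(reads: list[AlignedRead]) -> list[MolecularFamily]:
    """Group aligned reads by exact (barcode, amplicon) key.

    Every read lands in exactly one family; the family count equals the
    number of distinct keys.
    """
    groups: dict[tuple[str, str], list[AlignedRead]] = defaultdict(list)
    for read in reads:
        groups[(read.barcode, read.amplicon)].append(read)
    return [
        MolecularFamily(barcode, amplicon, members)
        for (barcode, amplicon), members in groups.items()
    ]


# ---------------------------------------------------------------------------
# Step 4: consensus
# ---------------------------------------------------------------------------


def consensus_families(
    families: list[MolecularFamily],
    min_family_size: int = 2,
    min_agreement: float = 0.7,
) -> tuple[list[ConsensusSequence], int]:
    """Consolidate every family to one consensus read.

    Families smaller than ``min_family_size`` are rejected and counted.
    Per reference position, the majority base among covering members wins
    when its fraction is at least ``min_agreement`` (ties at the threshold
    are kept); otherwise the position is ``N``. Positions no member covers
    stay uncovered. Returns ``(consensus reads, rejected family count)``.
    """
    retained = [f for f in families if f.size >= min_family_size]
    rejected = len(families) - len(retained)
    results: list[ConsensusSequence] = []

    by_amplicon: dict[str, list[MolecularFamily]] = defaultdict(list)
    for fam in retained:
        by_amplicon[fam.amplicon].append(fam)

    for amplicon, fams in by_amplicon.items():
        length = fams[0].members[0].bases.size
        n_fam = len(fams)
        reads = np.vstack([m.bases for fam in fams for m in fam.members])
        fam_idx = np.repeat(np.arange(n_fam), [f.size for f in fams])

        counts = np.zeros((len(BASE_CODES), n_fam, length), dtype=np.int32)
        for c, code in enumerate(BASE_CODES):
            np.add.at(counts[c], fam_idx, (reads == code).astype(np.int32))

        covered = counts.sum(axis=0)
        top = counts.max(axis=0)
        winner = BASE_CODES[counts.argmax(axis=0)]
        with np.errstate(invalid="ignore", divide="ignore"):
            agreement = np.where(covered > 0, top / np.maximum(covered, 1), 0.0)
        ok = (covered > 0) & (agreement >= min_agreement - 1e-12)
        bases = np.where(ok, winner, np.where(covered > 0, AMBIGUOUS, UNCOVERED))
        bases = bases.astype(np.uint8)

        for i, fam in enumerate(fams):
            results.append(
                ConsensusSequence(
                    barcode=fam.barcode,
                    amplicon=amplicon,
                    bases=bases[i],
                    family_size=fam.size,
                    agreement=agreement[i],
                )
            )
    return results, rejected


def consensus(
    family: MolecularFamily,
    min_family_size: int = 2,
    min_agreement: float = 0.7,
) -> ConsensusSequence | None:
    """Consensus of a single family, or ``None`` if the family is rejected."""
    if not family.members:
        raise ValueError("family has no members")
    made, _ = consensus_families([family], min_family_size, min_agreement)
    return made[0] if made else None


# ---------------------------------------------------------------------------
# Pileups for the two arms
# ---------------------------------------------------------------------------


def _pileup_from_vectors(
    groups: dict[str, list[np.ndarray]], unit: str
) -> Pileup:
    counts: dict[str, np.ndarray] = {}
    for amplicon, vectors in groups.items():
        mat = np.vstack(vectors)
        counts[amplicon] = np.vstack(
            [(mat == code).sum(axis=0) for code in BASE_CODES]
        ).astype(np.int64)
    return Pileup(counts=counts, unit=unit)


def raw_pileup(reads: list[AlignedRead]) -> Pileup:
    """Per-position base counts over raw reads — the "without MBS" arm."""
    groups: dict[str, list[np.ndarray]] = defaultdict(list)
    for read in reads:
        groups[read.amplicon].append(read.bases)
    return _pileup_from_vectors(groups, unit="read")


def consensus_pileup(consensuses: list[ConsensusSequence]) -> Pileup:
    """Per-position counts where each retained family contributes once."""
    groups: dict[str, list[np.ndarray]] = defaultdict(list)
    for cons in consensuses:
        groups[cons.amplicon].append(cons.bases)
    return _pileup_from_vectors(groups, unit="family")


def write_family_table(families: list[MolecularFamily], path: str | Path) -> None:
    """Inspection TSV: one row per molecular family (barcode, amplicon, size)."""
    with open(path, "w") as out:
        out.write("barcode\tamplicon\tsize\n")
        for fam in families:
            out.write(f"{fam.barcode}\t{fam.amplicon}\t{fam.size}\n")
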