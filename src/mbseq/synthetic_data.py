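"""Synthetic HaloPlex-HS-style amplicon data for an EGFR hotspot panel.

This module builds everything the downstream stages need without any
external download: a deterministic panel of EGFR exon 15-21 amplicons with
embedded hotspot variants, ground-truth sample profiles, and barcoded
paired-end reads with controlled PCR and sequencing errors.

The simulation models the molecular-barcoding library chemistry at the
level that matters for consensus calling:

* each input DNA molecule receives a unique random barcode (UMI) before
  amplification, so reads can be traced back to their source molecule;
* PCR errors arise once per molecule (a single pre-sequencing duplication
  stage) and propagate to a random subset of that molecule's reads,
  producing errors *correlated within a barcode family*;
* sequencing errors are independent per base per read.

Allele fractions are molecule fractions (ploidy-free design): a truth
fraction of 0.05 means each molecule carries the variant independently
with probability 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Amplicon",
    "Variant",
    "SampleProfile",
    "SimulationConfig",
    "Molecule",
    "TaggedReadPair",
    "PanelDesign",
    "build_default_panel",
    "make_sample_profile",
    "simulate_molecules",
    "amplify_and_sequence",
    "inject_artifact",
    "write_outputs",
    "read_fastq_pairs",
    "revcomp",
]

PANEL_CONTIG = "EGFR_panel"
_PANEL_SEED = 598_714  # fixed: panel sequences must be identical across runs
_BASES = "ACGT"
_Q30 = "?"  # phred+33 symbol for Q30; qualities are constant by design

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Amplicon:
    """A targeted interval with its reference sequence.

    Coordinates are 0-based half-open on ``contig``; ``sequence`` has
    length ``end - start`` over the {A,C,G,T} alphabet.
    """

    name: str
    contig: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"amplicon {self.name}: end must exceed start")
        if len(self.sequence) != self.end - self.start:
            raise ValueError(f"amplicon {self.name}: sequence length mismatch")
        if set(self.sequence) - set(_BASES):
            raise ValueError(f"amplicon {self.name}: non-ACGT characters")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Variant:
    """A substitution or left-aligned anchored indel on the panel contig.

    ``pos`` is 0-based. Deletions carry the anchor base plus deleted bases
    in ``ref`` and the anchor alone in ``alt``.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    label: str | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def is_deletion(self) -> bool:
        return len(self.ref) > len(self.alt)


@dataclass(frozen=True)
class SampleProfile:
    """Ground truth for one sample: variants with molecule fractions."""

    sample_id: str
    truth: tuple[tuple[Variant, float], ...]

    def __post_init__(self) -> None:
        keys = [v.key for v, _ in self.truth]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate variant in sample profile")
        for v, f in self.truth:
            if not 0.0 < f <= 1.0:
                raise ValueError(f"fraction {f} for {v.label or v.key} outside (0, 1]")


@dataclass
class SimulationConfig:
    """Knobs of the read simulator.

    Parameters
    ----------
    molecules_per_amplicon
        Input molecules tagged per amplicon (unique barcodes).
    barcode_length
        Bases per molecular barcode. 12 keeps the expected number of
        barcode collisions per amplicon below one at the default molecule
        count (birthday bound n^2 / (2 * 4^L)).
    reads_per_molecule
        ``(mean, fano)`` for the family-size distribution: ``fano == 0``
        gives a constant count, ``fano == 1`` Poisson, ``fano > 1`` a
        negative binomial with variance ``mean * fano``.
    pcr_error_rate
        Per-base probability on the single simulated PCR copy of each
        molecule; reads drawn from that copy share the error.
    seq_error_rate
        Independent per-base substitution probability per read.
    barcode_error_rate
        Per-base barcode substitution rate (fragments families). Off by
        default: the barcode is treated as sequenced losslessly.
    read_length
        Bases per mate; mates anchor at the two amplicon ends.
    """

    molecules_per_amplicon: int = 2000
    barcode_length: int = 12
    reads_per_molecule: tuple[float, float] = (5.0, 1.0)
    pcr_error_rate: float = 1e-4
    seq_error_rate: float = 0.005
    barcode_error_rate: float = 0.0
    read_length: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.molecules_per_amplicon <= 0:
            raise ValueError("molecules_per_amplicon must be positive")
        if self.barcode_length <= 0:
            raise ValueError("barcode_length must be positive")
        mean, fano = self.reads_per_molecule
        if mean <= 0 or fano < 0:
            raise ValueError("reads_per_molecule needs mean > 0 and fano >= 0")
        for name in ("pcr_error_rate", "seq_error_rate", "barcode_error_rate"):
            p = getattr(self, name)
            if not 0.0 <= p < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")

    # flat key-value config file, keys exactly as the field names
    def to_file(self, path: str | Path) -> None:
        lines = []
        for key, value in self.__dict__.items():
            if key == "reads_per_molecule":
                value = f"{value[0]},{value[1]}"
            lines.append(f"{key} = {value}\n")
        Path(path).write_text("".join(lines))

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        kwargs: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key == "reads_per_molecule":
                mean, fano = value.split(",")
                kwargs[key] = (float(mean), float(fano))
            elif key in ("molecules_per_amplicon", "barcode_length", "read_length", "seed"):
                kwargs[key] = int(value)
            elif key in ("pcr_error_rate", "seq_error_rate", "barcode_error_rate"):
                kwargs[key] = float(value)
            else:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        config = cls(**kwargs)
        config.validate()
        return config


@dataclass(frozen=True)
class Molecule:
    """One barcoded input molecule: the unit a consensus should recover."""

    molecule_id: int
    barcode: str
    amplicon: str
    haplotype: str
    variants: tuple[tuple[str, int, str, str], ...] = ()


@dataclass(frozen=True)
class TaggedReadPair:
    """A simulated read pair; ``origin`` is the truth channel (never in FASTQ)."""

    read_id: str
    barcode: str
    mate1: str
    mate2: str
    qual1: str
    qual2: str
    origin: int | None = None


@dataclass(frozen=True)
class PanelDesign:
    """Amplicon panel plus the hotspot variant catalog."""

    amplicons: tuple[Amplicon, ...]
    contig_sequence: str
    catalog: dict[str, Variant] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [a.name for a in self.amplicons]
        if len(names) != len(set(names)):
            raise ValueError("amplicon names must be unique")

    def amplicon(self, name: str) -> Amplicon:
        for a in self.amplicons:
            if a.name == name:
                return a
        raise KeyError(name)

    def amplicon_at(self, contig: str, pos: int) -> Amplicon | None:
        for a in self.amplicons:
            if a.contig == contig and a.start <= pos < a.end:
                return a
        return None

    def variants_in(self, amplicon: Amplicon) -> list[Variant]:
        return [
            v
            for v in self.catalog.values()
            if v.contig == amplicon.contig and amplicon.start <= v.pos < amplicon.end
        ]

    def deletion_hotspots(self, amplicon: Amplicon) -> list[Variant]:
        return [v for v in self.variants_in(amplicon) if v.is_deletion]

    def label_of(self, key: tuple[str, int, str, str]) -> str | None:
        for label, v in self.catalog.items():
            if v.key == key:
                return label
        return None

    def subset(self, names: Sequence[str]) -> "PanelDesign":
        """Panel restricted to the named amplicons (catalog pruned to match)."""
        amps = tuple(self.amplicon(n) for n in names)
        catalog = {
            label: v
            for label, v in self.catalog.items()
            if any(a.contig == v.contig and a.start <= v.pos < a.end for a in amps)
        }
        return PanelDesign(amps, self.contig_sequence, catalog)

    def expected_barcode_collisions(self, config: SimulationConfig) -> float:
        """Birthday bound on same-barcode molecule pairs per amplicon."""
        n = config.molecules_per_amplicon
        return n * (n - 1) / 2 / 4 ** config.barcode_length


# ---------------------------------------------------------------------------
# Panel construction
# ---------------------------------------------------------------------------

_AMPLICON_LENGTH = 150
_AMPLICON_SPACING = 200
_PANEL_OFFSET = 50

# (exon, label, offset-in-amplicon); alt bases are assigned deterministically
_SNV_HOTSPOTS = [
    (15, "G598V", 70),
    (18, "E709G", 40),
    (19, "D761Y", 110),
    (20, "R776H", 45),
    (20, "T790M", 90),
    (21, "L858R", 60),
    (21, "L861Q", 72),
]
_G719_EXON, _G719_OFFSET = 18, 80  # G719A/S/C: three alts at one codon position
_EX19DEL_OFFSET, _EX19DEL_LENGTH = 60, 15


def _amplicon_start(exon: int) -> int:
    return _PANEL_OFFSET + (exon - 15) * _AMPLICON_SPACING


def build_default_panel() -> PanelDesign:
    """Deterministic EGFR exon 15-21 stand-in panel with hotspot catalog.

    Seven amplicons (one per exon) are carved out of a fixed-seed random
    backbone contig. The catalog embeds the clamp-detectable hotspots
    (L858R, exon-19 deletion, G719A/S/C, T790M, L861Q) and the uncommon
    ones (E709G, R776H, D761Y, G598V) at fixed coordinates, so two calls
    always return byte-identical panels.
    """
    rng = np.random.default_rng(_PANEL_SEED)
    length = _PANEL_OFFSET + 7 * _AMPLICON_SPACING
    backbone = list(rng.choice(list(_BASES), size=length))

    # keep the exon-19 deletion left-aligned: the last deleted base must
    # differ from the anchor base so the deletion cannot shift left
    dstart = _amplicon_start(19) + _EX19DEL_OFFSET
    anchor = backbone[dstart - 1]
    if backbone[dstart + _EX19DEL_LENGTH - 1] == anchor:
        backbone[dstart + _EX19DEL_LENGTH - 1] = _BASES[(_BASES.index(anchor) + 1) % 4]

    contig_seq = "".join(backbone)
    amplicons = tuple(
        Amplicon(
            name=f"EGFR_ex{exon}",
            contig=PANEL_CONTIG,
            start=_amplicon_start(exon),
            end=_amplicon_start(exon) + _AMPLICON_LENGTH,
            sequence=contig_seq[_amplicon_start(exon) : _amplicon_start(exon) + _AMPLICON_LENGTH],
        )
        for exon in range(15, 22)
    )

    catalog: dict[str, Variant] = {}
    for exon, label, offset in _SNV_HOTSPOTS:
        pos = _amplicon_start(exon) + offset
        ref = contig_seq[pos]
        alt = _BASES[(_BASES.index(ref) + 1) % 4]
        catalog[label] = Variant(PANEL_CONTIG, pos, ref, alt, label)

    g719_pos = _amplicon_start(_G719_EXON) + _G719_OFFSET
    g719_ref = contig_seq[g719_pos]
    alts = [b for b in _BASES if b != g719_ref]
    for suffix, alt in zip("ASC", alts):
        label = f"G719{suffix}"
        catalog[label] = Variant(PANEL_CONTIG, g719_pos, g719_ref, alt, label)

    del_ref = contig_seq[dstart - 1 : dstart + _EX19DEL_LENGTH]
    catalog["exon19del"] = Variant(
        PANEL_CONTIG, dstart - 1, del_ref, del_ref[0], "exon19del"
    )
    return PanelDesign(amplicons, contig_seq, catalog)


def make_sample_profile(
    sample_id: str,
    spec: Iterable[tuple[str, float]],
    panel: PanelDesign | None = None,
) -> SampleProfile:
    """Resolve ``(hotspot label, fraction)`` pairs against the panel catalog.

    An empty spec yields a wild-type sample. Unknown labels and fractions
    outside (0, 1] raise ``ValueError``.
    """
    panel = panel or build_default_panel()
    truth = []
    for label, fraction in spec:
        if label not in panel.catalog:
            raise ValueError(f"unknown hotspot label {label!r}")
        if not 0.0 < fraction <= 1.0:
            raise ValueError(f"fraction {fraction} for {label!r} outside (0, 1]")
        truth.append((panel.catalog[label], float(fraction)))
    return SampleProfile(sample_id, tuple(truth))


# ---------------------------------------------------------------------------
# Molecule and read simulation
# ---------------------------------------------------------------------------


def _apply_variants(amplicon: Amplicon, variants: list[Variant]) -> str:
    """Amplicon haplotype with the given variants applied (deletions last)."""
    seq = bytearray(amplicon.sequence, "ascii")
    deletions = []
    for v in variants:
        offset = v.pos - amplicon.start
        if v.is_deletion:
            deletions.append((offset + len(v.alt), len(v.ref) - len(v.alt)))
        elif len(v.ref) == len(v.alt) == 1:
            if seq[offset] != ord(v.ref):
                raise ValueError(f"{v.label or v.key}: ref mismatch in panel")
            seq[offset] = ord(v.alt)
        else:
            raise ValueError("only SNVs and anchored deletions are supported")
    for offset, dlen in sorted(deletions, reverse=True):
        del seq[offset : offset + dlen]
    return seq.decode()


def simulate_molecules(
    profile: SampleProfile,
    config: SimulationConfig,
    panel: PanelDesign,
) -> list[Molecule]:
    """Tag ``molecules_per_amplicon`` molecules per amplicon with random barcodes.

    Each molecule carries each truth variant on its amplicon independently
    with probability equal to the variant's fraction. Fully determined by
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    n = config.molecules_per_amplicon
    molecules: list[Molecule] = []
    mol_id = 0
    base_arr = np.frombuffer(_BASES.encode(), dtype=np.uint8)
    for amplicon in panel.amplicons:
        barcodes = base_arr[rng.integers(0, 4, size=(n, config.barcode_length))]
        truth_here = [
            (v, f) for v, f in profile.truth
            if v.contig == amplicon.contig and amplicon.start <= v.pos < amplicon.end
        ]
        carry = {
            v.key: rng.random(n) < f for v, f in truth_here
        }
        for i in range(n):
            variants = [v for v, _ in truth_here if carry[v.key][i]]
            haplotype = _apply_variants(amplicon, variants) if variants else amplicon.sequence
            molecules.append(
                Molecule(
                    molecule_id=mol_id,
                    barcode=barcodes[i].tobytes().decode(),
                    amplicon=amplicon.name,
                    haplotype=haplotype,
                    variants=tuple(v.key for v in variants),
                )
            )
            mol_id += 1
    return molecules


def _family_sizes(rng: np.random.Generator, n: int, mean: float, fano: float) -> np.ndarray:
    if fano == 0:
        return np.full(n, int(round(mean)), dtype=np.int64)
    if fano == 1.0:
        return rng.poisson(mean, size=n)
    # negative binomial with variance mean * fano
    r = mean / (fano - 1.0)
    p = 1.0 / fano
    return rng.negative_binomial(r, p, size=n)


def _mutate(rng: np.random.Generator, seq: str, n_errors: int) -> str:
    """Substitute ``n_errors`` random positions with random different bases."""
    if n_errors == 0:
        return seq
    arr = bytearray(seq, "ascii")
    positions = rng.choice(len(arr), size=min(n_errors, len(arr)), replace=False)
    for pos in positions:
        current = chr(arr[pos])
        choices = [b for b in _BASES if b != current]
        arr[pos] = ord(choices[rng.integers(0, 3)])
    return arr.decode()


def amplify_and_sequence(
    molecules: list[Molecule],
    config: SimulationConfig,
) -> list[TaggedReadPair]:
    """Amplify each molecule into a barcode family of read pairs.

    PCR errors are injected on a single simulated copy of the molecule and
    shared by the reads drawn from that copy (about half the family);
    sequencing errors are independent per mate. Mate 1 reads the first
    ``read_length`` bases of the (mutated) molecule, mate 2 the reverse
    complement of the last ``read_length`` bases, mirroring a two-primer
    amplicon design.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    mean, fano = config.reads_per_molecule
    sizes = _family_sizes(rng, len(molecules), mean, fano)
    rl = config.read_length
    e_seq = config.seq_error_rate
    # pre-draw per-molecule PCR-error counts and per-mate sequencing-error
    # counts in bulk; scalar draws per read dominate runtime otherwise
    hap_lengths = np.fromiter((len(m.haplotype) for m in molecules), dtype=np.int64)
    pcr_counts = (
        rng.binomial(hap_lengths, config.pcr_error_rate)
        if config.pcr_error_rate > 0
        else np.zeros(len(molecules), dtype=np.int64)
    )
    total_reads = int(sizes.sum())
    if e_seq > 0:
        seq_counts = rng.binomial(rl, e_seq, size=(total_reads, 2))
    else:
        seq_counts = np.zeros((total_reads, 2), dtype=np.int64)
    read_cursor = 0
    pairs: list[TaggedReadPair] = []
    for mi, (mol, k) in enumerate(zip(molecules, sizes)):
        if k == 0:
            continue
        hap = mol.haplotype
        templates = [hap]
        if pcr_counts[mi]:
            templates.append(_mutate(rng, hap, int(pcr_counts[mi])))
        use_copy = (
            rng.random(k) < 0.5 if len(templates) == 2 else np.zeros(k, dtype=bool)
        )
        barcode = mol.barcode
        if config.barcode_error_rate > 0:
            n_bc = rng.binomial(len(barcode), config.barcode_error_rate)
            if n_bc:
                barcode = _mutate(rng, barcode, n_bc)
        for j in range(k):
            template = templates[1] if use_copy[j] else templates[0]
            m1 = template[:rl]
            m2 = revcomp(template[-rl:])
            n1, n2 = seq_counts[read_cursor]
            read_cursor += 1
            if len(m1) != rl:  # short molecule: the bulk draw assumed rl bases
                n1 = rng.binomial(len(m1), e_seq) if e_seq > 0 else 0
                n2 = rng.binomial(len(m2), e_seq) if e_seq > 0 else 0
            if e_seq > 0:
                m1 = _mutate(rng, m1, int(n1))
                m2 = _mutate(rng, m2, int(n2))
            pairs.append(
                TaggedReadPair(
                    read_id=f"mol{mol.molecule_id}.r{j}",
                    barcode=barcode,
                    mate1=m1,
                    mate2=m2,
                    qual1=_Q30 * len(m1),
                    qual2=_Q30 * len(m2),
                    origin=mol.molecule_id,
                )
            )
    return pairs


def inject_artifact(
    samples: list[list[TaggedReadPair]],
    site: Variant,
    mode: str,
    rate: float,
    panel: PanelDesign,
    config: SimulationConfig,
    seed: int = 0,
) -> list[list[TaggedReadPair]]:
    """Spike artifact-supporting reads into a cohort of read sets.

    ``systematic`` places the artifact in strictly more than half of the
    samples, ``singleton`` in exactly one. Every injected read carries a
    fresh barcode at family size one, so a barcode-consensus pass with a
    minimum family size of two suppresses it while the raw arm keeps it.
    ``rate`` is the injected fraction of each chosen sample's read count.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if rate == 0:
        return samples
    if mode not in ("systematic", "singleton"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "systematic" and len(samples) < 3:
        raise ValueError("systematic injection needs at least 3 samples")

    amplicon = panel.amplicon_at(site.contig, site.pos)
    if amplicon is None:
        raise ValueError("artifact site lies outside the panel")
    haplotype = _apply_variants(amplicon, [site])
    rl = config.read_length

    rng = np.random.default_rng([seed, 2])
    n = len(samples)
    if mode == "systematic":
        chosen = rng.choice(n, size=n // 2 + 1, replace=False)
    else:
        chosen = [int(rng.integers(0, n))]

    base_arr = np.frombuffer(_BASES.encode(), dtype=np.uint8)
    out = [list(reads) for reads in samples]
    for idx in chosen:
        count = max(1, int(round(rate * len(samples[idx]))))
        barcodes = base_arr[rng.integers(0, 4, size=(count, config.barcode_length))]
        for j in range(count):
            m1, m2 = haplotype[:rl], revcomp(haplotype[-rl:])
            out[idx].append(
                TaggedReadPair(
                    read_id=f"artifact.{site.pos}.{idx}.{j}",
                    barcode=barcodes[j].tobytes().decode(),
                    mate1=m1,
                    mate2=m2,
                    qual1=_Q30 * len(m1),
                    qual2=_Q30 * len(m2),
                    origin=None,
                )
            )
    return out


# ---------------------------------------------------------------------------
# File output / input
# ---------------------------------------------------------------------------


def write_outputs(
    reads: list[TaggedReadPair],
    panel: PanelDesign,
    profile: SampleProfile,
    outdir: str | Path,
    prefix: str | None = None,
) -> dict[str, Path]:
    """Write reference FASTA, amplicon BED, paired FASTQ and a truth TSV.

    The molecular barcode travels in the read name after the last ``:``.
    Returns the paths keyed by kind (``reference``, ``bed``, ``fastq1``,
    ``fastq2``, ``truth``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prefix = prefix or profile.sample_id

    paths = {
        "reference": outdir / "reference.fasta",
        "bed": outdir / "amplicons.bed",
        "fastq1": outdir / f"{prefix}_R1.fastq",
        "fastq2": outdir / f"{prefix}_R2.fastq",
        "truth": outdir / f"{prefix}_truth.tsv",
    }
    SeqIO.write(
        [SeqRecord(Seq(panel.contig_sequence), id=PANEL_CONTIG, description="")],
        paths["reference"],
        "fasta",
    )
    with open(paths["bed"], "w") as bed:
        for a in panel.amplicons:
            bed.write(f"{a.contig}\t{a.start}\t{a.end}\t{a.name}\n")

    def _records(mate: int):
        for pair in reads:
            seq = pair.mate1 if mate == 1 else pair.mate2
            qual = pair.qual1 if mate == 1 else pair.qual2
            rec = SeqRecord(
                Seq(seq), id=f"{pair.read_id}:{pair.barcode}", description=""
            )
            rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
            yield rec

    SeqIO.write(_records(1), paths["fastq1"], "fastq")
    SeqIO.write(_records(2), paths["fastq2"], "fastq")

    with open(paths["truth"], "w") as truth:
        truth.write("sample_id\tcontig\tpos\tref\talt\tlabel\tfraction\n")
        for v, f in profile.truth:
            truth.write(
                f"{profile.sample_id}\t{v.contig}\t{v.pos}\t{v.ref}\t{v.alt}"
                f"\t{v.label or '.'}\t{f}\n"
            )
    return paths


def read_fastq_pairs(
    fastq1: str | Path,
    fastq2: str | Path,
    barcode_fastq: str | Path | None = None,
) -> list[TaggedReadPair]:
    """Load paired FASTQ back into tagged read pairs.

    By default the barcode is parsed from the read-name suffix after the
    last ``:``. If ``barcode_fastq`` is given (index-read dialect), the
    barcode is taken from that file's sequences instead and read names are
    used verbatim.
    """
    recs1 = list(SeqIO.parse(str(fastq1), "fastq"))
    recs2 = list(SeqIO.parse(str(fastq2), "fastq"))
    if len(recs1) != len(recs2):
        raise ValueError("mate FASTQ files differ in read count")
    barcodes: list[str] | None = None
    if barcode_fastq is not None:
        barcodes = [str(r.seq) for r in SeqIO.parse(str(barcode_fastq), "fastq")]
        if len(barcodes) != len(recs1):
            raise ValueError("barcode FASTQ differs in read count")

    pairs = []
    for i, (r1, r2) in enumerate(zip(recs1, recs2)):
        if barcodes is None:
            name, _, barcode = r1.id.rpartition(":")
            if not name:
                raise ValueError(f"read {r1.id!r} has no ':BARCODE' suffix")
        else:
            name, barcode = r1.id, barcodes[i]
        pairs.append(
            TaggedReadPair(
                read_id=name,
                barcode=barcode,
                mate1=str(r1.seq),
                mate2=str(r2.seq),
                qual1="".join(
                    chr(q + 33) for q in r1.letter_annotations["phred_quality"]
                ),
                qual2="".join(
                    chr(q + 33) for q in r2.letter_annotations["phred_quality"]
                ),
            )
        )
    return pairs
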