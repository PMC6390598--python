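"""Replicate-library concordance and artifact bookkeeping.

Two libraries prepared independently from the same DNA should call the
same variants. Calls present in both replicates are *matched*; calls
private to one replicate are *orphans*. Reproducibility is
``100 * matched / (matched + orphan)`` — matched plus orphan is exactly
the size of the union of the two call sets — and the allele-frequency
agreement of matched calls is summarised by the ordinary-least-squares
R-squared of replicate 2 on replicate 1.

The artifact census compares the raw ("without MBS") arm against the
consensus arm across a cohort: raw-arm calls absent from a sample's MBS
arm are potential sequence artifacts, tabulated by how many samples share
them (singletons are private to one sample).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .variant_calling import CallSet, VariantKey

__all__ = [
    "ReplicatePair",
    "ReproducibilityResult",
    "ArtifactCensus",
    "match_replicates",
    "reproducibility",
    "af_correlation",
    "clinical_concordance",
    "artifact_census",
    "write_replicate_report",
]


@dataclass
class ReplicatePair:
    sample_id: str
    callset_1: CallSet
    callset_2: CallSet
    matched: list[VariantKey]
    orphans: list[tuple[VariantKey, int]]  # (key, replicate 1 or 2)


@dataclass
class ReproducibilityResult:
    sample_id: str
    matched_count: int
    orphan_count: int
    reproducibility: int  # whole percent
    af_r2: float | None  # None when fewer than 2 matched calls


def match_replicates(cs1: CallSet, cs2: CallSet) -> ReplicatePair:
    """Partition the union of two replicate call sets into matched/orphans.

    Matching is on the (contig, pos, ref, alt) key; each orphan is counted
    once with the replicate it came from. The two call sets must share the
    sample and arm.
    """
    if cs1.arm != cs2.arm:
        raise ValueError(f"arm mismatch: {cs1.arm} vs {cs2.arm}")
    k1, k2 = cs1.keys(), cs2.keys()
    matched = sorted(k1 & k2)
    orphans = [(k, 1) for k in sorted(k1 - k2)] + [(k, 2) for k in sorted(k2 - k1)]
    return ReplicatePair(cs1.sample_id, cs1, cs2, matched, orphans)


def reproducibility(matched: int, orphan: int) -> int:
    """Percent of the union called in both replicates, rounded to integer."""
    if matched < 0 or orphan < 0:
        raise ValueError("counts must be non-negative")
    if matched + orphan == 0:
        raise ValueError("reproducibility undefined: no calls in either replicate")
    return int(round(100.0 * matched / (matched + orphan)))


def af_correlation(pair: ReplicatePair) -> float:
    """OLS R-squared of replicate-2 allele frequency on replicate-1.

    Computed over matched calls only (orphans have no pair), on the
    percent scale. Requires at least two matched calls.
    """
    if len(pair.matched) < 2:
        raise ValueError("af_correlation needs at least 2 matched calls")
    x = np.array([pair.callset_1.calls[k].allele_frequency for k in pair.matched])
    y = np.array([pair.callset_2.calls[k].allele_frequency for k in pair.matched])
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: replicate-1 frequencies are constant")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        return 1.0  # constant y matched exactly by the fit
    return 1.0 - float((resid**2).sum()) / sst


def evaluate_pair(cs1: CallSet, cs2: CallSet) -> ReproducibilityResult:
    """Convenience wrapper: match, score and (when defined) correlate."""
    pair = match_replicates(cs1, cs2)
    r2 = None
    if len(pair.matched) >= 2:
        try:
            r2 = af_correlation(pair)
        except ValueError:
            r2 = None
    return ReproducibilityResult(
        sample_id=pair.sample_id,
        matched_count=len(pair.matched),
        orphan_count=len(pair.orphans),
        reproducibility=reproducibility(len(pair.matched), len(pair.orphans)),
        af_r2=r2,
    )


def clinical_concordance(
    callsets: list[CallSet],
    clinical: list[tuple[str, str]],
) -> tuple[int, float]:
    """Concordance of MBS calls with clinically reported common mutations.

    Each clinical record is ``(sample_id, common-mutation label)``; the
    sample is concordant when that label appears among its filtered calls
    (G719A/S/C and exon-19 deletions match on the label itself). Returns
    the concordant count and the percent to one decimal.
    """
    by_sample = {cs.sample_id: cs for cs in callsets}
    concordant = 0
    for sample_id, label in clinical:
        if sample_id not in by_sample:
            raise KeyError(f"no call set for clinical sample {sample_id!r}")
        if label in by_sample[sample_id].labels():
            concordant += 1
    return concordant, round(100.0 * concordant / len(clinical), 1)


@dataclass
class ArtifactCensus:
    """Sharing profile of potential artifacts across a cohort."""

    site_share: dict[VariantKey, int]  # raw-arm sample count per artifact site
    singleton_sites: list[VariantKey]  # shared by exactly one sample
    reductions: list[int]  # per-sample raw-arm minus MBS-arm call counts
    n_samples: int

    @property
    def singleton_fraction(self) -> float:
        if not self.site_share:
            return 0.0
        return len(self.singleton_sites) / len(self.site_share)

    @property
    def mean_reduction(self) -> float:
        return float(np.mean(self.reductions)) if self.reductions else 0.0


def artifact_census(
    raw_callsets: list[CallSet],
    mbs_callsets: list[CallSet],
) -> ArtifactCensus:
    """Tabulate raw-arm-only calls by how many samples share them.

    ``raw_callsets`` and ``mbs_callsets`` are paired by position (same
    sample order). A site is a *potential artifact* when some sample calls
    it on the raw arm but not on its MBS arm; its share is the number of
    raw-arm call sets containing it. Also reports the per-sample reduction
    in call count attributable to the barcode consensus.
    """
    if len(raw_callsets) < 2:
        raise ValueError("artifact census needs at least 2 samples")
    if len(raw_callsets) != len(mbs_callsets):
        raise ValueError("raw and MBS call-set lists must pair up")
    artifact_sites: set[VariantKey] = set()
    for raw, mbs in zip(raw_callsets, mbs_callsets):
        artifact_sites |= raw.keys() - mbs.keys()
    share = {
        site: sum(site in cs.calls for cs in raw_callsets)
        for site in sorted(artifact_sites)
    }
    singletons = [site for site, n in share.items() if n == 1]
    reductions = [
        len(raw.calls) - len(mbs.calls)
        for raw, mbs in zip(raw_callsets, mbs_callsets)
    ]
    return ArtifactCensus(
        site_share=share,
        singleton_sites=singletons,
        reductions=reductions,
        n_samples=len(raw_callsets),
    )


def write_replicate_report(
    results: list[ReproducibilityResult], path: str | Path
) -> None:
    with open(path, "w") as out:
        out.write("sample_id\tmatched\torphan\treproducibility_percent\taf_r2\n")
        for r in results:
            r2 = f"{r.af_r2:.3f}" if r.af_r2 is not None else "NA"
            out.write(
                f"{r.sample_id}\t{r.matched_count}\t{r.orphan_count}"
                f"\t{r.reproducibility}\t{r2}\n"
            )
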