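"""Bundled reference fixtures for offline worked examples.

These are the printed summaries of the clinical study cohort the package
models: per-patient allele frequencies of common/uncommon EGFR mutation
pairs, replicate matched/orphan tallies from the technical-reproducibility
experiment, genotype-by-compound-status counts for the main and TCGA
validation cohorts, and the clinicopathological comparison table.

:func:`build_cohort_frame` reconstructs a 64-patient cohort table from
those counts. The categorical columns reproduce the published margins
exactly; the age and tumor-size columns are synthetic draws affinely
adjusted to the published group mean and SD (individual patient values
are not published), so summary t-tests computed from the frame equal the
tests computed from the printed summaries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort_stats import GroupSummary

__all__ = [
    "AF_PAIRS",
    "REPLICATE_COUNTS_WITHOUT_MBS",
    "MAIN_COHORT_COMPOUND_RECORDS",
    "TCGA_COMPOUND_RECORDS",
    "SEX_TABLE",
    "SMOKING_TABLE",
    "PSTAGE_TABLE",
    "AGE_SUMMARIES",
    "TUMOR_SIZE_SUMMARIES",
    "build_cohort_frame",
]

#: per-patient (common label, common AF%, uncommon label, uncommon AF%,
#: printed AF difference) for the seven compound-mutation carriers
AF_PAIRS = [
    ("2294", "L858R", 6.56, "G598V", 6.8, 0.24),
    ("2312", "L858R", 13.3, "E709G", 13.9, 0.6),
    ("3013", "L858R", 20.4, "E709G", 20.4, 0.0),
    ("3290", "L858R", 20.2, "E709G", 18.4, 1.8),
    ("1877", "G719S", 11.8, "E709G", 12.3, 0.5),
    ("2233", "G719S", 30.9, "R776H", 48.1, 17.2),
    ("2921", "G719A", 19.4, "D761Y", 65.9, 46.5),
]

#: matched/orphan counts per replicate pair on the raw ("without MBS") arm
REPLICATE_COUNTS_WITHOUT_MBS = {
    "1873": (6, 5),
    "2279": (4, 7),
    "3236": (8, 3),
}

#: (genotype, compound status) per patient; 4/42, 0/17 and 3/5 compound
MAIN_COHORT_COMPOUND_RECORDS = (
    [("L858R", "compound")] * 4 + [("L858R", "single")] * 38
    + [("exon19del", "single")] * 17
    + [("G719X", "compound")] * 3 + [("G719X", "single")] * 2
)

#: TCGA lung-adenocarcinoma validation cohort: 5/27, 2/28, 3/5 compound
TCGA_COMPOUND_RECORDS = (
    [("L858R", "compound")] * 5 + [("L858R", "single")] * 22
    + [("exon19del", "compound")] * 2 + [("exon19del", "single")] * 26
    + [("G719X", "compound")] * 3 + [("G719X", "single")] * 2
)

# single-vs-compound counts per clinicopathological characteristic
SEX_TABLE = {"male": (23, 1), "female": (34, 6)}
SMOKING_TABLE = {"no": (31, 6), "yes": (26, 1)}
PSTAGE_TABLE = {"IA": (37, 2), "IB": (13, 1), "II-III": (7, 4)}
AGE_SUMMARIES = (GroupSummary(57, 66.4, 9.6), GroupSummary(7, 66.7, 9.3))
TUMOR_SIZE_SUMMARIES = (GroupSummary(57, 22.5, 8.9), GroupSummary(7, 33.7, 23.3))

_GENOTYPE_COUNTS = {
    "single": [("L858R", 38), ("exon19del", 17), ("G719X", 2)],
    "compound": [("L858R", 4), ("exon19del", 0), ("G719X", 3)],
}


def _matched_values(rng: np.random.Generator, summary: GroupSummary) -> np.ndarray:
    """Synthetic values with exactly the published mean and sample SD."""
    values = rng.normal(size=summary.n)
    values = (values - values.mean()) / values.std(ddof=1)
    return np.round(summary.mean + summary.sd * values, 6)


def _spread(pairs: list[tuple[str, int]]) -> list[str]:
    return [level for level, count in pairs for _ in range(count)]


def build_cohort_frame(seed: int = 0) -> pd.DataFrame:
    """Deterministic 64-patient cohort frame matching the published margins."""
    rng = np.random.default_rng(seed)
    rows = []
    for gi, status in enumerate(("single", "compound")):
        n = 57 if status == "single" else 7
        genotypes = _spread(_GENOTYPE_COUNTS[status])
        sexes = _spread([(s, SEX_TABLE[s][gi]) for s in SEX_TABLE])
        smoking = _spread([(s, SMOKING_TABLE[s][gi]) for s in SMOKING_TABLE])
        pstage = _spread([(s, PSTAGE_TABLE[s][gi]) for s in PSTAGE_TABLE])
        ages = _matched_values(rng, AGE_SUMMARIES[gi])
        sizes = _matched_values(rng, TUMOR_SIZE_SUMMARIES[gi])
        assert len(genotypes) == len(sexes) == len(smoking) == len(pstage) == n
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"{status[0].upper()}{i + 1:03d}",
                    "genotype": genotypes[i],
                    "compound_status": status,
                    "age": ages[i],
                    "sex": sexes[i],
                    "smoking": smoking[i],
                    "tumor_size_mm": sizes[i],
                    "pstage": pstage[i],
                }
            )
    return pd.DataFrame(rows)
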