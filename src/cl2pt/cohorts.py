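"""Published responder/non-responder counts of the ten study cohorts.

Each entry pairs a GDSC cell-line training cohort with one external test
cohort (clinical-trial GEO series, PDX encyclopedia, or TCGA patients) for
one drug.  NS/NR are the numbers of sensitive (responder) and resistant
(non-responder) samples.  These counts are the inputs to the prior-shift
cutoff adjustment; nothing else about the external cohorts is bundled.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class CohortCounts:
    drug: str
    test_set: str
    ns_source: int
    nr_source: int
    ns_target: int
    nr_target: int

    @property
    def n_target(self) -> int:
        return self.ns_target + self.nr_target


STUDY_COHORTS: dict[str, CohortCounts] = {
    "docetaxel_gse6434": CohortCounts("docetaxel", "GSE6434", 564, 286, 10, 14),
    "erlotinib_gse33072": CohortCounts("erlotinib", "GSE33072", 28, 342, 11, 14),
    "sorafenib_gse33072": CohortCounts("sorafenib", "GSE33072", 117, 286, 21, 16),
    "cetuximab_pdx": CohortCounts("cetuximab", "PDX", 40, 837, 5, 55),
    "erlotinib_pdx": CohortCounts("erlotinib", "PDX", 28, 342, 3, 18),
    "gemcitabine_pdx": CohortCounts("gemcitabine", "PDX", 680, 186, 7, 18),
    "paclitaxel_pdx": CohortCounts("paclitaxel", "PDX", 284, 115, 5, 38),
    "cisplatin_tcga": CohortCounts("cisplatin", "TCGA", 275, 575, 60, 6),
    "docetaxel_tcga": CohortCounts("docetaxel", "TCGA", 564, 286, 8, 8),
    "gemcitabine_tcga": CohortCounts("gemcitabine", "TCGA", 680, 186, 21, 36),
}
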