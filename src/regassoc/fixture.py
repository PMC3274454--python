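"""Published count tables of the ZNF750 psoriasis resequencing study.

The study sequenced the ZNF750 promoter (400 bp upstream of the
transcription start site), 5' UTR, coding exons and 3' UTR in 716 psoriasis
cases and 397 controls, reporting 9 common variants (control MAF >= 2%) with
allele frequencies and Fisher p-values, 38 rare variants with full
minor-allele counts and genotyped-allele denominators, 7 eight-marker
haplotype frequencies with association statistics, and six functional-group
rare-variant totals.  Those printed tables ship with the package and are the
ground truth that the pipeline is validated against.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .io import VariantRecord

N_CASES = 716
N_CONTROLS = 397

#: The 8 common markers forming the haplotype scaffold, ordered as the
#: haplotype strings are written (descending genomic position; the gene is
#: read on the minus strand).  rs71918228 is excluded: its CAAA/- alleles
#: never appear in the haplotype strings and the per-position letters match
#: the remaining 8 markers' alleles and frequencies.  This assignment is an
#: inference from allele matching, not stated in the source tables.
SCAFFOLD_MARKERS = [
    "rs3744165",
    "rs12450046",
    "rs8074277",
    "rs35653278",
    "rs34188981",
    "rs12948179",
    "rs12938126",
    "rs35156590",
]

#: Functional-group totals (case minor alleles, control minor alleles,
#: weighted-sum-statistic permutation p) as printed.
GROUP_TOTALS = {
    "5' Regulatory": (10, 1, 0.041),
    "All Coding": (30, 19, 0.575),
    "Non-synonymous": (25, 15, 0.560),
    "Predicted deleterious": (24, 11, 0.314),
    "3' UTR": (5, 2, 0.351),
    "All Rare": (67, 32, 0.192),
}


def _read(name: str) -> pd.DataFrame:
    with resources.files("regassoc.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", na_values=["NA"], keep_default_na=False)


@dataclass
class FixtureVariant:
    """One variant row with its printed association numbers."""

    record: VariantRecord
    rarity: str  # 'common' or 'rare' as printed
    fisher_p: float
    f_case: float | None = None
    f_control: float | None = None
    case_counts: tuple[int, int] | None = None  # (minor, genotyped alleles)
    control_counts: tuple[int, int] | None = None


class PaperFixture:
    """All printed tables, self-checked for internal count consistency."""

    def __init__(self) -> None:
        t1 = _read("table1_common.tsv")
        t2 = _read("table2_rare.tsv")
        self.table1 = t1
        self.table2 = t2
        self.table3 = _read("table3_haplotypes.tsv")
        self.group_totals = dict(GROUP_TOTALS)
        self._variants: dict[str, FixtureVariant] = {}
        for _, row in t1.iterrows():
            rec = self._record(row)
            self._variants[rec.variant_id] = FixtureVariant(
                record=rec,
                rarity="common",
                fisher_p=float(row.fisher_p),
                f_case=float(row.f_case),
                f_control=float(row.f_control),
            )
        for _, row in t2.iterrows():
            rec = self._record(row)
            self._variants[rec.variant_id] = FixtureVariant(
                record=rec,
                rarity="rare",
                fisher_p=float(row.fisher_p),
                case_counts=(int(row.case_minor), int(row.case_alleles)),
                control_counts=(int(row.control_minor), int(row.control_alleles)),
            )
        self._check_consistency()

    @staticmethod
    def _record(row) -> VariantRecord:
        notes = ""
        if row.variant_id == "rs71918228":
            # table prints alleles CAAA/- while the running text calls this a
            # single-base deletion; stored verbatim from the table
            notes = "table alleles CAAA/- conflict with text 'single base deletion'"
        delet = row.deleterious_class
        return VariantRecord(
            variant_id=row.variant_id,
            position=int(row.position),
            ref_allele=row.ref,
            alt_allele=row.alt,
            region_class=row.region_class,
            deleterious_class="NA" if pd.isna(delet) else delet,
            is_novel=bool(row.is_novel),
            notes=notes,
        )

    def _check_consistency(self) -> None:
        if len(self._variants) != 47:
            raise AssertionError("fixture must hold exactly 47 variants")
        case_sum = sum(v.case_counts[0] for v in self.rare_variants())
        ctrl_sum = sum(v.control_counts[0] for v in self.rare_variants())
        if (case_sum, ctrl_sum) != (67, 32):
            raise AssertionError(
                f"rare-variant count totals {case_sum}/{ctrl_sum} != printed 67/32"
            )

    # -- access -------------------------------------------------------------

    def variant(self, variant_id: str) -> FixtureVariant:
        return self._variants[variant_id]

    @property
    def variant_ids(self) -> list[str]:
        return list(self._variants)

    @property
    def records(self) -> list[VariantRecord]:
        return [v.record for v in self._variants.values()]

    def common_variants(self) -> list[FixtureVariant]:
        return [v for v in self._variants.values() if v.rarity == "common"]

    def rare_variants(self) -> list[FixtureVariant]:
        return [v for v in self._variants.values() if v.rarity == "rare"]

    @property
    def table3_pvalues(self) -> np.ndarray:
        return self.table3["p_value"].to_numpy(dtype=float)

    @property
    def haplotype_pool(self) -> list[tuple[str, float]]:
        return list(
            zip(self.table3["haplotype"], self.table3["hap_freq"].astype(float))
        )


def load_paper_fixture() -> PaperFixture:
    return PaperFixture()
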