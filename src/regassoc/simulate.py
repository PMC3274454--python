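"""Synthetic cohorts and the deterministic printed-count reconstruction.

``simulate_cohort`` generates case-control cohorts with the structure the
pipeline assumes: common markers ride a shared haplotype scaffold (each
individual draws two haplotypes independently from a frequency pool, so the
common markers are in Hardy-Weinberg equilibrium and their LD is induced
solely by the pool), rare variants are placed as heterozygous carriers in
configurable functional groups, genotypes go missing completely at random,
and an optional excess-homozygosity variant emulates a genotyping artifact.
Defaults mirror the study being emulated: 716 cases, 397 controls, the
published 7-haplotype pool over the 8 scaffold markers, per-variant carrier
counts from the printed rare-variant table and 2.7% missingness (the
study's mean per-variant genotyping rate was 97.3%).

``reconstruct_paper_cohort`` is RNG-free: it lays out individual genotypes
that reproduce the printed per-variant minor-allele counts exactly (all
rare carriers heterozygous, missingness placed on non-carriers so genotyped
totals match the printed denominators up to diploid parity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fixture import N_CASES, N_CONTROLS, SCAFFOLD_MARKERS, load_paper_fixture
from .io import GenotypeMatrix, PhenotypeVector, VariantRecord


@dataclass(frozen=True)
class RareVariantSpec:
    """One simulated rare variant (or a prescribed carrier layout)."""

    name: str
    region_class: str
    deleterious_class: str = "NA"
    case_carriers: int | None = None  # exact het-carrier count, or
    control_carriers: int | None = None
    case_prob: float | None = None  # per-individual carrier probability
    control_prob: float | None = None


@dataclass(frozen=True)
class HweViolatorSpec:
    """Variant simulated with excess homozygosity (inbreeding coefficient F)."""

    maf: float = 0.3
    inbreeding: float = 0.2
    name: str = "hwe_violator"


@dataclass
class CohortSimConfig:
    n_case: int = N_CASES
    n_control: int = N_CONTROLS
    haplotype_pool: list[tuple[str, float]] | None = None  # default: published pool
    rare_spec: list[RareVariantSpec] | None = None  # default: printed carrier counts
    missing_rate: float = 0.027
    hwe_violator: HweViolatorSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.haplotype_pool is not None:
            total = sum(f for _, f in self.haplotype_pool)
            if abs(total - 1.0) > 1e-9:
                raise ValueError("haplotype pool frequencies must sum to 1")


def table3_pool() -> list[tuple[str, float]]:
    """The published 7-haplotype pool, renormalized to sum to 1.

    The printed frequencies total 0.974; the unattributed remainder is
    spread proportionally rather than assigned to an invented haplotype.
    """
    pool = load_paper_fixture().haplotype_pool
    total = sum(f for _, f in pool)
    return [(h, f / total) for h, f in pool]


def scaffold_records() -> list[VariantRecord]:
    fx = load_paper_fixture()
    return [fx.variant(v).record for v in SCAFFOLD_MARKERS]


def _scaffold_minor_alleles() -> list[str]:
    # haplotype strings use the fixture's major/minor allele letters
    return [r.alt_allele for r in scaffold_records()]


def default_rare_spec() -> list[RareVariantSpec]:
    """Printed per-variant carrier counts (all carriers heterozygous)."""
    fx = load_paper_fixture()
    return [
        RareVariantSpec(
            name=v.record.variant_id,
            region_class=v.record.region_class,
            deleterious_class=v.record.deleterious_class,
            case_carriers=v.case_counts[0],
            control_carriers=v.control_counts[0],
        )
        for v in fx.rare_variants()
    ]


def simulate_cohort(
    config: CohortSimConfig,
) -> tuple[GenotypeMatrix, PhenotypeVector, list[VariantRecord]]:
    """Draw a cohort; fully reproducible from ``config.seed``."""
    ss = np.random.SeedSequence(config.seed)
    rng_hap, rng_rare, rng_miss, rng_hwe = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    n_case, n_ctrl = config.n_case, config.n_control
    n = n_case + n_ctrl
    sample_ids = [f"case{i:04d}" for i in range(n_case)] + [
        f"ctrl{i:04d}" for i in range(n_ctrl)
    ]
    is_case = np.zeros(n, dtype=bool)
    is_case[:n_case] = True

    pool = config.haplotype_pool if config.haplotype_pool is not None else table3_pool()
    haps, freqs = zip(*pool)
    m = len(haps[0])
    if any(len(h) != m for h in haps):
        raise ValueError("haplotype pool strings differ in length")
    minor = _scaffold_minor_alleles() if m == len(SCAFFOLD_MARKERS) else None
    draws = rng_hap.choice(len(haps), size=(n, 2), p=np.asarray(freqs))
    columns = []
    records: list[VariantRecord] = []
    scaffold = scaffold_records()
    for j in range(m):
        if minor is not None:
            is_minor = np.array([h[j] == minor[j] for h in haps])
            rec = scaffold[j]
        else:  # generic pool: treat '1' as the minor allele
            is_minor = np.array([h[j] == "1" for h in haps])
            rec = VariantRecord(
                variant_id=f"marker_{j + 1}",
                position=1000 + j,
                ref_allele="A",
                alt_allele="G",
                region_class="intron",
            )
        columns.append(is_minor[draws].sum(axis=1).astype(float))
        records.append(rec)

    rare = config.rare_spec if config.rare_spec is not None else default_rare_spec()
    fx = load_paper_fixture()
    pos0 = 78_400_000
    for i, spec in enumerate(rare):
        col = np.zeros(n)
        for arm, count, prob in (
            (np.flatnonzero(is_case), spec.case_carriers, spec.case_prob),
            (np.flatnonzero(~is_case), spec.control_carriers, spec.control_prob),
        ):
            if count is None:
                count = int(rng_rare.binomial(arm.size, prob)) if prob else 0
            if count > arm.size:
                raise ValueError(
                    f"{spec.name}: {count} carriers exceed arm size {arm.size}"
                )
            if count:
                col[rng_rare.choice(arm, size=count, replace=False)] = 1.0
        try:
            rec = fx.variant(spec.name).record
        except KeyError:
            rec = VariantRecord(
                variant_id=spec.name,
                position=pos0 + i,
                ref_allele="C",
                alt_allele="T",
                region_class=spec.region_class,
                deleterious_class=spec.deleterious_class,
                is_novel=True,
            )
        columns.append(col)
        records.append(rec)

    if config.hwe_violator is not None:
        v = config.hwe_violator
        q, F = v.maf, v.inbreeding
        probs = [
            (1 - q) ** 2 + F * q * (1 - q),
            2 * q * (1 - q) * (1 - F),
            q**2 + F * q * (1 - q),
        ]
        columns.append(rng_hwe.choice(3, size=n, p=probs).astype(float))
        records.append(
            VariantRecord(
                variant_id=v.name,
                position=pos0 + len(rare) + 1,
                ref_allele="G",
                alt_allele="A",
                region_class="utr3",
                is_novel=True,
            )
        )

    dosages = np.column_stack(columns)
    if config.missing_rate > 0:
        mask = rng_miss.random(dosages.shape) < config.missing_rate
        dosages[mask] = np.nan

    gm = GenotypeMatrix(
        sample_ids, [r.variant_id for r in records], dosages, {"seed": config.seed}
    )
    return gm, PhenotypeVector(sample_ids, is_case), records


# ---------------------------------------------------------------------------
# deterministic reconstruction of the printed cohort


def _place(
    col: np.ndarray, arm: np.ndarray, hom: int, het: int, missing: int, offset: int
) -> None:
    """Fill one arm of one variant: hom/het carriers then missing non-carriers.

    Positions rotate with ``offset`` so that carrier and missingness patterns
    of different variants land on different individuals.
    """
    order = np.roll(arm, -offset)
    col[order[:hom]] = 2.0
    col[order[hom : hom + het]] = 1.0
    noncarrier = order[hom + het :]
    col[noncarrier[:missing]] = np.nan


def reconstruct_paper_cohort() -> tuple[
    GenotypeMatrix, PhenotypeVector, list[VariantRecord]
]:
    """Individual-level genotypes matching the printed per-variant counts.

    RNG-free.  Rare-variant carriers are heterozygous (as the printed
    carrier tables imply); genotyped-sample totals are the printed allele
    denominators divided by two, rounded up where the printed value is odd
    (diploid counts are necessarily even), with missingness placed on
    non-carriers.  Common variants are instantiated from the printed
    case/control frequencies at full call rate, with genotype classes in
    Hardy-Weinberg proportions.
    """
    fx = load_paper_fixture()
    n = N_CASES + N_CONTROLS
    sample_ids = [f"case{i:04d}" for i in range(N_CASES)] + [
        f"ctrl{i:04d}" for i in range(N_CONTROLS)
    ]
    is_case = np.zeros(n, dtype=bool)
    is_case[:N_CASES] = True
    case_idx = np.flatnonzero(is_case)
    ctrl_idx = np.flatnonzero(~is_case)

    columns, records = [], []
    carrier_cursor = {"case": 0, "ctrl": 0}  # distinct carriers across variants
    for v_i, fv in enumerate(fx.common_variants()):
        col = np.zeros(n)
        for arm, f, size in (
            (case_idx, fv.f_case, N_CASES),
            (ctrl_idx, fv.f_control, N_CONTROLS),
        ):
            minor = round(f * 2 * size)
            hom = round(f * f * size)
            het = minor - 2 * hom
            if het < 0:  # rounding collision at high frequency
                hom += het  # reduce homozygotes; keep allele count exact
                het = minor - 2 * hom
            _place(col, arm, hom, het, 0, offset=37 * v_i)
        columns.append(col)
        records.append(fv.record)

    for v_i, fv in enumerate(fx.rare_variants()):
        col = np.zeros(n)
        for arm_name, arm, counts, size in (
            ("case", case_idx, fv.case_counts, N_CASES),
            ("ctrl", ctrl_idx, fv.control_counts, N_CONTROLS),
        ):
            carriers, alleles = counts
            genotyped = (alleles + 1) // 2
            missing = size - genotyped
            cur = carrier_cursor[arm_name]
            order = np.roll(arm, -cur)
            col[order[:carriers]] = 1.0
            carrier_cursor[arm_name] = cur + carriers
            noncarrier = np.array(
                [s for s in np.roll(arm, -(53 * v_i) % size) if col[s] != 1.0]
            )
            col[noncarrier[:missing]] = np.nan
        columns.append(col)
        records.append(fv.record)

    gm = GenotypeMatrix(
        sample_ids, [r.variant_id for r in records], np.column_stack(columns)
    )
    return gm, PhenotypeVector(sample_ids, is_case), records
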