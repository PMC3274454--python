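"""Cohort input/output.

Genotypes are held as a samples x variants matrix of minor-allele dosages
(0, 1, 2 or missing).  "Minor" is defined from the control-sample allele
frequency: resequencing studies classify variants by control MAF, so the
orientation of every downstream count table is anchored in the controls.
Ties at 0.5 are broken toward the alt allele.

Supported formats
-----------------
* VCF v4.2 (GT field only; biallelic records only) via cyvcf2.
* Genotype table: tab-separated, header row of variant ids, first column
  ``sample_id``, cells in {0, 1, 2, NA} counting alt (on read) alleles.
* Phenotype table: tab-separated ``sample_id``, ``status`` in {case, control}.
* Annotation table: tab-separated with the VariantRecord columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

REGION_CLASSES = (
    "promoter",
    "utr5",
    "coding_syn",
    "coding_nonsyn",
    "intron",
    "utr3",
    "downstream",
)
DELETERIOUS_CLASSES = ("benign", "possibly", "probably", "NA")


class ParseError(ValueError):
    """Malformed input file; message names the offending line/record."""


class ReconciliationError(ValueError):
    """Genotype and phenotype files do not describe the same samples."""


@dataclass(frozen=True)
class VariantRecord:
    """Identity and annotation of one biallelic variant.

    ``position`` is 1-based on the build named in ``build`` (metadata only,
    never used in computation).  ``ref_allele``/``alt_allele`` may be "-" for
    a deletion allele as printed in variant tables.  ``deleterious_class``
    (a predicted-impact label such as PolyPhen2's benign/possibly/probably)
    is only meaningful for non-synonymous coding variants.
    """

    variant_id: str
    position: int
    ref_allele: str
    alt_allele: str
    region_class: str
    deleterious_class: str = "NA"
    is_novel: bool = False
    build: str = "hg18"
    notes: str = ""

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise ValueError(f"{self.variant_id}: position must be positive")
        if self.region_class not in REGION_CLASSES:
            raise ValueError(
                f"{self.variant_id}: unknown region class {self.region_class!r}"
            )
        if self.deleterious_class not in DELETERIOUS_CLASSES:
            raise ValueError(
                f"{self.variant_id}: unknown deleteriousness {self.deleterious_class!r}"
            )
        if self.deleterious_class != "NA" and self.region_class != "coding_nonsyn":
            raise ValueError(
                f"{self.variant_id}: deleteriousness class only applies to "
                "non-synonymous coding variants"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.variant_id}: ref and alt allele are identical")


@dataclass
class GenotypeMatrix:
    """Samples x variants minor-allele dosage matrix with missing entries.

    ``dosages`` is a float array; missing genotypes are ``nan`` and every
    non-missing entry is 0, 1 or 2.
    """

    sample_ids: list[str]
    variant_ids: list[str]
    dosages: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or m != len(self.variant_ids):
            raise ValueError("dosage matrix shape does not match id lists")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.variant_ids)) != m:
            raise ValueError("duplicate variant ids")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing dosages must be 0, 1 or 2")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def column(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self.variant_ids.index(variant_id)]

    def subset_variants(self, keep: list[str]) -> "GenotypeMatrix":
        idx = [self.variant_ids.index(v) for v in keep]
        return GenotypeMatrix(
            list(self.sample_ids), list(keep), self.dosages[:, idx], dict(self.meta)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosages, index=self.sample_ids, columns=self.variant_ids
        )


@dataclass
class PhenotypeVector:
    """Case/control status for exactly the samples of one GenotypeMatrix."""

    sample_ids: list[str]
    is_case: np.ndarray

    def __post_init__(self) -> None:
        self.is_case = np.asarray(self.is_case, dtype=bool)
        if self.is_case.shape != (len(self.sample_ids),):
            raise ValueError("status vector length does not match sample ids")

    @property
    def n_cases(self) -> int:
        return int(self.is_case.sum())

    @property
    def n_controls(self) -> int:
        return int((~self.is_case).sum())

    def aligned_to(self, gm: GenotypeMatrix) -> "PhenotypeVector":
        """Reorder to the sample order of ``gm``; error on any mismatch."""
        lookup = dict(zip(self.sample_ids, self.is_case))
        missing = [s for s in gm.sample_ids if s not in lookup]
        if missing:
            raise ReconciliationError(
                f"samples in genotypes but not in phenotype file: {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )
        return PhenotypeVector(
            list(gm.sample_ids), np.array([lookup[s] for s in gm.sample_ids])
        )


# ---------------------------------------------------------------------------
# readers


def read_phenotypes(path) -> PhenotypeVector:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "sample_id" not in df.columns or "status" not in df.columns:
        raise ParseError(f"{path}: phenotype table needs sample_id and status columns")
    bad = ~df["status"].isin(["case", "control"])
    if bad.any():
        line = df.index[bad][0] + 2
        raise ParseError(f"{path}: line {line}: status must be 'case' or 'control'")
    return PhenotypeVector(df["sample_id"].tolist(), (df["status"] == "case").to_numpy())


def read_annotations(path) -> list[VariantRecord]:
    # "NA" is a literal deleteriousness class, not a missing value
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    required = {"variant_id", "position", "ref_allele", "alt_allele", "region_class"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: annotation table missing {required - set(df.columns)}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                VariantRecord(
                    variant_id=row["variant_id"],
                    position=int(row["position"]),
                    ref_allele=row["ref_allele"],
                    alt_allele=row["alt_allele"],
                    region_class=row["region_class"],
                    deleterious_class=row.get("deleterious_class", "NA") or "NA",
                    is_novel=str(row.get("is_novel", "0")) in ("1", "True", "true"),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: line {i + 2}: {exc}") from exc
    return records


def read_genotype_table(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.columns[0] != "sample_id":
        raise ParseError(f"{path}: first column must be sample_id")
    samples = df["sample_id"].tolist()
    body = df.drop(columns="sample_id").replace("NA", np.nan)
    try:
        dosages = body.to_numpy(dtype=float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric genotype cell ({exc})") from exc
    return GenotypeMatrix(samples, list(body.columns), dosages)


def read_vcf(path) -> tuple[GenotypeMatrix, list[VariantRecord]]:
    """Read GT dosages (alt-allele counts) from a biallelic VCF.

    Multi-allelic records are rejected.  Returned records carry positional
    annotation only; region/deleteriousness classes come from the separate
    annotation table.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    ids, cols, records = [], [], []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ParseError(
                f"{path}: non-biallelic record at {v.CHROM}:{v.POS} "
                f"({v.REF}/{','.join(v.ALT)})"
            )
        vid = v.ID or f"{v.CHROM}:{v.POS}"
        ids.append(vid)
        gt = np.asarray(v.gt_types, dtype=float)  # 0/1/2, 3 = unknown
        gt[gt == 3] = np.nan
        cols.append(gt)
        records.append(
            VariantRecord(
                variant_id=vid,
                position=v.POS,
                ref_allele=v.REF,
                alt_allele=v.ALT[0],
                region_class="intron",
            )
        )
    if not ids:
        raise ParseError(f"{path}: no variant records")
    return GenotypeMatrix(samples, ids, np.column_stack(cols)), records


def orient_to_minor(gm: GenotypeMatrix, phen: PhenotypeVector) -> GenotypeMatrix:
    """Recode dosages so each column counts the control-minor allele.

    A column is flipped (d -> 2-d) when the counted allele's frequency among
    genotyped controls exceeds 0.5; at exactly 0.5 the alt allele stays the
    counted ("minor") allele.
    """
    phen = phen.aligned_to(gm)
    ctrl = ~phen.is_case
    d = gm.dosages.copy()
    flipped = []
    for j, vid in enumerate(gm.variant_ids):
        col = d[ctrl, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            continue
        if col.sum() / (2 * col.size) > 0.5:
            d[:, j] = 2 - d[:, j]
            flipped.append(vid)
    meta = dict(gm.meta)
    meta["flipped_to_minor"] = flipped
    return GenotypeMatrix(list(gm.sample_ids), list(gm.variant_ids), d, meta)


def read_genotypes(
    path, phenotype_path, annotation_path=None
) -> tuple[GenotypeMatrix, PhenotypeVector, list[VariantRecord]]:
    """Load a cohort and recode dosages to control-minor orientation."""
    path = Path(path)
    if path.suffix in (".vcf", ".gz") or path.name.endswith(".vcf.gz"):
        gm, records = read_vcf(path)
    else:
        gm = read_genotype_table(path)
        records = []
    phen = read_phenotypes(phenotype_path).aligned_to(gm)
    if annotation_path is not None:
        records = read_annotations(annotation_path)
        by_id = {r.variant_id: r for r in records}
        missing = [v for v in gm.variant_ids if v not in by_id]
        if missing:
            raise ReconciliationError(f"variants without annotation: {missing[:5]}")
        records = [by_id[v] for v in gm.variant_ids]
    gm = orient_to_minor(gm, phen)
    return gm, phen, records


# ---------------------------------------------------------------------------
# writers

_HEADER = "# regassoc 0.1.0"


def write_genotype_table(gm: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(_HEADER + "\n")
        fh.write("sample_id\t" + "\t".join(gm.variant_ids) + "\n")
        for i, s in enumerate(gm.sample_ids):
            cells = [
                "NA" if np.isnan(x) else str(int(x)) for x in gm.dosages[i]
            ]
            fh.write(s + "\t" + "\t".join(cells) + "\n")


def write_phenotypes(phen: PhenotypeVector, path) -> None:
    with open(path, "w") as fh:
        fh.write(_HEADER + "\nsample_id\tstatus\n")
        for s, c in zip(phen.sample_ids, phen.is_case):
            fh.write(f"{s}\t{'case' if c else 'control'}\n")


def write_annotations(records: list[VariantRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(_HEADER + "\n")
        fh.write(
            "variant_id\tposition\tref_allele\talt_allele\tregion_class\t"
            "deleterious_class\tis_novel\n"
        )
        for r in records:
            fh.write(
                f"{r.variant_id}\t{r.position}\t{r.ref_allele}\t{r.alt_allele}\t"
                f"{r.region_class}\t{r.deleterious_class}\t{int(r.is_novel)}\n"
            )


def _vcf_alleles(ref: str, alt: str) -> tuple[str, str]:
    # plain "-" deletion notation is not legal VCF; anchor with N
    if ref == "-":
        return "N", "N" + alt
    if alt == "-":
        return "N" + ref, "N"
    return ref, alt


def write_vcf(gm: GenotypeMatrix, records: list[VariantRecord], path) -> None:
    """Write dosages as an unphased single-chromosome VCF v4.2 (GT only).

    Dosages are written as counts of the ALT allele, i.e. the matrix is
    assumed minor-oriented with alt = minor.
    """
    by_id = {r.variant_id: r for r in records}
    gts = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=17>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        order = sorted(range(gm.n_variants), key=lambda j: by_id[gm.variant_ids[j]].position)
        for j in order:
            r = by_id[gm.variant_ids[j]]
            ref, alt = _vcf_alleles(r.ref_allele, r.alt_allele)
            cells = [
                "./." if np.isnan(x) else gts[int(x)] for x in gm.dosages[:, j]
            ]
            fh.write(
                f"17\t{r.position}\t{r.variant_id}\t{ref}\t{alt}\t.\t.\t.\tGT\t"
                + "\t".join(cells)
                + "\n"
            )
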