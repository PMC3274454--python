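"""End-to-end orchestration: QC -> single-variant -> haplotype -> burden -> FDR.

Each stage writes one tab-separated table mirroring the corresponding
published table layout, plus a machine-readable JSON manifest recording
settings, seed, package version, input checksums and every QC exclusion.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .burden import burden_frame, burden_scan
from .haplotype import (
    em_haplotype_freqs,
    gabriel_blocks,
    haplotype_empirical_p,
    ld_ci_matrix,
)
from .io import read_genotypes
from .multiple_testing import bh_qvalues
from .qc import qc_frame, run_qc
from .single_variant import scan_frame, single_variant_scan

_TABLE_HEADER = f"# regassoc {__version__}\n"


@dataclass
class PipelineConfig:
    genotypes: str
    phenotypes: str
    annotations: str | None = None
    hwe_alpha: float = 0.05
    rare_maf: float = 0.02
    hap_permutations: int = 100_000
    burden_permutations: int = 10_000
    min_hap_freq: float = 0.01
    seed: int = 0
    outdir: str = "regassoc_out"


def _checksum(path: str) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(_TABLE_HEADER)
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns the manifest dictionary."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gm, phen, records = read_genotypes(cfg.genotypes, cfg.phenotypes, cfg.annotations)

    reports = run_qc(gm, phen, hwe_alpha=cfg.hwe_alpha, rare_maf=cfg.rare_maf)
    _write(qc_frame(reports), outdir / "qc.tsv")
    excluded = [r.variant_id for r in reports if r.excluded]
    keep = [r.variant_id for r in reports if not r.excluded]
    rarity = {r.variant_id: r.rarity for r in reports if not r.excluded}
    gm = gm.subset_variants(keep)
    records = [r for r in records if r.variant_id in set(keep)]

    single = scan_frame(single_variant_scan(gm, phen))
    _write(single, outdir / "single_variant.tsv")

    # haplotype stage over blocks of common markers (ordered by position)
    common = [r for r in records if rarity[r.variant_id] == "common"]
    common.sort(key=lambda r: r.position, reverse=True)
    hap_rows = []
    if len(common) >= 2:
        idx = [gm.variant_ids.index(r.variant_id) for r in common]
        ci = ld_ci_matrix(gm.dosages[:, idx])
        blocks = gabriel_blocks(ci)
        for b, block in enumerate(blocks):
            cols = [idx[j] for j in block.markers]
            fs = em_haplotype_freqs(gm.dosages[:, cols])
            res = haplotype_empirical_p(
                fs,
                phen.aligned_to(gm).is_case,
                min_report_freq=cfg.min_hap_freq,
                k=cfg.hap_permutations,
                seed=cfg.seed,
            )
            alleles = [
                (common[j].ref_allele, common[j].alt_allele) for j in block.markers
            ]
            qvals = bh_qvalues([r.p for r in res])
            for r, q in zip(res, qvals):
                hap_rows.append(
                    {
                        "block": b + 1,
                        "markers": ",".join(common[j].variant_id for j in block.markers),
                        "haplotype": "".join(
                            alleles[i][int(c)] for i, c in enumerate(r.haplotype)
                        ),
                        "hap_freq": r.freq_all,
                        "f_case": r.freq_case,
                        "f_control": r.freq_control,
                        "chi2": r.chi2,
                        "p_value": r.p,
                        "emp_p": r.empirical_p,
                        "q_value": q,
                        "odds_ratio": r.odds_ratio,
                    }
                )
    _write(pd.DataFrame(hap_rows), outdir / "haplotypes.tsv")

    results = burden_scan(
        gm, phen, records, rarity, k=cfg.burden_permutations, seed=cfg.seed
    )
    _write(burden_frame(results), outdir / "burden.tsv")

    manifest = {
        "version": __version__,
        "settings": {
            "hwe_alpha": cfg.hwe_alpha,
            "rare_maf": cfg.rare_maf,
            "hap_permutations": cfg.hap_permutations,
            "burden_permutations": cfg.burden_permutations,
            "seed": cfg.seed,
        },
        "inputs": {
            p: _checksum(p)
            for p in (cfg.genotypes, cfg.phenotypes, cfg.annotations)
            if p
        },
        "n_samples": gm.n_samples,
        "n_cases": int(phen.aligned_to(gm).is_case.sum()),
        "n_variants_input": len(reports),
        "excluded": excluded,
        "analyzed_variants": keep,
        "outputs": [
            str(outdir / f)
            for f in ("qc.tsv", "single_variant.tsv", "haplotypes.tsv", "burden.tsv")
        ],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
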