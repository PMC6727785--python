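"""Germline variant filtering: calls -> binary functional-mutation matrix.

A variant is counted as a functional germline event when (a) its variant
allele fraction (VAF = alt reads / depth) falls in the heterozygous window
[0.45, 0.55] or the homozygous window (0.90, 1.0], and (b) its scaled
deleteriousness score (CADD-style) reaches the functional threshold
(default 15).  Gene-level collapsing is an indicator — a gene/sample cell is
1 when at least one call passes both filters — and the burden score is the
per-sample count of mutated genes within a gene set.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "VariantCall",
    "classify_genotype",
    "is_functional",
    "build_mutation_matrix",
    "burden",
    "write_vcf",
    "read_vcf",
    "write_mutation_matrix",
    "read_mutation_matrix",
    "DEFAULT_SCORE_THRESHOLD",
]

DEFAULT_SCORE_THRESHOLD = 15.0

HET_LOW, HET_HIGH = 0.45, 0.55  # inclusive heterozygous VAF window
HOM_LOW = 0.90  # exclusive lower bound of the homozygous window


@dataclasses.dataclass(frozen=True)
class VariantCall:
    """One variant call for one sample, annotated with its gene and score."""

    sample: str
    gene: str
    position: int
    depth: int
    alt_depth: int
    score: float
    chrom: str = "1"
    ref: str = "A"
    alt: str = "T"

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError(f"depth must be positive, got {self.depth}")
        if not 0 <= self.alt_depth <= self.depth:
            raise ValueError(
                f"alt_depth {self.alt_depth} outside [0, depth={self.depth}]"
            )
        if self.position < 1:
            raise ValueError("position is 1-based and must be >= 1")

    @property
    def vaf(self) -> float:
        return self.alt_depth / self.depth


def classify_genotype(vaf: float) -> str:
    """Classify a VAF as ``het``, ``hom`` or ``reject``.

    The germline windows are 0.45-0.55 (heterozygous, inclusive) and
    above 0.90 (homozygous); everything else is rejected as a likely
    artifact or somatic contamination.
    """
    if not 0.0 <= vaf <= 1.0:
        raise ValueError(f"vaf {vaf} outside [0, 1]")
    if HET_LOW <= vaf <= HET_HIGH:
        return "het"
    if vaf > HOM_LOW:
        return "hom"
    return "reject"


def is_functional(call: VariantCall, threshold: float = DEFAULT_SCORE_THRESHOLD) -> bool:
    """True when the deleteriousness score reaches the threshold (inclusive)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return call.score >= threshold


def build_mutation_matrix(
    calls: list[VariantCall],
    genes: list[str],
    samples: list[str],
    threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> pd.DataFrame:
    """Collapse calls to a binary genes x samples functional-mutation matrix.

    Entry (g, s) is 1 iff at least one call for that gene/sample passes both
    the VAF genotype filter and the deleteriousness filter.  Calls naming a
    gene or sample outside the supplied lists raise an error listing the
    offenders.
    """
    gene_idx = {g: i for i, g in enumerate(genes)}
    sample_idx = {s: j for j, s in enumerate(samples)}
    unknown_genes = sorted({c.gene for c in calls if c.gene not in gene_idx})
    unknown_samples = sorted({c.sample for c in calls if c.sample not in sample_idx})
    if unknown_genes or unknown_samples:
        raise ValueError(
            f"calls reference unknown genes {unknown_genes[:5]} "
            f"and/or unknown samples {unknown_samples[:5]}"
        )
    mat = np.zeros((len(genes), len(samples)), dtype=np.int8)
    for call in calls:
        if classify_genotype(call.vaf) == "reject":
            continue
        if not is_functional(call, threshold):
            continue
        mat[gene_idx[call.gene], sample_idx[call.sample]] = 1
    out = pd.DataFrame(mat, index=pd.Index(genes, name="gene"), columns=samples)
    return out


def burden(matrix: pd.DataFrame, gene_set: list[str]) -> pd.Series:
    """Per-sample count of mutated genes within ``gene_set``.

    Genes absent from the matrix are ignored with a warning; an empty gene
    set is an error.
    """
    if len(gene_set) == 0:
        raise ValueError("empty gene set")
    present = [g for g in gene_set if g in matrix.index]
    missing = sorted(set(gene_set) - set(present))
    if missing:
        warnings.warn(
            f"{len(missing)} gene(s) absent from mutation matrix ignored: {missing[:5]}",
            stacklevel=2,
        )
    if not present:
        raise ValueError("no gene of the set is present in the matrix")
    counts = matrix.loc[present].sum(axis=0).astype(int)
    counts.name = "burden"
    return counts


def write_mutation_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene", lineterminator="\n")


def read_mutation_matrix(path: str | Path) -> pd.DataFrame:
    mat = pd.read_csv(path, sep="\t", index_col=0)
    values = mat.to_numpy()
    if not np.isin(values, [0, 1]).all():
        raise ValueError(f"{Path(path).name}: mutation matrix entries must be 0/1")
    return mat.astype(np.int8)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Annotated gene">
##INFO=<ID=SCORE,Number=1,Type=Float,Description="Scaled deleteriousness score">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=1,Type=Integer,Description="Alt-supporting read depth">
##contig=<ID=1>
"""


def write_vcf(calls: list[VariantCall], samples: list[str], path: str | Path) -> None:
    """Write calls as a minimal multi-sample VCF 4.2 (FORMAT ``DP:AD``).

    Each record carries one sample's data; other sample columns are missing.
    """
    sample_pos = {s: j for j, s in enumerate(samples)}
    unknown = sorted({c.sample for c in calls if c.sample not in sample_pos})
    if unknown:
        raise ValueError(f"calls reference samples not in header: {unknown[:5]}")
    ordered = sorted(calls, key=lambda c: (c.chrom, c.position, c.sample))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_VCF_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for call in ordered:
            cells = ["."] * len(samples)
            cells[sample_pos[call.sample]] = f"{call.depth}:{call.alt_depth}"
            row = [
                call.chrom,
                str(call.position),
                ".",
                call.ref,
                call.alt,
                ".",
                "PASS",
                f"GENE={call.gene};SCORE={call.score!r}",
                "DP:AD",
                *cells,
            ]
            fh.write("\t".join(row) + "\n")


def read_vcf(path: str | Path) -> list[VariantCall]:
    """Read the minimal VCF dialect back into :class:`VariantCall` records.

    Multi-allelic records are rejected; records or sample columns without
    DP/AD are skipped (no call for that sample).
    """
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_names = list(vcf.header.samples)
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(
                    f"{Path(path).name}: multi-allelic record at {rec.chrom}:{rec.pos}"
                )
            gene = rec.info.get("GENE")
            score = rec.info.get("SCORE")
            if gene is None or score is None:
                raise ValueError(
                    f"{Path(path).name}: record at {rec.chrom}:{rec.pos} lacks GENE/SCORE"
                )
            for sample in sample_names:
                fmt = rec.samples[sample]
                dp = fmt.get("DP")
                ad = fmt.get("AD")
                if dp is None or ad is None:
                    continue
                calls.append(
                    VariantCall(
                        sample=sample,
                        gene=str(gene),
                        position=rec.pos,
                        depth=int(dp),
                        alt_depth=int(ad),
                        score=float(score),
                        chrom=rec.chrom,
                        ref=rec.ref,
                        alt=rec.alts[0],
                    )
                )
    return calls
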