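"""VCF v4.2 round-tripping for sampled cohorts (via pysam).

Genotype matrices are written as diploid GT records on one synthetic contig,
with the simulator's per-site annotations carried in INFO fields S (selection
coefficient), HDOM (dominance coefficient) and KIND (neutral/deleterious).
Positions are converted between the package's 0-based half-open convention
and VCF's 1-based coordinates at this boundary only.
"""

from __future__ import annotations

import numpy as np
import pysam

from .engine import GenotypeMatrix
from .genome_model import DELETERIOUS

__all__ = ["write_vcf", "read_vcf", "CONTIG"]

CONTIG = "chrSim"


def write_vcf(gm: GenotypeMatrix, path: str, contig_length: int | None = None) -> None:
    """Write a genotype matrix as an uncompressed VCF v4.2 file."""
    if contig_length is None:
        contig_length = int(gm.positions[-1]) + 1 if gm.n_sites else 1
    header = pysam.VariantHeader()
    header.contigs.add(CONTIG, length=contig_length)
    header.info.add("S", 1, "Float", "Homozygous selection coefficient")
    header.info.add("HDOM", 1, "Float", "Dominance coefficient")
    header.info.add("KIND", 1, "String", "Mutation kind (neutral/deleterious)")
    header.formats.add("GT", 1, "String", "Genotype")
    samples = gm.sample_ids or [f"ind{i}" for i in range(gm.n_individuals)]
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(path, "w", header=header) as vf:
        for j in range(gm.n_sites):
            rec = vf.new_record(
                contig=CONTIG,
                start=int(gm.positions[j]),
                alleles=("A", "T"),
            )
            if gm.s is not None:
                rec.info["S"] = float(gm.s[j])
            if gm.h is not None:
                rec.info["HDOM"] = float(gm.h[j])
            if gm.kind is not None:
                rec.info["KIND"] = (
                    "deleterious" if gm.kind[j] == DELETERIOUS else "neutral"
                )
            for i, name in enumerate(samples):
                g = int(gm.genotypes[i, j])
                if g < 0:
                    rec.samples[name]["GT"] = (None, None)
                else:
                    rec.samples[name]["GT"] = (1, 1) if g == 2 else ((0, 1) if g == 1 else (0, 0))
            vf.write(rec)


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a diploid VCF into a genotype matrix (alt-allele dosage coding)."""
    kinds = {"neutral": 0, "deleterious": 1}
    positions, geno_cols, s_vals, h_vals, kind_vals = [], [], [], [], []
    has_info = False
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            positions.append(rec.start)
            col = []
            for name in samples:
                gt = rec.samples[name].get("GT", (None, None))
                if gt is None or any(a is None for a in gt):
                    col.append(-1)
                else:
                    col.append(sum(1 for a in gt if a and a > 0))
            geno_cols.append(col)
            if "S" in rec.info:
                has_info = True
                s_vals.append(float(rec.info["S"]))
                h_vals.append(float(rec.info.get("HDOM", 0.5)))
                k = rec.info.get("KIND", "neutral")
                kind_vals.append(kinds.get(str(k), 0))
            else:
                s_vals.append(0.0)
                h_vals.append(0.5)
                kind_vals.append(0)
    geno = (
        np.array(geno_cols, dtype=np.int8).T
        if geno_cols
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(
        geno,
        np.array(positions, dtype=np.int64),
        s=np.array(s_vals) if has_info else None,
        h=np.array(h_vals) if has_info else None,
        kind=np.array(kind_vals, dtype=np.uint8) if has_info else None,
        sample_ids=samples,
    )
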