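"""Readers and writers for the pipeline's file interfaces.

Phased genotypes travel as VCF with phased GT fields and ``##contig``
headers (read back through cyvcf2); variant panels as VCF with a
``CLASS=`` INFO key carrying the consequence class; pedigree as TSV and
litters as CSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import (
    MISSING,
    LitterRecord,
    Pedigree,
    PhasedGenotypes,
    VariantRecord,
)

_VCF_HEADER = "##fileformat=VCFv4.2\n"


def write_phased_vcf(genotypes: PhasedGenotypes, path: str) -> None:
    """Write phased genotypes as a VCF with '|'-separated GT calls."""
    mm = genotypes.marker_map
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom, grp in mm.groupby("chrom", sort=False):
            fh.write(f"##contig=<ID={chrom},length={int(grp['pos'].max()) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, genotypes.animal_ids)) + "\n")
        a = genotypes.alleles
        for j in range(genotypes.n_markers):
            row = mm.iloc[j]
            calls = []
            for i in range(genotypes.n_animals):
                h0, h1 = a[i, j]
                calls.append(".|." if h0 == MISSING else f"{h0}|{h1}")
            fh.write(f"{row['chrom']}\t{row['pos']}\tm{j}\t{row['ref']}\t"
                     f"{row['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n")


def read_phased_vcf(path: str) -> PhasedGenotypes:
    """Read a phased VCF into a PhasedGenotypes container (via cyvcf2)."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    ids = np.array(vcf.samples)
    chroms, poss, refs, alts = [], [], [], []
    allele_rows = []
    phased = True
    for var in vcf:
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0] if var.ALT else ".")
        g = np.array(var.genotypes)  # (n, 3): allele0, allele1, phased flag
        row = g[:, :2].astype(np.int8)
        row[row < 0] = MISSING
        miss = (row == MISSING).any(axis=1)
        row[miss] = MISSING
        if not np.all(g[~miss, 2]):
            phased = False
        allele_rows.append(row)
    vcf.close()
    alleles = np.stack(allele_rows, axis=1)  # (n_animals, n_markers, 2)
    marker_map = pd.DataFrame({"chrom": chroms, "pos": poss,
                               "ref": refs, "alt": alts})
    return PhasedGenotypes(ids, marker_map, alleles, phased=phased)


def write_variant_panel_vcf(panel: list[VariantRecord], animal_ids,
                            path: str) -> None:
    """Write a variant panel VCF with a CLASS INFO key and GT dosages."""
    variants = sorted(panel, key=lambda v: (str(v.chrom), v.pos))
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom in dict.fromkeys(str(v.chrom) for v in variants):
            length = max(v.pos for v in variants if str(v.chrom) == chrom) + 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=CLASS,Number=1,Type=String,'
                 'Description="Consequence class">\n')
        fh.write('##INFO=<ID=DEL,Number=0,Type=Flag,'
                 'Description="Predicted deleterious">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, animal_ids)) + "\n")
        gt = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for k, v in enumerate(variants):
            info = f"CLASS={v.consequence_class}" + (";DEL" if v.deleterious else "")
            calls = [gt.get(d, "./.") for d in v.dosages]
            vid = v.vid or f"v{k}"
            fh.write(f"{v.chrom}\t{v.pos}\t{vid}\t{v.ref}\t{v.alt}\t.\tPASS\t"
                     f"{info}\tGT\t" + "\t".join(calls) + "\n")


def read_variant_panel_vcf(path: str) -> tuple[list[VariantRecord], np.ndarray]:
    """Read a CLASS-annotated variant panel VCF; returns (panel, animal ids)."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    ids = np.array(vcf.samples)
    panel = []
    for var in vcf:
        g = np.array(var.genotypes)
        d = g[:, :2].astype(float)
        d[d < 0] = np.nan
        dosages = d.sum(axis=1)
        cls = var.INFO.get("CLASS") or "intergenic"
        panel.append(VariantRecord(var.CHROM, var.POS, var.REF,
                                   var.ALT[0] if var.ALT else ".",
                                   cls, dosages,
                                   deleterious=bool(var.INFO.get("DEL")),
                                   vid=var.ID))
    vcf.close()
    return panel, ids


def write_pedigree(pedigree: Pedigree, path: str) -> None:
    df = pedigree.records.copy()
    df["birthdate"] = pd.to_datetime(df["birthdate"]).dt.date
    df.to_csv(path, sep="\t", index=False)


def read_pedigree(path: str) -> Pedigree:
    df = pd.read_csv(path, sep="\t", dtype={"animal": str, "sire": str,
                                            "dam": str})
    return Pedigree(df)


def write_litters(litters: list[LitterRecord] | pd.DataFrame, path: str) -> None:
    from .types import litters_to_frame

    df = litters if isinstance(litters, pd.DataFrame) else litters_to_frame(litters)
    df.to_csv(path, index=False)


def read_litters(path: str) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"sire": str, "dam": str})
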