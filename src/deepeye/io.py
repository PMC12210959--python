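"""Readers and writers for the fixture bundle formats.

VCF 4.2 with phased GT, INFO/AA for the ancestral allele and per-site QC
INFO fields (MQ, MQ0F, ExcHet, SBP = strand-bias P, ABR/ABA = pooled
heterozygote ref/alt read counts for the allele-balance test); GFF3 gene
models; plain TSV tables; Newick trees.  Writers emit canonical formatting
(floats via %.6g) so that write -> read -> write is byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from skbio import TreeNode

from .panel import HaplotypePanel, SiteTable

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_gff3",
    "read_gff3",
    "write_newick",
    "read_newick",
]

_INFO_FLOAT_FIELDS = ("mq", "mq0f", "exchet", "strandbias_p")
_INFO_KEYS = {"mq": "MQ", "mq0f": "MQ0F", "exchet": "ExcHet", "strandbias_p": "SBP"}


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def write_vcf(
    path,
    panel: HaplotypePanel,
    site_info: pd.DataFrame | None = None,
    filters: list[str] | None = None,
) -> None:
    """Write a phased, polarized panel as VCF 4.2.

    REF is the ancestral allele (AA tag set accordingly), ALT the derived
    allele.  ``site_info`` may carry QC INFO columns (mq, mq0f, exchet,
    strandbias_p, ab_ref, ab_alt) aligned with the panel's sites.
    ``filters`` gives the FILTER column per site ("PASS" or a
    semicolon-joined list of failed rule names).
    """
    path = Path(path)
    lines = ["##fileformat=VCFv4.2"]
    for c in dict.fromkeys(panel.chrom.tolist()):
        length = panel.chrom_lengths.get(str(c))
        if length is None:
            length = int(panel.pos[panel.chrom == c].max())
        lines.append(f"##contig=<ID={c},length={length}>")
    lines += [
        '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">',
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
        '##INFO=<ID=MQ0F,Number=1,Type=Float,Description="Fraction of MQ0 reads">',
        '##INFO=<ID=ExcHet,Number=1,Type=Float,Description="Excess heterozygosity statistic">',
        '##INFO=<ID=SBP,Number=1,Type=Float,Description="Strand bias P-value">',
        '##INFO=<ID=ABR,Number=1,Type=Integer,Description="Pooled het ref reads">',
        '##INFO=<ID=ABA,Number=1,Type=Integer,Description="Pooled het alt reads">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(panel.samples)
    )
    h = panel.haplotypes
    for s in range(panel.n_sites):
        info = ["AA=A"]
        if site_info is not None:
            row = site_info.iloc[s]
            for col in _INFO_FLOAT_FIELDS:
                if col in site_info.columns and pd.notna(row[col]):
                    info.append(f"{_INFO_KEYS[col]}={_fmt(float(row[col]))}")
            for col, key in (("ab_ref", "ABR"), ("ab_alt", "ABA")):
                if col in site_info.columns and pd.notna(row[col]):
                    info.append(f"{key}={int(row[col])}")
        gts = "\t".join(
            f"{h[2 * i, s]}|{h[2 * i + 1, s]}" for i in range(panel.n_samples)
        )
        filt = "PASS" if filters is None else (filters[s] or "PASS")
        lines.append(
            f"{panel.chrom[s]}\t{panel.pos[s]}\t.\tA\tT\t.\t{filt}\t{';'.join(info)}\tGT\t{gts}"
        )
    path.write_text("\n".join(lines) + "\n")


def read_vcf(path, species: pd.Series | dict | None = None) -> tuple[HaplotypePanel, SiteTable]:
    """Read a phased VCF into a panel plus site table.

    ``species`` maps sample id -> species; samples without a mapping get
    species "unknown" (the VCF itself does not carry species)."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if species is None:
        species_arr = np.array(["unknown"] * len(samples))
    else:
        getter = species.get if hasattr(species, "get") else species.__getitem__
        species_arr = np.array([getter(s, "unknown") for s in samples])
    chrom_lengths = {}
    for c, ln in zip(vcf.seqnames, vcf.seqlens or []):
        chrom_lengths[c] = int(ln)
    chroms, poss, haps, rows = [], [], [], []
    for v in vcf:
        chroms.append(v.CHROM)
        poss.append(v.POS)
        gt = np.array(v.genotypes)  # (n_samples, 3): a, b, phased
        haps.append(np.stack([gt[:, 0], gt[:, 1]], axis=1).reshape(-1))
        info = {"chrom": v.CHROM, "pos": v.POS, "n_alleles": 1 + len(v.ALT)}
        for col, key in _INFO_KEYS.items():
            val = v.INFO.get(key)
            if val is not None:
                info[col] = float(val)
        for col, key in (("ab_ref", "ABR"), ("ab_alt", "ABA")):
            val = v.INFO.get(key)
            if val is not None:
                info[col] = int(val)
        rows.append(info)
    hap_matrix = np.stack(haps, axis=1).astype(np.int8)
    panel = HaplotypePanel(
        haplotypes=hap_matrix,
        samples=samples,
        species=species_arr,
        chrom=np.array(chroms),
        pos=np.array(poss, dtype=np.int64),
        chrom_lengths=chrom_lengths,
    )
    return panel, SiteTable(pd.DataFrame(rows))


_GFF_COLS = ["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]


def write_gff3(path, genes: pd.DataFrame, features: pd.DataFrame) -> None:
    """Write gene models as GFF3.

    ``genes``: gene_id, chrom, start, end, strand (1-based inclusive).
    ``features``: gene_id, type (CDS / three_prime_UTR / intron), start, end.
    """
    lines = ["##gff-version 3"]
    feats = features.set_index("gene_id", drop=False)
    for _, g in genes.iterrows():
        lines.append(
            f"{g['chrom']}\tdeepeye\tgene\t{int(g['start'])}\t{int(g['end'])}\t.\t{g['strand']}\t.\tID={g['gene_id']}"
        )
        if g["gene_id"] in feats.index:
            sub = feats.loc[[g["gene_id"]]]
            for _, f in sub.iterrows():
                phase = "0" if f["type"] == "CDS" else "."
                lines.append(
                    f"{g['chrom']}\tdeepeye\t{f['type']}\t{int(f['start'])}\t{int(f['end'])}\t.\t{g['strand']}\t{phase}\tParent={g['gene_id']}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the gene-model GFF3 back into (genes, features) DataFrames."""
    df = pd.read_csv(path, sep="\t", comment="#", names=_GFF_COLS, dtype={"start": int, "end": int})

    def _attr(s: str, key: str) -> str:
        for part in s.split(";"):
            if part.startswith(key + "="):
                return part.split("=", 1)[1]
        return ""

    genes = df[df["type"] == "gene"].copy()
    genes["gene_id"] = genes["attributes"].map(lambda s: _attr(s, "ID"))
    genes = genes.rename(columns={"seqid": "chrom"})[
        ["gene_id", "chrom", "start", "end", "strand"]
    ].reset_index(drop=True)
    genes["tss"] = np.where(genes["strand"] == "+", genes["start"], genes["end"])
    feats = df[df["type"] != "gene"].copy()
    feats["gene_id"] = feats["attributes"].map(lambda s: _attr(s, "Parent"))
    feats = feats[["gene_id", "type", "start", "end"]].reset_index(drop=True)
    return genes, feats


def write_newick(path, tree: TreeNode) -> None:
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")
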