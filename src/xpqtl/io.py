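"""Plain-text I/O: TSV matrices, minimal VCF, BED regions, GraphML.

In-memory coordinates are 1-based inclusive; BED files are 0-based
half-open and converted at this boundary. The minimal VCF is v4.2 with
GT-only genotype fields (hard calls; the effect allele is written as ALT).
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .types import (
    AssayMatrix,
    GenotypeMatrix,
    NetworkEdge,
    Region,
)

# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def write_genotype_tsv(geno: GenotypeMatrix, path: str | Path) -> None:
    """Dosage matrix as TSV: variant metadata columns then one column per
    sample."""
    meta = geno.variants.copy()
    dos = pd.DataFrame(
        geno.dosages.T, columns=geno.sample_ids, index=meta.index
    )
    pd.concat([meta, dos], axis=1).to_csv(path, sep="\t", index=False)


def read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    # keep_default_na: the literal role value "null" must survive the trip
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    meta_cols = ["variant_id", "chrom", "pos", "effect_allele", "other_allele",
                 "eaf", "role"]
    sample_cols = [c for c in df.columns if c not in meta_cols]
    return GenotypeMatrix(
        dosages=df[sample_cols].to_numpy(dtype=float).T,
        variants=df[meta_cols].reset_index(drop=True),
        sample_ids=sample_cols,
    )


_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Minimal VCF v4.2, GT only; ALT is the effect allele."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(geno.sample_ids),
    ]
    for j, row in geno.variants.iterrows():
        calls = "\t".join(
            _GT.get(int(d), "./.") if np.isfinite(d) else "./."
            for d in geno.dosages[:, j]
        )
        lines.append(
            f"{row['chrom']}\t{row['pos']}\t{row['variant_id']}\t"
            f"{row['other_allele']}\t{row['effect_allele']}\t.\tPASS\t.\tGT\t{calls}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a GT-only VCF back into a GenotypeMatrix (ALT = effect allele)."""
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    rows, dosage_rows = [], []
    for rec in vf:
        dos = []
        for s in samples:
            gt = rec.samples[s]["GT"]
            if gt is None or any(a is None for a in gt):
                dos.append(np.nan)
            else:
                dos.append(float(sum(gt)))
        arr = np.array(dos)
        eaf = float(np.nanmean(arr) / 2.0)
        rows.append(
            dict(
                variant_id=rec.id or f"{rec.chrom}_{rec.pos}",
                chrom=rec.chrom, pos=rec.pos,
                effect_allele=rec.alts[0], other_allele=rec.ref,
                eaf=min(max(eaf, 1e-6), 1 - 1e-6), role="null",
            )
        )
        dosage_rows.append(arr)
    return GenotypeMatrix(
        dosages=np.array(dosage_rows).T,
        variants=pd.DataFrame(rows),
        sample_ids=samples,
    )


# ---------------------------------------------------------------------------
# assays
# ---------------------------------------------------------------------------


def write_assay_tsv(assay: AssayMatrix, values_path: str | Path,
                    meta_path: str | Path) -> None:
    """Intensity matrix plus a sidecar of sample metadata and bin map."""
    assay.values.to_csv(values_path, sep="\t", index_label="sample_id")
    meta = pd.DataFrame(
        {"sample_id": assay.values.index,
         "sample_type": assay.sample_type.values}
    )
    bins = pd.DataFrame(
        {"analyte": list(assay.dilution_bin),
         "dilution_bin": [assay.dilution_bin[a] for a in assay.dilution_bin]}
    )
    with open(meta_path, "w") as fh:
        fh.write("#samples\n")
        meta.to_csv(fh, sep="\t", index=False)
        fh.write("#analytes\n")
        bins.to_csv(fh, sep="\t", index=False)


def read_assay_tsv(values_path: str | Path, meta_path: str | Path,
                   platform: str) -> AssayMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col="sample_id")
    values.index.name = None  # in-memory matrices carry an unnamed index
    text = Path(meta_path).read_text().splitlines()
    split = text.index("#analytes")
    import io as _io

    meta = pd.read_csv(_io.StringIO("\n".join(text[1:split])), sep="\t")
    bins = pd.read_csv(_io.StringIO("\n".join(text[split + 1:])), sep="\t")
    return AssayMatrix(
        values=values,
        platform=platform,
        sample_type=pd.Series(
            meta["sample_type"].values, index=meta["sample_id"].values
        ),
        dilution_bin=dict(zip(bins["analyte"], bins["dilution_bin"])),
    )


# ---------------------------------------------------------------------------
# summary statistics, regions, calls, networks
# ---------------------------------------------------------------------------


def write_sumstats(stats: pd.DataFrame, path: str | Path) -> None:
    stats.to_csv(path, sep="\t", index=False)


def read_sumstats(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_regions_bed(regions: list[Region], path: str | Path) -> None:
    """Regions as BED (0-based half-open on disk)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.lead}\t"
                     f"{int(r.is_mhc)}\n")


def read_regions_bed(path: str | Path) -> list[Region]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        chrom, start, end, lead, is_mhc = line.split("\t")
        out.append(
            Region(chrom=chrom, start=int(start) + 1, end=int(end),
                   lead=lead, members=(lead,), is_mhc=bool(int(is_mhc)))
        )
    return out


def write_network(edges: list[NetworkEdge], tsv_path: str | Path,
                  graphml_path: str | Path | None = None) -> None:
    df = pd.DataFrame(
        [
            dict(protein=e.protein, phenotype=e.phenotype,
                 platforms=",".join(e.platforms), direction=e.direction,
                 consistency=e.consistency)
            for e in edges
        ]
    )
    df.to_csv(tsv_path, sep="\t", index=False)
    if graphml_path is not None:
        g = nx.Graph()
        for e in edges:
            g.add_node(e.protein, kind="protein")
            g.add_node(e.phenotype, kind="phenotype")
            g.add_edge(e.protein, e.phenotype,
                       platforms=",".join(e.platforms),
                       direction=e.direction, consistency=e.consistency)
        nx.write_graphml(g, graphml_path)


__all__ = [
    "write_genotype_tsv", "read_genotype_tsv",
    "write_vcf", "read_vcf",
    "write_assay_tsv", "read_assay_tsv",
    "write_sumstats", "read_sumstats",
    "write_regions_bed", "read_regions_bed",
    "write_network",
]
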