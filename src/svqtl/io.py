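"""Readers and writers for the tabular and genomic formats used by the pipeline.

Text formats only: genotype/map/phenotype TSV, bedGraph depth, VCF for SV
calls (SVTYPE/SVLEN/END), GFF3 gene annotation and BED intervals.  Every
writer can embed the simulation seed as a header comment so outputs are
self-describing.  Internal coordinates are 0-based half-open; VCF and GFF3
are converted at this boundary (1-based inclusive).
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
import numpy as np
import pandas as pd

from .genotypes import CALL_LABELS, LABEL_CALLS, GeneticMap, GenotypeMatrix
from .simulate import DepthTrack
from .svcat import GeneModel, SVRecord


def _header(seed: Optional[int]) -> list[str]:
    return [f"# seed={seed}"] if seed is not None else []


# -- genotypes ---------------------------------------------------------------


def write_genotypes_tsv(g: GenotypeMatrix, path: str, seed: Optional[int] = None) -> None:
    """Markers x individuals TSV with map columns and A/B/NA/FAIL cells,
    plus a companion ``<path>.individuals.tsv`` with subfamily labels."""
    map_cols = [c for c in ("chrom", "bp", "cm") if c in g.markers]
    labels = np.vectorize(CALL_LABELS.get)(g.calls)
    frame = pd.concat(
        [
            g.markers[map_cols],
            pd.DataFrame(labels, index=g.marker_ids, columns=g.individual_ids),
        ],
        axis=1,
    )
    with open(path, "w") as fh:
        fh.write("".join(line + "\n" for line in _header(seed)))
        frame.to_csv(fh, sep="\t", index_label="marker")
    g.individuals.to_csv(path + ".individuals.tsv", sep="\t", index_label="individual")


def read_genotypes_tsv(path: str) -> GenotypeMatrix:
    frame = pd.read_csv(
        path, sep="\t", comment="#", index_col="marker", keep_default_na=False, na_values=[]
    )
    map_cols = [c for c in ("chrom", "bp", "cm") if c in frame.columns]
    markers = frame[map_cols]
    ind_cols = [c for c in frame.columns if c not in map_cols]
    calls = np.vectorize(LABEL_CALLS.get)(frame[ind_cols].to_numpy()).astype(np.int8)
    individuals = pd.read_csv(path + ".individuals.tsv", sep="\t", index_col="individual")
    individuals = individuals.loc[ind_cols]
    return GenotypeMatrix(calls, markers, individuals)


# -- map, phenotypes, depth --------------------------------------------------


def write_map_tsv(gmap: GeneticMap, path: str, seed: Optional[int] = None) -> None:
    """Four-column marker map: chrom, marker, bp, cm."""
    table = gmap.table.reset_index()
    table = table.rename(columns={table.columns[0]: "marker"})[["chrom", "marker", "bp", "cm"]]
    with open(path, "w") as fh:
        fh.write("".join(line + "\n" for line in _header(seed)))
        table.to_csv(fh, sep="\t", index=False)


def read_map_tsv(path: str) -> GeneticMap:
    table = pd.read_csv(path, sep="\t", comment="#").set_index("marker")
    return GeneticMap(table[["chrom", "bp", "cm"]])


def write_phenotypes_tsv(pheno: pd.DataFrame, path: str, seed: Optional[int] = None) -> None:
    """Long-format phenotype table (individual, environment, replicate, days)."""
    with open(path, "w") as fh:
        fh.write("".join(line + "\n" for line in _header(seed)))
        pheno.to_csv(fh, sep="\t", index=False)


def read_phenotypes_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_depth_bedgraph(track: DepthTrack, path: str, seed: Optional[int] = None) -> None:
    """Run-length-encoded bedGraph (0-based half-open) of a depth track."""
    depth = track.depth
    change = np.flatnonzero(np.diff(depth)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(depth)]])
    with open(path, "w") as fh:
        fh.write("".join(line + "\n" for line in _header(seed)))
        fh.write('track type=bedGraph name="depth"\n')
        for s, e in zip(starts, ends):
            fh.write(f"{track.chrom}\t{track.start + s}\t{track.start + e}\t{depth[s]}\n")


def read_depth_bedgraph(path: str) -> DepthTrack:
    rows = pd.read_csv(
        path, sep="\t", comment="#", skiprows=lambda i: False, header=None,
        names=["chrom", "start", "end", "depth"],
        dtype={"chrom": str},
        engine="python",
        skip_blank_lines=True,
    )
    rows = rows[~rows["chrom"].str.startswith(("track", "#"))]
    rows = rows.astype({"start": int, "end": int, "depth": float})
    start = int(rows["start"].min())
    end = int(rows["end"].max())
    depth = np.zeros(end - start, dtype=np.int32)
    for r in rows.itertuples(index=False):
        depth[r.start - start : r.end - start] = int(r.depth)
    return DepthTrack(str(rows["chrom"].iloc[0]), start, depth)


# -- SV: VCF and BED ---------------------------------------------------------


def write_sv_vcf(
    svs: Sequence[SVRecord],
    path: str,
    contigs: Optional[Mapping[str, int]] = None,
    seed: Optional[int] = None,
) -> None:
    """Minimal SV VCF with SVTYPE/SVLEN/END info and per-founder GT columns.

    Internal 0-based starts become 1-based POS; SVLEN is negative for
    deletions, per convention.
    """
    founders: list[str] = []
    for sv in svs:
        for f in sv.founder_alleles:
            if f not in founders:
                founders.append(f)
    lines = ["##fileformat=VCFv4.2"]
    if seed is not None:
        lines.append(f"##seed={seed}")
    if contigs:
        for name, length in contigs.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    lines += [
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position (1-based inclusive)">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(founders),
    ]
    for sv in svs:
        pos = sv.start + 1
        svlen = -sv.size if sv.svtype == "DEL" else sv.size
        end = sv.end if sv.svtype == "DEL" else sv.start + 1
        info = f"SVTYPE={sv.svtype};SVLEN={svlen};END={end}"
        alt = f"<{sv.svtype}>"
        gts = []
        for f in founders:
            a = sv.founder_alleles.get(f)
            gts.append("./." if a is None else ("1/1" if a == 1 else "0/0"))
        lines.append(
            f"{sv.chrom}\t{pos}\t{sv.id}\tN\t{alt}\t.\tPASS\t{info}\tGT\t" + "\t".join(gts)
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_sv_vcf(path: str) -> list[SVRecord]:
    """Read DEL/INS records (SVTYPE/SVLEN/END) with founder alleles via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    founders = list(vcf.samples)
    records = []
    for variant in vcf:
        svtype = variant.INFO.get("SVTYPE")
        if svtype not in ("DEL", "INS"):
            continue
        svlen = abs(int(variant.INFO.get("SVLEN")))
        start = variant.POS - 1
        end = int(variant.INFO.get("END")) if svtype == "DEL" else start
        alleles = {}
        for f, gt in zip(founders, variant.gt_types):
            # cyvcf2: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            alleles[f] = {0: 0, 1: 1, 3: 1}.get(int(gt))
        records.append(
            SVRecord(
                id=variant.ID or f"{variant.CHROM}:{variant.POS}",
                chrom=variant.CHROM,
                start=start,
                end=end,
                svtype=svtype,
                size=svlen,
                founder_alleles=alleles,
            )
        )
    return records


def write_sv_bed(svs: Sequence[SVRecord], path: str, seed: Optional[int] = None) -> None:
    with open(path, "w") as fh:
        fh.write("".join(line + "\n" for line in _header(seed)))
        for sv in svs:
            s, e = sv.interval()
            fh.write(f"{sv.chrom}\t{s}\t{e}\t{sv.id}\t{sv.size}\t{sv.svtype}\n")


# -- genes: GFF3 -------------------------------------------------------------


def write_genes_gff3(genes: Sequence[GeneModel], path: str, seed: Optional[int] = None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for line in _header(seed):
            fh.write(line + "\n")
        for g in genes:
            note = g.annotation.replace(";", "%3B").replace("=", "%3D")
            attrs = f"ID={g.id};Note={note}"
            fh.write(
                f"{g.chrom}\tsvqtl\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def read_genes_gff3(path: str) -> list[GeneModel]:
    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        note = feat.attributes.get("Note", [""])[0]
        genes.append(
            GeneModel(
                id=feat.id,
                chrom=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand,
                annotation=note,
            )
        )
    return genes
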