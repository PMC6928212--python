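"""Readers and writers for the package's plain-text interchange formats.

* genetic map        — CSV ``marker,chrom,cm[,bp][,marker_class]``
* RIL genotypes      — TSV, one row per line, A/H/B/NA codes
* panel genotypes    — HapMap-style TSV or VCF v4.2 (read via cyvcf2)
* phenotypes         — CSV ``line,trial,protein[,oil][,yield]``
* anchors/regions    — CSV ``name,chrom,bp[,type]``

All loaders validate the type invariants and name the offending record in
their error messages.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    RIL_CHAR_TO_CODE,
    RIL_CODE_TO_CHAR,
    PanelGenotypes,
    PhenotypeRecords,
    RILGenotypes,
)
from .genmap import GeneticMap

__all__ = [
    "read_map", "write_map",
    "read_ril_tsv", "write_ril_tsv",
    "read_hapmap", "write_hapmap",
    "read_vcf", "write_vcf",
    "read_phenotypes", "write_phenotypes",
    "read_anchors",
    "load_dataset",
]

_HAPMAP_COLS = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]


# -- genetic map ------------------------------------------------------------

def read_map(path) -> GeneticMap:
    t = pd.read_csv(path, comment="#")
    return GeneticMap(t)


def write_map(gmap: GeneticMap, path, header: str | None = None) -> None:
    _write_table(gmap.table, path, sep=",", header=header)


# -- RIL genotypes ----------------------------------------------------------

def read_ril_tsv(path, gmap: GeneticMap, generation: int = 5) -> RILGenotypes:
    t = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if t.columns[0] != "line":
        raise ValueError("RIL TSV must start with a 'line' column")
    markers = list(t.columns[1:])
    if markers != gmap.marker_names:
        extra = set(markers) - set(gmap.marker_names)
        missing = set(gmap.marker_names) - set(markers)
        raise ValueError(
            f"RIL TSV markers do not match map (extra: {sorted(extra)[:3]}, "
            f"missing: {sorted(missing)[:3]})"
        )
    lines = list(t["line"])
    codes = np.empty((len(lines), len(markers)), dtype=np.int8)
    for j, m in enumerate(markers):
        for i, v in enumerate(t[m].fillna("NA")):
            try:
                codes[i, j] = RIL_CHAR_TO_CODE[v]
            except KeyError:
                raise ValueError(
                    f"unknown genotype code {v!r} for line {lines[i]!r} "
                    f"at marker {m!r}"
                ) from None
    return RILGenotypes(codes=codes, lines=lines, gmap=gmap, generation=generation)


def write_ril_tsv(genotypes: RILGenotypes, path, header: str | None = None) -> None:
    _write_table(
        genotypes.to_frame().reset_index(), path, sep="\t", header=header
    )


# -- HapMap panel -----------------------------------------------------------

def write_hapmap(panel: PanelGenotypes, path, header: str | None = None) -> None:
    s = panel.snps
    base = pd.DataFrame(
        {
            "rs#": s["snp"],
            "alleles": s["ref"] + "/" + s["alt"],
            "chrom": s["chrom"],
            "pos": s["bp"],
            "strand": "+",
            "assembly#": "NA", "center": "NA", "protLSID": "NA",
            "assayLSID": "NA", "panelLSID": "NA", "QCcode": "NA",
        }
    )
    ref = s["ref"].to_numpy()
    alt = s["alt"].to_numpy()
    lookup = np.stack([ref + ref, ref + alt, alt + alt], axis=0)
    cols = {
        line: np.where(
            panel.calls[i] == -1, "NN",
            lookup[np.clip(panel.calls[i], 0, 2), np.arange(len(s))],
        )
        for i, line in enumerate(panel.lines)
    }
    base = pd.concat([base, pd.DataFrame(cols)], axis=1)
    _write_table(base, path, sep="\t", header=header)


def read_hapmap(path) -> PanelGenotypes:
    # column names contain '#' (rs#, assembly#), so strip full-line comments
    # by hand instead of using pandas' comment= option
    text = Path(path).read_text()
    body = "\n".join(ln for ln in text.splitlines() if not ln.startswith("#"))
    t = pd.read_csv(_io.StringIO(body), sep="\t", dtype=str)
    for c in _HAPMAP_COLS:
        if c not in t.columns:
            raise ValueError(f"HapMap file missing column {c!r}")
    lines = [c for c in t.columns if c not in _HAPMAP_COLS]
    alleles = t["alleles"].str.split("/", expand=True)
    snps = pd.DataFrame(
        {
            "snp": t["rs#"],
            "chrom": t["chrom"],
            "bp": t["pos"].astype(np.int64),
            "ref": alleles[0],
            "alt": alleles[1],
        }
    )
    calls = np.empty((len(lines), len(t)), dtype=np.int8)
    ref = snps["ref"].to_numpy()
    alt = snps["alt"].to_numpy()
    for i, line in enumerate(lines):
        g = t[line].to_numpy()
        hom_ref = g == ref + ref
        hom_alt = g == alt + alt
        het = (g == ref + alt) | (g == alt + ref)
        missing = g == "NN"
        bad = ~(hom_ref | hom_alt | het | missing)
        if bad.any():
            j = int(np.argmax(bad))
            raise ValueError(
                f"unknown genotype {g[j]!r} for line {line!r} at SNP "
                f"{snps['snp'].iloc[j]!r}"
            )
        calls[i] = np.select([hom_ref, het, hom_alt], [0, 1, 2], default=-1)
    return PanelGenotypes(calls=calls, lines=lines, snps=snps)


# -- VCF panel --------------------------------------------------------------

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(panel: PanelGenotypes, path, header: str | None = None) -> None:
    buf = _io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    if header:
        for line in header.splitlines():
            buf.write(f"##{line}\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    for chrom in panel.snps["chrom"].unique():
        buf.write(f"##contig=<ID={chrom}>\n")
    cols = "\t".join(["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER",
                      "INFO", "FORMAT"] + list(panel.lines))
    buf.write(cols + "\n")
    s = panel.snps
    for j in range(panel.n_snps):
        gts = "\t".join(_GT_STRINGS[int(c)] for c in panel.calls[:, j])
        buf.write(
            f"{s['chrom'].iloc[j]}\t{s['bp'].iloc[j]}\t{s['snp'].iloc[j]}\t"
            f"{s['ref'].iloc[j]}\t{s['alt'].iloc[j]}\t.\tPASS\t.\tGT\t{gts}\n"
        )
    Path(path).write_text(buf.getvalue())


def read_vcf(path) -> PanelGenotypes:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    lines = list(vcf.samples)
    rows, call_rows = [], []
    # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
    remap = np.array([0, 1, -1, 2], dtype=np.int8)
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(f"SNP {v.ID!r} is not biallelic")
        rows.append(
            {"snp": v.ID, "chrom": v.CHROM, "bp": np.int64(v.POS),
             "ref": v.REF, "alt": v.ALT[0]}
        )
        call_rows.append(remap[np.asarray(v.gt_types, dtype=int)])
    vcf.close()
    snps = pd.DataFrame(rows, columns=["snp", "chrom", "bp", "ref", "alt"])
    calls = np.array(call_rows, dtype=np.int8).T if call_rows else np.empty((len(lines), 0), np.int8)
    return PanelGenotypes(calls=calls, lines=lines, snps=snps)


# -- phenotypes and anchors -------------------------------------------------

def read_phenotypes(path) -> PhenotypeRecords:
    t = pd.read_csv(path, comment="#")
    return PhenotypeRecords(table=t)


def write_phenotypes(phenotypes: PhenotypeRecords, path, header: str | None = None) -> None:
    _write_table(phenotypes.table, path, sep=",", header=header)


def read_anchors(path) -> pd.DataFrame:
    t = pd.read_csv(path, comment="#")
    required = {"name", "chrom", "bp"}
    missing = required - set(t.columns)
    if missing:
        raise ValueError(f"anchor table missing columns: {sorted(missing)}")
    t["bp"] = t["bp"].astype(np.int64)
    return t


# -- generic loader ---------------------------------------------------------

def load_dataset(path, kind: str, gmap: GeneticMap | None = None, **kw):
    """Load a typed dataset: kind in {panel, ril, map, phenotype, anchors}.

    Panel files ending in ``.vcf`` are parsed as VCF, anything else as
    HapMap TSV.  ``ril`` requires the matching genetic map.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if kind == "map":
        return read_map(path)
    if kind == "panel":
        if path.suffix.lower() in (".vcf", ".gz"):
            return read_vcf(path)
        return read_hapmap(path)
    if kind == "ril":
        if gmap is None:
            raise ValueError("loading RIL genotypes requires the genetic map")
        return read_ril_tsv(path, gmap, **kw)
    if kind == "phenotype":
        return read_phenotypes(path)
    if kind == "anchors":
        return read_anchors(path)
    raise ValueError(f"unknown dataset kind {kind!r}")


def _write_table(df: pd.DataFrame, path, sep: str, header: str | None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep=sep, index=False)
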