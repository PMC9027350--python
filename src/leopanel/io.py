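"""Readers and writers for the formats the pipeline touches.

VCF v4.2 (GT + DP) is the interchange format for the discovery cohort,
FASTA for flanking and numt sequences, and CSV for sample sheets, panel
call tables and scaffold-to-chromosome maps.  All readers and writers are
exact inverses on valid data; coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from cyvcf2 import VCF

from .datamodel import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    NUCLEOTIDES,
    FormatError,
    PanelCalls,
    SiteRecord,
    VariantDataset,
    validate_sample_sheet,
)

logger = logging.getLogger(__name__)

# cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
_CYVCF2_TO_CODE = np.array([HOM_REF, HET, MISSING, HOM_ALT], dtype=np.int8)

_GT_STRING = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def read_vcf(path: str | Path) -> VariantDataset:
    """Load biallelic SNP records from a VCF v4.x file.

    Multi-allelic and indel records are skipped with a logged count.  A
    missing DP value becomes depth 0 while the genotype call is retained as
    provided.
    """
    path = Path(path)
    try:
        vcf = VCF(str(path))
        samples = list(vcf.samples)
    except Exception as exc:  # htslib raises bare Exceptions on bad headers
        raise FormatError(f"{path}: malformed VCF header ({exc})") from exc
    if not samples:
        raise FormatError(f"{path}: VCF has no sample columns")

    sites: list[SiteRecord] = []
    genotypes: list[np.ndarray] = []
    depths: list[np.ndarray] = []
    n_skipped = 0
    for i, var in enumerate(vcf, start=1):
        alts = var.ALT
        if len(alts) != 1 or len(var.REF) != 1 or len(alts[0]) != 1:
            n_skipped += 1
            continue
        if var.REF not in NUCLEOTIDES or alts[0] not in NUCLEOTIDES:
            n_skipped += 1
            continue
        gt = var.gt_types
        if len(gt) != len(samples):
            raise FormatError(f"{path}: record {i}: malformed GT field")
        genotypes.append(_CYVCF2_TO_CODE[gt])
        dp = var.format("DP")  # None when the record carries no DP
        if dp is None:
            depths.append(np.zeros(len(samples), dtype=np.int32))
        else:
            depths.append(np.clip(dp.ravel(), 0, None).astype(np.int32))
        sites.append(SiteRecord(var.CHROM, var.POS, var.REF, alts[0]))
    if n_skipped:
        logger.warning(
            "%s: skipped %d non-biallelic-SNP record(s)", path, n_skipped
        )
    n = len(sites)
    dataset = VariantDataset(
        sites=sites,
        samples=samples,
        genotypes=np.asarray(genotypes, dtype=np.int8).reshape(n, len(samples)),
        depths=np.asarray(depths, dtype=np.int32).reshape(n, len(samples)),
    )
    return dataset


def write_vcf(
    dataset: VariantDataset,
    path: str | Path,
    header_comments: dict[str, str] | None = None,
) -> Path:
    """Serialize a :class:`VariantDataset` as an uncompressed VCF v4.2 file.

    ``read_vcf(write_vcf(d))`` reproduces calls and depths exactly.
    Optional ``header_comments`` become ``##leopanel_<key>=<value>`` lines
    (used to embed parameter snapshots in outputs).
    """
    path = Path(path)
    lines = ["##fileformat=VCFv4.2"]
    for key, value in (header_comments or {}).items():
        lines.append(f"##leopanel_{key}={value}")
    for scaffold in dict.fromkeys(s.scaffold for s in dataset.sites):
        lines.append(f"##contig=<ID={scaffold}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(dataset.samples)
    )
    for i, site in enumerate(dataset.sites):
        cells = [
            f"{_GT_STRING[int(g)]}:{int(d)}"
            for g, d in zip(dataset.genotypes[i], dataset.depths[i])
        ]
        lines.append(
            f"{site.scaffold}\t{site.position}\t.\t{site.ref}\t{site.alt}"
            "\t.\t.\t.\tGT:DP\t" + "\t".join(cells)
        )
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write VCF to {path}: {exc}") from exc
    return path


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercased sequence mapping.

    Ids are taken up to the first whitespace; duplicate ids are an error.
    """
    result: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in result:
            raise FormatError(f"{path}: duplicate FASTA id {record.id!r}")
        result[record.id] = str(record.seq).upper()
    return result


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


def read_panel_calls(
    path: str | Path,
    missing_token: str = "NA",
    mtdna_prefix: str = "mt_",
) -> PanelCalls:
    """Read a panel genotype CSV: one row per sample, one column per SNP.

    Autosomal cells hold dosages ``0/1/2``, mitochondrial cells haploid
    states ``0/1``; the missing token (default ``"NA"``) maps to ``-1``.
    SNP ids starting with ``mtdna_prefix`` are flagged as mitochondrial.
    """
    frame = pd.read_csv(path, index_col="sample", dtype=str, keep_default_na=False)
    is_mtdna = pd.Series(
        [c.startswith(mtdna_prefix) for c in frame.columns], index=frame.columns
    )
    allowed_auto = {"0", "1", "2"}
    allowed_mito = {"0", "1"}
    coded = pd.DataFrame(index=frame.index, columns=frame.columns, dtype=np.int8)
    for snp in frame.columns:
        allowed = allowed_mito if is_mtdna[snp] else allowed_auto
        col = frame[snp].astype(str).str.strip()
        bad = ~(col.isin(allowed) | (col == missing_token))
        if bad.any():
            sample = col.index[bad][0]
            raise FormatError(
                f"{path}: unknown allele symbol {col[sample]!r} "
                f"at sample {sample!r}, SNP {snp!r}"
            )
        coded[snp] = np.where(col == missing_token, MISSING, col.replace(missing_token, "0").astype(int)).astype(np.int8)
    return PanelCalls(calls=coded, is_mtdna=is_mtdna)


def write_panel_calls(
    calls: PanelCalls, path: str | Path, missing_token: str = "NA"
) -> Path:
    path = Path(path)
    out = calls.calls.astype(object).where(calls.calls != MISSING, missing_token)
    out.index.name = "sample"
    out.to_csv(path)
    return path


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a ``sample,population,region,lat,lon`` CSV and validate it."""
    sheet = pd.read_csv(path)
    return validate_sample_sheet(sheet)


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    validate_sample_sheet(sheet).to_csv(path, index=False)
    return path


def read_scaffold_map(path: str | Path) -> dict[str, str]:
    """Read a two-column ``scaffold,chromosome`` CSV into a dict."""
    frame = pd.read_csv(path)
    if not {"scaffold", "chromosome"} <= set(frame.columns):
        raise FormatError(f"{path}: expected columns scaffold,chromosome")
    if frame["scaffold"].duplicated().any():
        dupes = frame.loc[frame["scaffold"].duplicated(), "scaffold"].tolist()
        raise FormatError(f"{path}: duplicate scaffold(s) in map: {dupes}")
    return dict(zip(frame["scaffold"], frame["chromosome"]))


def write_scaffold_map(mapping: dict[str, str], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"scaffold": list(mapping.keys()), "chromosome": list(mapping.values())}
    ).to_csv(path, index=False)
    return path


def read_mt_key(key_path: str | Path, meta_path: str | Path | None = None) -> pd.DataFrame:
    """Read a haplogroup-key CSV (haplogroup x mtDNA SNP states); per-site
    metadata, when given, is attached as ``key.attrs["site_meta"]``."""
    key = pd.read_csv(key_path, index_col="haplogroup").astype(np.int8)
    for a in key.index:
        for b in key.index:
            if a < b and (key.loc[a] == key.loc[b]).all():
                raise FormatError(f"haplogroups {a!r} and {b!r} are indistinguishable in the key")
    if meta_path is not None:
        key.attrs["site_meta"] = pd.read_csv(meta_path, index_col="snp_id")
    return key
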