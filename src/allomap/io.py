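"""Readers and writers for the pipeline's tab-separated interchange formats.

TSV is the canonical format (UTF-8, ``#`` comment lines, 1-based inclusive
coordinates).  Variants may also arrive as a minimal 8-column VCF where REF is
the human allele and ALT the chimpanzee allele; breakpoints can be exported as
BED (0-based half-open).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def read_counts(counts_path, samples_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a gene x sample count matrix and its sample-metadata sidecar.

    The count TSV has gene ids in the first column and one column per sample;
    counts must be non-negative integers and gene ids unique.  The sample
    table must cover exactly the matrix's columns.
    """
    counts = _read_tsv(counts_path, index_col=0)
    counts.index.name = "gene_id"
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()][0]
        raise ValueError(f"duplicate gene id {dup!r} in {counts_path}")
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"non-numeric count in {counts_path}")
    bad = np.argwhere((values < 0) | (values != np.floor(values)))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"invalid count at gene {counts.index[r]!r} (row {r + 2}), "
            f"sample {counts.columns[c]!r} in {counts_path}: must be a "
            "non-negative integer")
    samples = _read_tsv(samples_path)
    if "sample_id" not in samples.columns:
        raise ValueError(f"{samples_path} lacks a sample_id column")
    if set(samples["sample_id"]) != set(counts.columns):
        raise ValueError("sample table and count matrix columns disagree")
    return counts.astype(np.int64), samples


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def write_table(obj: pd.DataFrame, path) -> None:
    obj.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return _read_tsv(path)


VARIANT_COLUMNS = ["chrom", "pos", "human_allele", "chimp_allele"]


def read_variants(path) -> pd.DataFrame:
    """Read a diagnostic-variant table from TSV or a minimal VCF.

    VCF input (detected by the ``.vcf`` suffix or a ``##fileformat`` header)
    is the headerless-friendly 8-column dialect: CHROM POS ID REF ALT QUAL
    FILTER INFO, with REF the human allele and ALT the chimpanzee allele.
    Positions must be unique and sorted per chromosome.
    """
    path = Path(path)
    first = ""
    with open(path) as fh:
        for line in fh:
            first = line
            break
    if path.suffix == ".vcf" or first.startswith("##fileformat"):
        rows = []
        with open(path) as fh:
            for i, line in enumerate(fh, 1):
                if line.startswith("#") or not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 5:
                    raise ValueError(f"{path}:{i}: fewer than 5 VCF columns")
                try:
                    pos = int(fields[1])
                except ValueError as e:
                    raise ValueError(f"{path}:{i}: non-integer POS") from e
                rows.append((fields[0], pos, fields[3], fields[4]))
        variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    else:
        variants = _read_tsv(path)
        missing = set(VARIANT_COLUMNS) - set(variants.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        variants = variants[VARIANT_COLUMNS]
    if variants[["chrom", "pos"]].duplicated().any():
        raise ValueError(f"{path}: duplicate variant positions")
    if (variants["human_allele"] == variants["chimp_allele"]).any():
        raise ValueError(f"{path}: human and chimp alleles must differ")
    return variants.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def write_bed(calls, path) -> None:
    """Export breakpoint calls as BED (0-based half-open intervals).

    ``calls`` is an iterable of BreakpointCall; the 1-based inclusive interval
    [left, right] becomes the BED interval (left-1, right).
    """
    with open(path, "w") as fh:
        for call in calls:
            name = f"breakpoint_{call.lost_species}_lost"
            fh.write(f"{call.chrom}\t{call.left_position - 1}\t"
                     f"{call.right_position}\t{name}\t"
                     f"{call.delta_loglik:.3f}\t.\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
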