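"""Readers, writers and run manifests for the package's table formats.

All tables are tab-separated text with a one-line header; missing values
are written as ``NA`` and never silently zero.  Gene identifiers are
treated as opaque strings — no symbol/model translation is attempted.
Expression matrices carry genes as rows and samples (or days) as columns;
allele-count tables are long-format (snp, day, ref_count, alt_count);
Ig count tables carry a ``class`` column before the per-sample counts.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_reference_matrix",
    "read_ig_counts",
    "read_snp_counts",
    "write_table",
    "vcf_to_snp_counts",
    "write_manifest",
]

TPM_SCALE = 1.0e6


def _read_tsv(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=index_col, na_values=["NA"],
                         float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed tab-separated table: {exc}") from exc
    return df


def read_expression_matrix(
    path: str | Path, expected_unit: str = "TPM", tpm_tolerance: float = 1.0
) -> pd.DataFrame:
    """Read a gene x sample expression matrix from a tab-separated file.

    Validates uniqueness of gene and sample names, numeric non-negative
    values, and — for TPM input — records whether every column sums to 1e6
    within ``tpm_tolerance`` in ``df.attrs["tpm_complete"]`` (a flag, not an
    enforcement: sub-matrices of a TPM table are legitimate input).
    """
    df = _read_tsv(path)
    dup_genes = df.index[df.index.duplicated()].unique()
    if len(dup_genes):
        raise ValueError(f"{path}: duplicated gene names: {list(dup_genes)[:5]}")
    dup_samples = df.columns[df.columns.duplicated()].unique()
    if len(dup_samples):
        raise ValueError(f"{path}: duplicated sample names: {list(dup_samples)[:5]}")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression values: {exc}") from exc
    if (values.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative expression values")
    if expected_unit == "TPM":
        sums = values.sum(axis=0)
        values.attrs["tpm_complete"] = bool(
            np.allclose(sums, TPM_SCALE, atol=tpm_tolerance)
        )
    return values


def write_expression_matrix(df: pd.DataFrame, path: str | Path) -> None:
    """Write a gene x sample matrix as tab-separated text at full precision."""
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g",
              index_label="gene")


def read_reference_matrix(path: str | Path) -> pd.DataFrame:
    """Read an entity x gene reference matrix (entities as rows)."""
    df = _read_tsv(path)
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicated entity names")
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicated gene names")
    return df.astype(float)


def read_ig_counts(path: str | Path) -> pd.DataFrame:
    """Read a segment x sample Ig count table (``segment``, ``class``, days...)."""
    df = _read_tsv(path)
    if "class" not in df.columns:
        raise ValueError(f"{path}: Ig count table needs a 'class' column")
    counts = df.drop(columns="class")
    if (counts.to_numpy() < 0).any() or not np.allclose(
        counts.to_numpy(), counts.to_numpy().round()
    ):
        raise ValueError(f"{path}: Ig counts must be non-negative integers")
    out = counts.astype(int)
    out.insert(0, "class", df["class"].astype(str))
    # day columns read as strings; restore integers where possible
    try:
        out.columns = ["class"] + [int(c) for c in out.columns[1:]]
    except ValueError:
        pass
    return out


def read_snp_counts(path: str | Path) -> pd.DataFrame:
    """Read a long-format allele-count table (snp, day, ref_count, alt_count)."""
    df = _read_tsv(path, index_col=None)
    required = {"snp", "day", "ref_count", "alt_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: allele-count table lacks columns {sorted(missing)}")
    df["day"] = df["day"].astype(int)
    df[["ref_count", "alt_count"]] = df[["ref_count", "alt_count"]].astype(int)
    return df


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    """Write any result table as tab-separated text."""
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g", index=index)


def vcf_to_snp_counts(
    path: str | Path,
    sample_name: str | None = None,
    day_mapping: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Build an allele-count table from a VCF with per-sample allelic depths.

    Each biallelic record contributes one row per mapped sample, keyed by
    ``CHROM:POS`` and the day assigned to that sample through
    ``day_mapping`` (sample name -> day relative to transplant).  With a
    single ``sample_name`` and no mapping, day defaults to 0.  Records with
    more than one ALT allele are skipped and counted in the log; a missing
    allelic-depth (AD) field is an error.
    """
    import pysam

    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    if day_mapping is None:
        if sample_name is None:
            if len(samples) != 1:
                raise ValueError("multi-sample VCF requires a day_mapping")
            sample_name = samples[0]
        day_mapping = {sample_name: 0}
    unknown = set(day_mapping) - set(samples)
    if unknown:
        raise ValueError(f"samples not in VCF: {sorted(unknown)}")

    records, skipped = [], 0
    for rec in vcf:
        if rec.alts is None or len(rec.alts) != 1:
            skipped += 1
            continue
        snp_id = f"{rec.chrom}:{rec.pos}"
        for sample, day in day_mapping.items():
            ad = rec.samples[sample].get("AD")
            if ad is None or ad[0] is None:
                raise ValueError(
                    f"{path}: record {snp_id} sample {sample} lacks an AD field"
                )
            records.append((snp_id, int(day), int(ad[0]), int(ad[1])))
    if skipped:
        logger.info("skipped %d multi-allelic records in %s", skipped, path)
    out = pd.DataFrame(records, columns=["snp", "day", "ref_count", "alt_count"])
    out.attrs["skipped_multiallelic"] = skipped
    return out


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    config: dict,
    inputs: list[str | Path] | None = None,
) -> None:
    """Record a run's configuration, seeds and input checksums as YAML.

    Together with the deterministic seeding of every stochastic stage this
    is sufficient to reproduce a run byte-identically.
    """
    from cfmarrow import __version__

    manifest = {
        "cfmarrow_version": __version__,
        "config": config,
        "inputs": {
            str(p): _sha256(p) for p in (inputs or []) if Path(p).exists()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
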