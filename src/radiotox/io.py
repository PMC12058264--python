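"""Readers for genotype dosage inputs (VCF or TSV) and result writers."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .risk import DosagePanel

logger = logging.getLogger(__name__)


def read_dosage_vcf(path) -> DosagePanel:
    """Load per-sample dosages from a VCF (plain or bgzipped).

    Dosage is taken from the DS FORMAT field (ALT-allele dosage); records
    without DS fall back to summing GT hard calls.  Multi-allelic records
    are skipped with a warning.  ``allele_a`` is REF and ``allele_b`` ALT,
    so panel dosages count ALT copies.
    """
    from cyvcf2 import VCF  # deferred: only needed for VCF input

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    cols = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            logger.warning("skipping multi-allelic record %s at %s:%d", rec.ID, rec.CHROM, rec.POS)
            continue
        ds = None
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            d = np.asarray(ds, dtype=float).reshape(-1)
            d = np.where(d < -1, np.nan, d)  # cyvcf2 encodes missing as large negative
        else:
            gts = rec.genotype.array()[:, :2]
            d = np.where((gts < 0).any(axis=1), np.nan, (gts > 0).sum(axis=1)).astype(float)
        rows.append(
            {
                "variant_id": rec.ID or f"{rec.CHROM}:{rec.POS}",
                "chrom": str(rec.CHROM),
                "pos": int(rec.POS),
                "allele_a": rec.REF,
                "allele_b": rec.ALT[0],
            }
        )
        cols.append(d)
    if not rows:
        raise ValueError(f"no usable biallelic records in {path}")
    dosage = np.column_stack(cols)
    return DosagePanel(sample_ids=samples, variants=pd.DataFrame(rows), dosage=dosage)


def read_dosage_tsv(path, sidecar_path=None) -> DosagePanel:
    """Load a sample-by-variant dosage TSV plus its allele-metadata sidecar.

    The TSV's first column is ``sample_id``; remaining columns are variant
    ids.  The sidecar (default ``<stem>_variants.tsv`` next to the table)
    carries ``variant_id, chrom, pos, allele_a, allele_b``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    if sidecar_path is None:
        sidecar_path = path.with_name(path.stem + "_variants.tsv")
    meta = pd.read_csv(sidecar_path, sep="\t", dtype={"chrom": str, "variant_id": str})
    required = {"variant_id", "chrom", "pos", "allele_a", "allele_b"}
    if not required <= set(meta.columns):
        raise ValueError(f"sidecar {sidecar_path} lacks columns {sorted(required - set(meta.columns))}")
    meta = meta.set_index("variant_id").loc[list(df.columns)].reset_index()
    return DosagePanel(
        sample_ids=[str(s) for s in df.index],
        variants=meta,
        dosage=df.to_numpy(dtype=float),
    )


def read_dosages(path, sidecar_path=None) -> DosagePanel:
    """Dispatch on extension: .vcf/.vcf.gz or dosage TSV."""
    name = str(path)
    if name.endswith((".vcf", ".vcf.gz", ".bcf")):
        return read_dosage_vcf(path)
    return read_dosage_tsv(path, sidecar_path)
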