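"""Readers/writers for the interchange formats and coordinate conventions.

TSV (gzip-transparent via pandas) is the canonical interchange format.
Mutation positions are 1-based (VCF convention); arm and window intervals are
0-based half-open (BED convention); every conversion between the two lives
here.  VCF input is optional and requires pysam; the core pipeline never
needs a genome file.
"""

from __future__ import annotations

import json
import platform
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .clusters import ArmSet
from .signatures import SBS96_CLASSES, validate_catalog

__all__ = [
    "read_mutations",
    "write_mutations",
    "read_catalog",
    "write_catalog",
    "read_exposures",
    "read_bed",
    "read_timecourse",
    "write_provenance",
    "pos_to_interval_index",
]

_MUT_REQUIRED = ["individual_id", "sample_id", "chrom", "pos", "ref", "alt"]
_SNV_BASES = {"A", "C", "G", "T"}


def pos_to_interval_index(pos_1based: int, start_0based: int, end_0based: int) -> bool:
    """Whether a 1-based position lies in a 0-based half-open interval."""
    return start_0based + 1 <= pos_1based <= end_0based


def read_mutations(path, fmt: str = "tsv", arms: ArmSet | None = None) -> pd.DataFrame:
    """Read a mutation table from TSV or VCF.

    TSV needs a header with (individual_id, sample_id, chrom, pos, ref, alt
    [, sbs96]).  VCF records are split per ALT; non-SNV records are dropped
    with a count warning; the sample/individual identity comes from the VCF
    sample columns (genotypes with an alternate allele).  When ``arms`` is
    given, an ``arm_id`` assignment is added.
    """
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        missing = [c for c in _MUT_REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"mutation table is missing columns {missing}")
    elif fmt == "vcf":
        df = _read_vcf(path)
    else:
        raise ValueError(f"unknown mutation format {fmt!r}")
    bad = ~(df.ref.isin(_SNV_BASES) & df.alt.isin(_SNV_BASES))
    same = df.ref == df.alt
    n_drop = int((bad | same).sum())
    if n_drop:
        warnings.warn(f"dropped {n_drop} non-SNV or ref==alt records")
        df = df[~(bad | same)].reset_index(drop=True)
    if (df.pos < 1).any():
        raise ValueError("positions must be 1-based (>= 1)")
    if arms is not None:
        df = arms.assign(df)
    return df


def _read_vcf(path) -> pd.DataFrame:
    import pysam  # optional dependency, only for VCF input

    rows = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            for alt in rec.alts or ():
                if len(rec.ref) != 1 or len(alt) != 1:
                    rows.append(dict(individual_id=None, sample_id=None,
                                     chrom=rec.chrom, pos=rec.pos,
                                     ref=rec.ref, alt=alt))
                    continue
                carriers = [
                    s for s in samples
                    if any(a is not None and a > 0 for a in (rec.samples[s].get("GT") or ()))
                ] or [samples[0] if samples else "sample0"]
                for s in carriers:
                    rows.append(dict(individual_id=s, sample_id=s, chrom=rec.chrom,
                                     pos=rec.pos, ref=rec.ref, alt=alt))
    df = pd.DataFrame(rows, columns=_MUT_REQUIRED)
    df["ref"] = df.ref.fillna("N")
    df["alt"] = df.alt.fillna("N")
    return df


def write_mutations(df: pd.DataFrame, path) -> None:
    cols = [c for c in df.columns if not c.startswith("arm_")]
    df[cols].to_csv(path, sep="\t", index=False)


def read_catalog(path) -> pd.DataFrame:
    """COSMIC-style catalog TSV: first column 'Type' (e.g. A[C>A]A), one column per signature."""
    df = pd.read_csv(path, sep="\t")
    first = df.columns[0]
    if first.lower() != "type":
        raise ValueError(f"first catalog column must be 'Type', got {first!r}")
    df = df.set_index(first)
    df.index.name = "Type"
    if sorted(df.index) != SBS96_CLASSES:
        raise ValueError("catalog must contain exactly the 96 canonical classes")
    return validate_catalog(df.sort_index())


def write_catalog(catalog: pd.DataFrame, path) -> None:
    out = catalog.copy()
    out.index.name = "Type"
    out.to_csv(path, sep="\t")


def read_exposures(path) -> pd.DataFrame:
    """Exposure table TSV; requires sample_id plus signature/covariate columns."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError("exposure table needs a 'sample_id' column")
    return df


def read_bed(path) -> ArmSet:
    """BED4 (chrom, start, end, name) as an ArmSet; half-open semantics preserved."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "arm_id"],
                     dtype={"chrom": str, "arm_id": str})
    if (df.end <= df.start).any():
        bad = df[df.end <= df.start].iloc[0]
        raise ValueError(f"BED interval with end <= start: {tuple(bad)}")
    return ArmSet(df)


def write_bed(arms: ArmSet, path) -> None:
    arms.table[["chrom", "start", "end", "arm_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_timecourse(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"window_id", "time", "count"} - set(df.columns)
    if missing:
        raise ValueError(f"time course is missing columns {sorted(missing)}")
    return df


def write_provenance(out_dir, config: dict) -> Path:
    """Record the run configuration, seeds and versions next to the outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "funnelsig_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": {k: (str(v) if isinstance(v, Path) else v) for k, v in config.items()},
    }
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(record, indent=2, default=str))
    return path
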