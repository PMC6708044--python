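"""Readers and writers for the pipeline's file formats.

Genotype matrices travel as CSV (first column ``line_id``, header row of
marker names, cells in {A,H,B,-}); marker maps as TSV with columns name,
chrom, pos_bp and optional pos_cM; phenotypes as long CSV (line_id,
environment, replicate, trait, value); SNP matrices as VCF (biallelic
sites, GT field) or a CSV dialect; diagnostic marker calls as CSV with the
enumerated column names.  All coordinates are 1-based inclusive
internally; VCF positions are already 1-based, and optional half-open
region queries are converted at the boundary.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .genetics import GENOTYPE_CODES, GeneticMap, GenotypeMatrix, Marker
from .haplotypes import DiagnosticGenotype, LINKED_SNP_STATES, SNPMatrix


# ---------------------------------------------------------------------------
# Marker maps
# ---------------------------------------------------------------------------

def read_map_tsv(path: "str | Path", map_function: str = "kosambi",
                 cm_per_mb: float | None = None) -> GeneticMap:
    df = pd.read_csv(path, sep="\t")
    required = {"name", "chrom", "pos_bp"}
    if not required <= set(df.columns):
        raise ValueError(f"map file must have columns {sorted(required)}")
    has_cm = "pos_cM" in df.columns
    markers = [
        Marker(
            name=str(r["name"]),
            chrom=str(r["chrom"]),
            pos_bp=int(r["pos_bp"]),
            pos_cM=(float(r["pos_cM"]) if has_cm and pd.notna(r["pos_cM"]) else None),
        )
        for _, r in df.iterrows()
    ]
    return GeneticMap(markers=markers, map_function=map_function,  # type: ignore[arg-type]
                      cm_per_mb=cm_per_mb)


def write_map_tsv(gmap: GeneticMap, path: "str | Path") -> None:
    gmap.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genotype matrices
# ---------------------------------------------------------------------------

def read_genotype_csv(path: "str | Path", gmap: GeneticMap | None = None) -> GenotypeMatrix:
    """Read a genotype CSV; marker coordinates come from ``gmap`` when
    given, otherwise markers get placeholder positions in column order."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.empty or df.shape[1] < 2:
        raise ValueError(f"{path}: empty or malformed genotype matrix")
    first = df.columns[0]
    df = df.set_index(first)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate line_ids {dupes}")
    bad = ~df.isin(GENOTYPE_CODES)
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: invalid code {df.iat[r, c]!r} for line {df.index[r]!r} "
            f"at marker {df.columns[c]!r}"
        )
    if gmap is not None:
        by_name = {m.name: m for m in gmap.markers}
        try:
            markers = [by_name[n] for n in df.columns]
        except KeyError as e:
            raise ValueError(f"{path}: marker {e.args[0]!r} not in map")
    else:
        markers = [Marker(n, "un", j + 1) for j, n in enumerate(df.columns)]
    return GenotypeMatrix(calls=df, markers=markers)


def write_genotype_csv(gm: GenotypeMatrix, path: "str | Path") -> None:
    out = gm.calls.copy()
    out.index.name = "line_id"
    out.to_csv(path)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

PHENOTYPE_COLUMNS = ["line_id", "environment", "replicate", "trait", "value"]


def read_phenotype_csv(path: "str | Path") -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: phenotype table lacks columns {sorted(missing)}")
    df["value"] = df["value"].astype(float)
    if not np.isfinite(df["value"]).all():
        raise ValueError(f"{path}: non-finite phenotype values")
    return df[PHENOTYPE_COLUMNS]


def write_phenotype_csv(df: pd.DataFrame, path: "str | Path") -> None:
    df[PHENOTYPE_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# SNP matrices
# ---------------------------------------------------------------------------

def read_snp_vcf(
    path: "str | Path",
    region: "tuple[str, int, int] | None" = None,
    half_open: bool = False,
) -> SNPMatrix:
    """Read biallelic SNP genotypes from a (plain-text) VCF.

    Multi-allelic and indel records are skipped (counts logged on the
    returned object); heterozygous and ``./.`` calls become missing, as
    accessions are treated as inbred.  ``region`` is (chrom, start, end),
    1-based inclusive by default; set ``half_open`` for BED-style
    [start, end) input, converted at this boundary.
    """
    import pysam

    if region is not None:
        chrom, start, end = region
        if half_open:
            start, end = start + 1, end
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        positions, rows = [], []
        skipped = {"multiallelic": 0, "indel": 0}
        seen_chrom = None
        for rec in vf:
            if region is not None and (
                rec.chrom != chrom or not (start <= rec.pos <= end)
            ):
                continue
            if rec.alts is None or len(rec.alts) != 1:
                skipped["multiallelic"] += 1
                continue
            if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                skipped["indel"] += 1
                continue
            seen_chrom = seen_chrom or rec.chrom
            if rec.chrom != seen_chrom:
                raise ValueError("SNP matrix must cover a single chromosome window")
            calls = []
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or None in gt:
                    calls.append(-1)
                elif all(a == 0 for a in gt):
                    calls.append(0)
                elif all(a == 1 for a in gt):
                    calls.append(1)
                else:
                    calls.append(-1)  # heterozygous in an inbred panel
            positions.append(rec.pos)
            rows.append(calls)
    if not positions:
        raise ValueError(f"{path}: no usable biallelic SNP records")
    mat = SNPMatrix(
        accession_ids=samples,
        positions=np.array(positions),
        genotypes=np.array(rows, dtype=np.int8).T,
        chrom=seen_chrom or "un",
    )
    mat.skipped = skipped  # type: ignore[attr-defined]
    return mat


def read_snp_csv(path: "str | Path", chrom: str = "7A") -> SNPMatrix:
    """CSV dialect: first column accession, remaining headers are bp
    positions, cells 0/1 or '-' for missing."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.set_index(df.columns[0])
    geno = df.replace("-", "-1").astype(np.int8)
    return SNPMatrix(
        accession_ids=list(df.index),
        positions=np.array([int(c) for c in df.columns]),
        genotypes=geno.to_numpy(),
        chrom=chrom,
    )


# ---------------------------------------------------------------------------
# Diagnostic genotypes
# ---------------------------------------------------------------------------

def read_diagnostics_csv(path: "str | Path") -> "pd.DataFrame":
    """Diagnostic marker calls: columns accession, promoter, codon47,
    codon384 and optional linked-SNP columns; returns the frame with a
    ``genotype`` column of :class:`DiagnosticGenotype` objects."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"accession", "promoter", "codon47", "codon384"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: diagnostics need columns {sorted(required)}")
    snp_cols = [c for c in df.columns if c in LINKED_SNP_STATES]
    genos = []
    for _, r in df.iterrows():
        linked = {
            c: r[c] for c in snp_cols if r[c] not in ("", "missing", "-")
        }
        genos.append(
            DiagnosticGenotype(
                promoter_indel=r["promoter"] or "missing",
                codon47=r["codon47"] or "missing",
                codon384=r["codon384"] or "missing",
                linked_snps=linked,
            )
        )
    out = df.copy()
    out["genotype"] = genos
    return out


# ---------------------------------------------------------------------------
# Config and JSON reports
# ---------------------------------------------------------------------------

def write_json(obj, path: "str | Path") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


DEFAULT_CONFIG = {
    "seed": 0,
    "n_ril_lines": 150,
    "ril_generation": 6,
    "n_hif_families": 6,
    "hif_family_size": 30,
    "alpha": 0.05,
    "lod_threshold": 2.0,
    "reps_per_env": 2,
    "out_dir": "hifmap_out",
}


def load_config(path: "str | Path | None") -> dict:
    """Load and validate the YAML run configuration (defaults applied)."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    if not isinstance(cfg["seed"], int) or cfg["seed"] < 0:
        raise ValueError("seed must be a non-negative integer")
    for key in ("n_ril_lines", "ril_generation", "n_hif_families",
                "hif_family_size", "reps_per_env"):
        if not isinstance(cfg[key], int) or cfg[key] < 1:
            raise ValueError(f"{key} must be a positive integer")
    if not 0 < cfg["alpha"] < 1:
        raise ValueError("alpha must be in (0, 1)")
    return cfg
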