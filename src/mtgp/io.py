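"""File formats: dosage/depth TSV, phenotype CSV schemas, GRM TSV, provenance.

Formats are plain text throughout:

* **Dosage TSV** — rows = individuals, columns = SNPs, tab-separated,
  fractional dosages in [0, 2]; an *empty field* (not 0) marks a missing
  call.  A paired depth TSV of identical shape carries reads per call
  (0 = missing).
* **Plot table CSV** — long format, one record per row:
  ``family,population,location,measure,replicate,row,column,trait,value``.
* **BLUP table CSV** — long ``family,trait,blup`` or wide with a
  ``family`` column and one column per trait.
* **GRM TSV** — square matrix with the sample ids as header row and first
  column; round-trips exactly to 12 significant digits.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time

import numpy as np
import pandas as pd

from mtgp.genotypes import GenotypeMatrix
from mtgp.grm import GRM

logger = logging.getLogger(__name__)

__all__ = [
    "write_dosages",
    "read_dosages",
    "write_grm",
    "read_grm",
    "read_phenotypes",
    "write_plot_table",
    "write_blup_table",
    "read_vcf",
    "write_vcf",
    "provenance_record",
]

PLOT_COLUMNS = ["family", "population", "location", "measure", "replicate", "row", "column", "trait", "value"]
_PLOT_REQUIRED = {"family", "replicate", "trait", "value"}


def write_dosages(g: GenotypeMatrix, dosage_path, depth_path) -> None:
    """Write a genotype panel as paired dosage + depth TSV files."""
    dos = pd.DataFrame(g.dosages, index=g.sample_ids, columns=g.snp_ids)
    dep = pd.DataFrame(g.depths, index=g.sample_ids, columns=g.snp_ids)
    dos.to_csv(dosage_path, sep="\t", float_format="%.10g", na_rep="")
    dep.to_csv(depth_path, sep="\t", float_format="%.10g")


def read_dosages(dosage_path, depth_path=None) -> GenotypeMatrix:
    """Read paired dosage/depth TSVs; empty dosage fields are missing calls.

    Without a depth file, depths default to 1 for observed calls (no
    depth correction possible downstream) and 0 for missing.
    """
    dos = pd.read_csv(dosage_path, sep="\t", index_col=0)
    dosages = dos.to_numpy(dtype=float)
    if depth_path is not None:
        dep = pd.read_csv(depth_path, sep="\t", index_col=0)
        if list(dep.index) != list(dos.index) or list(dep.columns) != list(dos.columns):
            raise ValueError("dosage and depth files have mismatched labels")
        depths = dep.to_numpy(dtype=float)
    else:
        depths = np.where(np.isnan(dosages), 0.0, 1.0)
    return GenotypeMatrix(
        dosages=dosages,
        depths=depths,
        sample_ids=[str(s) for s in dos.index],
        snp_ids=[str(s) for s in dos.columns],
    )


def write_grm(K: GRM, path) -> None:
    """Write a GRM as a square TSV with id header row and column."""
    df = pd.DataFrame(K.values, index=K.sample_ids, columns=K.sample_ids)
    df.to_csv(path, sep="\t", float_format="%.15g")


def read_grm(path) -> GRM:
    """Read a square GRM TSV.

    Row and column ids must agree as sets; if the column order differs it
    is permuted to the row order (the file's row order is canonical).
    Asymmetry beyond 1e-8 is symmetrized with a warning (inside
    :class:`~mtgp.grm.GRM`).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    rows = [str(s) for s in df.index]
    cols = [str(s) for s in df.columns]
    if len(rows) != len(cols):
        raise ValueError("GRM file is not square")
    if rows != cols:
        if set(rows) != set(cols):
            raise ValueError("GRM row and column ids do not match")
        df = df[rows]
        logger.info("GRM column order permuted to match row order")
    return GRM(df.to_numpy(dtype=float), rows)


def _sniff_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype CSV/TSV; returns a plot table or a BLUP table.

    The schema is detected from the columns: a ``value`` column together
    with trial-design columns means plot-level records (returned long);
    a ``blup`` column or a wide family × trait layout means family-level
    BLUPs (returned wide, indexed by family).  The detected kind is in
    ``DataFrame.attrs['kind']`` ("plot" or "blup").
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep)
    df.columns = [str(c).strip() for c in df.columns]
    if "family" not in df.columns:
        raise ValueError(f"{path}: missing required column 'family'")

    if "value" in df.columns and _PLOT_REQUIRED <= set(df.columns):
        bad = df[pd.to_numeric(df["value"], errors="coerce").isna() & df["value"].notna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric value at row {bad.index[0] + 2} "
                f"(family {bad.iloc[0]['family']!r})"
            )
        df["value"] = pd.to_numeric(df["value"])
        key_cols = [c for c in ("family", "location", "measure", "replicate", "trait") if c in df.columns]
        dup = df.duplicated(subset=key_cols)
        if dup.any():
            k = df.loc[dup, key_cols].iloc[0].to_dict()
            raise ValueError(f"{path}: duplicate plot record for key {k}")
        logger.info(
            "plot table: %d records, levels %s",
            len(df),
            {c: df[c].nunique() for c in key_cols},
        )
        df.attrs["kind"] = "plot"
        return df

    if "blup" in df.columns:
        if "trait" not in df.columns:
            raise ValueError(f"{path}: long BLUP table requires a 'trait' column")
        dup = df.duplicated(subset=["family", "trait"])
        if dup.any():
            k = df.loc[dup, ["family", "trait"]].iloc[0].to_dict()
            raise ValueError(f"{path}: duplicate BLUP for key {k}")
        wide = df.pivot(index="family", columns="trait", values="blup")
        wide.columns.name = None
        wide.attrs["kind"] = "blup"
        return wide

    # wide family × trait table
    wide = df.set_index("family")
    num = wide.apply(pd.to_numeric, errors="coerce")
    if num.isna().to_numpy().sum() > wide.isna().to_numpy().sum():
        col = num.columns[(num.isna() & wide.notna()).any(axis=0)][0]
        raise ValueError(f"{path}: non-numeric value in trait column {col!r}")
    if wide.index.duplicated().any():
        raise ValueError(f"{path}: duplicate family {wide.index[wide.index.duplicated()][0]!r}")
    num.attrs["kind"] = "blup"
    return num


def write_plot_table(plots: pd.DataFrame, path) -> None:
    cols = [c for c in PLOT_COLUMNS if c in plots.columns]
    plots[cols].to_csv(path, index=False)


def write_blup_table(blups: pd.DataFrame, path) -> None:
    """Write a family × trait BLUP table in long `family,trait,blup` form."""
    long = blups.reset_index().melt(id_vars="family", var_name="trait", value_name="blup")
    long.dropna(subset=["blup"]).to_csv(path, index=False)


# -- optional VCF support -------------------------------------------------

def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF with AD (allele depth) or DP+GT fields into dosages/depths."""
    try:
        from cyvcf2 import VCF
    except ImportError as e:  # pragma: no cover
        raise ImportError("VCF support requires cyvcf2") from e
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    dosages, depths, ids = [], [], []
    for var in vcf:
        try:
            ad = var.format("AD")
        except KeyError:
            ad = None
        if ad is not None:
            ref = ad[:, 0].astype(float)
            alt = ad[:, 1].astype(float)
            k = ref + alt
            with np.errstate(divide="ignore", invalid="ignore"):
                dose = np.where(k > 0, 2.0 * alt / np.maximum(k, 1.0), np.nan)
        else:
            # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            gts = np.asarray(var.gt_types)
            dose = np.choose(gts, [0.0, 1.0, np.nan, 2.0])
            dp = var.format("DP")
            k = dp[:, 0].astype(float) if dp is not None else np.where(np.isnan(dose), 0.0, 1.0)
            k = np.where(np.isnan(dose), 0.0, np.maximum(k, 1.0))
        dosages.append(dose)
        depths.append(np.where(np.isnan(dose), 0.0, k))
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
    return GenotypeMatrix(
        dosages=np.array(dosages).T,
        depths=np.array(depths).T,
        sample_ids=samples,
        snp_ids=ids,
    )


def write_vcf(g: GenotypeMatrix, path, chrom: str = "1") -> None:
    """Export hard integer calls (rounded dosages) as a minimal VCF."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(g.sample_ids) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, snp in enumerate(g.snp_ids):
            cells = []
            for i in range(g.n_samples):
                d = g.dosages[i, j]
                k = int(g.depths[i, j])
                cells.append("./.:0" if np.isnan(d) else f"{gt_map[int(round(d))]}:{k}")
            fh.write(f"{chrom}\t{j + 1}\t{snp}\tA\tC\t.\tPASS\t.\tGT:DP\t" + "\t".join(cells) + "\n")


def provenance_record(inputs: dict, seed: "int | None", config: "dict | None" = None,
                      started: "float | None" = None) -> dict:
    """Build the provenance dict every CLI artifact is written with."""
    from mtgp import __version__

    cfg_json = json.dumps(config or {}, sort_keys=True, default=str)
    return {
        "mtgp_version": __version__,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "seed": seed,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
        "config": config or {},
        "wall_time_s": None if started is None else round(time.time() - started, 3),
    }
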