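"""I/O for the minimal TCGA MAF dialect, sample sheets and gene lists.

MAF files are tab-separated with a header; positions are written 1-based
inclusive (the MAF convention) and converted back to the package's 0-based
half-open coordinates on read.  Extra columns in incoming files are ignored.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .records import MUTATION_COLUMNS, ValidationError

#: Package column -> MAF column.
_MAF_COLUMN_MAP = {
    "gene_symbol": "Hugo_Symbol",
    "chromosome": "Chromosome",
    "position": "Start_Position",
    "ref_allele": "Reference_Allele",
    "alt_allele": "Tumor_Seq_Allele2",
    "variant_classification": "Variant_Classification",
    "sample_id": "Tumor_Sample_Barcode",
    "t_depth": "t_depth",
    "t_alt_count": "t_alt_count",
    "is_hotspot": "is_hotspot",
}
_REQUIRED_MAF_COLUMNS = [v for k, v in _MAF_COLUMN_MAP.items() if k != "is_hotspot"]


def write_maf(mutations: pd.DataFrame, path) -> None:
    """Write mutations as tab-separated MAF (1-based Start_Position)."""
    out = pd.DataFrame(
        {maf: mutations[col] for col, maf in _MAF_COLUMN_MAP.items()}
    )
    out["Start_Position"] = mutations["position"].astype(int) + 1
    out["FILTER"] = "PASS"
    out["is_hotspot"] = mutations["is_hotspot"].astype(bool).map({True: "True", False: "False"})
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_maf(path) -> pd.DataFrame:
    """Read a MAF file into the mutation schema (0-based positions).

    VAF is recomputed as t_alt_count / t_depth.  Rows with a non-PASS
    FILTER value are dropped when the column is present; columns beyond the
    dialect are ignored.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"Chromosome": str})
    missing = [c for c in _REQUIRED_MAF_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing MAF columns {missing}")
    if "FILTER" in df.columns:
        df = df[df["FILTER"].isin(["PASS", ".", ""]) | df["FILTER"].isna()]
    out = pd.DataFrame(
        {
            "sample_id": df["Tumor_Sample_Barcode"].astype(str),
            "gene_symbol": df["Hugo_Symbol"].astype(str),
            "chromosome": df["Chromosome"].astype(str),
            "position": df["Start_Position"].astype(int) - 1,
            "ref_allele": df["Reference_Allele"].astype(str),
            "alt_allele": df["Tumor_Seq_Allele2"].astype(str),
            "variant_classification": df["Variant_Classification"].astype(str),
            "t_depth": df["t_depth"].astype(int),
            "t_alt_count": df["t_alt_count"].astype(int),
        }
    )
    out["vaf"] = out["t_alt_count"] / out["t_depth"]
    if "is_hotspot" in df.columns:
        out["is_hotspot"] = df["is_hotspot"].astype(str).str.lower().isin(["true", "1", "yes"]).to_numpy()
    else:
        out["is_hotspot"] = False
    return out[MUTATION_COLUMNS].reset_index(drop=True)


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    """TSV of sample_id, tumor purity and reference wesTMB (+ class)."""
    cols = [c for c in ["sample_id", "tumor_purity", "ref_wes_tmb", "tmb_class"] if c in samples]
    samples[cols].to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValidationError(f"{path}: sample sheet needs a sample_id column")
    df["sample_id"] = df["sample_id"].astype(str)
    return df


def read_gene_list(path) -> set[str]:
    """One gene symbol per line; blank lines and #-comments skipped."""
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            sym = line.strip()
            if sym and not sym.startswith("#"):
                out.add(sym)
    return out


def write_gene_list(genes: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for sym in sorted(genes):
            fh.write(f"{sym}\n")
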