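"""Bundled published summary tables.

Small TSV transcriptions of the printed summary tables of the cotton
BES-SNP mining study: the interspecific KASP screening table, the SNP-type
counts per species tier, the final-VCF per-sample call statistics, and the
genic/nongenic annotation counts. They are inputs for recomputing the
study's derived percentages and ratios, not outputs of this package.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

GRAND_TOTAL_SAMPLES = 14  # 12 hirsutum lines + 1 barbadense + 1 longicalyx


def _path(name: str):
    return importlib.resources.files("bessnp") / "data" / name


def snp_type_counts() -> dict[str, dict[str, int]]:
    """Per-tier IUPAC-class counts of the published master table."""
    df = pd.read_csv(_path("snp_type_counts.tsv"), sep="\t")
    return {
        row["tier"]: {c: int(row[c]) for c in ("M", "R", "W", "S", "Y", "K")}
        for _, row in df.iterrows()
    }


def final_callstats() -> pd.DataFrame:
    """Published per-sample missing / heterozygous counts."""
    return pd.read_csv(_path("final_callstats.tsv"), sep="\t")


def genic_annotation() -> pd.DataFrame:
    """Published genic / nongenic SNP counts per species tier."""
    return pd.read_csv(_path("genic_annotation.tsv"), sep="\t")


def kasp_screen_path() -> str:
    """Path of the bundled KASP screening table (32 markers)."""
    return str(_path("kasp_screen_barbadense.tsv"))
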