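"""Plain-text readers and writers for the pipeline's interchange formats.

Everything is TSV, GMT or YAML so results remain diffable and portable:
counts as genes x samples TSV (first column ``gene_id``), the sample sheet
as a four-column TSV, gene sets in the standard GMT line format and run
configuration in YAML.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Mapping

import pandas as pd
import yaml

SAMPLE_SHEET_COLUMNS = ["sample_id", "fraction", "condition", "pair_id"]


def read_counts_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Read a genes x samples count TSV (first column gene id) into an
    integer DataFrame indexed by gene id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dup[:5]}")
    return df.astype("int64")


def write_counts_tsv(counts: pd.DataFrame, path: str | os.PathLike) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_sheet(path: str | os.PathLike) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet {path} lacks columns {missing}")
    return sheet[SAMPLE_SHEET_COLUMNS]


def write_sample_sheet(sheet: pd.DataFrame, path: str | os.PathLike) -> None:
    sheet[SAMPLE_SHEET_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gmt(path: str | os.PathLike) -> Dict[str, List[str]]:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>gene...``."""
    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line in {path}: {line[:80]!r}")
            name = fields[0]
            if name in sets:
                raise ValueError(f"duplicate gene set name {name!r} in {path}")
            sets[name] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | os.PathLike,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_gene_list(path: str | os.PathLike) -> List[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: Iterable[str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def write_table(df: pd.DataFrame, path: str | os.PathLike, index: bool = False,
                index_label: str | None = None) -> None:
    """Write a result table with a fixed float format so that repeated runs
    with the same seed are byte-identical."""
    df.to_csv(path, sep="\t", index=index, index_label=index_label,
              float_format="%.6g")


def read_yaml(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_yaml(obj: dict, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def read_qpcr_tsv(path: str | os.PathLike) -> pd.DataFrame:
    plate = pd.read_csv(path, sep="\t")
    required = {"sample_id", "fraction", "condition", "pair_id", "target",
                "technical_replicate", "ct"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"qPCR table {path} lacks columns {sorted(missing)}")
    return plate
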