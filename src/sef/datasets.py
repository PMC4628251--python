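"""Bundled published inputs: validated-enhancer coordinates and expression.

Two small TSVs ship with the package: the genomic spans (1-based inclusive,
browser style) and shared-n-mer counts of the five experimentally validated
syntenic zebrafish/mouse enhancer pairs, and the tissue/time expression
annotations of every tested reporter construct.  They are inputs to the
chance-statistics and consistency stages, not outputs of this package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from sef.core_io.intervals import GenomicInterval, parse_region


def _data_path(name: str):
    return resources.files("sef").joinpath("data", name)


def load_validated_enhancers() -> pd.DataFrame:
    """Validated syntenic enhancer pairs with parsed intervals and lengths.

    Columns: ecr, zf_region, mm_region, shared_nmers, zf_interval,
    mm_interval, zf_length, mm_length (inclusive lengths, i.e. end - start
    of the converted half-open interval).
    """
    with resources.as_file(_data_path("validated_enhancers.tsv")) as path:
        df = pd.read_csv(path, sep="\t", dtype={"ecr": int, "shared_nmers": int})
    df["zf_interval"] = [parse_region(r, "danRer7") for r in df["zf_region"]]
    df["mm_interval"] = [parse_region(r, "mm9") for r in df["mm_region"]]
    df["zf_length"] = [iv.length for iv in df["zf_interval"]]
    df["mm_length"] = [iv.length for iv in df["mm_interval"]]
    return df


def load_validated_expression() -> pd.DataFrame:
    """Expression annotations of tested constructs.

    Columns: ecr, species ('zf'/'mm'), construct, tissue, time_hpf.
    Constructs that scored negative or were not tested have no rows.
    """
    with resources.as_file(_data_path("validated_expression.tsv")) as path:
        return pd.read_csv(path, sep="\t", dtype={"ecr": int, "time_hpf": int})


def expression_calls(
    df: pd.DataFrame | None = None,
) -> dict[tuple[int, str], set[tuple[str, int]]]:
    """(ecr, species) -> set of positive (tissue, time_hpf) cells."""
    if df is None:
        df = load_validated_expression()
    out: dict[tuple[int, str], set[tuple[str, int]]] = {}
    for _, row in df.iterrows():
        out.setdefault((int(row["ecr"]), row["species"]), set()).add(
            (row["tissue"], int(row["time_hpf"]))
        )
    return out
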