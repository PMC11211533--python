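"""Loaders for the small data tables packaged with the library.

The sharing table, cohort composition, pathway summary and dating profile
are transcriptions of published summary tables; the DDR catalog is a
synthetic stand-in (the published gene panel prints per-pathway counts but
no roster or intervals), built to match those counts with literature-named
genes in their true pathways and filler symbols elsewhere.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterator

import pandas as pd

from .catalog_io import GeneCatalog, read_gene_catalog

_DATA = resources.files("pvarch") / "data"


def _path(name: str) -> Path:
    with resources.as_file(_DATA / name) as p:
        return Path(p)


def load_ddr_catalog() -> GeneCatalog:
    """Synthetic 169-gene DNA-damage-repair catalog across 8 pathways."""
    return read_gene_catalog(_path("ddr_catalog_synthetic.tsv"))


def load_nonafrican_composition() -> pd.DataFrame:
    """Non-African cohort composition: 9 population groups with case counts."""
    return pd.read_csv(_path("nonafrican_composition.tsv"), sep="\t")


def load_pathway_pv_summary() -> pd.DataFrame:
    """Published per-pathway gene and pathogenic-variant counts."""
    return pd.read_csv(_path("pathway_pv_summary.tsv"), sep="\t")


def load_ancient_dating_profile() -> pd.DataFrame:
    """Epoch-binned counts of dated ancient samples (plus an NA row)."""
    return pd.read_csv(_path("ancient_sample_dating.tsv"), sep="\t",
                       keep_default_na=False)


def load_ancient_sharing_table() -> pd.DataFrame:
    """Ancient TP53/BRCA pathogenic variants with modern-cohort share flags.

    Columns: gene, hgvs_c, hgvs_p, consequence, african, nonafrican ("+"/"-"),
    earliest_bp (years BP of the oldest dated carrier; NA if undated).
    Labels are stored verbatim from the source table, including its
    typographic quirks; ``earliest_bp`` is parsed to nullable integers.
    """
    df = pd.read_csv(_path("ancient_tp53_brca_sharing.tsv"), sep="\t",
                     dtype=str)
    df["earliest_bp"] = (df["earliest_bp"].str.replace(",", "", regex=False)
                         .replace("NA", pd.NA).astype("Int64"))
    return df


def synthetic_partition_sets(n_a: int, n_b: int, n_shared: int
                             ) -> tuple[set[str], set[str]]:
    """Two synthetic key sets with prescribed sizes and intersection."""
    if n_shared > min(n_a, n_b):
        raise ValueError("intersection cannot exceed either set size")
    shared = {f"S{i}" for i in range(n_shared)}
    a = shared | {f"A{i}" for i in range(n_a - n_shared)}
    b = shared | {f"B{i}" for i in range(n_b - n_shared)}
    return a, b


def dating_profile_samples() -> Iterator[tuple[str, int]]:
    """(bin label, count) pairs from the packaged dating profile."""
    df = load_ancient_dating_profile()
    for _, row in df.iterrows():
        yield str(row["timing_bp"]), int(row["count"])
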