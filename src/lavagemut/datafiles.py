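"""Loaders for the bundled reference data.

Bundled files:

* ``kb_12gene.yaml`` — knowledge base for the 12-gene endometrial panel.
* ``panel_12gene_synthetic.bed`` — synthetic stand-in amplicon coordinates
  (102 amplicons inside the true GRCh37 gene spans).
* ``snp_spikein_synthetic.tsv`` — synthetic stand-in SNP fingerprint loci.
* ``mutation_catalog_synthetic.tsv`` — synthetic stand-in for the study-scale
  unique-mutation list (126 mutations with truth labels).
* ``af_bin_table_published.tsv`` / ``af_bin_patients_published.tsv`` —
  published per-gene AF-bin counts and per-bin patient counts, used as input
  data for the cohort-level summaries.
"""

from __future__ import annotations

from importlib import resources
from typing import List, Tuple

import pandas as pd

from .variant_io import PanelDefinition


def _data_path(name: str):
    return resources.files("lavagemut.data").joinpath(name)


def load_snp_loci() -> pd.DataFrame:
    with resources.as_file(_data_path("snp_spikein_synthetic.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#", dtype={"chrom": str})


def load_default_panel() -> PanelDefinition:
    """The bundled 12-gene panel (102 amplicons) with its SNP spike-in loci."""
    snps = load_snp_loci()
    snp_loci: List[Tuple[str, int]] = list(zip(snps["chrom"], snps["pos"].astype(int)))
    with resources.as_file(_data_path("panel_12gene_synthetic.bed")) as p:
        return PanelDefinition.from_bed(p, name="endometrial-12gene", snp_loci=snp_loci)


def load_mutation_catalog() -> pd.DataFrame:
    """Synthetic stand-in unique-mutation catalogue (gene, protein_change, expected_label)."""
    with resources.as_file(_data_path("mutation_catalog_synthetic.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def load_published_af_table() -> pd.DataFrame:
    """Published per-gene mutation counts by AF bin for both lavage fractions."""
    with resources.as_file(_data_path("af_bin_table_published.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def load_published_bin_patients() -> pd.DataFrame:
    """Published cancer/total patient counts per fraction x AF bin."""
    with resources.as_file(_data_path("af_bin_patients_published.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def default_kb_path():
    return _data_path("kb_12gene.yaml")
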