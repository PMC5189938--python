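import numpy as np
import pandas as pd
import pytest

from lavagemut.datafiles import (load_default_panel, load_mutation_catalog,
                                 load_published_af_table,
                                 load_published_bin_patients)
from lavagemut.nomination import default_knowledge_base
from lavagemut.simulate import CohortSimulator, SimulationConfig


@pytest.fixture(scope="session")
def kb():
    return default_knowledge_base()


@pytest.fixture(scope="session")
def panel():
    return load_default_panel()


@pytest.fixture(scope="session")
def catalog():
    return load_mutation_catalog()


@pytest.fixture(scope="session")
def published_af_table():
    return load_published_af_table()


@pytest.fixture(scope="session")
def published_bin_patients():
    return load_published_bin_patients()


@pytest.fixture(scope="session")
def simulator():
    return CohortSimulator(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def cohort_seed11(simulator):
    return simulator.simulate_cohort()


def write_vcf_text(path, records, sample="S1"):
    """Write a minimal single-sample VCF for test fixtures.

    records: iterable of (chrom, pos, ref, alts, dp, ads) where alts is a
    tuple of ALT alleles and ads the allelic depths (ref first).
    """
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
    ]
    chroms = []
    for chrom, *_ in records:
        if chrom not in chroms:
            chroms.append(chrom)
    for chrom in chroms:
        lines.append(f"##contig=<ID={chrom},length=249250621>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample)
    for chrom, pos, ref, alts, dp, ads in records:
        alt = ",".join(alts)
        ad = ",".join(str(a) for a in ads)
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\tGT:DP:AD\t0/1:{dp}:{ad}")
    path.write_text("\n".join(lines) + "\n")
    return path
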