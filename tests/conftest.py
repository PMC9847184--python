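import numpy as np
import pytest

from melonprint import (
    GenotypeMatrix,
    Marker,
    MarkerPanel,
    melon_panel,
    simulate_panel,
)
from melonprint.simulate import GenomeSimConfig, simulate_genome_and_vcf


def make_matrix(rows, types=None, varieties=None):
    """Build a GenotypeMatrix from a list of per-variety cell lists.

    ``rows[i][j]`` is an allele tuple or None.  Marker types default to SSR
    for integer alleles and SNP for strings (detected per column).
    """
    n_loci = len(rows[0])
    markers = []
    for j in range(n_loci):
        first = next((r[j] for r in rows if r[j] is not None), (0, 0))
        is_snp = isinstance(first[0], str)
        t = (types[j] if types else ("SNP" if is_snp else "SSR"))
        markers.append(
            Marker(
                f"M{j + 1:03d}",
                t,
                "chr01",
                (j + 1) * 1000,
                motif="AT" if t == "SSR" else None,
                ref=(first[0] if t == "SNP" else None),
            )
        )
    names = varieties or [f"v{i + 1}" for i in range(len(rows))]
    return GenotypeMatrix(names, MarkerPanel(markers), rows)


def random_matrix(rng, n, m, max_alleles=4, missing=0.1, marker_type="SSR"):
    cells = []
    for _ in range(n):
        row = []
        for j in range(m):
            if rng.random() < missing:
                row.append(None)
            elif marker_type == "SSR":
                row.append(tuple(sorted(rng.integers(8, 8 + max_alleles, size=2).tolist())))
            else:
                bases = ["A", "C", "G", "T"][:max_alleles]
                row.append(tuple(sorted(rng.choice(bases, size=2).tolist())))
        cells.append(row)
    types = [marker_type] * m
    return make_matrix(cells, types=types)


@pytest.fixture(scope="session")
def panel_sim():
    """The default synthetic 259-variety panel, shared across tests."""
    return simulate_panel(melon_panel(1))


@pytest.fixture(scope="session")
def pure_labels(panel_sim):
    return {
        v: l
        for v, l in zip(panel_sim.matrix.varieties, panel_sim.labels)
        if l != "admixed"
    }


@pytest.fixture(scope="session")
def genome_fixture(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("genome_fixture")
    genome, records, freq_tbl, manifest = simulate_genome_and_vcf(
        GenomeSimConfig(seed=7), outdir=outdir
    )
    return {
        "genome": genome,
        "records": records,
        "freq": freq_tbl,
        "manifest": manifest,
        "dir": outdir,
    }
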