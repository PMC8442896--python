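import numpy as np
import pandas as pd
import pytest

import sexlinkage as sl


def balanced_newick(n_tips: int, depth: float) -> str:
    """Balanced ultrametric tree string with tips t0..t{n-1}."""

    def rec(labels, d):
        if len(labels) == 1:
            return f"{labels[0]}:{d}"
        mid = len(labels) // 2
        return f"({rec(labels[:mid], d / 2)},{rec(labels[mid:], d / 2)}):{d / 2}"

    return rec([f"t{i}" for i in range(n_tips)], depth) + ";"


@pytest.fixture
def balanced_tree16():
    return sl.timetree_from_string(balanced_newick(16, 10.0))


@pytest.fixture
def panel10():
    return sl.default_panel(10)


@pytest.fixture
def lgs5():
    return sl.default_lg_table(5, 2_000_000)


@pytest.fixture
def planted_xy_truth():
    """Ten species sharing a 1-Mb fully differentiated XY region on LG01."""
    species = {
        f"sp{i:02d}": sl.SpeciesTruth("LG01", "XY", (500_000, 1_500_000), 1.0)
        for i in range(1, 11)
    }
    return sl.SimTruth(species=species, seed=1)


def make_variant_table(records, individuals):
    """Build a VariantTable from (lg, pos, ref, alt, genotypes) tuples.

    Genotypes are (a0, a1) allele-index pairs, or None for missing.
    """
    rows, a0s, a1s = [], [], []
    for lg, pos, ref, alt, gts in records:
        size = max((abs(len(a) - len(ref)) for a in alt.split(",")), default=0)
        rows.append((lg, pos, ref, alt, size > 0, size))
        a0s.append([(-1 if g is None else g[0]) for g in gts])
        a1s.append([(-1 if g is None else g[1]) for g in gts])
    sites = pd.DataFrame(
        rows, columns=["lg", "pos", "ref", "alt", "is_indel", "indel_size"]
    )
    n, m = len(rows), len(individuals)
    return sl.VariantTable(
        sites,
        np.array(a0s, dtype=np.int8).reshape(n, m),
        np.array(a1s, dtype=np.int8).reshape(n, m),
        np.full((n, m), 99, dtype=np.int16),
        np.full((n, m), 20, dtype=np.int16),
        list(individuals),
    )
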