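"""Sex-chromosome differentiation sizing and X/Y haplotype extraction.

The degree of differentiation of a called sex chromosome is the proportion
of the linkage group covered by 10-kb windows whose density of sex-specific
SNPs exceeds twice the genome-wide mean over all windows; the qualifying
windows' summed length and coordinate range size the sex-differentiated
region. Differentiation is related to the estimated age of the system (the
turnover point) by pGLS. For convergence testing, X and Y haplotypes are
extracted from male/female genotype pairs: at sites where a focal male is
heterozygous and its female homozygous, the allele shared with the female is
the presumed X and the other the presumed Y.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .call_integration import SpeciesCall
from .io_prep import (
    GT_MISSING,
    SamplePanel,
    SexlinkageError,
    TimeTree,
    VariantTable,
)
from .phylo_turnover import PglsFit, pgls_fit
from .wgs_sexscan import CXY, CZW, SiteClassTable

DIFF_WINDOW_BP = 10_000


@dataclass
class DifferentiationRegion:
    species_id: str
    lg: str
    cumulative_bp: int
    range_start: int | None
    range_end: int | None
    proportion_of_lg: float
    n_qualifying_windows: int


def differentiation_regions(
    sct: SiteClassTable,
    call: SpeciesCall,
    lgs: pd.DataFrame,
    window: int = DIFF_WINDOW_BP,
) -> list[DifferentiationRegion]:
    """Size the sex-differentiated region(s) of a called species.

    Density is the count of system-matching sex-specific SNPs per 10-kb
    nonoverlapping window; a window on a called LG qualifies when its count
    strictly exceeds twice the mean over all genome windows (empty windows
    included). Returns one region record per called LG.
    """
    if call.species_id not in sct.species:
        raise SexlinkageError(f"species {call.species_id} not in site class table")
    j = sct.species.index(call.species_id)
    code = CXY if call.system == "XY" else CZW
    match = sct.classes[:, j] == code

    lg_len = dict(zip(lgs["lg_id"], lgs["length_bp"]))
    counts: dict[str, np.ndarray] = {}
    total_windows = 0
    total_snps = 0
    for lg, length in lg_len.items():
        n_win = max(math.ceil(length / window), 1)
        acc = np.zeros(n_win)
        in_lg = (sct.sites["lg"] == lg).to_numpy()
        if in_lg.any():
            pos = sct.sites.loc[in_lg, "pos"].to_numpy()
            hits = match[in_lg]
            bins = np.minimum((pos - 1) // window, n_win - 1)
            np.add.at(acc, bins, hits.astype(float))
        counts[lg] = acc
        total_windows += n_win
        total_snps += int(acc.sum())
    mean_density = total_snps / total_windows if total_windows else 0.0
    threshold = 2.0 * mean_density

    regions = []
    for lg in sorted(call.lg_ids):
        if lg not in counts:
            continue
        acc = counts[lg]
        length = lg_len[lg]
        qual = np.flatnonzero(acc > threshold) if threshold > 0 else np.array([], int)
        if threshold == 0:
            qual = np.array([], dtype=int)  # zero genome-wide mean: nothing qualifies
        if qual.size:
            starts = qual * window + 1
            ends = np.minimum(starts + window - 1, length)
            cumulative = int((ends - starts + 1).sum())
            regions.append(
                DifferentiationRegion(
                    call.species_id, lg, cumulative,
                    int(starts.min()), int(ends.max()),
                    cumulative / length, int(qual.size),
                )
            )
        else:
            regions.append(
                DifferentiationRegion(call.species_id, lg, 0, None, None, 0.0, 0)
            )
    return regions


def species_proportion(regions: list[DifferentiationRegion], lgs: pd.DataFrame) -> float:
    """Aggregate proportion over a species' called LGs (multi-LG calls)."""
    lg_len = dict(zip(lgs["lg_id"], lgs["length_bp"]))
    cum = sum(r.cumulative_bp for r in regions)
    tot = sum(lg_len[r.lg] for r in regions)
    return cum / tot if tot else 0.0


def age_differentiation_pgls(
    proportions: dict, ages: dict, tree: TimeTree
) -> PglsFit:
    """pGLS of differentiation proportion on estimated system age.

    ``proportions`` and ``ages`` map species_id -> value; the tree is pruned
    to the species present in both.
    """
    common = sorted(set(proportions) & set(ages) & set(tree.tip_labels))
    if len(common) < 3:
        raise SexlinkageError("need at least 3 species with age and proportion")
    sub = tree.pruned_to(common)
    labels = [t for t in sub.tip_labels]
    y = [proportions[s] for s in labels]
    x = [ages[s] for s in labels]
    return pgls_fit(y, x, sub, labels)


# ---------------------------------------------------------------------------
# X/Y haplotypes
# ---------------------------------------------------------------------------


@dataclass
class HaplotypeSet:
    """Per-individual haplotype pairs over the selected sites."""

    sequences: dict  # id -> sequence string (alleles; N = missing)
    site_index: pd.DataFrame  # lg, pos of the selected sites

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n{seq}\n")


def extract_sex_haplotypes(
    vt: VariantTable,
    panel: SamplePanel,
    focal_species: list[str],
    max_missing: float = 0.10,
    seed: int = 0,
) -> HaplotypeSet:
    """Extract presumed X and Y haplotypes at shared XY sites.

    Sites must be XY-classified (male heterozygous, female homozygous) in at
    least one focal species and carry less than ``max_missing`` missing data
    across all included individuals. For each focal male the allele shared
    with its female is the X, the other the Y; all other individuals
    contribute their two unphased alleles in seeded-random order.
    """
    rng = np.random.default_rng(seed)
    gt = vt.genotype_codes()
    pairs = {}
    for sp in focal_species:
        pair = panel.pair_for(sp)
        if pair is None:
            warnings.warn(f"focal species {sp} lacks a pair; excluded", stacklevel=2)
            continue
        pairs[sp] = (vt.column_of(pair[0]), vt.column_of(pair[1]))
    xy_any = np.zeros(vt.n_sites, dtype=bool)
    dropped = []
    for sp, (cm, cf) in list(pairs.items()):
        xy_sp = (gt[:, cm] == 1) & ((gt[:, cf] == 0) | (gt[:, cf] == 2))
        if not xy_sp.any():
            warnings.warn(f"focal species {sp} has no XY sites; excluded", stacklevel=2)
            dropped.append(sp)
            continue
        xy_any |= xy_sp
    for sp in dropped:
        del pairs[sp]
    if not pairs:
        raise SexlinkageError("no focal species with XY-classified sites")
    missing_frac = (gt == GT_MISSING).mean(axis=1)
    selected = np.flatnonzero(xy_any & (missing_frac < max_missing))
    if selected.size == 0:
        raise SexlinkageError("no sites pass the XY and missingness filters")

    alleles = []
    for i in selected:
        row = vt.sites.iloc[i]
        alleles.append([row["ref"]] + row["alt"].split(","))

    focal_male_cols = {cm: (sp, cf) for sp, (cm, cf) in pairs.items()}
    sequences: dict[str, list[str]] = {}
    for j, ind in enumerate(vt.individuals):
        h1, h2 = [], []
        is_focal_male = j in focal_male_cols
        cf = focal_male_cols[j][1] if is_focal_male else None
        for si, i in enumerate(selected):
            a, b = vt.a0[i, j], vt.a1[i, j]
            if a < 0 or b < 0:
                h1.append("N")
                h2.append("N")
                continue
            ca, cb = alleles[si][a], alleles[si][b]
            if a == b:
                h1.append(ca)
                h2.append(cb)
                continue
            if is_focal_male:
                fa, fb = vt.a0[i, cf], vt.a1[i, cf]
                if fa >= 0 and fa == fb and fa in (a, b):
                    shared = alleles[si][fa]
                    other = cb if ca == shared else ca
                    h1.append(shared)  # presumed X
                    h2.append(other)  # presumed Y
                    continue
            if rng.random() < 0.5:
                ca, cb = cb, ca
            h1.append(ca)
            h2.append(cb)
        suffixes = ("X", "Y") if is_focal_male else ("h1", "h2")
        sequences[f"{ind}_{suffixes[0]}"] = "".join(h1)
        sequences[f"{ind}_{suffixes[1]}"] = "".join(h2)
    site_index = vt.sites.iloc[selected][["lg", "pos"]].reset_index(drop=True)
    return HaplotypeSet(sequences, site_index)


def haplotype_nj_tree(sequences: dict) -> str:
    """Neighbor-joining tree (newick) from Hamming distances ignoring N.

    Negative branch lengths are clamped to zero. Requires at least three
    equal-length sequences.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    names = list(sequences)
    if len(names) < 3:
        raise SexlinkageError("need at least 3 sequences")
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) != 1:
        raise SexlinkageError("sequences must have equal length")
    arrs = [np.frombuffer(sequences[n].encode(), dtype="S1") for n in names]
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (arrs[i] != b"N") & (arrs[j] != b"N")
            denom = int(ok.sum())
            dist = float((arrs[i][ok] != arrs[j][ok]).mean()) if denom else 0.0
            d[i, j] = d[j, i] = dist
    tree = nj(DistanceMatrix(d, ids=names), neg_as_zero=True)
    return str(tree).strip()
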