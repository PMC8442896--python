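"""Input/output and variant-level preparation.

Containers for the whole-genome substrate of the sex-linkage scans — a sample
panel (one male and one female genome per species, grouped into tribes), a
genotype table with per-call quality (GQ) and depth (DP), a linkage-group
length table, and a time-calibrated ultrametric species tree — together with
the variant-level filters applied before any scan:

* masking of SNPs around indels with a width that grows with indel size,
* per-genotype GQ/DP masking, biallelic/missingness site retention,
* re-anchoring of the reference allele at sites where no retained individual
  carries it.

Coordinates are 1-based inclusive throughout (VCF convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

# genotype codes used throughout the package
GT_MISSING = -1
GT_HOM_REF = 0
GT_HET = 1
GT_HOM_ALT = 2

#: mask half-widths (bp) around an indel, keyed by indel size class
#: size 2 bp is interpolated to 3 bp (monotone widths; see docs/methods.md)
INDEL_MASK_WIDTHS = ((1, 2), (2, 3), (3, 3), (5, 5))  # (max_size, width)
INDEL_MASK_WIDTH_LARGE = 10  # sizes > 5 bp

#: pseudo-LG under which unplaced scaffolds are concatenated
UNPLACED_LG = "UNPLACED"

MALE = "male"
FEMALE = "female"


class SexlinkageError(ValueError):
    """Raised on invalid inputs (malformed files, violated invariants)."""


# ---------------------------------------------------------------------------
# sample panel
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SamplePanel:
    """Mapping of sequenced individuals to species, tribe and sex."""

    table: pd.DataFrame  # columns: individual_id, species_id, tribe_id, sex

    def __post_init__(self):
        t = self.table
        required = ["individual_id", "species_id", "tribe_id", "sex"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise SexlinkageError(f"panel missing columns: {missing}")
        if t["individual_id"].duplicated().any():
            dup = t.loc[t["individual_id"].duplicated(), "individual_id"].tolist()
            raise SexlinkageError(f"duplicate individual_ids in panel: {dup}")
        bad_sex = set(t["sex"]) - {MALE, FEMALE}
        if bad_sex or t["sex"].isna().any():
            raise SexlinkageError(f"sex must be male/female, got {bad_sex}")
        object.__setattr__(self, "table", t.reset_index(drop=True))

    @property
    def individuals(self) -> list[str]:
        return self.table["individual_id"].tolist()

    @property
    def species(self) -> list[str]:
        return list(dict.fromkeys(self.table["species_id"]))

    def tribe_of(self, species_id: str) -> str:
        rows = self.table[self.table["species_id"] == species_id]
        return rows["tribe_id"].iloc[0]

    def sex_of(self, individual_id: str) -> str:
        rows = self.table[self.table["individual_id"] == individual_id]
        return rows["sex"].iloc[0]

    def pair_for(self, species_id: str) -> tuple[str, str] | None:
        """Designated (male, female) individual pair, or None if incomplete.

        When a species contributes more than one individual per sex, the first
        listed of each sex is the designated pair; extra individuals are kept
        for clustering but ignored in site classification.
        """
        rows = self.table[self.table["species_id"] == species_id]
        males = rows.loc[rows["sex"] == MALE, "individual_id"]
        females = rows.loc[rows["sex"] == FEMALE, "individual_id"]
        if len(males) == 0 or len(females) == 0:
            return None
        return males.iloc[0], females.iloc[0]

    def subset_tribe(self, tribe_id: str) -> "SamplePanel":
        return SamplePanel(self.table[self.table["tribe_id"] == tribe_id])

    @classmethod
    def from_tsv(cls, path) -> "SamplePanel":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# variant table
# ---------------------------------------------------------------------------


@dataclass
class VariantTable:
    """Per-site variant records plus per-individual genotype/GQ/DP matrices.

    ``sites`` columns: lg, pos (1-based), ref, alt (comma-joined), is_indel,
    indel_size (bp; 0 for SNPs). Allele matrices ``a0``/``a1`` hold allele
    indices per individual (-1 = missing); GQ and DP are phred-scaled quality
    and read depth per call.
    """

    sites: pd.DataFrame
    a0: np.ndarray  # (n_sites, n_individuals) int8
    a1: np.ndarray
    gq: np.ndarray  # int16
    dp: np.ndarray  # int16
    individuals: list[str]

    def __post_init__(self):
        n = len(self.sites)
        m = len(self.individuals)
        for name in ("a0", "a1", "gq", "dp"):
            arr = getattr(self, name)
            if arr.shape != (n, m):
                raise SexlinkageError(
                    f"{name} shape {arr.shape} != sites x individuals ({n}, {m})"
                )
        self.sites = self.sites.reset_index(drop=True)
        # positions strictly increasing within each LG
        for lg, grp in self.sites.groupby("lg", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                order = np.lexsort((self.sites["pos"], self.sites["lg"]))
                self._reorder(order)
                break
        bad = self.sites["is_indel"] & (self.sites["indel_size"] < 1)
        if bad.any():
            raise SexlinkageError("is_indel set but indel_size < 1")

    def _reorder(self, order: np.ndarray) -> None:
        self.sites = self.sites.iloc[order].reset_index(drop=True)
        for name in ("a0", "a1", "gq", "dp"):
            setattr(self, name, getattr(self, name)[order])

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def genotype_codes(self) -> np.ndarray:
        """Collapse allele pairs to {missing, hom_ref, het, hom_alt} codes."""
        gt = np.full(self.a0.shape, GT_MISSING, dtype=np.int8)
        called = (self.a0 >= 0) & (self.a1 >= 0)
        hom = called & (self.a0 == self.a1)
        gt[hom & (self.a0 == 0)] = GT_HOM_REF
        gt[hom & (self.a0 > 0)] = GT_HOM_ALT
        gt[called & (self.a0 != self.a1)] = GT_HET
        return gt

    def subset_sites(self, mask: np.ndarray) -> "VariantTable":
        idx = np.flatnonzero(mask) if mask.dtype == bool else np.asarray(mask)
        return VariantTable(
            self.sites.iloc[idx].reset_index(drop=True),
            self.a0[idx].copy(),
            self.a1[idx].copy(),
            self.gq[idx].copy(),
            self.dp[idx].copy(),
            list(self.individuals),
        )

    def column_of(self, individual_id: str) -> int:
        return self.individuals.index(individual_id)


# ---------------------------------------------------------------------------
# LG table and time tree
# ---------------------------------------------------------------------------


def read_lg_table(path) -> pd.DataFrame:
    """Read a linkage-group length table (TSV: lg_id, length_bp)."""
    lgs = pd.read_csv(path, sep="\t", dtype={"lg_id": str, "length_bp": np.int64})
    return validate_lg_table(lgs)


def validate_lg_table(lgs: pd.DataFrame) -> pd.DataFrame:
    if lgs["lg_id"].duplicated().any():
        raise SexlinkageError("duplicate lg_ids in LG table")
    if (lgs["length_bp"] <= 0).any():
        raise SexlinkageError("LG lengths must be > 0")
    return lgs.reset_index(drop=True)


@dataclass
class TimeTree:
    """A rooted time-calibrated tree with branch lengths in million years."""

    tree: dendropy.Tree
    is_ultrametric: bool = True

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def depth(self) -> float:
        return max(self._tip_depths().values())

    def _tip_depths(self) -> dict[str, float]:
        out = {}
        for leaf in self.tree.leaf_node_iter():
            out[leaf.taxon.label] = leaf.distance_from_root()
        return out

    def total_branch_length(self) -> float:
        return sum(
            e.length or 0.0 for e in self.tree.preorder_edge_iter() if e.head_node.parent_node
        )

    def pruned_to(self, labels) -> "TimeTree":
        t = self.tree.clone(depth=1)
        t.retain_taxa_with_labels(list(labels))
        return TimeTree(t, self.is_ultrametric)


def timetree_from_dendropy(tree: dendropy.Tree, rtol: float = 1e-6) -> TimeTree:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise SexlinkageError("duplicate tip labels in tree")
    for e in tree.preorder_edge_iter():
        if e.head_node.parent_node and (e.length or 0.0) < 0:
            raise SexlinkageError("negative branch length in tree")
    depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
    depth = max(depths)
    ultrametric = depth == 0 or (depth - min(depths)) <= rtol * depth
    if not ultrametric:
        warnings.warn(
            "tree is not ultrametric within tolerance; flagging", stacklevel=3
        )
    return TimeTree(tree, ultrametric)


def read_timetree(path, rtol: float = 1e-6) -> TimeTree:
    """Read a single rooted newick tree and validate ultrametricity."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:  # dendropy raises various parse errors
        raise SexlinkageError(f"cannot parse newick tree: {exc}") from exc
    return timetree_from_dendropy(tree, rtol=rtol)


def timetree_from_string(newick: str, rtol: float = 1e-6) -> TimeTree:
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick")
    except Exception as exc:
        raise SexlinkageError(f"cannot parse newick tree: {exc}") from exc
    return timetree_from_dendropy(tree, rtol=rtol)


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------


def read_genotype_vcf(path, panel: SamplePanel) -> VariantTable:
    """Read a VCF (v4.x, FORMAT GT/GQ/DP) into a :class:`VariantTable`.

    All panel individuals must be present as VCF samples; extra VCF samples
    are dropped. Multiallelic records are preserved (filtered later); missing
    calls map to missing genotypes.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_index = {s: i for i, s in enumerate(vcf.samples)}
    absent = [ind for ind in panel.individuals if ind not in sample_index]
    if absent:
        raise SexlinkageError(f"panel individuals absent from VCF: {absent}")
    cols = np.array([sample_index[ind] for ind in panel.individuals])

    rows, a0s, a1s, gqs, dps = [], [], [], [], []
    for rec_no, var in enumerate(vcf, start=1):
        try:
            alts = list(var.ALT)
            ref = var.REF
            size = max((abs(len(a) - len(ref)) for a in alts), default=0)
            is_indel = size > 0
            gts = np.array(var.genotypes, dtype=np.int16)[cols]
            a0 = gts[:, 0].astype(np.int8)
            a1 = gts[:, 1].astype(np.int8)
            gq = _format_field(var, "GQ", cols)
            dp = _format_field(var, "DP", cols)
            rows.append((var.CHROM, var.POS, ref, ",".join(alts), is_indel, size))
            a0s.append(a0)
            a1s.append(a1)
            gqs.append(gq)
            dps.append(dp)
        except SexlinkageError:
            raise
        except Exception as exc:
            raise SexlinkageError(f"malformed VCF record {rec_no}: {exc}") from exc
    sites = pd.DataFrame(
        rows, columns=["lg", "pos", "ref", "alt", "is_indel", "indel_size"]
    )
    n, m = len(sites), len(panel.individuals)
    return VariantTable(
        sites,
        np.array(a0s, dtype=np.int8).reshape(n, m),
        np.array(a1s, dtype=np.int8).reshape(n, m),
        np.array(gqs, dtype=np.int16).reshape(n, m),
        np.array(dps, dtype=np.int16).reshape(n, m),
        list(panel.individuals),
    )


def _format_field(var, key: str, cols: np.ndarray) -> np.ndarray:
    arr = var.format(key)
    if arr is None:
        return np.zeros(len(cols), dtype=np.int16)
    arr = np.asarray(arr).reshape(-1)[cols]
    arr = np.where(np.isfinite(arr.astype(float)), arr, -1)
    return arr.astype(np.int16)


def write_vcf(vt: VariantTable, path) -> None:
    """Write a VariantTable as uncompressed VCF v4.2 (GT:GQ:DP)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for lg in dict.fromkeys(vt.sites["lg"]):
            fh.write(f"##contig=<ID={lg}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(vt.individuals)
            + "\n"
        )
        for i in range(vt.n_sites):
            row = vt.sites.iloc[i]
            calls = []
            for j in range(len(vt.individuals)):
                x, y = vt.a0[i, j], vt.a1[i, j]
                gt = "./." if x < 0 or y < 0 else f"{x}/{y}"
                calls.append(f"{gt}:{vt.gq[i, j]}:{vt.dp[i, j]}")
            fh.write(
                f"{row['lg']}\t{row['pos']}\t.\t{row['ref']}\t{row['alt']}\t.\t.\t.\t"
                "GT:GQ:DP\t" + "\t".join(calls) + "\n"
            )


# ---------------------------------------------------------------------------
# bespoke variant-level filters
# ---------------------------------------------------------------------------


def indel_mask_width(size: int) -> int:
    for max_size, width in INDEL_MASK_WIDTHS:
        if size <= max_size:
            return width
    return INDEL_MASK_WIDTH_LARGE


def mask_around_indels(vt: VariantTable) -> VariantTable:
    """Remove SNPs near indels and the indel records themselves.

    The mask half-width w depends on indel size (1 bp -> 2, 2-3 bp -> 3,
    4-5 bp -> 5, >5 bp -> 10); the masked interval is [pos-w, pos+span+w]
    where span is the indel's reference span. Idempotent.
    """
    sites = vt.sites
    is_indel = sites["is_indel"].to_numpy(dtype=bool)
    if not is_indel.any():
        return vt.subset_sites(~is_indel)
    keep = ~is_indel
    for lg, grp in sites.groupby("lg", sort=False):
        g_indel = grp["is_indel"].to_numpy(dtype=bool)
        if not g_indel.any():
            continue
        ipos = grp.loc[g_indel, "pos"].to_numpy()
        isize = grp.loc[g_indel, "indel_size"].to_numpy()
        ispan = grp.loc[g_indel, "ref"].str.len().to_numpy()
        widths = np.array([indel_mask_width(s) for s in isize])
        lo = ipos - widths
        hi = ipos + ispan + widths
        # merge intervals, then interval-stab each SNP position
        order = np.argsort(lo)
        lo, hi = lo[order], hi[order]
        merged_lo, merged_hi = [lo[0]], [hi[0]]
        for a, b in zip(lo[1:], hi[1:]):
            if a <= merged_hi[-1]:
                merged_hi[-1] = max(merged_hi[-1], b)
            else:
                merged_lo.append(a)
                merged_hi.append(b)
        merged_lo = np.array(merged_lo)
        merged_hi = np.array(merged_hi)
        snp_rows = grp.index[~g_indel]
        snp_pos = grp.loc[snp_rows, "pos"].to_numpy()
        k = np.searchsorted(merged_lo, snp_pos, side="right") - 1
        inside = (k >= 0) & (snp_pos <= merged_hi[np.clip(k, 0, None)])
        keep[snp_rows[inside]] = False
    return vt.subset_sites(keep.to_numpy() if hasattr(keep, "to_numpy") else keep)


def apply_genotype_filters(
    vt: VariantTable,
    min_gq: int = 20,
    min_dp: int = 4,
    max_missing_frac: float = 0.5,
) -> VariantTable:
    """Genotype-level masking and site retention.

    Masks genotypes with GQ < min_gq or DP < min_dp, removes sites with more
    than ``max_missing_frac`` missing calls, keeps only biallelic sites,
    removes monomorphic sites (all retained calls homozygous reference), and
    at sites where no retained individual carries the reference allele makes
    the first alternative the reference, recoding genotypes.
    """
    a0 = vt.a0.copy()
    a1 = vt.a1.copy()
    low = (vt.gq < min_gq) | (vt.dp < min_dp)
    a0[low] = GT_MISSING
    a1[low] = GT_MISSING

    n_ind = len(vt.individuals)
    missing = (a0 < 0) | (a1 < 0)
    a0[missing] = GT_MISSING
    a1[missing] = GT_MISSING
    miss_frac = missing.sum(axis=1) / n_ind
    n_alt = vt.sites["alt"].str.count(",").to_numpy() + 1
    has_call = ~missing
    carries_ref = ((a0 == 0) & has_call) | ((a1 == 0) & has_call)
    carries_nonref = ((a0 > 0) & has_call) | ((a1 > 0) & has_call)
    monomorphic = ~carries_nonref.any(axis=1)  # all retained calls hom_ref (or none)

    keep = (miss_frac <= max_missing_frac) & (n_alt <= 1) & ~monomorphic
    out = VariantTable(
        vt.sites.loc[keep].reset_index(drop=True),
        a0[keep],
        a1[keep],
        vt.gq[keep].copy(),
        vt.dp[keep].copy(),
        list(vt.individuals),
    )
    # reference flip: no retained individual carries the reference allele
    flip = ~(((out.a0 == 0) | (out.a1 == 0)) & (out.a0 >= 0)).any(axis=1)
    if flip.any():
        rows = np.flatnonzero(flip)
        for name in ("a0", "a1"):
            arr = getattr(out, name)
            sub = arr[rows]
            sub[sub > 0] -= 1
            arr[rows] = sub
        ref = out.sites["ref"].to_numpy().copy()
        alt = out.sites["alt"].to_numpy().copy()
        for i in rows:
            alts = alt[i].split(",")
            new_ref = alts[0]
            alt[i] = ",".join([ref[i]] + alts[1:]) if len(alts) > 1 else ref[i]
            ref[i] = new_ref
        out.sites["ref"] = ref
        out.sites["alt"] = alt
    return out


# ---------------------------------------------------------------------------
# compact variant store (versioned TSV dump)
# ---------------------------------------------------------------------------

STORE_VERSION = 1


def write_variant_store(vt: VariantTable, path) -> None:
    """Write a VariantTable as a compact, versioned TSV store."""
    with open(path, "w") as fh:
        fh.write(f"#sexlinkage-store\tv{STORE_VERSION}\n")
        fh.write("#individuals\t" + "\t".join(vt.individuals) + "\n")
        header = ["lg", "pos", "ref", "alt", "is_indel", "indel_size"] + [
            f"{ind}:{f}" for ind in vt.individuals for f in ("gt", "gq", "dp")
        ]
        fh.write("\t".join(header) + "\n")
        for i in range(vt.n_sites):
            row = vt.sites.iloc[i]
            fields = [
                str(row["lg"]),
                str(row["pos"]),
                row["ref"],
                row["alt"],
                "1" if row["is_indel"] else "0",
                str(row["indel_size"]),
            ]
            for j in range(len(vt.individuals)):
                x, y = vt.a0[i, j], vt.a1[i, j]
                gt = "." if x < 0 else f"{x}/{y}"
                fields += [gt, str(vt.gq[i, j]), str(vt.dp[i, j])]
            fh.write("\t".join(fields) + "\n")


def read_variant_store(path) -> VariantTable:
    with open(path) as fh:
        magic = fh.readline().rstrip("\n").split("\t")
        if magic[0] != "#sexlinkage-store":
            raise SexlinkageError("not a sexlinkage variant store")
        individuals = fh.readline().rstrip("\n").split("\t")[1:]
        df = pd.read_csv(fh, sep="\t")
    n, m = len(df), len(individuals)
    a0 = np.full((n, m), GT_MISSING, dtype=np.int8)
    a1 = np.full((n, m), GT_MISSING, dtype=np.int8)
    gq = np.zeros((n, m), dtype=np.int16)
    dp = np.zeros((n, m), dtype=np.int16)
    for j, ind in enumerate(individuals):
        gts = df[f"{ind}:gt"].astype(str)
        called = gts != "."
        pairs = gts[called].str.split("/", expand=True).astype(np.int8)
        a0[called.to_numpy(), j] = pairs[0].to_numpy()
        a1[called.to_numpy(), j] = pairs[1].to_numpy()
        gq[:, j] = df[f"{ind}:gq"].to_numpy()
        dp[:, j] = df[f"{ind}:dp"].to_numpy()
    sites = df[["lg", "pos", "ref", "alt", "is_indel", "indel_size"]].copy()
    sites["is_indel"] = sites["is_indel"].astype(bool)
    return VariantTable(sites, a0, a1, gq, dp, individuals)
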