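"""Synthetic cohorts with planted sex-chromosome truth.

Generators for (i) whole-genome genotype cohorts — one male and one female
genome per species grouped into tribes — with a planted sex-linked region of
configurable size, differentiation and heterogamety; (ii) replicate
transcriptome allele-count tables with sex-exclusive expressed SNPs in the
planted region; (iii) continuous-time Markov trait histories along a time
tree, for ground-truthing ancestral-state reconstruction. All generators are
deterministic under a fixed seed and return the planted truth alongside the
data.

Background genotypes are i.i.d. across individuals (no population structure,
no linkage disequilibrium): an individual is heterozygous with probability
``background_het`` and otherwise homozygous for the reference (share 0.8 of
the homozygotes) or the alternative allele.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .io_prep import SamplePanel, SexlinkageError, TimeTree, VariantTable
from .phylo_turnover import CharacterHistory, IndexedTree

#: share of homozygous background genotypes that are homozygous reference
HOM_REF_SHARE = 0.8


@dataclass
class SpeciesTruth:
    sex_lg: str | None = None
    system: str = "none"  # "XY", "ZW" or "none"
    region: tuple | None = None  # (start, end), 1-based inclusive
    differentiation: float = 1.0  # fraction of region sites that are sex-specific

    def __post_init__(self):
        if not 0.0 <= self.differentiation <= 1.0:
            raise SexlinkageError("differentiation must be in [0, 1]")
        if self.system not in ("XY", "ZW", "none"):
            raise SexlinkageError(f"invalid system {self.system!r}")


@dataclass
class SimTruth:
    """Planted ground truth for a simulated cohort."""

    species: dict = field(default_factory=dict)  # species_id -> SpeciesTruth
    seed: int = 0

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "species": {k: asdict(v) for k, v in self.species.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            species={
                k: SpeciesTruth(
                    v["sex_lg"], v["system"],
                    tuple(v["region"]) if v["region"] else None,
                    v["differentiation"],
                )
                for k, v in payload["species"].items()
            },
            seed=payload["seed"],
        )


def expected_background_class_fraction(background_het: float) -> float:
    """Closed-form P(male het) * P(female hom) for one background site."""
    h = background_het
    return h * (1.0 - h)


def simulate_wgs_cohort(
    panel: SamplePanel,
    lgs: pd.DataFrame,
    truth: SimTruth,
    n_sites_per_lg: int = 1000,
    background_het: float = 0.2,
    missing_frac: float = 0.0,
    seed: int = 0,
) -> tuple[VariantTable, SimTruth]:
    """Simulate a genotype cohort with planted sex-linked regions.

    Sites are uniform on each LG. Outside planted regions genotypes are drawn
    independently per individual; inside a planted XY region a fraction
    ``differentiation`` of sites is fully sex-specific for that species
    (males heterozygous, females homozygous reference; ZW mirrored).
    """
    rng = np.random.default_rng(seed)
    lg_len = dict(zip(lgs["lg_id"], lgs["length_bp"]))
    for sp, st in truth.species.items():
        if st.system == "none":
            continue
        if st.sex_lg not in lg_len:
            raise SexlinkageError(f"{sp}: planted LG {st.sex_lg!r} not in LG table")
        start, end = st.region
        if start < 1 or end > lg_len[st.sex_lg]:
            raise SexlinkageError(f"{sp}: region {st.region} outside LG")
        rows = panel.table[panel.table["species_id"] == sp]
        if not {"male", "female"} <= set(rows["sex"]):
            raise SexlinkageError(f"{sp}: planted species needs a male and a female")

    individuals = panel.individuals
    sex = np.array([panel.sex_of(i) for i in individuals])
    sp_of = np.array([panel.table.iloc[j]["species_id"] for j in range(len(individuals))])
    n_ind = len(individuals)

    frames, a0s, a1s = [], [], []
    for lg, length in lg_len.items():
        n = min(n_sites_per_lg, length)
        pos = np.sort(rng.choice(np.int64(length), size=n, replace=False) + 1)
        # background genotypes
        u = rng.random((n, n_ind))
        h = background_het
        a0 = np.zeros((n, n_ind), dtype=np.int8)
        a1 = np.zeros((n, n_ind), dtype=np.int8)
        het = u < h
        hom_alt = u >= h + (1 - h) * HOM_REF_SHARE
        a1[het] = 1
        a0[hom_alt] = 1
        a1[hom_alt] = 1
        # plant sex-specific sites
        for sp, st in truth.species.items():
            if st.system == "none" or st.sex_lg != lg:
                continue
            start, end = st.region
            region_idx = np.flatnonzero((pos >= start) & (pos <= end))
            n_spec = int(round(st.differentiation * region_idx.size))
            if n_spec == 0:
                continue
            planted = rng.choice(region_idx, size=n_spec, replace=False)
            het_sex = "male" if st.system == "XY" else "female"
            cols_het = np.flatnonzero((sp_of == sp) & (sex == het_sex))
            cols_hom = np.flatnonzero((sp_of == sp) & (sex != het_sex))
            for c in cols_het:
                a0[planted, c] = 0
                a1[planted, c] = 1
            for c in cols_hom:
                a0[planted, c] = 0
                a1[planted, c] = 0
        frames.append(
            pd.DataFrame(
                {
                    "lg": lg,
                    "pos": pos,
                    "ref": "A",
                    "alt": "G",
                    "is_indel": False,
                    "indel_size": 0,
                }
            )
        )
        a0s.append(a0)
        a1s.append(a1)
    sites = pd.concat(frames, ignore_index=True)
    a0 = np.vstack(a0s)
    a1 = np.vstack(a1s)
    if missing_frac > 0:
        miss = rng.random(a0.shape) < missing_frac
        a0[miss] = -1
        a1[miss] = -1
    gq = np.full(a0.shape, 99, dtype=np.int16)
    dp = np.full(a0.shape, 20, dtype=np.int16)
    return VariantTable(sites, a0, a1, gq, dp, list(individuals)), truth


def simulate_rna_counts(
    truth: SimTruth,
    species_id: str,
    lgs: pd.DataFrame,
    n_males: int = 3,
    n_females: int = 3,
    n_snps: int = 2000,
    depth_mean: float = 10.0,
    sex_snp_frac: float = 0.1,
    biased_frac: float = 0.05,
    n_region_genes: int = 20,
    gene_span_bp: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a replicate transcriptome allele-count table for one species.

    Background SNPs (uniform over the genome) have sex-balanced Poisson
    counts for both alleles; a fraction ``biased_frac`` of them is
    sex-*biased* (unequal allele proportions between the sexes, as produced
    by allele-specific expression differences) without being sex-exclusive,
    so the genome-wide landscape of test-passing windows is realistic. For a
    species with a planted system, a fraction ``sex_snp_frac *
    differentiation`` of SNPs is sex-exclusive and clustered into
    ``n_region_genes`` gene-sized blocks inside the planted region
    (transcriptome SNPs concentrate in expressed genes): the homogametic sex
    has zero variant-allele counts and the heterogametic replicates draw
    Poisson(depth_mean) with at least two nonzero enforced.
    """
    if depth_mean <= 0:
        raise SexlinkageError("depth_mean must be > 0")
    rng = np.random.default_rng(seed)
    st = truth.species.get(species_id, SpeciesTruth())
    reps = [f"m{i+1}" for i in range(n_males)] + [f"f{i+1}" for i in range(n_females)]
    cols = {"lg": [], "pos": []}
    for r in reps:
        cols[f"{r}_ref"] = []
        cols[f"{r}_alt"] = []
    if n_snps == 0:
        return pd.DataFrame(cols)

    n_planted = 0
    if st.system != "none":
        n_planted = int(round(sex_snp_frac * st.differentiation * n_snps))
    n_bg = n_snps - n_planted

    lengths = lgs["length_bp"].to_numpy(dtype=float)
    lg_ids = lgs["lg_id"].tolist()
    lg_choice = rng.choice(len(lg_ids), size=n_bg, p=lengths / lengths.sum())
    bg_pos = (rng.random(n_bg) * lengths[lg_choice]).astype(np.int64) + 1

    lg_col = [lg_ids[i] for i in lg_choice]
    pos_col = list(bg_pos)
    counts = {f"{r}_{al}": [] for r in reps for al in ("ref", "alt")}
    half = depth_mean / 2.0
    biased = rng.random(n_bg) < biased_frac
    for r in reps:
        ref = rng.poisson(half, n_bg).astype(np.int64)
        alt = rng.poisson(half, n_bg).astype(np.int64)
        # sex-biased (not exclusive) allele use: males favor alt, females ref
        hi = rng.poisson(depth_mean * 0.8, n_bg)
        lo = rng.poisson(depth_mean * 0.2, n_bg)
        if r.startswith("m"):
            alt[biased] = hi[biased]
            ref[biased] = lo[biased]
        else:
            alt[biased] = lo[biased]
            ref[biased] = hi[biased]
        counts[f"{r}_ref"] = list(ref)
        counts[f"{r}_alt"] = list(alt)

    if n_planted:
        start, end = st.region
        gene_starts = rng.integers(start, max(end - gene_span_bp, start) + 1,
                                   size=n_region_genes)
        gene_of = rng.integers(0, n_region_genes, size=n_planted)
        ppos = gene_starts[gene_of] + rng.integers(0, gene_span_bp, size=n_planted)
        ppos = np.minimum(ppos, end)
        lg_col += [st.sex_lg] * n_planted
        pos_col += list(ppos)
        het_reps = reps[:n_males] if st.system == "XY" else reps[n_males:]
        hom_reps = reps[n_males:] if st.system == "XY" else reps[:n_males]
        het_alt = rng.poisson(depth_mean, (n_planted, len(het_reps)))
        # enforce the detectability floor: >= 2 heterogametic replicates expressed
        for i in range(n_planted):
            nz = np.flatnonzero(het_alt[i])
            if nz.size < 2:
                fix = rng.choice(len(het_reps), size=2, replace=False)
                het_alt[i, fix] = np.maximum(het_alt[i, fix], 1)
        for j, r in enumerate(het_reps):
            counts[f"{r}_alt"] += list(het_alt[:, j])
            counts[f"{r}_ref"] += list(rng.poisson(half, n_planted))
        for r in hom_reps:
            counts[f"{r}_alt"] += [0] * n_planted
            counts[f"{r}_ref"] += list(rng.poisson(depth_mean, n_planted))

    out = pd.DataFrame({"lg": lg_col, "pos": pos_col, **counts})
    return out.sort_values(["lg", "pos"]).reset_index(drop=True)


def simulate_trait_history(
    tree: TimeTree,
    states: list[str],
    q_matrix: np.ndarray,
    root_state: str,
    seed: int = 0,
) -> tuple[dict, CharacterHistory]:
    """Simulate a continuous-time Markov trait history along a time tree.

    Returns tip state assignments (label -> state name) and the full planted
    history (every change with branch and time).
    """
    q = np.asarray(q_matrix, dtype=float)
    k = len(states)
    if q.shape != (k, k):
        raise SexlinkageError("q_matrix shape must match state list")
    if not np.allclose(q.sum(axis=1), 0, atol=1e-9):
        raise SexlinkageError("q_matrix rows must sum to 0")
    off = q[~np.eye(k, dtype=bool)]
    if (off < 0).any():
        raise SexlinkageError("off-diagonal rates must be >= 0")
    if root_state not in states:
        raise SexlinkageError(f"root_state {root_state!r} not in states")
    rng = np.random.default_rng(seed)
    it = IndexedTree.build(tree)
    node_state = np.zeros(it.n_nodes, dtype=int)
    node_state[0] = states.index(root_state)
    events: list[tuple[int, float, int, int]] = []
    for i in range(1, it.n_nodes):
        s = node_state[it.parent[i]]
        t = 0.0
        blen = it.blen[i]
        start = it.depth[it.parent[i]]
        while True:
            rate = -q[s, s]
            if rate <= 0:
                break
            t += rng.exponential(1.0 / rate)
            if t >= blen:
                break
            w = np.clip(q[s, :], 0, None)
            w[s] = 0.0
            s_new = int(rng.choice(k, p=w / w.sum()))
            events.append((i, start + t, s, s_new))
            s = s_new
        node_state[i] = s
    tips = {lab: states[node_state[nid]] for lab, nid in it.tip_ids.items()}
    return tips, CharacterHistory(node_state, events)


# ---------------------------------------------------------------------------
# convenience cohort builders
# ---------------------------------------------------------------------------


def default_panel(
    n_species: int = 10,
    tribe_id: str = "TribeA",
    prefix: str = "sp",
) -> SamplePanel:
    """One male + one female genome per species, a single tribe."""
    rows = []
    for i in range(1, n_species + 1):
        sp = f"{prefix}{i:02d}"
        rows.append((f"{sp}_m", sp, tribe_id, "male"))
        rows.append((f"{sp}_f", sp, tribe_id, "female"))
    return SamplePanel(
        pd.DataFrame(rows, columns=["individual_id", "species_id", "tribe_id", "sex"])
    )


def default_lg_table(n_lgs: int = 5, length_bp: int = 500_000) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lg_id": [f"LG{i:02d}" for i in range(1, n_lgs + 1)],
            "length_bp": [length_bp] * n_lgs,
        }
    )


def write_counts_tsv(act: pd.DataFrame, path) -> None:
    act.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
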