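"""Tribe-wise per-SNP sex association and genotype-cluster resolution (A1).

A Cochran-Armitage trend test of genotype dosage against sex replaces the
mixed-model association of a full GWAS (the synthetic cohorts carry no
population structure; the decisive step is the downstream clustering).
Selected SNPs — the top-k most associated (broad signals) or all SNPs above a
-log10(p) cutoff (narrow peaks) — are clustered over all individuals with the
same Gower/DIANA engine as the WGS scan, and a species is called XY (ZW
mirrored) when its male is heterozygous-enriched at the selected SNPs and its
individuals separate by sex at the 2-cluster cut.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import diana_two_clusters, gower_matrix, splits_by_sex
from .call_integration import SpeciesCall
from .io_prep import (
    GT_HET,
    GT_HOM_ALT,
    GT_HOM_REF,
    GT_MISSING,
    MALE,
    SamplePanel,
    SexlinkageError,
    VariantTable,
)

#: fraction of selected SNPs at which the heterogametic-sex individual must
#: be heterozygous (other sex homozygous) to call the system for a species
HET_ENRICHMENT_MIN = 0.8


def snp_sex_association(vt: VariantTable, panel: SamplePanel) -> pd.DataFrame:
    """Per-SNP Cochran-Armitage trend test of genotype dosage vs sex.

    Returns a frame with lg, pos, p_value and neglog10p; monomorphic sites
    get p = 1. Requires at least two individuals of each sex.
    """
    sexes = np.array([panel.sex_of(ind) for ind in vt.individuals])
    y = (sexes == MALE).astype(float)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise SexlinkageError("need at least 2 males and 2 females")
    gt = vt.genotype_codes().astype(float)
    gt[gt == GT_MISSING] = np.nan
    p = np.ones(vt.n_sites)
    for i in range(vt.n_sites):
        g = gt[i]
        ok = ~np.isnan(g)
        gi, yi = g[ok], y[ok]
        n = len(gi)
        if n < 4 or gi.std() == 0 or yi.std() == 0:
            continue
        r = np.corrcoef(gi, yi)[0, 1]
        stat = n * r * r  # trend score statistic, chi^2 with 1 df
        p[i] = float(stats.chi2.sf(stat, df=1))
    out = vt.sites[["lg", "pos"]].copy()
    out["p_value"] = np.clip(p, np.nextafter(0, 1), 1.0)
    out["neglog10p"] = -np.log10(out["p_value"])
    out["row"] = np.arange(vt.n_sites)
    return out


def cluster_top_genotypes(
    ar: pd.DataFrame,
    vt: VariantTable,
    panel: SamplePanel,
    mode: str = "top_k",
    k: int = 100,
    logp_min: float = 3.0,
    het_enrichment_min: float = HET_ENRICHMENT_MIN,
    min_lg_share: float = 0.25,
) -> list[SpeciesCall]:
    """Resolve species and heterogamety from genotypes at associated SNPs."""
    if len(ar) == 0:
        raise SexlinkageError("empty association result")
    if mode == "top_k":
        if k > len(ar):
            warnings.warn(f"only {len(ar)} SNPs available; using all", stacklevel=2)
            k = len(ar)
        sel = ar.nsmallest(k, "p_value")
    elif mode == "threshold":
        sel = ar[ar["neglog10p"] > logp_min]
    else:
        raise SexlinkageError(f"unknown selection mode {mode!r}")
    if len(sel) == 0:
        return []
    # focus on the associated region(s): keep the LG(s) where the selected
    # SNPs concentrate, so genotype inspection is not diluted by scattered
    # false positives (multi-LG signals from fusions are retained)
    shares = sel["lg"].value_counts(normalize=True)
    focus_lgs = list(shares[shares >= min_lg_share].index)
    if focus_lgs:
        sel = sel[sel["lg"].isin(focus_lgs)]
    rows = sel["row"].to_numpy()
    gt = vt.genotype_codes()[rows]
    labels = diana_two_clusters(gower_matrix(gt))
    sexes = [panel.sex_of(ind) for ind in vt.individuals]
    sp_of_ind = {r["individual_id"]: r["species_id"] for _, r in panel.table.iterrows()}
    calls = []
    for sp in panel.species:
        pair = panel.pair_for(sp)
        if pair is None:
            continue
        male, female = pair
        gm = gt[:, vt.column_of(male)]
        gf = gt[:, vt.column_of(female)]
        both = (gm != GT_MISSING) & (gf != GT_MISSING)
        if both.sum() == 0:
            continue
        hom = (GT_HOM_REF, GT_HOM_ALT)
        xy_frac = ((gm == GT_HET) & np.isin(gf, hom) & both).sum() / both.sum()
        zw_frac = ((gf == GT_HET) & np.isin(gm, hom) & both).sum() / both.sum()
        system = None
        if xy_frac > het_enrichment_min and xy_frac >= zw_frac:
            system = "XY"
        elif zw_frac > het_enrichment_min:
            system = "ZW"
        if system is None:
            continue
        idx = [j for j, ind in enumerate(vt.individuals) if sp_of_ind.get(ind) == sp]
        if not splits_by_sex(labels, sexes, idx):
            continue
        lgs_hit = sorted(set(sel["lg"]))
        calls.append(SpeciesCall(sp, frozenset(lgs_hit), system, frozenset({"A1"})))
    return calls


def scan_assoc_tribe(
    vt: VariantTable,
    panel: SamplePanel,
    mode: str = "top_k",
    k: int = 100,
    logp_min: float = 3.0,
) -> tuple[list[SpeciesCall], pd.DataFrame]:
    """Association scan for one tribe: test every SNP, then cluster the hits."""
    ar = snp_sex_association(vt, panel)
    calls = cluster_top_genotypes(ar, vt, panel, mode=mode, k=k, logp_min=logp_min)
    return calls, ar
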