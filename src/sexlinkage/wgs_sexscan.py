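"""Tribe-wise scan for an accumulation of sex-specific SNPs (WGS route, A2).

Each variant site is classified per species from the designated male/female
genome pair: "XY" when the male is heterozygous and the female homozygous,
"ZW" mirrored, "nosex" when neither individual is heterozygous while the
other is homozygous (equal genotypes, or the two opposite-homozygote case),
and "noinfo" when either call is missing. Class counts are accumulated in
10-kb windows sliding by 2 kb, compared with genome-wide expectations by a
2x3 exact (Freeman-Halton) or Pearson chi-squared test, and screened against
tribe-wise permutation thresholds on the species-normalized XY-ZW difference
plus a fixed -log10(p) > 20 retention cutoff. Outlier windows are merged into
regions and attributed to species by Gower/DIANA clustering of individual
genotypes, with calls requiring at least two species of the tribe to share
the signature.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .cluster import diana_two_clusters, gower_matrix, splits_by_sex
from .call_integration import SpeciesCall
from .io_prep import (
    GT_HET,
    GT_HOM_ALT,
    GT_HOM_REF,
    GT_MISSING,
    SamplePanel,
    SexlinkageError,
    UNPLACED_LG,
    VariantTable,
)

WINDOW_BP = 10_000
STEP_BP = 2_000

# site class codes
NOSEX, NOINFO, CXY, CZW = 0, 1, 2, 3
CLASS_NAMES = {NOSEX: "nosex", NOINFO: "noinfo", CXY: "XY", CZW: "ZW"}

#: retention cutoff on -log10(p) for outlier windows
NEGLOG10P_RETAIN = 20.0

#: total table count above which the exact test falls back to chi-squared
FISHER_MAX_TOTAL = 10_000

#: regions excluded from sex-chromosome calls: a protocadherin tandem array
#: on LG02 that attracts cross-mapping, and all of LG03 (poor assembly,
#: repeat-rich, excess missing data); plus the unplaced-scaffold pseudo-LG
DEFAULT_MASKS = (
    ("LG02", 21_360_000, 21_930_000),
    ("LG03", 1, None),
    (UNPLACED_LG, 1, None),
)


@dataclass
class SiteClassTable:
    """Per species x site sex-linkage classification."""

    sites: pd.DataFrame  # columns lg, pos, row (row index into source table)
    species: list
    classes: np.ndarray  # (n_sites, n_species) int8 codes

    def class_counts(self) -> pd.DataFrame:
        out = {}
        for code, name in CLASS_NAMES.items():
            out[name] = (self.classes == code).sum(axis=0)
        return pd.DataFrame(out, index=self.species)


def classify_sites(vt: VariantTable, panel: SamplePanel) -> SiteClassTable:
    """Classify every site per species from its male/female genome pair."""
    gt = vt.genotype_codes()
    species = []
    cols = []
    for sp in panel.species:
        pair = panel.pair_for(sp)
        if pair is None:
            warnings.warn(f"species {sp} lacks a male/female pair; skipped", stacklevel=2)
            continue
        male, female = pair
        species.append(sp)
        cols.append((vt.column_of(male), vt.column_of(female)))
    n_sites = vt.n_sites
    classes = np.full((n_sites, len(species)), NOSEX, dtype=np.int8)
    for j, (cm, cf) in enumerate(cols):
        gm, gf = gt[:, cm], gt[:, cf]
        missing = (gm == GT_MISSING) | (gf == GT_MISSING)
        male_het = (gm == GT_HET) & ((gf == GT_HOM_REF) | (gf == GT_HOM_ALT))
        female_het = (gf == GT_HET) & ((gm == GT_HOM_REF) | (gm == GT_HOM_ALT))
        col = np.full(n_sites, NOSEX, dtype=np.int8)
        col[male_het] = CXY
        col[female_het] = CZW
        col[missing] = NOINFO
        classes[:, j] = col
    sites = vt.sites[["lg", "pos"]].copy()
    sites["row"] = np.arange(n_sites)
    return SiteClassTable(sites, species, classes)


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------


def _window_counts(
    sct: SiteClassTable, lgs: pd.DataFrame, window: int, step: int
) -> pd.DataFrame:
    """Sliding-window class sums over all species-sites.

    The window grid starts at position 1 on each LG; only windows containing
    at least one site are emitted (a trailing partial window is therefore
    kept exactly when it has a site).
    """
    frames = []
    lg_len = dict(zip(lgs["lg_id"], lgs["length_bp"]))
    n_per_win = max(window // step, 1)
    per_site = {
        code: (sct.classes == code).sum(axis=1) for code in (CXY, CZW, NOSEX, NOINFO)
    }
    for lg, grp in sct.sites.groupby("lg", sort=False):
        length = lg_len.get(lg, int(grp["pos"].max()))
        n_bins = max(math.ceil(length / step), 1)
        pos = grp["pos"].to_numpy()
        bins = np.minimum((pos - 1) // step, n_bins - 1)
        rows = grp.index.to_numpy()
        binned = {}
        for code, counts in per_site.items():
            acc = np.zeros(n_bins)
            np.add.at(acc, bins, counts[rows])
            binned[code] = acc
        n_windows = n_bins  # window i covers bins i..i+n_per_win-1
        kern = np.ones(n_per_win)
        win = {
            code: np.convolve(acc, kern)[n_per_win - 1 : n_per_win - 1 + n_windows]
            for code, acc in binned.items()
        }
        starts = 1 + step * np.arange(n_windows)
        ends = np.minimum(starts + window - 1, length)
        df = pd.DataFrame(
            {
                "lg": lg,
                "start": starts,
                "end": ends,
                "obs_xy": win[CXY],
                "obs_zw": win[CZW],
                "obs_nosex": win[NOSEX],
                "obs_noinfo": win[NOINFO],
            }
        )
        df = df[(df[["obs_xy", "obs_zw", "obs_nosex", "obs_noinfo"]].sum(axis=1)) > 0]
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=["lg", "start", "end", "obs_xy", "obs_zw", "obs_nosex", "obs_noinfo"]
        )
    return pd.concat(frames, ignore_index=True)


def window_stats(
    sct: SiteClassTable,
    lgs: pd.DataFrame,
    window: int = WINDOW_BP,
    step: int = STEP_BP,
) -> pd.DataFrame:
    """Observed and expected class counts per sliding window.

    Expected counts are the genome-wide mean class fractions (mean over
    windows of per-window fractions among called sites) multiplied by the
    number of called sites in the window; the XY-ZW difference is normalized
    by the number of species in the tribe.
    """
    if len(sct.sites) == 0:
        raise SexlinkageError("empty site class table")
    wst = _window_counts(sct, lgs, window, step)
    wst["n_called"] = wst[["obs_xy", "obs_zw", "obs_nosex"]].sum(axis=1)
    called = wst["n_called"] > 0
    fracs = {}
    for cls in ("xy", "zw", "nosex"):
        with np.errstate(invalid="ignore"):
            per_win = wst.loc[called, f"obs_{cls}"] / wst.loc[called, "n_called"]
        fracs[cls] = float(per_win.mean()) if called.any() else 0.0
        wst[f"exp_{cls}"] = fracs[cls] * wst["n_called"]
    n_species = max(len(sct.species), 1)
    wst["xy_zw_diff"] = wst["obs_xy"] - wst["obs_zw"]
    wst["xy_zw_diff_norm"] = wst["xy_zw_diff"] / n_species
    wst.attrs["class_fractions"] = fracs
    wst.attrs["n_species"] = n_species
    return wst


# ---------------------------------------------------------------------------
# window tests
# ---------------------------------------------------------------------------


@lru_cache(maxsize=200_000)
def _fisher_2x3_cached(row1: tuple, row2: tuple) -> float:
    return _fisher_2x3(np.array([row1, row2], dtype=np.int64))


def _fisher_2x3(table: np.ndarray) -> float:
    """Freeman-Halton exact test for a 2x3 table, by enumeration.

    Sums the probabilities of all tables with the observed margins whose
    conditional probability does not exceed the observed table's.
    """
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = int(table.sum())
    if n == 0:
        return 1.0
    log_const = gammaln(r + 1).sum() + gammaln(c + 1).sum() - gammaln(n + 1)

    def logp(a, b):
        cells = np.array(
            [a, b, r[0] - a - b, c[0] - a, c[1] - b, r[1] - c[0] - c[1] + a + b]
        )
        return log_const - gammaln(cells + 1).sum()

    lp_obs = logp(table[0, 0], table[0, 1])
    total = 0.0
    a_lo = max(0, r[0] - c[1] - c[2])
    a_hi = min(r[0], c[0])
    for a in range(a_lo, a_hi + 1):
        b_lo = max(0, r[0] - a - c[2])
        b_hi = min(r[0] - a, c[1])
        if b_hi < b_lo:
            continue
        b = np.arange(b_lo, b_hi + 1)
        cells = np.stack(
            [
                np.full_like(b, a),
                b,
                r[0] - a - b,
                np.full_like(b, c[0] - a),
                c[1] - b,
                r[1] - c[0] - c[1] + a + b,
            ]
        )
        lps = log_const - gammaln(cells + 1).sum(axis=0)
        total += float(np.exp(lps[lps <= lp_obs + 1e-9]).sum())
    return min(total, 1.0)


def window_test_p(obs: np.ndarray, exp: np.ndarray, method: str = "fisher") -> float:
    """P value for one window's observed vs (rounded) expected class counts."""
    exp_r = np.round(exp).astype(np.int64)
    obs = np.asarray(obs, dtype=np.int64)
    table = np.array([obs, exp_r])
    total = int(table.sum())
    if total == 0 or exp_r.sum() == 0:
        return 1.0
    if method == "fisher" and total > FISHER_MAX_TOTAL:
        warnings.warn(
            "table too large for exact test; falling back to chi-squared",
            stacklevel=2,
        )
        method = "chi2"
    if method == "fisher":
        return _fisher_2x3_cached(tuple(table[0]), tuple(table[1]))
    if method == "chi2":
        keep = table.sum(axis=0) > 0
        t = table[:, keep]
        if t.shape[1] < 2 or (t.sum(axis=1) == 0).any():
            return 1.0
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.chi2_contingency(t, correction=False)
        return float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
    raise SexlinkageError(f"unknown test method {method!r}")


def test_windows(wst: pd.DataFrame, method: str = "fisher") -> pd.DataFrame:
    """Designate windows XY/ZW/ambiguous/nosex and attach p-values.

    A window is XY when observed XY exceeds its expectation while observed ZW
    falls below its own (ZW mirrored); both above is ambiguous, both at or
    below is nosex; ambiguous and nosex windows are not tested further.
    """
    wst = wst.copy()
    obs_xy, obs_zw = wst["obs_xy"].to_numpy(), wst["obs_zw"].to_numpy()
    exp_xy, exp_zw = wst["exp_xy"].to_numpy(), wst["exp_zw"].to_numpy()
    desig = np.full(len(wst), "nosex", dtype=object)
    desig[(obs_xy > exp_xy) & (obs_zw < exp_zw)] = "XY"
    desig[(obs_zw > exp_zw) & (obs_xy < exp_xy)] = "ZW"
    desig[(obs_xy > exp_xy) & (obs_zw > exp_zw)] = "ambiguous"
    wst["designation"] = desig
    p = np.full(len(wst), np.nan)
    sexed = np.flatnonzero((desig == "XY") | (desig == "ZW"))
    if method == "chi2":
        p[sexed] = _chi2_pvalues_vectorized(wst.iloc[sexed])
    else:
        for i in sexed:
            obs = np.array(
                [wst["obs_xy"].iat[i], wst["obs_zw"].iat[i], wst["obs_nosex"].iat[i]]
            )
            exp = np.array(
                [wst["exp_xy"].iat[i], wst["exp_zw"].iat[i], wst["exp_nosex"].iat[i]]
            )
            p[i] = window_test_p(obs, exp, method=method)
    wst["p_value"] = p
    return wst


def _chi2_pvalues_vectorized(rows: pd.DataFrame) -> np.ndarray:
    """Pearson chi-squared p for observed-vs-rounded-expected 2x3 tables."""
    obs = rows[["obs_xy", "obs_zw", "obs_nosex"]].to_numpy(dtype=float)
    exp = np.round(rows[["exp_xy", "exp_zw", "exp_nosex"]].to_numpy(dtype=float))
    r1 = obs.sum(axis=1, keepdims=True)
    r2 = exp.sum(axis=1, keepdims=True)
    col = obs + exp
    n = r1 + r2
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = r1 * col / n
        e2 = r2 * col / n
        stat = np.where(e1 > 0, (obs - e1) ** 2 / e1, 0.0).sum(axis=1)
        stat += np.where(e2 > 0, (exp - e2) ** 2 / e2, 0.0).sum(axis=1)
    df = (col > 0).sum(axis=1) - 1
    p = np.ones(len(rows))
    ok = (df > 0) & (n[:, 0] > 0)
    p[ok] = stats.chi2.sf(stat[ok], df[ok])
    return p


# ---------------------------------------------------------------------------
# permutation thresholds
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TribeThresholds:
    max_abs_diff_norm: float
    min_perm_p: float
    p_retention_cutoff: float = 10 ** (-NEGLOG10P_RETAIN)
    n_perm: int = 100


def permutation_thresholds(
    sct: SiteClassTable,
    lgs: pd.DataFrame,
    n_perm: int = 100,
    seed: int = 0,
    method: str = "chi2",
    window: int = WINDOW_BP,
    step: int = STEP_BP,
) -> TribeThresholds:
    """Tribe-wise null thresholds from label permutations.

    Each permutation shuffles, per species, the multiset of class labels over
    the fixed site positions, re-runs the window pipeline, and records the
    largest species-normalized absolute XY-ZW difference and the smallest
    XY/ZW-window p-value; the thresholds are the extremes over permutations.
    The permutation p-values default to the (vectorized) chi-squared test:
    the threshold consumed downstream is the difference threshold, with the
    fixed exact-test retention cutoff applied to the observed windows.
    """
    if n_perm <= 0:
        raise SexlinkageError("n_perm must be positive")
    if len(sct.sites) == 0:
        raise SexlinkageError("empty site class table")
    rng = np.random.default_rng(seed)
    max_diff = 0.0
    min_p = 1.0
    for _ in range(n_perm):
        perm_classes = sct.classes.copy()
        for j in range(perm_classes.shape[1]):
            rng.shuffle(perm_classes[:, j])
        perm = SiteClassTable(sct.sites, sct.species, perm_classes)
        wst = test_windows(window_stats(perm, lgs, window, step), method=method)
        if len(wst):
            max_diff = max(max_diff, float(wst["xy_zw_diff_norm"].abs().max()))
            pmin = wst["p_value"].min()
            if np.isfinite(pmin):
                min_p = min(min_p, float(pmin))
    return TribeThresholds(max_abs_diff_norm=max_diff, min_perm_p=min_p, n_perm=n_perm)


# ---------------------------------------------------------------------------
# outlier regions and species attribution
# ---------------------------------------------------------------------------


@dataclass
class OutlierRegion:
    lg: str
    start: int
    end: int
    direction: str  # "XY" or "ZW"
    peak_neglog10p: float
    contributing_species: list = field(default_factory=list)


def _overlaps_mask(lg, start, end, masks) -> bool:
    for m_lg, m_start, m_end in masks:
        if lg != m_lg:
            continue
        if m_end is None or (start <= m_end and end >= m_start):
            if m_end is None:
                return True
            return start <= m_end and end >= m_start
    return False


def call_outlier_regions(
    wst: pd.DataFrame,
    th: TribeThresholds,
    masks=DEFAULT_MASKS,
    neglog10p_min: float = NEGLOG10P_RETAIN,
) -> list[OutlierRegion]:
    """Merge drastic outlier windows into regions.

    Retained windows exceed the tribe's permutation threshold on the
    normalized |XY-ZW| difference and have -log10(p) above the fixed cutoff;
    windows overlapping masked regions are dropped. Windows sharing >= 1 bp
    merge; the merged region's direction comes from its minimum-p window
    (ties broken toward the larger |XY-ZW| difference).
    """
    if "p_value" not in wst.columns:
        raise SexlinkageError("run test_windows before calling outlier regions")
    w = wst[
        wst["designation"].isin(["XY", "ZW"])
        & (wst["xy_zw_diff_norm"].abs() > th.max_abs_diff_norm)
        & (-np.log10(wst["p_value"].clip(lower=1e-300)) > neglog10p_min)
    ].copy()
    if len(w) == 0:
        return []
    w = w[~w.apply(lambda r: _overlaps_mask(r["lg"], r["start"], r["end"], masks), axis=1)]
    if len(w) == 0:
        return []
    w = w.sort_values(["lg", "start"]).reset_index(drop=True)
    regions: list[OutlierRegion] = []
    cur = None  # (lg, start, end, rows)
    for _, row in w.iterrows():
        if cur is not None and row["lg"] == cur[0] and row["start"] <= cur[2]:
            cur = (cur[0], cur[1], max(cur[2], int(row["end"])), cur[3] + [row])
        else:
            if cur is not None:
                regions.append(_finish_region(cur))
            cur = (row["lg"], int(row["start"]), int(row["end"]), [row])
    regions.append(_finish_region(cur))
    return regions


def _finish_region(cur) -> OutlierRegion:
    lg, start, end, rows = cur
    best = min(rows, key=lambda r: (r["p_value"], -abs(r["xy_zw_diff"])))
    return OutlierRegion(
        lg=lg,
        start=start,
        end=end,
        direction=str(best["designation"]),
        peak_neglog10p=float(-np.log10(max(min(r["p_value"] for r in rows), 1e-300))),
    )


def attribute_species(
    regions: list[OutlierRegion],
    vt: VariantTable,
    sct: SiteClassTable,
    panel: SamplePanel,
    min_informative_sites: int = 10,
    min_shared_species: int = 2,
) -> list[SpeciesCall]:
    """Resolve which species carry each outlier region's signature.

    Individual genotypes over region sites are clustered (Gower distances,
    DIANA 2-cluster cut); a species receives the call when its individuals
    separate by sex and its within-region XY-ZW difference matches the region
    direction. A call is emitted only when at least ``min_shared_species``
    species of the tribe share it.
    """
    if not regions:
        return []
    gt = vt.genotype_codes()
    sexes = [panel.sex_of(ind) for ind in vt.individuals]
    sp_of_ind = {
        r["individual_id"]: r["species_id"] for _, r in panel.table.iterrows()
    }
    per_species_regions: dict[str, list[OutlierRegion]] = {}
    for region in regions:
        in_region = (
            (sct.sites["lg"] == region.lg)
            & (sct.sites["pos"] >= region.start)
            & (sct.sites["pos"] <= region.end)
        ).to_numpy()
        rows = sct.sites.loc[in_region, "row"].to_numpy()
        if rows.size == 0:
            continue
        sub_gt = gt[rows]
        labels = diana_two_clusters(gower_matrix(sub_gt))
        region.contributing_species = []
        for j, sp in enumerate(sct.species):
            cls = sct.classes[in_region, j]
            informative = int(((cls == CXY) | (cls == CZW) | (cls == NOSEX)).sum())
            if informative < min_informative_sites:
                continue
            diff = int((cls == CXY).sum() - (cls == CZW).sum())
            want = 1 if region.direction == "XY" else -1
            if np.sign(diff) != want:
                continue
            idx = [
                k for k, ind in enumerate(vt.individuals) if sp_of_ind.get(ind) == sp
            ]
            if len(idx) < 2 or not splits_by_sex(labels, sexes, idx):
                continue
            region.contributing_species.append(sp)
        if len(region.contributing_species) >= min_shared_species:
            for sp in region.contributing_species:
                per_species_regions.setdefault(sp, []).append(region)
    calls = []
    for sp, regs in sorted(per_species_regions.items()):
        for system in {r.direction for r in regs}:
            lg_ids = {r.lg for r in regs if r.direction == system}
            calls.append(
                SpeciesCall(sp, frozenset(lg_ids), system, frozenset({"A2"}))
            )
    return calls


def scan_wgs_tribe(
    vt: VariantTable,
    panel: SamplePanel,
    lgs: pd.DataFrame,
    seed: int = 0,
    n_perm: int = 100,
    method: str = "fisher",
    perm_method: str = "chi2",
    masks=DEFAULT_MASKS,
) -> tuple[list[SpeciesCall], pd.DataFrame, list[OutlierRegion]]:
    """Full accumulation scan for one tribe: classify, window, test, call."""
    sct = classify_sites(vt, panel)
    wst = test_windows(window_stats(sct, lgs), method=method)
    th = permutation_thresholds(sct, lgs, n_perm=n_perm, seed=seed, method=perm_method)
    regions = call_outlier_regions(wst, th, masks=masks)
    calls = attribute_species(regions, vt, sct, panel)
    return calls, wst, regions
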