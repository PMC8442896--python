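"""Species-level sex-linkage detection from transcriptome allele counts (A3).

Input is a per-SNP allele read-count table over sexed replicates (typically
three males and three females per species). SNPs with significant
sex-differential allele use (per-SNP exact test on sex-pooled ref/alt counts,
Benjamini-Hochberg adjusted) are classified as XY when the variant allele is
absent from all female replicates and seen in at least two males (ZW
mirrored). XY-ZW differences in 10-kb nonoverlapping windows are screened for
Tukey-style outliers (Q3 + 1.5*IQR; the mirrored low tail catches ZW
systems), heterogamety is decided by a paired two-sided signed-rank test over
outlier windows, and candidate linkage groups are the extreme outliers of the
length-normalized per-LG SNP counts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .call_integration import SpeciesCall
from .io_prep import SexlinkageError, UNPLACED_LG

RNA_WINDOW_BP = 10_000

#: LG names dropped before testing (mitochondrial / unplaced placements)
EXCLUDED_LG_PATTERNS = (r"^MT$", r"^chrM$", r"^mito", rf"^{UNPLACED_LG}$")

_REP_COL = re.compile(r"^([mf])(\d+)_(ref|alt)$")


def replicate_columns(act: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Male and female replicate ids from `<sex><idx>_ref/alt` columns."""
    males, females = set(), set()
    for col in act.columns:
        m = _REP_COL.match(col)
        if m:
            (males if m.group(1) == "m" else females).add(f"{m.group(1)}{m.group(2)}")
    return sorted(males), sorted(females)


def filter_sex_biased_snps(
    act: pd.DataFrame,
    alpha: float = 0.05,
    excluded_lg_patterns=EXCLUDED_LG_PATTERNS,
) -> pd.DataFrame:
    """Keep SNPs with BH-adjusted sex-differential allele use (p <= alpha).

    The per-SNP test is a two-sided Fisher exact test on sex-pooled ref/alt
    counts. SNPs on mitochondrial or unplaced sequence are removed first;
    replicates with zero total counts at a SNP do not contribute to its test
    (pooling makes this automatic).
    """
    males, females = replicate_columns(act)
    if len(males) < 2 or len(females) < 2:
        raise SexlinkageError("need at least 2 replicates per sex")
    keep_lg = ~act["lg"].astype(str).str.contains(
        "|".join(excluded_lg_patterns), regex=True, case=False
    )
    act = act[keep_lg].reset_index(drop=True)
    if len(act) == 0:
        out = act.copy()
        out["p_value"] = out["p_adj"] = pd.Series(dtype=float)
        return out
    m_ref = act[[f"{r}_ref" for r in males]].sum(axis=1).to_numpy()
    m_alt = act[[f"{r}_alt" for r in males]].sum(axis=1).to_numpy()
    f_ref = act[[f"{r}_ref" for r in females]].sum(axis=1).to_numpy()
    f_alt = act[[f"{r}_alt" for r in females]].sum(axis=1).to_numpy()
    p = np.ones(len(act))
    for i in range(len(act)):
        table = [[m_ref[i], m_alt[i]], [f_ref[i], f_alt[i]]]
        if (m_ref[i] + m_alt[i]) == 0 or (f_ref[i] + f_alt[i]) == 0:
            continue
        p[i] = stats.fisher_exact(table, alternative="two-sided")[1]
    act = act.copy()
    act["p_value"] = p
    act["p_adj"] = stats.false_discovery_control(p, method="bh")
    return act[act["p_adj"] <= alpha].reset_index(drop=True)


def classify_rna_snps(act: pd.DataFrame) -> pd.DataFrame:
    """Classify filtered SNPs by sex-exclusive expression of the variant.

    XY: zero variant-allele reads in every female and at least one read in at
    least two males; ZW mirrored; anything else is unclassified.
    """
    males, females = replicate_columns(act)
    m_alt = act[[f"{r}_alt" for r in males]].to_numpy()
    f_alt = act[[f"{r}_alt" for r in females]].to_numpy()
    xy = (f_alt == 0).all(axis=1) & ((m_alt >= 1).sum(axis=1) >= 2)
    zw = (m_alt == 0).all(axis=1) & ((f_alt >= 1).sum(axis=1) >= 2)
    out = act.copy()
    cls = np.full(len(act), "unclassified", dtype=object)
    cls[xy] = "XY"
    cls[zw] = "ZW"
    out["snp_class"] = cls
    return out


def rna_outlier_windows(
    classified: pd.DataFrame,
    window: int = RNA_WINDOW_BP,
    one_sided: bool = False,
) -> pd.DataFrame:
    """Per-window XY-ZW differences and Tukey outlier flags.

    Windows are 10-kb and nonoverlapping; the Q3/IQR statistics run over all
    windows holding at least one retained (sex-biased) SNP, classified or
    not, so the genome-wide landscape of expressed variation anchors the
    outlier threshold. A window is an XY outlier when its difference
    strictly exceeds Q3 + 1.5*IQR; unless ``one_sided``, differences below
    Q1 - 1.5*IQR flag ZW outliers symmetrically.
    """
    snps = classified
    if len(snps) == 0 or not snps["snp_class"].isin(["XY", "ZW"]).any():
        raise SexlinkageError("no classified SNPs")
    win_start = ((snps["pos"].to_numpy() - 1) // window) * window + 1
    df = pd.DataFrame(
        {
            "lg": snps["lg"].to_numpy(),
            "start": win_start,
            "is_xy": (snps["snp_class"] == "XY").to_numpy().astype(int),
            "is_zw": (snps["snp_class"] == "ZW").to_numpy().astype(int),
        }
    )
    rwt = (
        df.groupby(["lg", "start"], as_index=False)
        .agg(n_xy=("is_xy", "sum"), n_zw=("is_zw", "sum"))
        .sort_values(["lg", "start"])
        .reset_index(drop=True)
    )
    rwt["end"] = rwt["start"] + window - 1
    rwt["diff"] = rwt["n_xy"] - rwt["n_zw"]
    d = rwt["diff"].to_numpy(dtype=float)
    q1, q3 = np.quantile(d, [0.25, 0.75])  # linear interpolation (type 7)
    iqr = q3 - q1
    hi = q3 + 1.5 * iqr
    lo = q1 - 1.5 * iqr
    direction = np.full(len(rwt), "", dtype=object)
    direction[d > hi] = "XY"
    if not one_sided:
        direction[d < lo] = "ZW"
    rwt["outlier"] = direction != ""
    rwt["direction"] = direction
    rwt.attrs["q3_plus_1p5iqr"] = float(hi)
    rwt.attrs["q1_minus_1p5iqr"] = float(lo)
    return rwt


def decide_heterogamety(rwt: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Decide XY/ZW/none from outlier windows by paired signed-rank test.

    Compares the per-window XY and ZW SNP counts across outlier windows with
    a paired two-sided Wilcoxon signed-rank test; a significant difference
    assigns the system to the side with the larger total SNP count.
    """
    out = rwt[rwt["outlier"]]
    if len(out) < 3:
        return {"system": "none", "p_value": None,
                "reason": f"only {len(out)} outlier windows (<3)"}
    n_xy = out["n_xy"].to_numpy(dtype=float)
    n_zw = out["n_zw"].to_numpy(dtype=float)
    if np.all(n_xy == n_zw):
        return {"system": "none", "p_value": 1.0, "reason": "identical distributions"}
    res = stats.wilcoxon(n_xy, n_zw, alternative="two-sided")
    p = float(res.pvalue)
    if p >= alpha:
        return {"system": "none", "p_value": p, "reason": "not significant"}
    system = "XY" if n_xy.sum() > n_zw.sum() else "ZW"
    return {"system": system, "p_value": p, "reason": ""}


def call_candidate_lgs(
    rwt: pd.DataFrame,
    system: str,
    lgs: pd.DataFrame,
    sd_mode: str = "mean_sd",
) -> dict:
    """Candidate sex-linked LGs from length-normalized outlier-window counts.

    System-matching SNPs in outlier windows are summed per LG and divided by
    LG length (counts per Mb). Candidates must exceed Q3 + 3*IQR of the
    per-LG normalized counts and, to keep only the most extreme outliers,
    also the mean + 1 SD (``sd_mode="literal"`` compares the normalized count
    to the SD itself instead). An empty candidate set reports the system with
    the LG unassigned.
    """
    if system not in ("XY", "ZW"):
        raise SexlinkageError("system must be XY or ZW")
    count_col = "n_xy" if system == "XY" else "n_zw"
    out = rwt[rwt["outlier"]]
    per_lg = out.groupby("lg")[count_col].sum()
    norm = pd.Series(0.0, index=lgs["lg_id"].tolist())
    for lg in norm.index:
        length = float(lgs.loc[lgs["lg_id"] == lg, "length_bp"].iloc[0])
        norm[lg] = per_lg.get(lg, 0) / length * 1e6
    vals = norm.to_numpy()
    q1, q3 = np.quantile(vals, [0.25, 0.75])
    cut_iqr = q3 + 3 * (q3 - q1)
    cut_sd = (vals.mean() + vals.std(ddof=0)) if sd_mode == "mean_sd" else vals.std(ddof=0)
    candidates = [lg for lg in norm.index if norm[lg] > cut_iqr and norm[lg] > cut_sd]
    return {
        "system": system,
        "candidate_lgs": candidates if candidates else ["unassigned"],
        "normalized_counts": norm,
    }


def scan_rna_species(
    act: pd.DataFrame,
    lgs: pd.DataFrame,
    species_id: str,
    alpha: float = 0.05,
    one_sided: bool = False,
) -> tuple[SpeciesCall | None, dict]:
    """Full transcriptome scan for one species."""
    filtered = filter_sex_biased_snps(act, alpha=alpha)
    if len(filtered) == 0:
        return None, {"system": "none", "reason": "no sex-biased SNPs"}
    classified = classify_rna_snps(filtered)
    if not classified["snp_class"].isin(["XY", "ZW"]).any():
        return None, {"system": "none", "reason": "no sex-exclusive SNPs"}
    rwt = rna_outlier_windows(classified, one_sided=one_sided)
    decision = decide_heterogamety(rwt)
    if decision["system"] == "none":
        return None, decision
    lg_call = call_candidate_lgs(rwt, decision["system"], lgs)
    decision["candidate_lgs"] = lg_call["candidate_lgs"]
    decision["normalized_counts"] = lg_call["normalized_counts"]
    call = SpeciesCall(
        species_id,
        frozenset(lg_call["candidate_lgs"]),
        decision["system"],
        frozenset({"A3"}),
    )
    return call, decision
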