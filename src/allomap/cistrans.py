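"""Per-gene cis/trans regulatory classification from parental and hybrid counts.

The design follows the classic hybrid-ASE logic: if a regulatory difference is
cis-acting (linked to the allele), the expression difference between species
persists between the two alleles inside a hybrid cell, where both alleles see
the same trans environment.  If it is trans-acting, the difference between
parental lines disappears in the hybrid.  Writing ``L_DE`` for the parental
human-vs-chimp log2 fold change and ``L_ASE`` for the hybrid human-allele vs
chimp-allele log2 fold change, the cis component is ``C = L_ASE`` and the
trans component is ``T = L_DE - L_ASE``, so ``C + T = L_DE`` identically.

Each gene is assigned to one of seven categories from three significance
calls (DE, ASE, and the trans difference) and the signs of C and T:

========================  =====  ======  =====  ==================
category                  DE     ASE     trans  sign condition
========================  =====  ======  =====  ==================
conserved                 no     no      no
cis                       yes    yes     no
trans                     yes    no      yes
cis+trans                 yes    yes     yes    sign(C) == sign(T)
cis-trans                 yes    yes     yes    sign(C) != sign(T)
compensatory              no     yes     yes
ambiguous                 any other pattern
========================  =====  ======  =====  ==================

Contrasts use Welch's t on log2 normalized counts with a per-group variance
floor; the trans difference uses a two-tailed normal z-test on
``T / sqrt(SE_DE^2 + SE_ASE^2)``; each family of p-values is adjusted by
Benjamini-Hochberg separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CATEGORIES = ("cis", "trans", "cis+trans", "cis-trans", "compensatory",
              "conserved", "ambiguous")

CONTEXTS = ("human_parental", "chimp_parental",
            "hybrid_human_allele", "hybrid_chimp_allele")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def compute_size_factors(counts: pd.DataFrame, min_reference_genes: int = 50) -> pd.Series:
    """Median-of-ratios size factors, geometric-mean centered.

    The reference is the per-gene geometric mean over genes expressed in every
    sample; each sample's factor is the median ratio to that reference.  When
    fewer than ``min_reference_genes`` genes are expressed everywhere, falls
    back to total-count scaling.  Factors are rescaled to geometric mean 1.
    """
    values = counts.to_numpy(dtype=float)
    if values.shape[0] == 0 or not np.any(values > 0):
        raise ValueError("cannot compute size factors: count matrix is all zero")
    allpos = np.all(values > 0, axis=1)
    if allpos.sum() >= min_reference_genes or (allpos.sum() >= 1 and values.shape[0] < min_reference_genes):
        ref = np.exp(np.mean(np.log(values[allpos]), axis=1))
        factors = np.median(values[allpos] / ref[:, None], axis=0)
    else:
        totals = values.sum(axis=0)
        if np.any(totals == 0):
            raise ValueError("cannot compute size factors: a sample has zero total count")
        factors = totals
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def log_expression(counts: pd.DataFrame, factors: pd.Series,
                   pseudocount: float = 0.5) -> pd.DataFrame:
    """log2(count / size_factor + pseudocount)."""
    f = factors.reindex(counts.columns).to_numpy(dtype=float)
    if np.any(~np.isfinite(f)) or np.any(f <= 0):
        raise ValueError("size factors must be positive and cover every sample")
    return pd.DataFrame(
        np.log2(counts.to_numpy(dtype=float) / f[None, :] + pseudocount),
        index=counts.index, columns=counts.columns,
    )


# ---------------------------------------------------------------------------
# Contrasts
# ---------------------------------------------------------------------------

def estimate_contrast(
    logmat: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    variance_floor_quantile: float = 0.10,
) -> pd.DataFrame:
    """Welch two-sample contrast per gene: group_a minus group_b on log2 scale.

    Per-gene per-group variances are floored at the given quantile of all
    per-group variances in the matrix, preventing zero-variance degeneracy for
    genes whose replicates happen to be identical.  Returns columns
    ``L`` (difference of means), ``SE``, ``p`` (two-tailed, Welch df).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 samples for a Welch contrast")
    a = logmat[list(group_a)].to_numpy(dtype=float)
    b = logmat[list(group_b)].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    floor = float(np.quantile(np.concatenate([va, vb]), variance_floor_quantile))
    va = np.maximum(va, floor)
    vb = np.maximum(vb, floor)

    L = a.mean(axis=1) - b.mean(axis=1)
    se2 = va / na + vb / nb
    se = np.sqrt(se2)
    p = np.ones_like(L)
    ok = se > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(ok, L / np.where(ok, se, 1.0), 0.0)
        df = np.where(
            ok,
            se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)),
            1.0,
        )
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    # degenerate: zero variance everywhere; nonzero difference is then certain
    p[~ok & (L != 0)] = 0.0
    return pd.DataFrame({"L": L, "SE": se, "p": p}, index=logmat.index)


def test_trans(L_DE: np.ndarray, SE_DE: np.ndarray,
               L_ASE: np.ndarray, SE_ASE: np.ndarray) -> pd.DataFrame:
    """z-test for a trans component T = L_DE - L_ASE.

    SE_T = sqrt(SE_DE^2 + SE_ASE^2); p two-tailed normal.  A zero SE_T with
    T != 0 is degenerate and reported as p = 0.
    """
    L_DE, SE_DE = np.asarray(L_DE, float), np.asarray(SE_DE, float)
    L_ASE, SE_ASE = np.asarray(L_ASE, float), np.asarray(SE_ASE, float)
    if np.any(~np.isfinite(SE_DE)) or np.any(~np.isfinite(SE_ASE)):
        raise ValueError("standard errors must be finite")
    T = L_DE - L_ASE
    SE_T = np.sqrt(SE_DE**2 + SE_ASE**2)
    p = np.ones_like(T)
    ok = SE_T > 0
    p[ok] = 2.0 * stats.norm.sf(np.abs(T[ok] / SE_T[ok]))
    p[~ok & (T != 0)] = 0.0
    return pd.DataFrame({"T": T, "SE_T": SE_T, "p_T": p})


def adjust_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaN inputs stay NaN."""
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_regulatory(q_DE, q_ASE, q_T, C, T, alpha: float = 0.05) -> np.ndarray:
    """Map significance patterns and effect signs to the seven categories.

    A zero C or T in the all-significant pattern counts as sign agreement
    (vacuous), so such genes fall in cis+trans.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    q_DE, q_ASE, q_T = (np.asarray(x, float) for x in (q_DE, q_ASE, q_T))
    C, T = np.asarray(C, float), np.asarray(T, float)
    sde, sase, st = q_DE < alpha, q_ASE < alpha, q_T < alpha

    out = np.full(q_DE.shape, "ambiguous", dtype=object)
    out[~sde & ~sase & ~st] = "conserved"
    out[~sde & sase & st] = "compensatory"
    out[sde & sase & ~st] = "cis"
    out[sde & ~sase & st] = "trans"
    allsig = sde & sase & st
    agree = (np.sign(C) == np.sign(T)) | (C == 0) | (T == 0)
    out[allsig & agree] = "cis+trans"
    out[allsig & ~agree] = "cis-trans"
    return out.astype(str)


@dataclass
class ClassificationResult:
    effects: pd.DataFrame   # gene-level estimates (GeneEffect table)
    calls: pd.DataFrame     # gene, category, C, T (RegulatoryCall table)
    summary: pd.DataFrame   # per-category counts and percentages


def _context_samples(samples: pd.DataFrame, context: str) -> list[str]:
    return samples.loc[samples["context"] == context, "sample_id"].to_list()


def classify_all(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    alpha: float = 0.05,
    pseudocount: float = 0.5,
    variance_floor_quantile: float = 0.10,
) -> ClassificationResult:
    """Run the full chain: normalize, contrast, trans test, BH, classify.

    Percentages in the summary use two denominators: conserved and
    compensatory are percentages of the no-net-change genes (those two
    classes), and the four change categories are percentages of the
    regulatory-change genes (those four classes); ambiguous is reported
    separately.
    """
    missing = set(CONTEXTS) - set(samples["context"])
    if missing:
        raise ValueError(f"sample table lacks contexts: {sorted(missing)}")
    if samples["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in sample table")

    factors = compute_size_factors(counts)
    logmat = log_expression(counts, factors, pseudocount)
    de = estimate_contrast(
        logmat, _context_samples(samples, "human_parental"),
        _context_samples(samples, "chimp_parental"), variance_floor_quantile)
    ase = estimate_contrast(
        logmat, _context_samples(samples, "hybrid_human_allele"),
        _context_samples(samples, "hybrid_chimp_allele"), variance_floor_quantile)
    tt = test_trans(de["L"].to_numpy(), de["SE"].to_numpy(),
                    ase["L"].to_numpy(), ase["SE"].to_numpy())

    norm = counts.to_numpy(dtype=float) / factors.to_numpy()[None, :]
    effects = pd.DataFrame(
        {
            "gene_id": counts.index,
            "L_DE": de["L"].to_numpy(), "SE_DE": de["SE"].to_numpy(),
            "p_DE": de["p"].to_numpy(), "q_DE": adjust_bh(de["p"].to_numpy()),
            "L_ASE": ase["L"].to_numpy(), "SE_ASE": ase["SE"].to_numpy(),
            "p_ASE": ase["p"].to_numpy(), "q_ASE": adjust_bh(ase["p"].to_numpy()),
            "T": tt["T"].to_numpy(), "SE_T": tt["SE_T"].to_numpy(),
            "p_T": tt["p_T"].to_numpy(), "q_T": adjust_bh(tt["p_T"].to_numpy()),
            "mean_expr": norm.mean(axis=1),
        }
    )
    category = classify_regulatory(
        effects["q_DE"], effects["q_ASE"], effects["q_T"],
        effects["L_ASE"], effects["T"], alpha)
    calls = pd.DataFrame(
        {"gene_id": counts.index, "category": category,
         "C": effects["L_ASE"].to_numpy(), "T": effects["T"].to_numpy()}
    )
    summary = summarize_categories(calls)
    return ClassificationResult(effects=effects, calls=calls, summary=summary)


def summarize_categories(calls: pd.DataFrame) -> pd.DataFrame:
    counts = calls["category"].value_counts().reindex(CATEGORIES, fill_value=0)
    no_change = int(counts["conserved"] + counts["compensatory"])
    change = int(counts[["cis", "trans", "cis+trans", "cis-trans"]].sum())
    rows = []
    for cat in CATEGORIES:
        n = int(counts[cat])
        if cat in ("conserved", "compensatory"):
            denom = no_change
        elif cat == "ambiguous":
            denom = 0
        else:
            denom = change
        pct = 100.0 * n / denom if denom else np.nan
        rows.append((cat, n, pct))
    return pd.DataFrame(rows, columns=["category", "n_genes", "percent"])


# ---------------------------------------------------------------------------
# Downstream summaries
# ---------------------------------------------------------------------------

def filter_twofold(calls: pd.DataFrame, effects: pd.DataFrame,
                   threshold: float = 1.0, on: str = "L_DE") -> pd.Index:
    """Genes whose |log2 fold change| meets the threshold (boundary inclusive)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if on not in ("L_DE", "C"):
        raise ValueError("filter column must be 'L_DE' or 'C'")
    col = effects["L_DE"] if on == "L_DE" else effects["L_ASE"]
    keep = np.abs(col.to_numpy(dtype=float)) >= threshold
    return pd.Index(effects.loc[keep, "gene_id"])


def mannwhitney_exact_oracle(a, b) -> float:
    """Exact two-tailed Mann-Whitney p by full enumeration (tests/small n)."""
    from itertools import combinations

    a, b = list(a), list(b)
    pooled = a + b
    na = len(a)
    u_obs = sum(1.0 for x in a for y in b if x > y) + 0.5 * sum(
        1 for x in a for y in b if x == y)
    total = 0
    extreme = 0
    mu = na * len(b) / 2.0
    for idx in combinations(range(len(pooled)), na):
        sel = [pooled[i] for i in idx]
        oth = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = sum(1.0 for x in sel for y in oth if x > y) + 0.5 * sum(
            1 for x in sel for y in oth if x == y)
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            extreme += 1
    return extreme / total


def compare_effect_sizes(calls: pd.DataFrame, effects: pd.DataFrame,
                         min_genes: int = 2) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-category |L_DE| medians/means and all pairwise Mann-Whitney tests.

    Returns (per-category stats, pairwise table with BH-adjusted p).
    Categories with fewer than ``min_genes`` genes are excluded.
    """
    merged = calls.merge(effects[["gene_id", "L_DE"]], on="gene_id")
    merged["abs_lfc"] = merged["L_DE"].abs()
    groups = {
        cat: g["abs_lfc"].to_numpy()
        for cat, g in merged.groupby("category")
        if len(g) >= min_genes
    }
    if len(groups) < 2:
        raise ValueError("need >= 2 categories with enough genes to compare")
    stats_rows = [
        (cat, len(v), float(np.median(v)), float(np.mean(v)))
        for cat, v in sorted(groups.items())
    ]
    per_cat = pd.DataFrame(stats_rows, columns=["category", "n", "median_abs_lfc",
                                                "mean_abs_lfc"])
    pair_rows = []
    cats = sorted(groups)
    for i, ca in enumerate(cats):
        for cb in cats[i + 1:]:
            res = stats.mannwhitneyu(groups[ca], groups[cb],
                                     alternative="two-sided")
            pair_rows.append((ca, cb, float(res.statistic), float(res.pvalue)))
    pairwise = pd.DataFrame(pair_rows, columns=["category_a", "category_b", "U", "p"])
    pairwise["q"] = adjust_bh(pairwise["p"].to_numpy())
    return per_cat, pairwise


def annotation_burden_test(
    calls: pd.DataFrame,
    effects: pd.DataFrame,
    burden: pd.Series,
    threshold: float = 1.0,
    min_genes: int = 6,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Compare a per-gene annotation burden between each category and conserved.

    ``burden`` maps gene id -> non-negative integer (e.g. number of body parts
    a gene influences).  The cis, trans and cis+trans categories are first
    restricted to genes with |L_DE| >= threshold; a filtered category with
    fewer than ``min_genes`` genes is skipped.  Genes absent from the burden
    table are excluded.  Mann-Whitney two-tailed vs the conserved set, BH
    across tested categories.
    """
    merged = calls.merge(effects[["gene_id", "L_DE"]], on="gene_id")
    merged = merged[merged["gene_id"].isin(burden.index)]
    merged["burden"] = burden.reindex(merged["gene_id"]).to_numpy()

    conserved = merged.loc[merged["category"] == "conserved", "burden"].to_numpy()
    if conserved.size == 0:
        raise ValueError("no conserved genes with burden annotation")
    rows = []
    for cat in ("cis", "trans", "cis+trans", "cis-trans", "compensatory"):
        sub = merged[merged["category"] == cat]
        if cat in ("cis", "trans", "cis+trans", "cis-trans"):
            sub = sub[sub["L_DE"].abs() >= threshold]
        vals = sub["burden"].to_numpy()
        if vals.size < min_genes:
            continue
        res = stats.mannwhitneyu(vals, conserved, alternative="two-sided")
        rows.append((cat, vals.size, float(np.median(vals)), float(res.pvalue)))
    out = pd.DataFrame(rows, columns=["category", "n", "median_burden", "p"])
    if len(out):
        out["q"] = adjust_bh(out["p"].to_numpy())
        out["significant"] = out["q"] < alpha
    out.attrs["conserved_median"] = float(np.median(conserved))
    out.attrs["conserved_n"] = int(conserved.size)
    return out
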