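"""Chromosome-arm dosage classification, breakpoint mapping, and trans mapping.

Engineered lines carrying species-specific terminal deletions (or an
interspecific recombinant chromosome) are characterized three ways:

* genomic dosage at a proximal and a distal locus of the focal chromosome,
  normalized to a control autosome, separates deletions (one species' distal
  arm lost, the other unchanged) from recombinants (one lost, the other
  doubled) and whole-chromosome losses;
* the ratio of reads assignable to each species along the chromosome shows a
  step at the deletion breakpoint, fitted here by an exhaustive single-
  changepoint scan under a binomial likelihood;
* autosomal genes whose expression shifts in one species' deletion panel but
  not the other localize species-specific trans-acting factors to the deleted
  segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cistrans import adjust_bh, estimate_contrast

LINE_CLASSES = (
    "intact",
    "deletion_human", "deletion_chimp",
    "recombinant_gain_human", "recombinant_gain_chimp",
    "whole_chr_loss_human", "whole_chr_loss_chimp",
)


# ---------------------------------------------------------------------------
# Dosage classification
# ---------------------------------------------------------------------------

@dataclass
class DosageThresholds:
    """Windows around copy numbers 0, 1 and 2 (one intact copy = dosage 1)."""

    lost_max: float = 0.25
    single_range: tuple[float, float] = (0.75, 1.25)
    gain_min: float = 1.6


def classify_dosage(
    measurements: pd.DataFrame,
    thresholds: DosageThresholds | None = None,
) -> pd.DataFrame:
    """Classify each line from locus-level relative dosage.

    ``measurements`` columns: line, locus (control_autosome / chrX_proximal /
    chrX_distal), species (human / chimp), dosage.  Dosages are renormalized
    per line and species by the control autosome, so the classification is
    invariant to the normalization constant.

    Rules (per line): a species with distal dosage below ``lost_max`` is the
    targeted species; if its proximal dosage is also below ``lost_max`` the
    line is a whole-chromosome loss; otherwise the other species' distal
    dosage decides between deletion (single-copy window) and recombinant gain
    (>= ``gain_min``).  Lines matching no rule are flagged unresolved.
    """
    th = thresholds or DosageThresholds()
    required = {"control_autosome", "chrX_proximal", "chrX_distal"}
    rows = []
    for line, g in measurements.groupby("line", sort=True):
        dose = {}
        for species in ("human", "chimp"):
            sub = g[g["species"] == species].set_index("locus")["dosage"]
            missing = required - set(sub.index)
            if missing:
                raise ValueError(f"line {line}: missing locus {sorted(missing)} "
                                 f"for species {species}")
            ctrl = float(sub["control_autosome"])
            if ctrl <= 0:
                raise ValueError(f"line {line}: nonpositive control dosage")
            dose[species] = {
                "proximal": float(sub["chrX_proximal"]) / ctrl,
                "distal": float(sub["chrX_distal"]) / ctrl,
            }
        lost = [s for s in ("human", "chimp") if dose[s]["distal"] < th.lost_max]
        lo, hi = th.single_range
        cls, resolved = "intact", True
        if len(lost) == 1:
            target = lost[0]
            other = "chimp" if target == "human" else "human"
            if dose[target]["proximal"] < th.lost_max:
                cls = f"whole_chr_loss_{target}"
            elif dose[other]["distal"] >= th.gain_min:
                cls = f"recombinant_gain_{other}"
            elif lo <= dose[other]["distal"] <= hi:
                cls = f"deletion_{target}"
            else:
                cls, resolved = "intact", False
        elif len(lost) == 0:
            resolved = all(lo <= dose[s]["distal"] <= hi for s in ("human", "chimp"))
        else:
            cls, resolved = "intact", False
        rows.append((line, cls, resolved,
                     dose["human"]["distal"], dose["chimp"]["distal"]))
    return pd.DataFrame(rows, columns=["line", "line_class", "resolved",
                                       "human_distal", "chimp_distal"])


# ---------------------------------------------------------------------------
# Breakpoint fitting
# ---------------------------------------------------------------------------

@dataclass
class BreakpointCall:
    chrom: str
    left_position: int        # last feature position of the left segment
    right_position: int       # first feature position of the right segment
    index: int                # number of features in the left segment
    p_left: float             # human-read fraction left of the breakpoint
    p_right: float
    delta_loglik: float       # nats, vs the single-fraction model
    lost_species: str         # species whose reads drop distally ("human"/"chimp")


def _binom_loglik(k: float, n: float) -> float:
    """Maximized binomial log-likelihood of k successes in n trials."""
    if n == 0:
        return 0.0
    p = k / n
    out = 0.0
    if k > 0:
        out += k * np.log(p)
    if n - k > 0:
        out += (n - k) * np.log(1 - p)
    return out


def fit_breakpoint(
    track: pd.DataFrame,
    min_delta_loglik: float = 10.0,
    min_fraction_change: float = 0.1,
    chrom: str = "chrX",
) -> BreakpointCall | None:
    """Exhaustive single-changepoint scan under a binomial likelihood.

    Human counts per feature are modeled binomial(total, p_left) left of a
    split and binomial(total, p_right) right of it, with closed-form MLE
    fractions.  The split maximizing the total log-likelihood is chosen
    (leftmost on ties).  Returns ``None`` (no changepoint) when the
    improvement over the single-fraction model is below ``min_delta_loglik``
    nats or the fitted fractions differ by less than ``min_fraction_change``.
    """
    pos = track["position"].to_numpy(dtype=np.int64)
    h = track["count_human"].to_numpy(dtype=float)
    c = track["count_chimp"].to_numpy(dtype=float)
    if np.any(np.diff(pos) <= 0):
        raise ValueError("track positions must be strictly increasing")
    n = h + c
    if len(pos) < 4 or n.sum() == 0:
        raise ValueError("need >= 4 features with nonzero total counts")

    ch, cn = np.cumsum(h), np.cumsum(n)
    H, N = ch[-1], cn[-1]
    ll0 = _binom_loglik(H, N)
    best_b, best_ll = None, -np.inf
    for b in range(1, len(pos)):  # b features on the left
        ll = _binom_loglik(ch[b - 1], cn[b - 1]) + _binom_loglik(H - ch[b - 1], N - cn[b - 1])
        if ll > best_ll + 1e-12:
            best_ll, best_b = ll, b
    b = best_b
    p_left = ch[b - 1] / cn[b - 1] if cn[b - 1] > 0 else np.nan
    p_right = (H - ch[b - 1]) / (N - cn[b - 1]) if N - cn[b - 1] > 0 else np.nan
    delta = best_ll - ll0
    if delta < min_delta_loglik or abs(p_left - p_right) < min_fraction_change:
        return None
    lost = "human" if p_right < p_left else "chimp"
    return BreakpointCall(
        chrom=chrom, left_position=int(pos[b - 1]), right_position=int(pos[b]),
        index=int(b), p_left=float(p_left), p_right=float(p_right),
        delta_loglik=float(delta), lost_species=lost,
    )


def call_allele_loss(
    track: pd.DataFrame,
    breakpoint: BreakpointCall,
    retained_min: float = 0.7,
    lost_max: float = 0.15,
    control_ratio: float | None = None,
) -> pd.DataFrame:
    """Classify each feature's lost-species allele as retained/reduced/lost.

    The lost-species to other-species count ratio is compared with the
    control expectation (by default the fitted proximal-side ratio); the
    relative retention r is classified retained (r >= 0.7), lost (r <= 0.15)
    or reduced.  A contiguous run of "reduced" features adjacent to the
    breakpoint is annotated as the staggered interval.
    """
    h = track["count_human"].to_numpy(dtype=float)
    c = track["count_chimp"].to_numpy(dtype=float)
    lost_cnt, other_cnt = (h, c) if breakpoint.lost_species == "human" else (c, h)
    if control_ratio is None:
        p = breakpoint.p_left
        frac_lost = p if breakpoint.lost_species == "human" else 1 - p
        control_ratio = frac_lost / (1 - frac_lost)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(other_cnt > 0, lost_cnt / other_cnt, np.inf)
        retention = ratio / control_ratio
    status = np.where(retention >= retained_min, "retained",
                      np.where(retention <= lost_max, "lost", "reduced"))
    out = track.copy()
    out["retention"] = retention
    out["status"] = status
    # staggered interval: contiguous "reduced" run touching the breakpoint
    stag = np.zeros(len(out), dtype=bool)
    for i in range(breakpoint.index, len(out)):
        if status[i] != "reduced":
            break
        stag[i] = True
    for i in range(breakpoint.index - 1, -1, -1):
        if status[i] != "reduced":
            break
        stag[i] = True
    out["staggered"] = stag
    return out


# ---------------------------------------------------------------------------
# Trans-target mapping
# ---------------------------------------------------------------------------

def map_trans_targets(
    log_expression: pd.DataFrame,
    samples: pd.DataFrame,
    alpha: float = 0.05,
    variance_floor_quantile: float = 0.10,
) -> pd.DataFrame:
    """Locate species-specific trans effects from two deletion panels.

    ``samples`` needs columns sample_id and group with groups
    deletion_human / deletion_chimp / control (>= 2 samples each).  Genes
    should be restricted to chromosomes outside the deleted one.  Per gene,
    Welch contrasts of each deletion group vs control are BH-adjusted within
    their family; a gene is species-specific for group A when it is
    significant in A, not in B, and every A line deviates from the control
    mean with the group's sign.
    """
    groups = {g: samples.loc[samples["group"] == g, "sample_id"].to_list()
              for g in ("deletion_human", "deletion_chimp", "control")}
    for g, ids in groups.items():
        if len(ids) < 2:
            raise ValueError(f"group {g} needs >= 2 samples")
    con_a = estimate_contrast(log_expression, groups["deletion_human"],
                              groups["control"], variance_floor_quantile)
    con_b = estimate_contrast(log_expression, groups["deletion_chimp"],
                              groups["control"], variance_floor_quantile)
    q_a = adjust_bh(con_a["p"].to_numpy())
    q_b = adjust_bh(con_b["p"].to_numpy())

    ctrl_mean = log_expression[groups["control"]].to_numpy().mean(axis=1)

    def consistent(sign_cols: list[str], shift: np.ndarray) -> np.ndarray:
        dev = log_expression[sign_cols].to_numpy() - ctrl_mean[:, None]
        return np.all(np.sign(dev) == np.sign(shift)[:, None], axis=1)

    cons_a = consistent(groups["deletion_human"], con_a["L"].to_numpy())
    cons_b = consistent(groups["deletion_chimp"], con_b["L"].to_numpy())
    sig_a, sig_b = q_a < alpha, q_b < alpha
    out = pd.DataFrame(
        {
            "gene_id": log_expression.index,
            "shift_human_del": con_a["L"].to_numpy(), "q_human_del": q_a,
            "shift_chimp_del": con_b["L"].to_numpy(), "q_chimp_del": q_b,
            "specific_human_del": sig_a & ~sig_b & cons_a,
            "specific_chimp_del": sig_b & ~sig_a & cons_b,
        }
    )
    out["species_specific"] = out["specific_human_del"] | out["specific_chimp_del"]
    return out


def fraction_trans_explained(shift: float, trans_component: float) -> tuple[float, bool]:
    """Percent of an expected trans component recovered by a deletion shift.

    Returns (percent, discordant flag); negative percentages mean the shift
    opposes the expected trans direction.  Undefined for a zero component.
    """
    if trans_component == 0:
        raise ValueError("trans component is zero: fraction undefined")
    pct = 100.0 * shift / trans_component
    return float(pct), bool(pct < 0)


# ---------------------------------------------------------------------------
# Junction microhomology
# ---------------------------------------------------------------------------

def find_microhomology(seq_a: str, break_a: int, seq_b: str, break_b: int
                       ) -> tuple[int, int, int]:
    """Shared sequence at a junction joining seq_a[:break_a] to seq_b[break_b:].

    Cut positions are 0-based (junction between index ``break-1`` and
    ``break``) and mark the *outer* edges of any homology in each parent: a
    block present both at the end of the retained A segment and at the start
    of the retained B segment is microhomology, since the true crossover
    could lie anywhere within it.

    Returns (left_ext, right_ext, total) where ``left_ext`` is the longest m
    with ``seq_a[break_a-m:break_a] == seq_b[break_b:break_b+m]`` (homology
    left of the junction in the product) and ``right_ext`` the longest m with
    ``seq_a[break_a:break_a+m] == seq_b[break_b-m:break_b]``.
    """
    if not (0 <= break_a <= len(seq_a)) or not (0 <= break_b <= len(seq_b)):
        raise ValueError("cut position out of range")
    left = 0
    for m in range(1, min(break_a, len(seq_b) - break_b) + 1):
        if seq_a[break_a - m:break_a] == seq_b[break_b:break_b + m]:
            left = m
    right = 0
    for m in range(1, min(len(seq_a) - break_a, break_b) + 1):
        if seq_a[break_a:break_a + m] == seq_b[break_b - m:break_b]:
            right = m
    return left, right, left + right
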