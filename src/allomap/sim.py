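"""Synthetic data generators with exported ground truth.

Three generators emulate the inputs of the downstream analyses:

* :func:`simulate_expression_panel` — allele-resolved RNA counts from two
  parental species plus interspecies-hybrid lines in which both alleles share
  one trans environment, with known per-gene cis (``C``) and trans (``T``)
  log2 components.
* :func:`simulate_haplotag_molecules` — barcoded linked-read molecules over a
  chromosome carrying species-diagnostic variants, a configurable fraction of
  them with a single interspecific junction.
* :func:`simulate_deletion_panel` — lines carrying species-specific terminal
  deletions of a focal chromosome, with optional staggered (subclonal)
  breakpoints and trans-regulated autosomal target genes.

All generators derive child random streams from a single root seed keyed by
stage name, so identical config + seed reproduce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import check_finite, check_positive, check_prob, child_rng, nb_draw

REGULATORY_CATEGORIES = (
    "conserved",
    "cis",
    "trans",
    "cis+trans",
    "cis-trans",
    "compensatory",
)

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Expression panel
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSimConfig:
    """Generative parameters for the allele-resolved expression panel.

    Per gene g the baseline mean is mu_g ~ LogNormal(baseline_log_mean,
    baseline_log_sd) (natural-log parameters).  With cis component C and trans
    component T (log2 units) and per-sample size factor s_j, expected counts
    are::

        chimp parental        s_j * mu_g
        human parental        s_j * mu_g * 2**(C + T)
        hybrid chimp allele   s_j * mu_g
        hybrid human allele   s_j * mu_g * 2**C

    so log2 of the parental ratio minus log2 of the hybrid allele ratio equals
    T exactly.  Counts are negative binomial with variance m + dispersion*m^2.
    """

    n_genes: int = 2000
    reps_parental: int = 4
    n_hybrid_lines: int = 4
    baseline_log_mean: float = 5.5
    baseline_log_sd: float = 1.0
    dispersion: float = 0.05
    category_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "conserved": 0.55,
            "cis": 0.15,
            "trans": 0.12,
            "cis+trans": 0.08,
            "cis-trans": 0.04,
            "compensatory": 0.06,
        }
    )
    effect_mean: float = 2.0
    effect_sd: float = 0.5
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "reps_parental", "n_hybrid_lines"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        check_finite("baseline_log_mean", self.baseline_log_mean)
        check_finite("baseline_log_sd", self.baseline_log_sd)
        if self.baseline_log_sd < 0:
            raise ValueError("baseline_log_sd must be >= 0")
        if self.dispersion < 0 or not np.isfinite(self.dispersion):
            raise ValueError("dispersion must be finite and >= 0")
        unknown = set(self.category_proportions) - set(REGULATORY_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories in proportions: {sorted(unknown)}")
        weights = np.array(list(self.category_proportions.values()), dtype=float)
        check_finite("category_proportions", *weights)
        if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0):
            raise ValueError("category_proportions must be >= 0 and sum to 1")
        if self.effect_mean < 0 or self.effect_sd < 0:
            raise ValueError("effect magnitudes must be >= 0")
        check_finite("effect_mean", self.effect_mean, self.effect_sd)
        lo, hi = self.size_factor_range
        check_positive("size_factor_range lower bound", lo)
        if hi < lo:
            raise ValueError("size_factor_range must be (low, high) with high >= low")


def _draw_magnitude(rng: np.random.Generator, cfg: ExpressionSimConfig, size: int) -> np.ndarray:
    # |effect| in log2 units; truncated away from 0 so "nonzero" is meaningful
    mag = np.abs(rng.normal(cfg.effect_mean, cfg.effect_sd, size=size))
    return np.maximum(mag, 0.05)


def _draw_truth(rng: np.random.Generator, cfg: ExpressionSimConfig) -> pd.DataFrame:
    cats = list(cfg.category_proportions)
    weights = np.array([cfg.category_proportions[c] for c in cats], dtype=float)
    category = rng.choice(cats, size=cfg.n_genes, p=weights / weights.sum())
    C = np.zeros(cfg.n_genes)
    T = np.zeros(cfg.n_genes)
    sign = rng.choice([-1.0, 1.0], size=cfg.n_genes)
    magC = _draw_magnitude(rng, cfg, cfg.n_genes)
    magT = _draw_magnitude(rng, cfg, cfg.n_genes)

    is_cis = category == "cis"
    C[is_cis] = sign[is_cis] * magC[is_cis]
    is_trans = category == "trans"
    T[is_trans] = sign[is_trans] * magT[is_trans]
    both = category == "cis+trans"
    C[both] = sign[both] * magC[both]
    T[both] = sign[both] * magT[both]
    opp = category == "cis-trans"
    # opposite signs but non-cancelling net effect
    tied = np.isclose(magC, magT)
    magT = np.where(tied, 0.5 * magC, magT)
    C[opp] = sign[opp] * magC[opp]
    T[opp] = -sign[opp] * magT[opp]
    comp = category == "compensatory"
    C[comp] = sign[comp] * magC[comp]
    T[comp] = -C[comp]

    return pd.DataFrame(
        {
            "gene_id": [f"gene{i:05d}" for i in range(cfg.n_genes)],
            "true_category": category,
            "C_true": C,
            "T_true": T,
        }
    )


def simulate_expression_panel(
    cfg: ExpressionSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate an allele-resolved expression panel.

    Returns
    -------
    counts : DataFrame, genes x samples, integer counts (index = gene ids)
    samples : DataFrame with columns sample_id, line, context, replicate
    truth : DataFrame with columns gene_id, true_category, C_true, T_true
    """
    cfg.validate()
    rng = child_rng(cfg.seed, "expression")
    truth = _draw_truth(rng, cfg)
    mu = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=cfg.n_genes)

    records = []
    for r in range(cfg.reps_parental):
        records.append((f"hum_par_{r+1}", f"Hline{r+1}", "human_parental", r + 1))
        records.append((f"chi_par_{r+1}", f"Cline{r+1}", "chimp_parental", r + 1))
    for r in range(cfg.n_hybrid_lines):
        records.append((f"hyb{r+1}_hum", f"HC{r+1}", "hybrid_human_allele", r + 1))
        records.append((f"hyb{r+1}_chi", f"HC{r+1}", "hybrid_chimp_allele", r + 1))
    samples = pd.DataFrame(records, columns=["sample_id", "line", "context", "replicate"])

    lo, hi = cfg.size_factor_range
    size_factors = rng.uniform(lo, hi, size=len(samples))

    C = truth["C_true"].to_numpy()
    T = truth["T_true"].to_numpy()
    scale = {
        "chimp_parental": np.ones(cfg.n_genes),
        "human_parental": 2.0 ** (C + T),
        "hybrid_chimp_allele": np.ones(cfg.n_genes),
        "hybrid_human_allele": 2.0**C,
    }
    counts = np.empty((cfg.n_genes, len(samples)), dtype=np.int64)
    for j, (ctx, s_j) in enumerate(zip(samples["context"], size_factors)):
        counts[:, j] = nb_draw(rng, s_j * mu * scale[ctx], cfg.dispersion)

    count_df = pd.DataFrame(counts, index=pd.Index(truth["gene_id"], name="gene_id"),
                            columns=samples["sample_id"].to_list())
    return count_df, samples, truth


# ---------------------------------------------------------------------------
# Haplotag molecules
# ---------------------------------------------------------------------------

@dataclass
class HaplotagSimConfig:
    """Generative parameters for barcoded linked-read molecules.

    Diagnostic variants are placed by a homogeneous Poisson process at
    ``variant_density`` per bp; molecules start uniformly on the chromosome
    with exponential lengths; a fraction ``recomb_fraction`` carry exactly one
    interspecific junction at a uniform position within the molecule.  Each
    spanned variant is observed with probability ``site_detection_prob`` and
    its species call flipped with probability ``call_error`` (symmetric).
    With probability ``collision_rate`` a molecule reuses the barcode of an
    earlier, independent molecule.
    """

    chrom: str = "chrS"
    chrom_length: int = 50_000_000
    variant_density: float = 1e-3
    n_molecules: int = 10_000
    molecule_length_mean: float = 50_000.0
    site_detection_prob: float = 0.9
    recomb_fraction: float = 0.001
    call_error: float = 0.002
    collision_rate: float = 0.0
    generations: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        check_positive("chrom_length", self.chrom_length)
        check_positive("variant_density", self.variant_density)
        check_positive("molecule_length_mean", self.molecule_length_mean)
        check_positive("generations", self.generations)
        if self.n_molecules < 0:
            raise ValueError("n_molecules must be >= 0")
        for name in ("site_detection_prob", "recomb_fraction", "call_error", "collision_rate"):
            check_prob(name, getattr(self, name))


def simulate_haplotag_molecules(
    cfg: HaplotagSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate barcoded per-site species observations.

    Returns
    -------
    observations : DataFrame (barcode, chrom, pos, base), one observed site
        per row; ``pos`` 1-based
    variants : DataFrame (chrom, pos, human_allele, chimp_allele), sorted
    truth : per-molecule DataFrame (molecule_id, barcode, start, end,
        species_start, is_recombinant, junction); junction is NaN for
        non-recombinant molecules and lies strictly inside (start, end)
    """
    cfg.validate()
    rng = child_rng(cfg.seed, "haplotag")

    n_var = rng.poisson(cfg.variant_density * cfg.chrom_length)
    var_pos = np.unique(rng.integers(1, cfg.chrom_length + 1, size=n_var))
    human_idx = rng.integers(0, 4, size=var_pos.size)
    # chimp allele differs from human allele by construction
    chimp_idx = (human_idx + rng.integers(1, 4, size=var_pos.size)) % 4
    human, chimp = _BASES[human_idx], _BASES[chimp_idx]
    variants = pd.DataFrame(
        {"chrom": cfg.chrom, "pos": var_pos, "human_allele": human, "chimp_allele": chimp}
    )

    n = cfg.n_molecules
    if n == 0:
        empty_obs = pd.DataFrame(columns=["barcode", "chrom", "pos", "base"])
        empty_truth = pd.DataFrame(
            columns=["molecule_id", "barcode", "start", "end",
                     "species_start", "is_recombinant", "junction"]
        )
        return empty_obs, variants, empty_truth

    length = np.maximum(1, rng.exponential(cfg.molecule_length_mean, size=n)).astype(np.int64)
    start = rng.integers(1, cfg.chrom_length + 1, size=n)
    end = np.minimum(start + length - 1, cfg.chrom_length)
    species_start = rng.choice(np.array(["H", "C"]), size=n)
    is_rec = (rng.random(n) < cfg.recomb_fraction) & (end > start)
    junction = np.full(n, np.nan)
    u = np.clip(rng.random(is_rec.sum()), 1e-9, 1 - 1e-9)
    junction[is_rec] = start[is_rec] + u * (end[is_rec] - start[is_rec])

    barcodes = np.array([f"BC{i:07d}" for i in range(n)])
    if cfg.collision_rate > 0 and n > 1:
        collide = rng.random(n) < cfg.collision_rate
        collide[0] = False
        idx = np.flatnonzero(collide)
        barcodes[idx] = barcodes[(rng.random(idx.size) * idx).astype(np.int64)]

    # spanned variants per molecule, via searchsorted into the sorted positions
    lo = np.searchsorted(var_pos, start, side="left")
    hi = np.searchsorted(var_pos, end, side="right")
    n_sites = hi - lo
    total = int(n_sites.sum())
    mol_idx = np.repeat(np.arange(n), n_sites)
    # within-molecule offsets 0..n_sites-1, without a Python loop
    site_idx = (np.arange(total) - np.repeat(np.cumsum(n_sites) - n_sites, n_sites)
                + np.repeat(lo, n_sites)) if total else np.empty(0, dtype=np.int64)

    keep = rng.random(site_idx.size) < cfg.site_detection_prob
    mol_idx, site_idx = mol_idx[keep], site_idx[keep]
    pos = var_pos[site_idx]

    left_of_junction = ~(pos > junction[mol_idx])  # NaN comparison -> left (no junction)
    call_h = np.where(
        left_of_junction, species_start[mol_idx] == "H", species_start[mol_idx] == "C"
    )
    flip = rng.random(mol_idx.size) < cfg.call_error
    call_h ^= flip
    base = np.where(call_h, human[site_idx], chimp[site_idx])

    observations = pd.DataFrame(
        {"barcode": barcodes[mol_idx], "chrom": cfg.chrom, "pos": pos, "base": base}
    )
    truth = pd.DataFrame(
        {
            "molecule_id": [f"M{i:07d}" for i in range(n)],
            "barcode": barcodes,
            "start": start,
            "end": end,
            "species_start": species_start,
            "is_recombinant": is_rec,
            "junction": junction,
        }
    )
    return observations, variants, truth


# ---------------------------------------------------------------------------
# Deletion panel
# ---------------------------------------------------------------------------

def default_chrom_genes(n: int = 100, chrom_length: int = 150_000_000,
                        baseline: float = 300.0) -> pd.DataFrame:
    """Evenly spaced focal-chromosome genes with a constant per-allele baseline."""
    pos = np.linspace(chrom_length / (n + 1), chrom_length * n / (n + 1), n).astype(np.int64)
    return pd.DataFrame(
        {"gene_id": [f"xgene{i:03d}" for i in range(n)], "position": pos,
         "baseline": baseline}
    )


@dataclass
class DeletionSimConfig:
    """Generative parameters for a species-specific terminal-deletion panel.

    Each deletion line loses one species' allele of every focal-chromosome
    gene distal to its breakpoint.  ``staggered_width`` models subclonal
    breakpoint heterogeneity: the per-cell breakpoint is uniform on
    [b - w/2, b + w/2], so genes inside that window retain an intermediate
    fraction of the targeted allele.  ``trans_targets`` maps autosomal gene id
    -> (group, log2 shift) applied to both alleles in that group's lines only,
    emulating loss of a trans regulator encoded on the deleted segment.
    """

    breakpoints_human: dict[str, float] = field(
        default_factory=lambda: {"hXdel1": 95_000_000.0, "hXdel2": 110_000_000.0}
    )
    breakpoints_chimp: dict[str, float] = field(
        default_factory=lambda: {"cXdel1": 140_000_000.0, "cXdel2": 148_000_000.0}
    )
    n_control: int = 3
    chrom: str = "chrX"
    chrom_genes: pd.DataFrame | None = None
    n_autosomal: int = 200
    autosomal_baseline: float = 300.0
    trans_targets: dict[str, tuple[str, float]] = field(default_factory=dict)
    staggered_width: float = 0.0
    dispersion: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_control < 2:
            raise ValueError("n_control must be >= 2 for test validity")
        for d in (self.breakpoints_human, self.breakpoints_chimp):
            if d and len(d) < 2:
                raise ValueError("each non-empty deletion group needs >= 2 lines")
        if self.staggered_width < 0:
            raise ValueError("staggered_width must be >= 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        genes = self.chrom_genes if self.chrom_genes is not None else default_chrom_genes()
        span = (genes["position"].min(), genes["position"].max())
        for line, bp in {**self.breakpoints_human, **self.breakpoints_chimp}.items():
            check_finite(f"breakpoint[{line}]", bp)
            if not span[0] <= bp <= span[1]:
                raise ValueError(
                    f"breakpoint {bp} of line {line} outside gene span {span}"
                )
        for gene, (group, shift) in self.trans_targets.items():
            if group not in ("deletion_human", "deletion_chimp"):
                raise ValueError(f"trans target {gene}: unknown group {group}")
            check_finite(f"trans shift[{gene}]", shift)


def retained_fraction(position: np.ndarray, breakpoint: float, width: float) -> np.ndarray:
    """Expected retained fraction of the targeted allele at each gene.

    The per-cell breakpoint is uniform on [b - w/2, b + w/2] and a gene is
    retained in a cell iff it lies proximal to (<=) the cell's breakpoint.
    """
    position = np.asarray(position, dtype=float)
    if width == 0:
        return (position <= breakpoint).astype(float)
    return np.clip((breakpoint + width / 2.0 - position) / width, 0.0, 1.0)


def simulate_deletion_panel(
    cfg: DeletionSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, pd.DataFrame], pd.DataFrame]:
    """Simulate an allele-resolved deletion panel.

    Returns
    -------
    counts : DataFrame, genes x samples; samples are line/allele pairs
    samples : DataFrame (sample_id, line, group, allele)
    tracks : dict line -> AlleleRatioTrack DataFrame (position, count_human,
        count_chimp) over the focal-chromosome genes
    truth : DataFrame (line, group, breakpoint, staggered_width); one row per
        line, breakpoint NaN for controls
    """
    cfg.validate()
    rng = child_rng(cfg.seed, "deletion")
    genes = (cfg.chrom_genes if cfg.chrom_genes is not None else default_chrom_genes()).copy()
    pos = genes["position"].to_numpy(dtype=float)

    lines: list[tuple[str, str, float]] = []  # (line, group, breakpoint)
    for line, bp in cfg.breakpoints_human.items():
        lines.append((line, "deletion_human", bp))
    for line, bp in cfg.breakpoints_chimp.items():
        lines.append((line, "deletion_chimp", bp))
    for i in range(cfg.n_control):
        lines.append((f"ctrl{i+1}", "control", np.nan))

    auto = pd.DataFrame(
        {"gene_id": [f"agene{i:03d}" for i in range(cfg.n_autosomal)],
         "baseline": cfg.autosomal_baseline}
    )
    all_genes = genes["gene_id"].to_list() + auto["gene_id"].to_list()

    sample_rows, columns = [], {}
    for line, group, bp in lines:
        for allele, species in (("human", "H"), ("chimp", "C")):
            sid = f"{line}_{allele}"
            sample_rows.append((sid, line, group, allele))
            mean_x = genes["baseline"].to_numpy(dtype=float).copy()
            targeted = (group == "deletion_human" and allele == "human") or (
                group == "deletion_chimp" and allele == "chimp"
            )
            if targeted:
                mean_x *= retained_fraction(pos, bp, cfg.staggered_width)
            mean_a = auto["baseline"].to_numpy(dtype=float).copy()
            for gene, (tgt_group, shift) in cfg.trans_targets.items():
                if group == tgt_group:
                    mean_a[auto["gene_id"] == gene] *= 2.0**shift
            mean = np.concatenate([mean_x, mean_a])
            columns[sid] = nb_draw(rng, mean, cfg.dispersion)

    samples = pd.DataFrame(sample_rows, columns=["sample_id", "line", "group", "allele"])
    counts = pd.DataFrame(columns, index=pd.Index(all_genes, name="gene_id"))

    tracks = {}
    nx = len(genes)
    for line, group, bp in lines:
        tracks[line] = pd.DataFrame(
            {
                "position": genes["position"].to_numpy(),
                "count_human": counts[f"{line}_human"].to_numpy()[:nx],
                "count_chimp": counts[f"{line}_chimp"].to_numpy()[:nx],
            }
        )
    truth = pd.DataFrame(
        [(line, group, bp, cfg.staggered_width if group != "control" else 0.0)
         for line, group, bp in lines],
        columns=["line", "group", "breakpoint", "staggered_width"],
    )
    return counts, samples, tracks, truth
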