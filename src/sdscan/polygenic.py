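"""Polygenic selection test: QTL effect sizes versus trait-polarized sSDS.

If a trait is under directional polygenic selection, variants with larger
effects on it should show stronger selection signals, producing a positive
correlation between a QTL's effect-size proxy (|log10 of its association
P-value|) and the trait-polarized sSDS of the nearest scored SNP.  Because
sSDS is autocorrelated along the genome through linkage disequilibrium, the
observed Spearman correlation is compared against a permutation null that
resamples genome-wide sSDS scores matched on chromosome and derived-allele
frequency bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sds import trait_polarize

logger = logging.getLogger(__name__)

_ORIENTATIONS = ("derived", "ancestral", "unknown")


@dataclass
class QtlRecord:
    """One trait QTL from an association study or meta-analysis."""

    trait: str
    chromosome: str
    position: int
    p_value: float
    trait_increasing_allele: str
    populations_supported: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"QTL p-value must be in (0,1], got {self.p_value}")
        if self.trait_increasing_allele not in _ORIENTATIONS:
            raise ValueError(f"orientation must be one of {_ORIENTATIONS}")

    @property
    def effect_proxy(self) -> float:
        return abs(np.log10(self.p_value))


@dataclass
class QtlSnpPair:
    """A QTL matched to its nearest scored SNP within the matching window."""

    qtl: QtlRecord
    snp_pos: int
    daf: float
    ssds: float
    tsds: float

    @property
    def effect_proxy(self) -> float:
        return self.qtl.effect_proxy


@dataclass
class CorrelationResult:
    spearman_rho: float
    p_value: float
    n_pairs: int
    slope: float
    permutation_p: float | None = None

    def __post_init__(self) -> None:
        if not -1.0 <= self.spearman_rho <= 1.0 + 1e-12:
            raise ValueError("rho outside [-1, 1]")


@dataclass
class PermutationResult:
    permutation_p: float
    rho_observed: float
    n_perm: int
    rho_permuted: np.ndarray = field(repr=False, default=None)


def read_qtl_tsv(path) -> list[QtlRecord]:
    """QTL table: trait, chrom, pos, p_value, trait_increasing_allele,
    populations_supported."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"trait", "chrom", "pos", "p_value", "trait_increasing_allele", "populations_supported"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"QTL TSV missing columns: {sorted(missing)}")
    return [
        QtlRecord(
            trait=str(r.trait),
            chromosome=str(r.chrom),
            position=int(r.pos),
            p_value=float(r.p_value),
            trait_increasing_allele=str(r.trait_increasing_allele),
            populations_supported=int(r.populations_supported),
        )
        for r in df.itertuples(index=False)
    ]


def build_qtl_snp_set(
    qtls: list[QtlRecord],
    scores: pd.DataFrame,
    window_bp: int = 10_000,
    min_pops: int = 6,
) -> tuple[list[QtlSnpPair], dict]:
    """Match QTLs with population support >= ``min_pops`` to scored SNPs.

    For each retained QTL the nearest scored SNP within +-``window_bp`` is
    selected (ties broken toward the lower coordinate).  QTLs with no SNP
    in the window, or with unknown trait orientation, are dropped and
    counted in the returned diagnostics.
    """
    diagnostics = {"n_input": len(qtls), "n_low_support": 0, "n_no_snp_in_window": 0,
                   "n_unknown_orientation": 0, "n_paired": 0}
    pairs: list[QtlSnpPair] = []
    by_chrom = {str(c): sub.sort_values("pos") for c, sub in scores.groupby("chrom")}
    for qtl in qtls:
        if qtl.populations_supported < min_pops:
            diagnostics["n_low_support"] += 1
            continue
        sub = by_chrom.get(qtl.chromosome)
        if sub is None or not len(sub):
            diagnostics["n_no_snp_in_window"] += 1
            continue
        pos = sub["pos"].to_numpy()
        dist = np.abs(pos - qtl.position)
        in_win = dist <= window_bp
        if not in_win.any():
            diagnostics["n_no_snp_in_window"] += 1
            continue
        cand = np.flatnonzero(in_win)
        best = cand[np.lexsort((pos[cand], dist[cand]))][0]  # min distance, tie -> lower coord
        if qtl.trait_increasing_allele == "unknown":
            diagnostics["n_unknown_orientation"] += 1
            continue
        ssds = float(sub["ssds"].to_numpy()[best])
        tsds = float(trait_polarize(ssds, qtl.trait_increasing_allele)[0])
        pairs.append(QtlSnpPair(qtl=qtl, snp_pos=int(pos[best]), daf=float(sub["daf"].to_numpy()[best]),
                                ssds=ssds, tsds=tsds))
    diagnostics["n_paired"] = len(pairs)
    if not pairs:
        raise ValueError(f"no QTL could be paired with a scored SNP: {diagnostics}")
    logger.info("QTL-SNP matching: %s", diagnostics)
    return pairs, diagnostics


def _rank_rho(x_rank: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho via Pearson correlation of (midranked) values; a
    degenerate (constant) margin yields rho 0."""
    y_rank = stats.rankdata(y)
    xc = x_rank - x_rank.mean()
    yc = y_rank - y_rank.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    return float((xc * yc).sum() / denom) if denom > 0 else 0.0


def polygenic_correlation_test(
    pairs: list[QtlSnpPair],
    drop_outlier: bool = False,
) -> CorrelationResult:
    """Spearman correlation of (effect proxy, tSDS) with an OLS trend slope.

    ``drop_outlier`` removes the single pair with the most extreme effect
    proxy (a QTL with an extremely low association P-value can dominate the
    trend line).
    """
    if len(pairs) < 3:
        raise ValueError(f"need at least 3 QTL-SNP pairs, got {len(pairs)}")
    if drop_outlier:
        pairs = sorted(pairs, key=lambda p: p.effect_proxy)[:-1]
    x = np.array([p.effect_proxy for p in pairs])
    y = np.array([p.tsds for p in pairs])
    rho, p = stats.spearmanr(x, y)
    slope = float(np.polyfit(x, y, 1)[0])
    return CorrelationResult(spearman_rho=float(rho), p_value=float(p), n_pairs=len(pairs), slope=slope)


def permutation_null_test(
    pairs: list[QtlSnpPair],
    genome_scores: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | None = None,
    bin_width: float = 0.05,
    sign_rule: str = "random",
) -> PermutationResult:
    """Chromosome- and frequency-matched permutation null for Spearman rho.

    Each permutation replaces every QTL SNP's tSDS by the sSDS of a
    uniformly drawn genome SNP from the same chromosome and derived-allele
    frequency bin (the QTL-matched SNPs themselves are excluded from the
    draw pool, so each stratum's marginal sSDS distribution is preserved).
    Replacement scores carry no trait annotation; under
    ``sign_rule='random'`` their sign is flipped with probability 1/2 per
    draw (the orientation of a random SNP relative to the trait is
    arbitrary), while ``'inherit'`` applies the original QTL's orientation.
    The one-sided upper-tail empirical p uses the add-one correction:
    p = (1 + #{rho_perm >= rho_obs}) / (1 + n_perm).
    """
    if sign_rule not in ("random", "inherit"):
        raise ValueError("sign_rule must be 'random' or 'inherit'")
    n_bins = int(np.ceil(1.0 / bin_width))
    chrom = genome_scores["chrom"].astype(str).to_numpy()
    daf = genome_scores["daf"].to_numpy(dtype=float)
    ssds = genome_scores["ssds"].to_numpy(dtype=float)
    pos = genome_scores["pos"].to_numpy()
    bins = np.minimum((daf / bin_width).astype(int), n_bins - 1)
    qtl_positions = {(p.qtl.chromosome, p.snp_pos) for p in pairs}
    is_qtl_snp = np.array([(c, int(p_)) in qtl_positions for c, p_ in zip(chrom, pos)],
                          dtype=bool)

    pools: list[np.ndarray] = []
    for p in pairs:
        b = min(int(p.daf / bin_width), n_bins - 1)
        sel = (chrom == p.qtl.chromosome) & (bins == b) & ~is_qtl_snp & np.isfinite(ssds)
        pool = ssds[sel]
        if pool.size == 0:
            raise ValueError(
                f"empty permutation stratum: chromosome {p.qtl.chromosome}, "
                f"DAF bin [{b * bin_width:.2f}, {(b + 1) * bin_width:.2f})"
            )
        pools.append(pool)

    rng = np.random.default_rng(seed)
    x_rank = stats.rankdata([p.effect_proxy for p in pairs])
    rho_obs = _rank_rho(x_rank, np.array([p.tsds for p in pairs]))

    n_pairs = len(pairs)
    draws = np.empty((n_perm, n_pairs))
    for j, pool in enumerate(pools):
        draws[:, j] = pool[rng.integers(0, pool.size, size=n_perm)]
    if sign_rule == "random":
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n_pairs))
    else:
        signs = np.array([1.0 if p.qtl.trait_increasing_allele == "derived" else -1.0 for p in pairs])
        signs = np.broadcast_to(signs, (n_perm, n_pairs))
    perm_tsds = draws * signs

    y_rank = stats.rankdata(perm_tsds, axis=1)
    xc = x_rank - x_rank.mean()
    yc = y_rank - y_rank.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho_perm = np.where(denom > 0, (yc @ xc) / denom, 0.0)

    permutation_p = float((1 + np.sum(rho_perm >= rho_obs)) / (1 + n_perm))
    return PermutationResult(permutation_p=permutation_p, rho_observed=rho_obs,
                             n_perm=n_perm, rho_permuted=rho_perm)


def pairs_to_frame(pairs: list[QtlSnpPair]) -> pd.DataFrame:
    """Per-pair table for trend-line plots and downstream inspection."""
    return pd.DataFrame({
        "trait": [p.qtl.trait for p in pairs],
        "chrom": [p.qtl.chromosome for p in pairs],
        "qtl_pos": [p.qtl.position for p in pairs],
        "snp_pos": [p.snp_pos for p in pairs],
        "daf": [p.daf for p in pairs],
        "qtl_p_value": [p.qtl.p_value for p in pairs],
        "effect_proxy": [p.effect_proxy for p in pairs],
        "orientation": [p.qtl.trait_increasing_allele for p in pairs],
        "ssds": [p.ssds for p in pairs],
        "tsds": [p.tsds for p in pairs],
    })
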