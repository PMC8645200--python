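"""Singleton-density score (SDS) computation and genome-scan machinery.

The SDS contrasts the density of singletons flanking carriers of the
derived allele at a test SNP with that flanking carriers of the ancestral
allele.  Recent selection favouring the derived allele shortens the
external (tip) branches of derived haplotypes, depleting their singletons
and lengthening the distance to the nearest singleton on either side.

Model
-----
Each haplotype's singletons are treated as a homogeneous point process with
intensity proportional to its tip length, so for an individual whose two
tips have lengths (tx, ty) the distance from the test SNP to the nearest
singleton on one side is Exponential with rate c*(tx+ty).  Genotype classes
at the test SNP map to tip-length pairs (ta,ta), (ta,td), (td,td) for 0, 1
and 2 derived copies; the heterozygote rate is therefore constrained to the
mean of the homozygote rates (additive tip lengths).  Distances censored at
the chromosome ends contribute exponential survival terms.  The raw score
is log(ta_hat) - log(td_hat): positive values mean shorter derived tips,
i.e. selection favouring the derived allele.

Raw scores are then standardized to mean 0 / SD 1 within bins of
derived-allele frequency ("sSDS"), assigned normal-tail p-values with
Benjamini-Hochberg and Bonferroni control, and optionally re-signed so a
positive score reflects a trait-increasing effect ("tSDS").
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .variants import MISSING, GenotypePanel, SingletonSet

logger = logging.getLogger(__name__)

_LOG_RATIO_BOUND = 25.0


@dataclass
class GapObservations:
    """Per-individual flanking-singleton distances at one test SNP.

    Arrays are aligned over individuals with a called genotype; censored
    gaps run to the chromosome end on that side.
    """

    genotype: np.ndarray
    up_gap: np.ndarray
    down_gap: np.ndarray
    up_censored: np.ndarray
    down_censored: np.ndarray
    n_excluded_missing: int = 0

    def __post_init__(self) -> None:
        self.genotype = np.asarray(self.genotype, dtype=np.int8)
        self.up_gap = np.asarray(self.up_gap, dtype=float)
        self.down_gap = np.asarray(self.down_gap, dtype=float)
        self.up_censored = np.asarray(self.up_censored, dtype=bool)
        self.down_censored = np.asarray(self.down_censored, dtype=bool)
        if np.any(self.up_gap <= 0) or np.any(self.down_gap <= 0):
            raise ValueError("gaps must be positive")

    @property
    def n_individuals(self) -> int:
        return int(self.genotype.size)

    def n_with_uncensored_side(self) -> int:
        return int(np.sum(~self.up_censored | ~self.down_censored))

    def swap_labels(self) -> "GapObservations":
        """Relabel genotype classes 0 <-> 2 (ancestral/derived exchange)."""
        return GapObservations(
            genotype=2 - self.genotype,
            up_gap=self.up_gap,
            down_gap=self.down_gap,
            up_censored=self.up_censored,
            down_censored=self.down_censored,
            n_excluded_missing=self.n_excluded_missing,
        )


def singleton_gaps(
    test_pos: int,
    singletons: SingletonSet,
    chrom_length: int,
    genotypes: np.ndarray,
) -> GapObservations:
    """Distances from ``test_pos`` to each individual's nearest singleton.

    A singleton at ``test_pos`` itself is ignored.  With no singleton on a
    side, the gap is censored at the distance to coordinate 1 (upstream) or
    ``chrom_length`` (downstream).  Individuals with a missing genotype at
    the test SNP are excluded and counted.
    """
    genotypes = np.asarray(genotypes)
    keep = genotypes != MISSING
    n_missing = int((~keep).sum())

    gt, up, down, upc, downc = [], [], [], [], []
    for i in np.flatnonzero(keep):
        s = singletons.positions_for(int(i))
        j = np.searchsorted(s, test_pos)
        # upstream: greatest singleton position strictly < test_pos
        if j > 0:
            up.append(test_pos - int(s[j - 1]))
            upc.append(False)
        else:
            up.append(max(test_pos - 1, 1))
            upc.append(True)
        # downstream: smallest singleton position strictly > test_pos
        k = j
        while k < s.size and s[k] == test_pos:
            k += 1
        if k < s.size:
            down.append(int(s[k]) - test_pos)
            downc.append(False)
        else:
            down.append(max(chrom_length - test_pos, 1))
            downc.append(True)
        gt.append(int(genotypes[i]))

    return GapObservations(
        genotype=np.array(gt, dtype=np.int8),
        up_gap=np.array(up, dtype=float),
        down_gap=np.array(down, dtype=float),
        up_censored=np.array(upc, dtype=bool),
        down_censored=np.array(downc, dtype=bool),
        n_excluded_missing=n_missing,
    )


def _sufficient_stats(gaps: GapObservations) -> tuple[np.ndarray, np.ndarray]:
    """Per genotype class g: U[g] uncensored sides, T[g] total gap length."""
    U = np.zeros(3)
    T = np.zeros(3)
    for g in (0, 1, 2):
        sel = gaps.genotype == g
        U[g] = np.sum(sel & ~gaps.up_censored) + np.sum(sel & ~gaps.down_censored)
        T[g] = gaps.up_gap[sel].sum() + gaps.down_gap[sel].sum()
    return U, T


def _profile_fit(U: np.ndarray, T: np.ndarray) -> float | None:
    """MLE of s = log(lambda2/lambda0) by 1-D profile likelihood.

    Given the rate ratio rho = e^s, the common scale has the closed form
    lambda0_hat = U_tot / (T0 + (1+rho)/2*T1 + rho*T2), so only the ratio
    needs numerical optimisation.  Returns None when either homozygote
    class lacks an uncensored observation: the heterozygote rate only
    constrains the sum of the class rates, so without a direct observation
    of one homozygote rate the profile likelihood can be maximised at an
    infinite log-ratio (the MLE escapes to the boundary with positive
    probability).  Both U0 > 0 and U2 > 0 guarantee an interior maximum.
    """
    if U[0] <= 0 or U[2] <= 0:
        return None
    U_tot = U.sum()

    def neg_profile(s: float) -> float:
        rho = np.exp(s)
        denom = T[0] + 0.5 * (1.0 + rho) * T[1] + rho * T[2]
        return -(U_tot * (np.log(U_tot) - np.log(denom)) + U[1] * np.log(0.5 * (1.0 + rho)) + U[2] * s)

    res = optimize.minimize_scalar(
        neg_profile, bounds=(-_LOG_RATIO_BOUND, _LOG_RATIO_BOUND), method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success or abs(res.x) >= _LOG_RATIO_BOUND - 1e-6:
        return None
    return -float(res.x)  # raw = log lambda0 - log lambda2 = -s_hat


def _log_ratio_se(raw: float, U: np.ndarray, T: np.ndarray) -> float:
    """Asymptotic SE of the log tip-length ratio from the observed Fisher
    information of the two-parameter likelihood in (log rate) coordinates.

    The information differs widely across test SNPs (local singleton
    density, genotype-class counts, censoring), so the ratio itself is not
    comparable between SNPs; the Wald-scaled score raw/SE is.
    """
    rho = np.exp(-raw)  # lambda2 / lambda0
    denom = T[0] + 0.5 * (1.0 + rho) * T[1] + rho * T[2]
    a = U.sum() / denom          # lambda0_hat
    b = a * rho                  # lambda2_hat
    lam1 = 0.5 * (a + b)
    cross = U[1] * (a * b / 4.0) / lam1**2
    j_uu = a * T[0] + 0.5 * a * T[1] - cross
    j_vv = b * T[2] + 0.5 * b * T[1] - cross
    j_uv = cross
    det = j_uu * j_vv - j_uv**2
    if det <= 0 or j_uu <= 0 or j_vv <= 0:
        return np.inf
    var = (j_uu + j_vv + 2.0 * j_uv) / det
    return float(np.sqrt(var)) if var > 0 else np.inf


def raw_sds(
    gaps: GapObservations,
    min_defined: int = 1,
    return_se: bool = False,
):
    """Raw SDS: log tip-length ratio (ancestral/derived) at one test SNP.

    Undefined (``None``) when fewer than ``min_defined`` individuals have
    an uncensored side, or when the rate ratio is unidentifiable.  The
    returned estimate is antisymmetrised, raw = (fit(D) - fit(swap(D)))/2,
    which coincides with the plain MLE in exact arithmetic and makes the
    genotype-label antisymmetry property hold to the last bit.  With
    ``return_se`` the asymptotic standard error of the log-ratio is also
    returned (label-swap invariant).
    """
    if gaps.n_with_uncensored_side() < max(min_defined, 1):
        return (None, None) if return_se else None
    U, T = _sufficient_stats(gaps)
    fwd = _profile_fit(U, T)
    rev = _profile_fit(U[::-1].copy(), T[::-1].copy())
    if fwd is None or rev is None:
        return (None, None) if return_se else None
    raw = 0.5 * (fwd - rev)
    if not return_se:
        return raw
    se = _log_ratio_se(raw, U, T)
    if not np.isfinite(se):
        return None, None
    return raw, se


def standardize_scores(
    raw: np.ndarray,
    daf: np.ndarray,
    bin_width: float = 0.05,
) -> np.ndarray:
    """z-score raw SDS within derived-allele-frequency bins ("sSDS").

    Uses the population SD (denominator n).  Bins with fewer than two
    defined scores are dropped (NaN) with a warning.  Output is aligned
    with the input; NaN marks dropped or undefined scores.
    """
    raw = np.asarray(raw, dtype=float)
    daf = np.asarray(daf, dtype=float)
    out = np.full(raw.shape, np.nan)
    if raw.size == 0:
        return out
    n_bins = int(np.ceil(1.0 / bin_width))
    bin_idx = np.minimum((daf / bin_width).astype(int), n_bins - 1)
    defined = np.isfinite(raw) & np.isfinite(daf)
    n_dropped = 0
    for b in np.unique(bin_idx[defined]):
        sel = defined & (bin_idx == b)
        n = int(sel.sum())
        if n < 2:
            n_dropped += n
            continue
        mu = raw[sel].mean()
        sd = raw[sel].std(ddof=0)
        if sd == 0:
            n_dropped += n
            continue
        out[sel] = (raw[sel] - mu) / sd
    if n_dropped:
        warnings.warn(f"{n_dropped} scores dropped from bins with <2 scores or zero spread")
    return out


def score_significance(
    ssds: np.ndarray,
    side: str = "upper",
    alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Normal-tail p-values, BH q-values and the Bonferroni cutoff.

    ``side='upper'`` targets significantly high sSDS (selection favouring
    derived alleles); ``'two_sided'`` is available for symmetric scans.
    """
    ssds = np.asarray(ssds, dtype=float)
    defined = np.isfinite(ssds)
    if not defined.any():
        raise ValueError("no defined sSDS values to test")
    if side == "upper":
        p_def = stats.norm.sf(ssds[defined])
    elif side == "two_sided":
        p_def = 2.0 * stats.norm.sf(np.abs(ssds[defined]))
    else:
        raise ValueError(f"side must be 'upper' or 'two_sided', got {side!r}")
    p = np.full(ssds.shape, np.nan)
    q = np.full(ssds.shape, np.nan)
    p[defined] = p_def
    q[defined] = stats.false_discovery_control(p_def, method="bh")
    bonferroni_cutoff = alpha / int(defined.sum())
    return p, q, bonferroni_cutoff


@dataclass
class GeneRecord:
    """Gene interval from an annotation (1-based closed)."""

    name: str
    chromosome: str
    start: int
    end: int
    biotype: str = "unknown"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.name}: start {self.start} > end {self.end}")


def read_genes_gff3(path) -> list[GeneRecord]:
    """Gene features from a GFF3 file, via an in-memory gffutils database."""
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")
    genes = []
    for feat in db.features_of_type("gene"):
        attrs = feat.attributes
        name = (attrs.get("Name") or attrs.get("gene_name") or attrs.get("gene_id") or attrs.get("ID") or [feat.id])[0]
        biotype = (attrs.get("biotype") or attrs.get("gene_biotype") or ["unknown"])[0]
        genes.append(GeneRecord(name=name, chromosome=feat.seqid, start=feat.start, end=feat.end, biotype=biotype))
    return genes


def annotate_candidate_genes(
    sig_snps: list[tuple[str, int]],
    genes: list[GeneRecord],
    flank_bp: int = 10_000,
) -> dict[tuple[str, int], list[GeneRecord]]:
    """Genes overlapping each SNP or within ``flank_bp`` of it.

    A gene is returned for a SNP when its interval expanded by ``flank_bp``
    on both sides (closed) contains the SNP position.  Lists are
    deduplicated and sorted by (chromosome, start, name).
    """
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    out: dict[tuple[str, int], list[GeneRecord]] = {}
    for chrom, pos in sig_snps:
        hits = {
            (g.chromosome, g.start, g.end, g.name): g
            for g in by_chrom.get(chrom, [])
            if g.start - flank_bp <= pos <= g.end + flank_bp
        }
        out[(chrom, pos)] = sorted(hits.values(), key=lambda g: (g.chromosome, g.start, g.name))
    return out


def trait_polarize(ssds: np.ndarray, trait_increasing_allele) -> np.ndarray:
    """Re-sign sSDS so positive values reflect a trait-increasing effect.

    ``trait_increasing_allele`` entries are 'derived', 'ancestral' or
    'unknown'; unknown orientations yield NaN (excluded, counted by the
    caller).
    """
    ssds = np.atleast_1d(np.asarray(ssds, dtype=float))
    orient = np.atleast_1d(np.asarray(trait_increasing_allele, dtype=object))
    if orient.size == 1 and ssds.size > 1:
        orient = np.repeat(orient, ssds.size)
    out = np.full(ssds.shape, np.nan)
    for i, o in enumerate(orient):
        if o == "derived":
            out[i] = ssds[i]
        elif o == "ancestral":
            out[i] = -ssds[i]
        elif o != "unknown":
            raise ValueError(f"unknown orientation label {o!r}")
    return out


def genome_scan(
    panels: dict[str, GenotypePanel],
    singleton_sets: dict[str, SingletonSet],
    maf_min: float = 0.05,
    bin_width: float = 0.05,
    max_censored_individuals: int = 10,
    side: str = "upper",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full sSDS scan: raw SDS per test SNP, pooled standardization, p/q.

    Test SNPs are those with minor-allele frequency above ``maf_min``.
    Scores are undefined when more than ``max_censored_individuals``
    individuals lack an uncensored side.  Chromosomes whose singleton set
    is too sparse to define any score are skipped with a warning.
    Returns a table with columns chrom, pos, daf, raw, ssds, p, q.
    """
    frames = []
    for chrom in sorted(panels):
        panel = panels[chrom]
        ss = singleton_sets.get(chrom)
        if ss is None or panel.n_sites == 0:
            warnings.warn(f"chromosome {chrom}: no singletons or no sites; skipped")
            continue
        daf = panel.daf if panel.daf is not None else panel.compute_daf()
        maf = np.minimum(daf, 1.0 - daf)
        test_idx = np.flatnonzero(maf > maf_min)
        min_defined = max(panel.n_samples - max_censored_individuals, 1)
        raws = np.full(test_idx.size, np.nan)
        walds = np.full(test_idx.size, np.nan)
        for k, i in enumerate(test_idx):
            gaps = singleton_gaps(int(panel.positions[i]), ss, panel.chrom_length, panel.dosage[i])
            score, se = raw_sds(gaps, min_defined=min_defined, return_se=True)
            if score is not None:
                raws[k] = score
                walds[k] = score / se
        n_def = int(np.isfinite(raws).sum())
        if n_def == 0:
            warnings.warn(
                f"chromosome {chrom}: insufficient singletons to define any SDS score; skipped"
            )
            continue
        logger.info("chromosome %s: %d/%d test SNPs scored", chrom, n_def, test_idx.size)
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "pos": panel.positions[test_idx],
            "daf": daf[test_idx],
            "raw": raws,
            "wald": walds,
        }))

    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "daf", "raw", "wald", "ssds", "p", "q"])
    scores = pd.concat(frames, ignore_index=True)
    scores = scores[np.isfinite(scores["raw"])].reset_index(drop=True)
    # standardize the information-scaled score: the log-ratio's sampling
    # spread varies across SNPs, the Wald score's does not
    scores["ssds"] = standardize_scores(scores["wald"].to_numpy(), scores["daf"].to_numpy(), bin_width)
    scores = scores[np.isfinite(scores["ssds"])].reset_index(drop=True)
    if len(scores):
        p, q, cutoff = score_significance(scores["ssds"].to_numpy(), side=side, alpha=alpha)
        scores["p"] = p
        scores["q"] = q
        scores.attrs["bonferroni_cutoff"] = cutoff
    return scores
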