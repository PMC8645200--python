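"""Coalescent simulation studies: tip-age timescale and sweep-detection power.

Two questions are addressed here.  First, over what timescale can a
singleton-based statistic detect selection?  Singletons arise on the
external (tip) branches of the genealogy, so the mean tip age under the
population's demography sets the look-back horizon; it is estimated by
simulating single-locus genealogies and extrapolated across sample sizes
with a log-log linear fit.  Second, how much power is there to detect a
partial sweep in a bottlenecked population?  A 10-Mb (configurable) region
is simulated with and without a sweep at its midpoint, the full
singleton-density scoring pipeline is run at the sweep site, and
singleton-count and Watterson-Ne summaries quantify how the bottleneck
depletes the signal.

The demography models ship as editable JSON epoch lists.  The Holstein
epoch parameters are a documented placeholder (log-spaced decline from an
ancestral diploid Ne of ~70,000 over the ~2,000 generations since
domestication to a present-day Ne of 793, or 49 for the pedigree-based
variant); substitute published epochs to reproduce literature values.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources

import msprime
import numpy as np
import pandas as pd
from scipy import stats

from .variants import GenotypePanel, SingletonSet, extract_singletons
from . import sds as _sds

logger = logging.getLogger(__name__)

_SEED_MAX = 2**31 - 2


@dataclass
class DemographicModel:
    """Piecewise-constant diploid Ne epochs, most recent first.

    ``epochs`` is a list of (start generation before present, diploid Ne)
    with starts strictly increasing from 0.
    """

    epochs: list[tuple[float, float]]
    generation_time_years: float = 5.0
    label: str = "custom"

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("at least one epoch required")
        starts = [t for t, _ in self.epochs]
        if starts[0] != 0:
            raise ValueError("first epoch must start at generation 0")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("epoch starts must be strictly increasing")
        if any(ne <= 0 for _, ne in self.epochs):
            raise ValueError("all Ne must be positive")

    @property
    def present_ne(self) -> float:
        return self.epochs[0][1]

    @property
    def deepest_epoch_start(self) -> float:
        return self.epochs[-1][0]

    def to_msprime(self) -> msprime.Demography:
        dem = msprime.Demography()
        dem.add_population(name="pop0", initial_size=self.present_ne)
        for t, ne in self.epochs[1:]:
            dem.add_population_parameters_change(time=t, initial_size=ne)
        return dem

    def deferred(self, min_change_time: float) -> "DemographicModel":
        """Push every size change earlier than ``min_change_time`` back to it.

        Used for sweep simulations: the structured sweep coalescent cannot
        process demographic events mid-sweep, so the population is held at
        present-day Ne until the sweep phase has safely completed.
        """
        kept = [(0.0, self.present_ne)]
        deferred_ne = None
        for t, ne in self.epochs[1:]:
            if t < min_change_time:
                deferred_ne = ne
            else:
                if deferred_ne is not None:
                    kept.append((float(min_change_time), deferred_ne))
                    deferred_ne = None
                kept.append((float(t), ne))
        if deferred_ne is not None:
            kept.append((float(min_change_time), deferred_ne))
        return DemographicModel(epochs=kept, generation_time_years=self.generation_time_years,
                                label=f"{self.label}_deferred")

    @classmethod
    def constant(cls, ne: float, generation_time_years: float = 5.0) -> "DemographicModel":
        return cls(epochs=[(0.0, float(ne))], generation_time_years=generation_time_years,
                   label=f"constant_{ne:g}")

    @classmethod
    def from_dict(cls, d: dict) -> "DemographicModel":
        return cls(
            epochs=[(float(t), float(ne)) for t, ne in d["epochs"]],
            generation_time_years=float(d.get("generation_time_years", 5.0)),
            label=str(d.get("label", "custom")),
        )

    @classmethod
    def from_file(cls, path) -> "DemographicModel":
        """JSON {'epochs': [[t, Ne], ...], ...} or two-column TSV (t, Ne)."""
        text = open(path).read()
        try:
            return cls.from_dict(json.loads(text))
        except json.JSONDecodeError:
            rows = [line.split() for line in text.splitlines()
                    if line.strip() and not line.startswith("#")]
            return cls(epochs=[(float(t), float(ne)) for t, ne in rows])

    @classmethod
    def high_n0(cls) -> "DemographicModel":
        """Holstein-style decline with present-day diploid Ne 793 (placeholder epochs)."""
        return _load_packaged("holstein_high_n0.json")

    @classmethod
    def low_n0(cls) -> "DemographicModel":
        """Same decline with present-day diploid Ne 49 (placeholder epochs)."""
        return _load_packaged("holstein_low_n0.json")


def _load_packaged(name: str) -> DemographicModel:
    with resources.files("sdscan").joinpath("data", name).open() as fh:
        return DemographicModel.from_dict(json.load(fh))


@dataclass
class TipAgePoint:
    n_haplotypes: int
    mean_tip_age: float
    ci_low: float
    ci_high: float
    replicates: int

    def __post_init__(self) -> None:
        if self.mean_tip_age <= 0:
            raise ValueError("mean tip age must be positive")
        if not (self.ci_low <= self.mean_tip_age <= self.ci_high):
            raise ValueError("confidence interval must contain the mean")


def mean_tip_age(
    model: DemographicModel,
    n_haplotypes: int,
    replicates: int,
    seed: int | None = None,
) -> TipAgePoint:
    """Mean external-branch length (generations) over simulated genealogies.

    Simulates single-locus, non-recombining genealogies of ``n_haplotypes``
    sampled haploid genomes on the diploid time scale, averages the tip
    (first-coalescence) age over all tips and replicates, and reports a
    normal-approximation 95% CI over replicate means.
    """
    if n_haplotypes < 2:
        raise ValueError("need at least 2 haplotypes")
    if replicates < 1:
        raise ValueError("need at least 1 replicate")
    reps = msprime.sim_ancestry(
        samples=[msprime.SampleSet(n_haplotypes, ploidy=1)],
        ploidy=2,
        demography=model.to_msprime(),
        num_replicates=replicates,
        random_seed=seed,
    )
    means = np.empty(replicates)
    for r, ts in enumerate(reps):
        tree = ts.first()
        parents = tree.parent_array
        times = ts.nodes_time
        samp = ts.samples()
        means[r] = float(np.mean(times[parents[samp]] - times[samp]))
    mean = float(means.mean())
    half = 1.96 * float(means.std(ddof=1)) / np.sqrt(replicates) if replicates > 1 else 0.0
    return TipAgePoint(n_haplotypes=n_haplotypes, mean_tip_age=mean,
                       ci_low=mean - half, ci_high=mean + half, replicates=replicates)


@dataclass
class ScalingFit:
    slope: float
    intercept: float
    r_squared: float
    predict_n: int
    predicted_tip_age: float


def fit_tip_age_scaling(points: list[TipAgePoint], predict_n: int) -> ScalingFit:
    """Least-squares fit of log(mean tip age) on log(n); extrapolated at
    ``predict_n`` (e.g. the number of alleles in the real cohort)."""
    if len(points) < 3 or len({p.n_haplotypes for p in points}) < 3:
        raise ValueError("need at least 3 points with distinct sample sizes")
    if any(p.mean_tip_age <= 0 for p in points):
        raise ValueError("tip ages must be positive")
    x = np.log([p.n_haplotypes for p in points])
    y = np.log([p.mean_tip_age for p in points])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return ScalingFit(slope=float(slope), intercept=float(intercept), r_squared=r2,
                      predict_n=predict_n,
                      predicted_tip_age=float(np.exp(intercept + slope * np.log(predict_n))))


#: cattle-like per-bp per-generation mutation rate used as the standard rate
STANDARD_MU = 1.2e-8
#: mutation/recombination ratio (cattle has several informative SNPs per haplotype)
MU_OVER_R = 3.25


@dataclass
class SweepSimConfig:
    """Partial-sweep simulation at the midpoint of a genomic region."""

    region_length: int = 10_000_000
    # a young partial sweep: at s = 0.3 the sweep phase lasts ~20 generations,
    # inside the singleton-based detection horizon of a bottlenecked cohort;
    # slower sweeps outlive the tip timescale and leave no singleton signal
    selection_coefficient: float = 0.3
    current_frequency: float = 0.2
    mu: float = STANDARD_MU
    recombination_rate: float | None = None
    n_diploids: int = 102
    replicates: int = 100
    seed: int | None = None
    freq_tolerance: float = 0.05
    max_retries: int = 1000

    def __post_init__(self) -> None:
        if self.region_length <= 0 or self.mu < 0:
            raise ValueError("region length must be positive and rates non-negative")
        if not (0.0 < self.current_frequency < 1.0):
            raise ValueError("current derived frequency must be in (0,1)")
        if self.recombination_rate is None:
            # always derived from the standard rate: an elevated mu models a
            # hypermutable region, not elevated recombination
            self.recombination_rate = STANDARD_MU / MU_OVER_R

    @property
    def sweep_position(self) -> int:
        return self.region_length // 2


@dataclass
class SweepRegionResult:
    panel: GenotypePanel
    singletons: SingletonSet
    test_position: int
    test_daf: float
    retries: int
    selected: bool


class SweepConditioningError(RuntimeError):
    pass


def _sweep_duration_bound(s: float, n0: float) -> float:
    """Conservative bound on the sweep phase duration (generations)."""
    return 1.5 * (2.0 / max(s, 1e-9)) * np.log(max(2.0 * n0, 2.0))


def _plant_test_allele(ts, position: float, target: float, tol: float,
                       selected: bool, rng: np.random.Generator):
    """Place the test allele on a node of the local tree at ``position``.

    Candidate nodes are those whose sample fraction lies within ``tol`` of
    the target frequency.  In the selected case the sweeping clade is the
    candidate with the most recent MRCA (the swept lineages coalesced
    during the sweep; the root-sibling subtree at the complementary
    frequency is ancient).  In the neutral case a candidate is drawn with
    probability proportional to the branch length above it, i.e. how a
    neutral derived mutation at that frequency actually arises.  Returns
    (carrier sample ids, sample frequency) or None if no candidate exists.
    """
    tree = ts.at(position)
    n = ts.num_samples
    times = ts.nodes_time
    cands = [u for u in tree.nodes()
             if 0 < tree.num_samples(u) < n and abs(tree.num_samples(u) / n - target) <= tol]
    if not cands:
        return None
    if selected:
        best = min(cands, key=lambda u: times[u])
    else:
        weights = np.array([tree.branch_length(u) for u in cands], dtype=float)
        if not np.all(weights > 0):
            weights = np.ones(len(cands))
        best = cands[int(rng.choice(len(cands), p=weights / weights.sum()))]
    return np.fromiter(tree.samples(best), dtype=np.int64), tree.num_samples(best) / n


def simulate_sweep_region(
    cfg: SweepSimConfig,
    model: DemographicModel,
    selected: bool,
    mean_depth: float = 12.0,
) -> SweepRegionResult:
    """Simulate one replicate region and package it as a GenotypePanel.

    When ``selected``, a beneficial allele sweeps at the region midpoint,
    conditioned to segregate near the configured current frequency at
    sampling; the population is held at present-day Ne for the duration of
    the sweep phase (epoch changes are deferred past a conservative bound)
    because the structured sweep coalescent cannot process demographic
    events mid-sweep.  The neutral case uses the identical deferred
    demography so neutral/selected comparisons differ only by the sweep.
    In both cases the test SNP at the midpoint is planted on the genealogy
    node whose sample fraction is nearest the target frequency (rejection
    sampling within ``freq_tolerance``, bounded retries), giving a
    frequency-matched neutral control.  The emitted panel is polarized
    (simulation knows ancestral states) with noise-free depth fields.
    """
    s = cfg.selection_coefficient
    # defer epochs whenever a sweep arm exists so neutral/selected replicate
    # pairs share the identical demography
    bound = _sweep_duration_bound(s, model.present_ne) if s > 0 else 0.0
    rng = np.random.default_rng(cfg.seed)

    retries = 0
    while retries <= cfg.max_retries:
        msp_seed = int(rng.integers(1, _SEED_MAX))
        work_model = model.deferred(bound) if bound > 0 else model
        dem = work_model.to_msprime()
        if selected and s > 0:
            sweep = msprime.SweepGenicSelection(
                position=cfg.sweep_position,
                start_frequency=1.0 / (2.0 * model.present_ne),
                end_frequency=cfg.current_frequency,
                s=s,
                dt=1e-6,
            )
            sim_model = [sweep, msprime.StandardCoalescent()]
        else:
            sim_model = msprime.StandardCoalescent()
        try:
            ts = msprime.sim_ancestry(
                samples=cfg.n_diploids,
                demography=dem,
                sequence_length=cfg.region_length,
                recombination_rate=cfg.recombination_rate,
                model=sim_model,
                random_seed=msp_seed,
            )
        except Exception as exc:  # sweep phase outlived the deferral bound
            if "during a sweep" in str(exc):
                bound *= 2.0
                retries += 1
                continue
            raise
        planted = _plant_test_allele(ts, cfg.sweep_position, cfg.current_frequency,
                                     cfg.freq_tolerance, selected and s > 0, rng)
        if planted is None:
            retries += 1
            continue
        carriers, freq = planted
        mut_seed = int(rng.integers(1, _SEED_MAX))
        mts = msprime.sim_mutations(ts, rate=cfg.mu, random_seed=mut_seed)
        panel, test_pos = _panel_from_ts(mts, cfg, carriers, mean_depth)
        singletons = extract_singletons(panel)
        return SweepRegionResult(panel=panel, singletons=singletons, test_position=test_pos,
                                 test_daf=float(freq), retries=retries, selected=selected)
    raise SweepConditioningError(
        f"no genealogy node within {cfg.freq_tolerance} of frequency "
        f"{cfg.current_frequency} after {retries} retries"
    )


def _panel_from_ts(mts, cfg: SweepSimConfig, carriers: np.ndarray, mean_depth: float):
    """Biallelic derived-dosage panel from a mutated tree sequence, with the
    planted test allele inserted at the midpoint."""
    n_dip = cfg.n_diploids
    G = mts.genotype_matrix()  # (sites, 2*n_dip) allele indices per haplotype
    site_pos = (mts.tables.sites.position.astype(np.int64) + 1)  # 1-based

    test_pos = cfg.sweep_position + 1
    keep = site_pos != test_pos
    G = G[keep]
    site_pos = site_pos[keep]
    # collapse recurrent mutations at a site to presence/absence of a derived state
    G = np.minimum(G, 1)
    dosage = G[:, 0::2] + G[:, 1::2]

    test_hap = np.zeros(2 * n_dip, dtype=np.int8)
    test_hap[carriers] = 1
    test_dosage = (test_hap[0::2] + test_hap[1::2]).astype(np.int8)

    insert = np.searchsorted(site_pos, test_pos)
    positions = np.insert(site_pos, insert, test_pos)
    dosage = np.insert(dosage.astype(np.int8), insert, test_dosage, axis=0)

    # de-duplicate positions (distinct sites can round to the same bp)
    uniq, first_idx = np.unique(positions, return_index=True)
    panel = GenotypePanel(
        chromosome="sim",
        positions=uniq,
        samples=[f"ind{i}" for i in range(n_dip)],
        dosage=dosage[first_idx],
        site_depth=np.full(uniq.size, float(mean_depth)),
        allele_depths=None,
        chrom_length=int(cfg.region_length),
        polarized=True,
    )
    panel.compute_daf()
    return panel, test_pos


@dataclass
class WattersonEstimate:
    """Watterson's theta from segregating sites, converted to diploid Ne."""

    S: int
    n: int
    mu: float
    L: float
    a_n: float = field(init=False)
    theta_w: float = field(init=False)
    ne: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least 2 haplotypes")
        if self.mu <= 0 or self.L <= 0:
            raise ValueError("mu and L must be positive")
        self.a_n = float(np.sum(1.0 / np.arange(1, self.n)))
        self.theta_w = self.S / self.a_n
        self.ne = self.theta_w / (4.0 * self.mu * self.L)


def watterson_ne(S: int, n: int, mu: float, L: float) -> WattersonEstimate:
    return WattersonEstimate(S=int(S), n=int(n), mu=mu, L=L)


def constant_ne_watterson(
    ne: float,
    n_haplotypes: int,
    mu: float,
    L: float,
    recombination_rate: float = 0.0,
    replicates: int = 50,
    seed: int | None = None,
) -> list[WattersonEstimate]:
    """Watterson Ne estimates from neutral constant-size simulations.

    Recombination spreads the genealogical variance over many marginal
    trees, tightening the estimator around the simulated Ne.
    """
    rng = np.random.default_rng(seed)
    anc_seed = int(rng.integers(1, _SEED_MAX))
    reps = msprime.sim_ancestry(
        samples=[msprime.SampleSet(n_haplotypes, ploidy=1)],
        ploidy=2,
        population_size=ne,
        sequence_length=L,
        recombination_rate=recombination_rate,
        num_replicates=replicates,
        random_seed=anc_seed,
    )
    out = []
    for ts in reps:
        mts = msprime.sim_mutations(ts, rate=mu, random_seed=int(rng.integers(1, _SEED_MAX)))
        out.append(watterson_ne(mts.num_sites, n_haplotypes, mu, L))
    return out


@dataclass
class PowerSummary:
    """Neutral-versus-selected contrasts at the sweep site."""

    singleton_means: dict
    zero_singleton_means: dict
    ssds: dict
    n_replicates: dict
    n_defined: dict
    ranksum_statistic: float | None
    ranksum_p: float | None
    comparison_skipped: bool

    def fraction_defined(self, case: str) -> float:
        return self.n_defined[case] / self.n_replicates[case]

    def table(self) -> pd.DataFrame:
        rows = []
        for case in ("neutral", "selected"):
            rows.append({
                "case": case,
                "replicates": self.n_replicates[case],
                "n_defined_sds": self.n_defined[case],
                "fraction_defined": self.fraction_defined(case),
                "mean_singletons_per_individual": float(np.mean(self.singleton_means[case])),
                "mean_zero_singleton_individuals": float(np.mean(self.zero_singleton_means[case])),
                "mean_ssds": float(np.mean(self.ssds[case])) if len(self.ssds[case]) else np.nan,
            })
        df = pd.DataFrame(rows)
        df.attrs["ranksum_p"] = self.ranksum_p
        return df


def rank_sum_compare(scores_a: np.ndarray, scores_b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) comparison."""
    res = stats.mannwhitneyu(scores_a, scores_b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def sweep_power_summary(
    neutral_results: list[SweepRegionResult],
    selected_results: list[SweepRegionResult],
    max_censored_individuals: int = 10,
    bin_width: float = 0.05,
) -> PowerSummary:
    """Score the sweep-site SNP in every replicate and contrast the cases.

    Raw SDS at the test SNP is computed per replicate (undefined replicates
    are recorded), raw scores from both cases are standardized together
    within DAF bins, and defined sSDS values are compared with a two-sided
    Wilcoxon rank-sum test.  Per-individual singleton counts (and the count
    of zero-singleton individuals) summarize the singleton depletion that
    drives undefined scores.
    """
    if not neutral_results or not selected_results:
        raise ValueError("need at least one replicate per case")

    cases = {"neutral": neutral_results, "selected": selected_results}
    singleton_means: dict[str, list] = {c: [] for c in cases}
    zero_means: dict[str, list] = {c: [] for c in cases}
    raws: dict[str, list] = {c: [] for c in cases}
    dafs: dict[str, list] = {c: [] for c in cases}
    n_def = {c: 0 for c in cases}

    for case, results in cases.items():
        for res in results:
            counts = res.singletons.counts_per_individual()
            singleton_means[case].append(float(counts.mean()))
            zero_means[case].append(int((counts == 0).sum()))
            panel = res.panel
            i = int(np.searchsorted(panel.positions, res.test_position))
            if i >= panel.n_sites or panel.positions[i] != res.test_position:
                raws[case].append(np.nan)
                dafs[case].append(res.test_daf)
                continue
            gaps = _sds.singleton_gaps(res.test_position, res.singletons, panel.chrom_length,
                                       panel.dosage[i])
            min_defined = max(panel.n_samples - max_censored_individuals, 1)
            score, se = _sds.raw_sds(gaps, min_defined=min_defined, return_se=True)
            raws[case].append(np.nan if score is None else score / se)
            dafs[case].append(res.test_daf)
            if score is not None:
                n_def[case] += 1

    all_raw = np.array(raws["neutral"] + raws["selected"], dtype=float)
    all_daf = np.array(dafs["neutral"] + dafs["selected"], dtype=float)
    ssds_all = _sds.standardize_scores(all_raw, all_daf, bin_width)
    k = len(raws["neutral"])
    ssds = {
        "neutral": ssds_all[:k][np.isfinite(ssds_all[:k])],
        "selected": ssds_all[k:][np.isfinite(ssds_all[k:])],
    }

    skipped = min(len(ssds["neutral"]), len(ssds["selected"])) == 0
    if skipped:
        logger.warning("all SDS scores undefined in at least one case; rank-sum comparison skipped")
        stat = pval = None
    else:
        stat, pval = rank_sum_compare(ssds["selected"], ssds["neutral"])

    return PowerSummary(
        singleton_means={c: np.array(v, float) for c, v in singleton_means.items()},
        zero_singleton_means={c: np.array(v, float) for c, v in zero_means.items()},
        ssds=ssds,
        n_replicates={c: len(v) for c, v in cases.items()},
        n_defined=n_def,
        ranksum_statistic=stat,
        ranksum_p=pval,
        comparison_skipped=skipped,
    )


def run_power_study(
    cfg: SweepSimConfig,
    model: DemographicModel,
    seed: int | None = None,
) -> PowerSummary:
    """Paired neutral/selected replicates under one configuration."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    neutral, selected = [], []
    for _ in range(cfg.replicates):
        s_neu = int(rng.integers(1, _SEED_MAX))
        s_sel = int(rng.integers(1, _SEED_MAX))
        cfg_n = SweepSimConfig(**{**cfg.__dict__, "seed": s_neu})
        cfg_s = SweepSimConfig(**{**cfg.__dict__, "seed": s_sel})
        neutral.append(simulate_sweep_region(cfg_n, model, selected=False))
        selected.append(simulate_sweep_region(cfg_s, model, selected=True))
    return sweep_power_summary(neutral, selected)
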