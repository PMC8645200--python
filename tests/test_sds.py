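"""SDS estimator, standardization, significance and gene annotation."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from sdscan import sds, variants
from sdscan.sds import (
    GapObservations,
    GeneRecord,
    annotate_candidate_genes,
    raw_sds,
    score_significance,
    singleton_gaps,
    standardize_scores,
    trait_polarize,
)
from sdscan.variants import MISSING, SingletonSet

from conftest import make_panel


def _singleton_set(per_individual, chrom_length=1_500_000):
    positions, carriers = [], []
    for i, plist in enumerate(per_individual):
        positions.extend(plist)
        carriers.extend([i] * len(plist))
    return SingletonSet("1", positions, carriers, None, len(per_individual), chrom_length)


class TestSingletonGaps:
    def test_flanking_distances(self):
        ss = _singleton_set([[900_000, 1_250_000]])
        g = singleton_gaps(1_000_000, ss, 1_500_000, np.array([0]))
        assert g.up_gap[0] == 100_000 and not g.up_censored[0]
        assert g.down_gap[0] == 250_000 and not g.down_censored[0]

    def test_censoring_at_chromosome_end(self):
        ss = _singleton_set([[900_000]])
        g = singleton_gaps(1_000_000, ss, 1_500_000, np.array([1]))
        assert g.down_gap[0] == 500_000 and g.down_censored[0]

    def test_singleton_at_test_position_ignored(self):
        ss = _singleton_set([[1_000_000]])
        g = singleton_gaps(1_000_000, ss, 1_500_000, np.array([2]))
        assert g.up_censored[0] and g.down_censored[0]

    def test_missing_genotype_excluded(self):
        ss = _singleton_set([[500], [600]])
        g = singleton_gaps(1000, ss, 2000, np.array([MISSING, 0]))
        assert g.n_individuals == 1
        assert g.n_excluded_missing == 1


def _two_class_gaps(mean_anc=50_000.0, mean_der=100_000.0, n=10):
    return GapObservations(
        genotype=[0] * n + [2] * n,
        up_gap=[mean_anc] * n + [mean_der] * n,
        down_gap=[mean_anc] * n + [mean_der] * n,
        up_censored=[False] * (2 * n),
        down_censored=[False] * (2 * n),
    )


def _random_gaps(seed, n=60, censor=0.2):
    rng = np.random.default_rng(seed)
    return GapObservations(
        genotype=rng.integers(0, 3, n),
        up_gap=rng.exponential(5e4, n) + 1,
        down_gap=rng.exponential(5e4, n) + 1,
        up_censored=rng.random(n) < censor,
        down_censored=rng.random(n) < censor,
    )


class TestRawSds:
    def test_closed_form_homozygote_example(self):
        """Two homozygote classes with per-side mean gaps 50 kb and 100 kb:
        the exponential MLE rate ratio is exactly 2."""
        assert raw_sds(_two_class_gaps()) == pytest.approx(np.log(2.0), abs=1e-6)

    def test_identical_gap_distributions_give_zero(self):
        assert raw_sds(_two_class_gaps(5e4, 5e4)) == 0.0

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_antisymmetry_exact(self, seed):
        g = _random_gaps(seed)
        fwd = raw_sds(g)
        rev = raw_sds(g.swap_labels())
        assert fwd is not None
        assert rev == -fwd  # bitwise, by construction of the estimator

    @given(seed=st.integers(0, 10_000), censor=st.floats(0.0, 0.6),
           n=st.integers(6, 120))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_antisymmetry_property(self, seed, censor, n):
        """Exchanging ancestral and derived labels negates the score (or
        leaves it undefined) for arbitrary gap data."""
        g = _random_gaps(seed, n=n, censor=censor)
        fwd = raw_sds(g)
        rev = raw_sds(g.swap_labels())
        if fwd is None:
            assert rev is None
        else:
            assert rev == -fwd

    def test_grid_oracle_with_censoring(self):
        """Full-likelihood grid search over both rates agrees with the
        profile-likelihood implementation on censored data."""
        g = _random_gaps(42, n=80, censor=0.3)
        est = raw_sds(g)

        def loglik(l0, l2):
            lam = {0: l0, 1: 0.5 * (l0 + l2), 2: l2}
            ll = 0.0
            for gt, up, down, upc, downc in zip(g.genotype, g.up_gap, g.down_gap,
                                                g.up_censored, g.down_censored):
                for gap, cens in ((up, upc), (down, downc)):
                    ll += -lam[gt] * gap if cens else np.log(lam[gt]) - lam[gt] * gap
            return ll

        # two-stage grid refinement on (log l0, log l2)
        center = np.log(1.0 / 5e4)
        u = v = np.linspace(center - 2, center + 2, 41)
        for _ in range(5):
            grid = np.array([[loglik(np.exp(a), np.exp(b)) for b in v] for a in u])
            i, j = np.unravel_index(np.argmax(grid), grid.shape)
            best = (u[i], v[j])
            span_u = (u[-1] - u[0]) / 8
            span_v = (v[-1] - v[0]) / 8
            u = np.linspace(best[0] - span_u, best[0] + span_u, 41)
            v = np.linspace(best[1] - span_v, best[1] + span_v, 41)
        oracle = best[0] - best[1]
        assert est == pytest.approx(oracle, abs=1e-3)

    def test_all_censored_undefined(self):
        g = GapObservations([0, 2], [100.0, 100.0], [100.0, 100.0],
                            [True, True], [True, True])
        assert raw_sds(g, min_defined=1) is None

    def test_min_defined_threshold(self):
        g = _two_class_gaps(n=5)
        assert raw_sds(g, min_defined=10) is not None
        assert raw_sds(g, min_defined=11) is None

    def test_homozygote_class_without_data_undefined(self):
        """With no uncensored homozygote-derived observation, the rate
        ratio's MLE can sit at infinity; the score must be undefined."""
        g = GapObservations([0, 0, 1], [1e4, 2e4, 3e4], [1e4, 2e4, 3e4],
                            [False] * 3, [False] * 3)
        assert raw_sds(g) is None

    def test_wald_se_is_swap_invariant(self):
        g = _random_gaps(7)
        r, se = raw_sds(g, return_se=True)
        r2, se2 = raw_sds(g.swap_labels(), return_se=True)
        assert se == pytest.approx(se2, rel=1e-12)
        assert se > 0


class TestStandardize:
    def test_two_score_bin(self):
        out = standardize_scores(np.array([1.0, 3.0]), np.array([0.31, 0.32]))
        np.testing.assert_allclose(out, [-1.0, 1.0])

    def test_zscore_identity_per_bin(self):
        rng = np.random.default_rng(0)
        raw = rng.normal(2.0, 3.0, 500)
        daf = rng.uniform(0.05, 0.95, 500)
        out = standardize_scores(raw, daf)
        bins = np.minimum((daf / 0.05).astype(int), 19)
        for b in np.unique(bins):
            sel = (bins == b) & np.isfinite(out)
            if sel.sum() >= 2:
                assert abs(out[sel].mean()) < 1e-12
                assert abs(out[sel].std(ddof=0) - 1.0) < 1e-12

    def test_empty_input(self):
        assert standardize_scores(np.array([]), np.array([])).size == 0

    def test_single_score_bin_dropped(self):
        with pytest.warns(UserWarning):
            out = standardize_scores(np.array([1.0, 5.0, 6.0]),
                                     np.array([0.1, 0.52, 0.53]))
        assert np.isnan(out[0]) and np.isfinite(out[1:]).all()


class TestSignificance:
    def test_normal_tail(self):
        p, q, _ = score_significance(np.array([0.0, 4.46]))
        assert p[0] == pytest.approx(0.5)
        assert p[1] == pytest.approx(stats.norm.sf(4.46))
        assert p[1] == pytest.approx(4.3e-6, rel=0.1)

    def test_bonferroni_cutoff_scale(self):
        m = 1_850_000
        rng = np.random.default_rng(1)
        _, _, cutoff = score_significance(rng.normal(size=m // 1000))
        assert cutoff == 0.05 / (m // 1000)
        # at a whole-autosome scan size the cutoff lands at ~2.7e-8
        assert 0.05 / m == pytest.approx(2.7e-8, rel=0.01)

    def test_two_sided_and_errors(self):
        p, _, _ = score_significance(np.array([1.5, -1.5]), side="two_sided")
        assert p[0] == pytest.approx(p[1])
        with pytest.raises(ValueError):
            score_significance(np.array([np.nan]))

    def test_bh_matches_stepup_oracle(self):
        """BH q-values equal a hand-written step-up implementation."""
        rng = np.random.default_rng(2)
        for _ in range(100):
            m = int(rng.integers(1, 60))
            p = rng.uniform(size=m)
            _, q, _ = score_significance(stats.norm.isf(p))  # p round-trips through sf
            order = np.argsort(p, kind="stable")
            ranked = p[order] * m / np.arange(1, m + 1)
            ranked = np.minimum.accumulate(ranked[::-1])[::-1]
            oracle = np.empty(m)
            oracle[order] = np.minimum(ranked, 1.0)
            np.testing.assert_allclose(q, oracle, rtol=1e-9, atol=1e-12)


class TestGenes:
    GENES = [
        GeneRecord("TDO2", "17", 43_386_894, 43_403_747, "protein_coding"),
        GeneRecord("FARAWAY", "17", 43_500_000, 43_600_000, "protein_coding"),
        GeneRecord("OTHERCHROM", "3", 1, 1_000, "protein_coding"),
    ]

    def test_overlapping_gene_returned(self):
        hits = annotate_candidate_genes([("17", 43_390_000)], self.GENES)
        assert [g.name for g in hits[("17", 43_390_000)]] == ["TDO2"]

    def test_no_gene_within_flank(self):
        hits = annotate_candidate_genes([("17", 43_450_000)], self.GENES)
        assert hits[("17", 43_450_000)] == []

    def test_closed_boundary_at_flank(self):
        # gene ends exactly flank_bp before the SNP -> still included
        snp = 43_403_747 + 10_000
        hits = annotate_candidate_genes([("17", snp)], self.GENES, flank_bp=10_000)
        assert [g.name for g in hits[("17", snp)]] == ["TDO2"]
        hits = annotate_candidate_genes([("17", snp + 1)], self.GENES, flank_bp=10_000)
        assert hits[("17", snp + 1)] == []


def test_trait_polarize_signs():
    out = trait_polarize(np.array([1.2, 1.2, 1.2]),
                         np.array(["derived", "ancestral", "unknown"]))
    assert out[0] == 1.2 and out[1] == -1.2 and np.isnan(out[2])


def test_read_genes_gff3(cohort):
    genes = sds.read_genes_gff3(cohort.paths["gff3"])
    assert len(genes) == len(cohort.genes)
    names = {g.name for g in genes}
    assert set(cohort.genes["name"]) == names
    assert all(g.start <= g.end for g in genes)


def test_genome_scan_skips_sparse_chromosome():
    """A chromosome whose singleton set defines no score is skipped with a
    warning rather than contaminating the output."""
    rng = np.random.default_rng(4)
    dosage = rng.integers(0, 3, size=(50, 12)).astype(np.int8)
    panel = make_panel(np.arange(1, 51) * 1000, dosage, polarized=True,
                       chrom_length=60_000)
    empty = SingletonSet("1", [], [], None, 12, 60_000)
    with pytest.warns(UserWarning, match="insufficient singletons"):
        scores = sds.genome_scan({"1": panel}, {"1": empty},
                                 max_censored_individuals=0)
    assert len(scores) == 0
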