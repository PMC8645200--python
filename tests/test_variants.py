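"""Variant filtering, OAR detection, polarization and singleton extraction."""

import warnings

import numpy as np
import pytest

from sdscan import variants
from sdscan.variants import MISSING, OarInterval

from conftest import make_panel, write_vcf


def _ten_site_records(clean_only=False):
    """10-site fixture on chromosome 1: 2 triallelic, 3 with mean depth
    outside [6, 24], 1 inside a planted OAR at [5000, 6000], 4 clean."""
    def calls(depth):
        return [("0/1", (depth // 2, depth - depth // 2)), ("0/0", (depth, 0)),
                ("1/1", (0, depth))]
    recs = []
    for i, pos in enumerate([1000, 1500, 2000, 2500, 3000, 3500, 4000, 4500, 5500, 7000]):
        alt, depth = "G", 12
        if not clean_only:
            if i in (0, 1):
                alt = "G,T"          # triallelic
            elif i in (2, 3):
                depth = 4            # below depth bounds
            elif i == 4:
                depth = 40           # above depth bounds
            # i == 8 (pos 5500) falls inside the planted OAR
        recs.append(("1", pos, "A", alt, calls(depth)))
    return recs


def test_load_and_filter_applies_each_filter(tmp_path):
    path = write_vcf(tmp_path / "ten.vcf", _ten_site_records(), ["a", "b", "c"],
                     {"1": 10_000})
    oar = OarInterval("1", 5000, 6000)
    panels = variants.load_and_filter_snps(path, depth_bounds=(6, 24), oars=[oar])
    panel = panels["1"]
    assert panel.n_sites == 4
    assert panel.filter_log["n_removed_depth"] == 3
    assert panel.filter_log["n_removed_oar"] == 1
    assert panel.filter_log["n_not_biallelic_snp_total"] == 2
    assert panel.chrom_length == 10_000


def test_load_and_filter_passthrough_and_empty(tmp_path):
    clean = write_vcf(tmp_path / "clean.vcf", _ten_site_records(clean_only=True),
                      ["a", "b", "c"], {"1": 10_000})
    panels = variants.load_and_filter_snps(clean, depth_bounds=(6, 24))
    assert panels["1"].n_sites == 10

    empty = write_vcf(tmp_path / "empty.vcf", [], ["a"], {"1": 10_000})
    assert variants.load_and_filter_snps(empty) == {}


def test_filter_order_insensitive(tmp_path):
    """Depth and OAR filters commute: both-orders equals the intersection."""
    path = write_vcf(tmp_path / "ten.vcf", _ten_site_records(), ["a", "b", "c"],
                     {"1": 10_000})
    oar = OarInterval("1", 5000, 6000)
    depth_only = variants.load_and_filter_snps(path, depth_bounds=(6, 24))["1"].positions
    oar_only = variants.load_and_filter_snps(path, depth_bounds=(1, 1000), oars=[oar])["1"].positions
    both = variants.load_and_filter_snps(path, depth_bounds=(6, 24), oars=[oar])["1"].positions
    assert set(both) == set(depth_only) & set(oar_only)


class TestPolarize:
    def _toy_panel(self):
        # 5 sites x 4 samples, REF=A ALT=G everywhere
        dosage = np.array([
            [0, 1, 2, 1],
            [2, 2, 1, 0],
            [0, 0, 1, 0],
            [1, 1, 0, 2],
            [2, 0, 0, MISSING],
        ], dtype=np.int8)
        ad = np.zeros((5, 4, 2), dtype=np.int64)
        ad[..., 0] = 6
        ad[..., 1] = 6
        return make_panel([100, 200, 300, 400, 500], dosage)

    def test_outgroup_equals_ref(self):
        panel = self._toy_panel()
        og = {("1", p): ("A",) for p in [100, 200, 300, 400, 500]}
        out = variants.polarize_snps(panel, og)
        assert out.n_sites == 5
        called = out.dosage != MISSING
        alt_freq = np.where(called, out.dosage, 0).sum(1) / (2 * called.sum(1))
        np.testing.assert_allclose(out.daf, alt_freq)

    def test_missing_site_dropped_and_alt_flip(self):
        panel = self._toy_panel()
        # outgroup = ALT at sites 200 and 400 (flip), missing at 300, third allele at 500
        og = {("1", 100): ("A",), ("1", 200): ("G",), ("1", 400): ("G",), ("1", 500): ("T",)}
        out = variants.polarize_snps(panel, og)
        assert list(out.positions) == [100, 200, 400]
        # hand-checked: site 200 dosage (2,2,1,0) -> (0,0,1,2); site 400 (1,1,0,2) -> (1,1,2,0)
        np.testing.assert_array_equal(out.dosage[1], [0, 0, 1, 2])
        np.testing.assert_array_equal(out.dosage[2], [1, 1, 2, 0])
        np.testing.assert_array_equal(out.dosage[0], [0, 1, 2, 1])
        assert out.ref[1] == "G" and out.alt[1] == "A"  # ancestral/derived labels swapped

    def test_missing_genotype_survives_flip(self):
        panel = self._toy_panel()
        og = {("1", 500): ("G",)}
        out = variants.polarize_snps(panel, og)
        np.testing.assert_array_equal(out.dosage[0], [0, 2, 2, MISSING])

    def test_involution_flips_daf(self):
        """Flipping every outgroup call to the other panel allele maps
        DAF -> 1 - DAF site-wise."""
        rng = np.random.default_rng(3)
        dosage = rng.integers(0, 3, size=(40, 10)).astype(np.int8)
        panel = make_panel(np.arange(1, 41) * 100, dosage)
        og_a = {("1", int(p)): ("A",) for p in panel.positions}
        og_b = {("1", int(p)): ("G",) for p in panel.positions}
        daf_a = variants.polarize_snps(panel, og_a).daf
        daf_b = variants.polarize_snps(panel, og_b).daf
        np.testing.assert_allclose(daf_a + daf_b, 1.0)

    def test_no_overlap_warns_empty(self):
        panel = self._toy_panel()
        with pytest.warns(UserWarning):
            out = variants.polarize_snps(panel, {})
        assert out.n_sites == 0


class TestSingletons:
    def _panel(self, dosage, ad):
        dosage = np.asarray(dosage, dtype=np.int8)
        return make_panel(np.arange(1, len(dosage) + 1) * 1000, dosage,
                          allele_depths=ad, polarized=True)

    def test_definition_and_balance(self):
        dosage = [
            [1, 0, 0],   # singleton, balanced -> kept
            [1, 1, 0],   # derived count 2 -> excluded
            [0, 1, 0],   # singleton but unbalanced (18,2) -> removed
            [2, 0, 0],   # hom derived, count 2 -> excluded
        ]
        ad = np.zeros((4, 3, 2), dtype=np.int64)
        ad[..., 0] = 10
        ad[0, 0] = (10, 10)
        ad[2, 1] = (18, 2)
        ss = variants.extract_singletons(self._panel(dosage, ad), depth_bounds=(1, 100))
        assert list(ss.positions) == [1000]
        assert list(ss.carriers) == [0]

    def test_brute_force_oracle(self):
        """Singleton extraction agrees with a direct scan of the dosage
        matrix on random panels."""
        rng = np.random.default_rng(11)
        n_sites, n_samples = 300, 8
        dosage = rng.choice([0, 0, 0, 1, 2, MISSING], size=(n_sites, n_samples),
                            p=[0.5, 0.2, 0.1, 0.12, 0.05, 0.03]).astype(np.int8)
        depth = rng.poisson(12, size=(n_sites, n_samples))
        ad = np.zeros((n_sites, n_samples, 2), dtype=np.int64)
        for i in range(n_sites):
            for j in range(n_samples):
                d = max(int(depth[i, j]), 1)
                if dosage[i, j] == 1:
                    k = rng.integers(0, d + 1)
                    ad[i, j] = (d - k, k)
                elif dosage[i, j] == 2:
                    ad[i, j] = (0, d)
                else:
                    ad[i, j] = (d, 0)
        site_depth = ad.sum(2).mean(1)
        panel = make_panel(np.arange(1, n_sites + 1) * 50, dosage,
                           allele_depths=ad, site_depth=site_depth, polarized=True)
        bounds = (0.25, 0.75)
        dbounds = (6.0, 24.0)
        ss = variants.extract_singletons(panel, balance_bounds=bounds, depth_bounds=dbounds)

        expected = []
        for i in range(n_sites):
            derived = sum(d for d in dosage[i] if d != MISSING)
            hets = [j for j in range(n_samples) if dosage[i, j] == 1]
            if derived != 1 or len(hets) != 1:
                continue
            j = hets[0]
            tot = ad[i, j].sum()
            frac = ad[i, j, 1] / tot if tot else np.nan
            if not (bounds[0] <= frac <= bounds[1] and min(ad[i, j]) >= 3):
                continue
            if not (dbounds[0] <= site_depth[i] <= dbounds[1]):
                continue
            expected.append((int(panel.positions[i]), j))
        assert sorted(zip(ss.positions, ss.carriers)) == sorted(expected)
        counts = ss.counts_per_individual()
        for j in range(n_samples):
            assert counts[j] == sum(1 for _, c in expected if c == j)


class TestDetectOars:
    def _flat_panel(self, length=2_000_000, spacing=500, n=20, seed=0,
                    oar_regions=(), depth_mult=2.0, oar_het=0.9):
        rng = np.random.default_rng(seed)
        pos = np.arange(spacing, length + 1, spacing, dtype=np.int64)
        S = pos.size
        dosage = rng.choice([0, 1, 2], size=(S, n), p=[0.5, 0.3, 0.2]).astype(np.int8)
        depth = rng.poisson(12.0, size=(S, n)).astype(float)
        for start, end in oar_regions:
            sel = (pos >= start) & (pos <= end)
            depth[sel] = rng.poisson(12.0 * depth_mult, size=(int(sel.sum()), n))
            dosage[sel] = np.where(rng.random((int(sel.sum()), n)) < oar_het, 1,
                                   dosage[sel]).astype(np.int8)
        return make_panel(pos, dosage, site_depth=depth.mean(1), chrom_length=length)

    @staticmethod
    def _jaccard(a, b):
        inter = max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)
        union = max(a[1], b[1]) - min(a[0], b[0]) + 1
        return inter / union

    def test_uniform_panel_yields_nothing(self):
        assert variants.detect_oars(self._flat_panel(length=500_000)) == []

    def test_window_longer_than_chromosome(self):
        panel = self._flat_panel(length=50_000)
        intervals, windows = variants.detect_oars(panel, window_bp=100_000, step_bp=100_000,
                                                  return_windows=True)
        assert len(windows) == 1
        assert intervals == []

    def test_planted_segment_recovered(self):
        truth = (900_001, 1_000_000)  # 100 kb at 2x depth, 0.9 heterozygosity
        panel = self._flat_panel(oar_regions=[truth], seed=5)
        found = variants.detect_oars(panel)
        assert len(found) >= 1
        best = max(self._jaccard((o.start, o.end), truth) for o in found)
        assert best >= 0.8

    def test_recall_of_planted_intervals(self):
        """At default thresholds, at least 90% of planted OARs are found."""
        length = 4_000_000
        truths = [(s, s + 40_000 - 1) for s in range(300_000, 3_900_000, 400_000)]  # 10 OARs
        panel = self._flat_panel(length=length, oar_regions=truths, seed=9)
        found = variants.detect_oars(panel)
        recalled = sum(
            any(self._jaccard((o.start, o.end), t) >= 0.5 for o in found) for t in truths
        )
        assert recalled / len(truths) >= 0.9


def test_cohort_round_trip_and_oar_recovery(cohort, tmp_path):
    """Generated VCF parses cleanly; planted OARs are recovered; DAF after
    polarization matches the generator's truth at concordant sites."""
    vcf = cohort.paths["vcf"]
    panels = variants.load_and_filter_snps(vcf)
    assert set(panels) == {"1", "2", "3"}
    assert all(p.n_sites > 100 for p in panels.values())

    detected = []
    for chrom in panels:
        detected.extend(variants.detect_oars(panels[chrom]))
    truths = [(o["chrom"], o["start"], o["end"]) for o in cohort.truth.oars]
    recovered = 0
    for chrom, start, end in truths:
        for o in detected:
            if o.chromosome != chrom:
                continue
            inter = max(0, min(o.end, end) - max(o.start, start) + 1)
            union = max(o.end, end) - min(o.start, start) + 1
            if inter / union >= 0.5:
                recovered += 1
                break
    assert recovered >= 2  # at least 2 of the 3 planted intervals

    og = variants.read_outgroup_tsv(cohort.paths["outgroup"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        polarized = {c: variants.polarize_snps(p, og) for c, p in panels.items()}
    for chrom, p in polarized.items():
        assert p.n_sites > 0
        assert np.nanmin(p.daf) >= 0 and np.nanmax(p.daf) <= 1
        truth_panel = cohort.panels[chrom]
        common, ti, pi = np.intersect1d(truth_panel.positions, p.positions,
                                        return_indices=True)
        agree = np.isclose(truth_panel.daf[ti], p.daf[pi], atol=1e-9)
        # discordant-outgroup sites (~1%) legitimately polarize backwards
        assert agree.mean() > 0.95
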