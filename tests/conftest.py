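"""Shared fixtures: hand-built panels, minimal VCF writing, session cohorts."""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pytest

from sdscan.variants import MISSING, GenotypePanel
from sdscan import synthetic


def make_panel(
    positions,
    dosage,
    chromosome="1",
    site_depth=None,
    allele_depths=None,
    chrom_length=None,
    polarized=False,
    ref=None,
    alt=None,
):
    positions = np.asarray(positions, dtype=np.int64)
    dosage = np.asarray(dosage, dtype=np.int8)
    n_sites, n_samples = dosage.shape
    panel = GenotypePanel(
        chromosome=chromosome,
        positions=positions,
        samples=[f"s{i}" for i in range(n_samples)],
        dosage=dosage,
        site_depth=np.full(n_sites, 12.0) if site_depth is None else np.asarray(site_depth, float),
        allele_depths=allele_depths if allele_depths is None else np.asarray(allele_depths),
        chrom_length=int(chrom_length or (positions.max() + 1000 if n_sites else 1000)),
        ref=np.array(["A"] * n_sites, dtype=object) if ref is None else np.asarray(ref, object),
        alt=np.array(["G"] * n_sites, dtype=object) if alt is None else np.asarray(alt, object),
        polarized=polarized,
    )
    if polarized:
        panel.compute_daf()
    return panel


def write_vcf(path, records, samples, contigs):
    """Minimal VCF v4.2 writer for hand fixtures.

    ``records``: iterable of (chrom, pos, ref, alt, [(gt, (ad_ref, ad_alt)), ...])
    where gt is a string like '0/1'; ``contigs``: {name: length}.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for chrom, pos, ref, alt, calls in records:
            cells = [f"{gt}:{a},{b}" for gt, (a, b) in calls]
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:AD\t" + "\t".join(cells) + "\n")
    return path


@pytest.fixture(scope="session")
def cohort(tmp_path_factory):
    """Written cohort with planted OARs and one sweep, for round-trip tests."""
    out = tmp_path_factory.mktemp("cohort")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bundle = synthetic.generate_cohort(
            out_dir=out,
            n_diploids=16,
            chrom_lengths=(250_000, 250_000, 200_000),
            planted_oars=3,
            planted_sweeps=1,
            oar_length=20_000,
            qtl_coupling=1.0,
            seed=12345,
        )
    return bundle


@pytest.fixture(scope="session")
def small_cohort_dir(tmp_path_factory):
    """Tiny written cohort for CLI smoke tests (fast scans)."""
    out = tmp_path_factory.mktemp("small_cohort")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        synthetic.generate_cohort(
            out_dir=out,
            n_diploids=16,
            chrom_lengths=(80_000, 60_000),
            planted_oars=1,
            planted_sweeps=1,
            oar_length=10_000,
            qtl_coupling=1.0,
            seed=777,
        )
    return Path(out)
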