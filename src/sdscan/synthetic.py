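"""Synthetic cohort generation with machine-readable ground truth.

Everything the scan and polygenic pipelines consume — a diploid VCF with
GT/AD fields, an outgroup allele table, GFF3 genes, QTL tables — can be
generated here at desk scale, with planted over-assembled regions (OARs),
planted partial sweeps and a JSON truth file sufficient to recompute every
expected outcome.  Genotypes come from coalescent simulation under a
bottlenecked demography; read depths are Poisson around a configurable
mean (doubled inside OARs, where heterozygosity is also forced high, the
signature of collapsed duplications).

Default cohort sizes are desk scale (a pipeline round-trip in seconds);
the bottleneck shape, mutation/recombination rates and sweep parameters
follow the cattle-like conditions used throughout the package.  The
outgroup table is emitted from the simulation's known ancestral states
(with configurable missing/discordant/third-allele fractions) rather than
from a simulated divergent lineage, so that sweep chromosomes — which the
structured sweep coalescent only supports in a single population — carry
outgroup information too.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import msprime
import numpy as np
import pandas as pd

from .coalsim import DemographicModel, SweepSimConfig, simulate_sweep_region, _SEED_MAX
from .variants import MISSING, GenotypePanel, OarInterval

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass
class CohortTruth:
    """Ground truth for a generated cohort; JSON-serializable."""

    seed: int
    parameters: dict
    oars: list[dict]
    sweeps: list[dict]
    qtls: list[dict]
    chrom_lengths: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "CohortTruth":
        return cls(**json.load(open(path)))


@dataclass
class CohortBundle:
    """In-memory cohort: panels plus sidecar tables and truth."""

    panels: dict[str, GenotypePanel]
    outgroup: dict[tuple[str, int], tuple[str, ...]]
    genes: pd.DataFrame
    qtls: pd.DataFrame
    truth: CohortTruth
    paths: dict[str, Path] = field(default_factory=dict)


def generate_cohort(
    out_dir=None,
    n_diploids: int = 20,
    chrom_lengths: tuple[int, ...] = (200_000, 200_000, 150_000),
    mu: float = 1.2e-7,
    demography: DemographicModel | None = None,
    planted_oars: int = 2,
    planted_sweeps: int = 1,
    qtl_coupling: float = 1.0,
    seed: int = 1,
    mean_depth: float = 12.0,
    oar_length: int = 15_000,
    oar_depth_multiplier: float = 2.0,
    oar_heterozygosity: float = 0.9,
    missing_genotype_rate: float = 0.01,
    outgroup_missing_rate: float = 0.02,
    outgroup_discordant_rate: float = 0.01,
    outgroup_third_allele_rate: float = 0.005,
    sweep_s: float = 0.3,
    sweep_frequency: float = 0.2,
    n_background_qtls: int = 30,
    write: bool = True,
) -> CohortBundle:
    """Generate a full cohort bundle; deterministic for a fixed seed.

    Sweeps are planted at the midpoints of the first ``planted_sweeps``
    chromosomes; OARs are placed on the remaining chromosomes (or away
    from midpoints).  QTL association P-values couple to planted sweep
    strength with strength ``qtl_coupling`` in [0, 1]; background QTLs
    get uniform -log10 P draws and random orientation.  With ``write``,
    the bundle is also emitted under ``out_dir`` as VCF, outgroup TSV,
    GFF3, QTL TSV, truth BED + JSON.
    """
    if n_diploids < 2 or not chrom_lengths or mu <= 0:
        raise ValueError("need >=2 diploids, >=1 chromosome and mu > 0")
    if planted_sweeps > len(chrom_lengths):
        raise ValueError("more planted sweeps than chromosomes")
    if not (0.0 <= qtl_coupling <= 1.0):
        raise ValueError("qtl_coupling must be in [0, 1]")
    model = demography or DemographicModel.high_n0()
    rng = np.random.default_rng(seed)

    chrom_names = [str(i + 1) for i in range(len(chrom_lengths))]
    panels: dict[str, GenotypePanel] = {}
    oar_truth: list[dict] = []
    sweep_truth: list[dict] = []

    for ci, (chrom, length) in enumerate(zip(chrom_names, chrom_lengths)):
        swept = ci < planted_sweeps
        cfg = SweepSimConfig(
            region_length=int(length),
            selection_coefficient=sweep_s if swept else 0.0,
            current_frequency=sweep_frequency,
            mu=mu,
            n_diploids=n_diploids,
            replicates=1,
            seed=int(rng.integers(1, _SEED_MAX)),
        )
        res = simulate_sweep_region(cfg, model, selected=swept, mean_depth=mean_depth)
        panel = res.panel
        panel.chromosome = chrom
        if swept:
            sweep_truth.append({
                "chrom": chrom,
                "position": int(res.test_position),
                "s": float(sweep_s),
                "frequency": float(res.test_daf),
            })
        panels[chrom] = panel

    # plant OARs on non-sweep territory, away from chromosome ends
    oar_slots = []
    for ci, chrom in enumerate(chrom_names):
        length = chrom_lengths[ci]
        if length < 4 * oar_length:
            continue
        lo, hi = int(0.1 * length), int(0.6 * length) - oar_length
        if ci < planted_sweeps:  # keep clear of the midpoint sweep site
            hi = min(hi, length // 2 - 2 * oar_length)
        if hi > lo:
            oar_slots.append((chrom, lo, hi))
    for k in range(planted_oars):
        chrom, lo, hi = oar_slots[k % len(oar_slots)]
        start = int(rng.integers(lo, hi))
        # nudge apart multiple OARs sharing a chromosome
        start += (k // len(oar_slots)) * 3 * oar_length
        end = start + oar_length - 1
        oar_truth.append({"chrom": chrom, "start": int(start), "end": int(end)})

    site_data = _attach_read_data(
        panels, oar_truth, rng,
        mean_depth=mean_depth,
        oar_depth_multiplier=oar_depth_multiplier,
        oar_heterozygosity=oar_heterozygosity,
        missing_genotype_rate=missing_genotype_rate,
    )

    outgroup = _outgroup_table(
        panels, site_data, rng,
        missing_rate=outgroup_missing_rate,
        discordant_rate=outgroup_discordant_rate,
        third_allele_rate=outgroup_third_allele_rate,
    )

    genes = _toy_genes(chrom_names, chrom_lengths, sweep_truth, rng)
    qtls, qtl_truth = _qtl_tables(panels, sweep_truth, qtl_coupling, n_background_qtls, rng)

    truth = CohortTruth(
        seed=int(seed),
        parameters={
            "n_diploids": n_diploids,
            "chrom_lengths": list(map(int, chrom_lengths)),
            "mu": mu,
            "demography_label": model.label,
            "planted_oars": planted_oars,
            "planted_sweeps": planted_sweeps,
            "qtl_coupling": qtl_coupling,
            "mean_depth": mean_depth,
            "oar_depth_multiplier": oar_depth_multiplier,
            "oar_heterozygosity": oar_heterozygosity,
            "sweep_s": sweep_s,
            "sweep_frequency": sweep_frequency,
        },
        oars=oar_truth,
        sweeps=sweep_truth,
        qtls=qtl_truth,
        chrom_lengths={c: int(l) for c, l in zip(chrom_names, chrom_lengths)},
    )

    bundle = CohortBundle(panels=panels, outgroup=outgroup, genes=genes, qtls=qtls, truth=truth)
    if write:
        if out_dir is None:
            raise ValueError("out_dir required when write=True")
        bundle.paths = _write_bundle(bundle, site_data, Path(out_dir))
    return bundle


def _attach_read_data(panels, oar_truth, rng, *, mean_depth, oar_depth_multiplier,
                      oar_heterozygosity, missing_genotype_rate):
    """Draw per-site REF/ALT alleles, depths and ADs; overwrite OAR segments.

    Returns {chrom: dict} with arrays needed for VCF/outgroup emission.
    The panel's own dosage/AD/site_depth fields are updated in place so the
    in-memory bundle matches the written files.
    """
    out = {}
    for chrom, panel in panels.items():
        S, N = panel.n_sites, panel.n_samples
        anc_idx = rng.integers(0, 4, size=S)
        der_idx = (anc_idx + rng.integers(1, 4, size=S)) % 4
        anc = _BASES[anc_idx]
        der = _BASES[der_idx]
        # the derived allele is REF at ~30% of sites: polarization is non-trivial
        derived_is_ref = rng.random(S) < 0.3

        dosage = panel.dosage.copy()
        in_oar = np.zeros(S, dtype=bool)
        for oar in oar_truth:
            if oar["chrom"] == chrom:
                in_oar |= (panel.positions >= oar["start"]) & (panel.positions <= oar["end"])

        depth = rng.poisson(mean_depth, size=(S, N)).astype(np.int64)
        depth[in_oar] = rng.poisson(mean_depth * oar_depth_multiplier, size=(int(in_oar.sum()), N))
        depth = np.maximum(depth, 1)

        # collapsed duplications: excess heterozygotes inside OARs
        if in_oar.any():
            sub = dosage[in_oar]
            force_het = rng.random(sub.shape) < oar_heterozygosity
            sub = np.where(force_het, 1, np.where(rng.random(sub.shape) < 0.5, 0, 2)).astype(np.int8)
            dosage[in_oar] = sub

        miss = rng.random((S, N)) < missing_genotype_rate
        dosage[miss] = MISSING

        ad = np.zeros((S, N, 2), dtype=np.int64)  # (ancestral, derived) reads
        hom_anc = dosage == 0
        hom_der = dosage == 2
        het = dosage == 1
        ad[hom_anc, 0] = depth[hom_anc]
        ad[hom_der, 1] = depth[hom_der]
        d_het = rng.binomial(depth[het], 0.5)
        ad[het, 1] = d_het
        ad[het, 0] = depth[het] - d_het

        # give singleton carriers balanced, well-covered allele depths
        called = dosage != MISSING
        derived_total = np.where(called, dosage, 0).sum(axis=1)
        singleton_sites = np.flatnonzero((derived_total == 1) & (het.sum(axis=1) == 1) & ~in_oar)
        for i in singleton_sites:
            j = int(np.argmax(dosage[i] == 1))
            d = max(int(depth[i, j]), 8)
            ad[i, j] = (d - d // 2, d // 2)
            depth[i, j] = d

        site_depth = depth.mean(axis=1)

        panel.dosage = dosage
        panel.allele_depths = ad
        panel.site_depth = site_depth
        panel.polarized = True
        panel.compute_daf()

        out[chrom] = {
            "anc": anc, "der": der, "derived_is_ref": derived_is_ref,
            "depth": depth, "in_oar": in_oar,
        }
    return out


def _outgroup_table(panels, site_data, rng, *, missing_rate, discordant_rate, third_allele_rate):
    table = {}
    for chrom, panel in panels.items():
        sd = site_data[chrom]
        for i, pos in enumerate(panel.positions):
            u = rng.random()
            if u < missing_rate:
                continue
            if u < missing_rate + discordant_rate:
                allele = sd["der"][i]
            elif u < missing_rate + discordant_rate + third_allele_rate:
                others = [b for b in "ACGT" if b not in (sd["anc"][i], sd["der"][i])]
                allele = others[int(rng.integers(0, len(others)))]
            else:
                allele = sd["anc"][i]
            table[(chrom, int(pos))] = (str(allele),)
    return table


def _toy_genes(chrom_names, chrom_lengths, sweep_truth, rng):
    rows = []
    gi = 0
    for sw in sweep_truth:
        start = sw["position"] - int(rng.integers(2_000, 8_000))
        end = sw["position"] + int(rng.integers(2_000, 8_000))
        rows.append((sw["chrom"], max(start, 1), end, f"SWG{gi}", "protein_coding"))
        gi += 1
    for chrom, length in zip(chrom_names, chrom_lengths):
        for _ in range(3):
            start = int(rng.integers(1, max(length - 20_000, 2)))
            end = start + int(rng.integers(1_000, 15_000))
            rows.append((chrom, start, min(end, length), f"GENE{gi}", "protein_coding"))
            gi += 1
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "biotype"])
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def _qtl_tables(panels, sweep_truth, coupling, n_background, rng):
    """QTL TSV rows; sweep-linked QTLs get P-values coupled to sweep strength."""
    traits = ("milk_fat_percentage", "milk_protein_percentage", "stature")
    rows, truth = [], []
    for sw in sweep_truth:
        # stronger sweeps get more extreme association P-values under coupling
        strength = sw["s"] / 0.3
        neg_log_p = 3.0 + coupling * 4.0 * strength + rng.normal(0.0, 0.5)
        neg_log_p = float(np.clip(neg_log_p, 1.5, 12.0))
        rows.append({
            "trait": traits[0],
            "chrom": sw["chrom"],
            "pos": int(sw["position"]),
            "p_value": 10.0 ** -neg_log_p,
            "trait_increasing_allele": "derived",
            "populations_supported": 7,
        })
        truth.append({"chrom": sw["chrom"], "pos": int(sw["position"]), "coupled": True,
                      "coupling": coupling, "sweep_s": sw["s"]})
    for _ in range(n_background):
        chrom = list(panels)[int(rng.integers(0, len(panels)))]
        panel = panels[chrom]
        if panel.n_sites == 0:
            continue
        i = int(rng.integers(0, panel.n_sites))
        rows.append({
            "trait": traits[int(rng.integers(0, len(traits)))],
            "chrom": chrom,
            "pos": int(panel.positions[i]),
            "p_value": 10.0 ** -float(rng.uniform(1.5, 8.0)),
            "trait_increasing_allele": ["derived", "ancestral"][int(rng.integers(0, 2))],
            "populations_supported": int(rng.integers(4, 8)),
        })
        truth.append({"chrom": chrom, "pos": int(panel.positions[i]), "coupled": False,
                      "coupling": 0.0, "sweep_s": 0.0})
    return pd.DataFrame(rows), truth


def _write_bundle(bundle: CohortBundle, site_data, out_dir: Path) -> dict[str, Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out_dir / "cohort.vcf",
        "outgroup": out_dir / "outgroup.tsv",
        "gff3": out_dir / "genes.gff3",
        "qtl": out_dir / "qtls.tsv",
        "truth_bed": out_dir / "truth_oars.bed",
        "truth_json": out_dir / "truth.json",
    }
    _write_vcf(bundle, site_data, paths["vcf"])
    with open(paths["outgroup"], "w") as fh:
        fh.write("chrom\tpos\tallele\n")
        for (chrom, pos), alleles in sorted(bundle.outgroup.items(), key=lambda kv: (kv[0][0], kv[0][1])):
            fh.write(f"{chrom}\t{pos}\t{alleles[0]}\n")
    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in sorted(bundle.truth.chrom_lengths.items()):
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for i, row in bundle.genes.iterrows():
            fh.write(
                f"{row['chrom']}\tsdscan\tgene\t{row['start']}\t{row['end']}\t.\t+\t.\t"
                f"ID=gene{i};Name={row['name']};biotype={row['biotype']}\n"
            )
    bundle.qtls.to_csv(paths["qtl"], sep="\t", index=False)
    with open(paths["truth_bed"], "w") as fh:
        for oar in bundle.truth.oars:
            fh.write(f"{oar['chrom']}\t{oar['start'] - 1}\t{oar['end']}\toar\n")
    bundle.truth.to_json(paths["truth_json"])
    logger.info("cohort bundle written to %s", out_dir)
    return paths


def _write_vcf(bundle: CohortBundle, site_data, path: Path) -> None:
    """Plain-text VCF v4.2 with GT and AD; REF/ALT orientation follows the
    per-site derived_is_ref draw so polarization is exercised downstream."""
    any_panel = next(iter(bundle.panels.values()))
    samples = any_panel.samples
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sdscan-synthetic\n")
        for chrom, length in sorted(bundle.truth.chrom_lengths.items()):
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for chrom in sorted(bundle.panels):
            panel = bundle.panels[chrom]
            sd = site_data[chrom]
            gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
            for i, pos in enumerate(panel.positions):
                if sd["derived_is_ref"][i]:
                    ref, alt = sd["der"][i], sd["anc"][i]
                    # panel dosage counts derived alleles; VCF counts ALT (=ancestral here)
                    dos_alt = np.where(panel.dosage[i] == MISSING, MISSING, 2 - panel.dosage[i])
                    ad_pairs = panel.allele_depths[i][:, ::-1]  # (ref=derived, alt=ancestral)
                else:
                    ref, alt = sd["anc"][i], sd["der"][i]
                    dos_alt = panel.dosage[i]
                    ad_pairs = panel.allele_depths[i]
                fields = [
                    f"{gt_strings[int(d)]}:{a},{b}" for d, (a, b) in zip(dos_alt, ad_pairs)
                ]
                fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:AD\t" + "\t".join(fields) + "\n")


def generate_score_table(
    n_snps: int = 2_000,
    n_chromosomes: int = 3,
    n_qtls: int = 40,
    coupling: float = 0.0,
    seed: int = 1,
    chrom_length: int = 1_000_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score-level cohort: a genome-wide sSDS table plus a QTL table.

    Under ``coupling`` c in [0, 1], each QTL SNP's sSDS is rebuilt as
    sign * (c * z_effect + sqrt(1-c^2) * noise) where z_effect is the
    standardized effect proxy and sign matches the QTL's orientation, so
    tSDS correlates with the effect proxy at strength ~c; c = 0 is an
    exact null.  Used for permutation-test calibration and power studies
    where full cohort simulation would be needlessly slow.
    """
    if not (0.0 <= coupling <= 1.0):
        raise ValueError("coupling must be in [0, 1]")
    rng = np.random.default_rng(seed)
    chroms = np.array([str(1 + i % n_chromosomes) for i in range(n_snps)])
    pos = np.empty(n_snps, dtype=np.int64)
    for c in np.unique(chroms):
        sel = chroms == c
        pos[sel] = np.sort(rng.choice(np.arange(1, chrom_length), size=int(sel.sum()), replace=False))
    scores = pd.DataFrame({
        "chrom": chroms,
        "pos": pos,
        "daf": rng.uniform(0.05, 0.95, size=n_snps),
        "ssds": rng.normal(0.0, 1.0, size=n_snps),
    })

    qtl_idx = rng.choice(n_snps, size=n_qtls, replace=False)
    neg_log_p = rng.uniform(1.5, 8.0, size=n_qtls)
    z_eff = (neg_log_p - neg_log_p.mean()) / neg_log_p.std(ddof=0)
    orientation = rng.choice(["derived", "ancestral"], size=n_qtls)
    sign = np.where(orientation == "derived", 1.0, -1.0)
    if coupling > 0:
        new_ssds = sign * (coupling * z_eff + np.sqrt(1 - coupling**2) * rng.normal(size=n_qtls))
        scores.loc[qtl_idx, "ssds"] = new_ssds
    qtls = pd.DataFrame({
        "trait": "synthetic_trait",
        "chrom": scores.loc[qtl_idx, "chrom"].to_numpy(),
        "pos": scores.loc[qtl_idx, "pos"].to_numpy(),
        "p_value": 10.0 ** -neg_log_p,
        "trait_increasing_allele": orientation,
        "populations_supported": 7,
    })
    return scores, qtls
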