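"""Variant ingestion, quality filtering and outgroup polarization.

This module turns a diploid VCF (GT + AD per-sample fields) into a
:class:`GenotypePanel` of biallelic SNPs, detects putatively over-assembled
regions (OARs: collapsed duplications that show up as jointly elevated read
depth and heterozygosity), polarizes alleles into ancestral/derived state
against one or more outgroups, and extracts the per-individual singletons
that the singleton-density score is built on.

Coordinates are 1-based closed internally (VCF/GFF convention); BED output
is converted to 0-based half-open at emission time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel for a missing genotype call in the dosage matrix
MISSING = -1

_NUCLEOTIDES = frozenset("ACGT")


@dataclass
class OarInterval:
    """Putatively over-assembled region (1-based closed coordinates)."""

    chromosome: str
    start: int
    end: int
    mean_depth: float = float("nan")
    mean_heterozygosity: float = float("nan")

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"OAR start {self.start} > end {self.end}")

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    def to_bed_fields(self) -> tuple[str, int, int]:
        """0-based half-open BED representation."""
        return self.chromosome, self.start - 1, self.end


@dataclass
class GenotypePanel:
    """Filtered biallelic SNP matrix for one chromosome.

    ``dosage`` counts non-reference alleles (0/1/2, :data:`MISSING` for
    no-calls) until :func:`polarize_snps` recodes it to derived-allele
    counts and fills ``daf``.  ``allele_depths`` is ``(sites, samples, 2)``
    ordered (ref, alt) before polarization and (ancestral, derived) after;
    it may be ``None`` for simulated panels without read-level noise, in
    which case read-balance filters pass vacuously.
    """

    chromosome: str
    positions: np.ndarray
    samples: list[str]
    dosage: np.ndarray
    site_depth: np.ndarray
    allele_depths: np.ndarray | None
    chrom_length: int
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None
    polarized: bool = False
    daf: np.ndarray | None = None
    filter_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.dosage = np.asarray(self.dosage)
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("panel positions must be strictly increasing")
        if self.dosage.shape != (self.n_sites, self.n_samples):
            raise ValueError("dosage shape does not match positions/samples")
        bad = (self.dosage < MISSING) | (self.dosage > 2)
        if np.any(bad):
            raise ValueError("dosage entries must be in {0,1,2} or missing")

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset(self, mask: np.ndarray) -> "GenotypePanel":
        """New panel restricted to sites where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return GenotypePanel(
            chromosome=self.chromosome,
            positions=self.positions[mask],
            samples=self.samples,
            dosage=self.dosage[mask],
            site_depth=np.asarray(self.site_depth)[mask],
            allele_depths=None if self.allele_depths is None else self.allele_depths[mask],
            chrom_length=self.chrom_length,
            ref=None if self.ref is None else np.asarray(self.ref)[mask],
            alt=None if self.alt is None else np.asarray(self.alt)[mask],
            polarized=self.polarized,
            daf=None if self.daf is None else np.asarray(self.daf)[mask],
            filter_log=dict(self.filter_log),
        )

    def compute_daf(self) -> np.ndarray:
        """Derived-allele frequency per site; missing calls excluded."""
        if not self.polarized:
            raise ValueError("panel must be polarized before computing DAF")
        called = self.dosage != MISSING
        n_alleles = 2 * called.sum(axis=1)
        derived = np.where(called, self.dosage, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            daf = np.where(n_alleles > 0, derived / np.maximum(n_alleles, 1), np.nan)
        self.daf = daf
        return daf


@dataclass
class SingletonSet:
    """Quality-filtered singletons (derived allele count exactly 1).

    ``positions`` are sorted; ``carriers`` holds the sample index of the
    heterozygous carrier of each singleton.
    """

    chromosome: str
    positions: np.ndarray
    carriers: np.ndarray
    allele_depths: np.ndarray | None
    n_samples: int
    chrom_length: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.carriers = np.asarray(self.carriers, dtype=np.int64)
        order = np.argsort(self.positions, kind="stable")
        self.positions = self.positions[order]
        self.carriers = self.carriers[order]
        if self.allele_depths is not None:
            self.allele_depths = np.asarray(self.allele_depths)[order]
        self._per_sample: dict[int, np.ndarray] = {}

    def positions_for(self, sample_index: int) -> np.ndarray:
        """Sorted singleton positions carried by one individual."""
        cached = self._per_sample.get(sample_index)
        if cached is None:
            cached = self.positions[self.carriers == sample_index]
            self._per_sample[sample_index] = cached
        return cached

    def counts_per_individual(self) -> np.ndarray:
        return np.bincount(self.carriers, minlength=self.n_samples)

    @property
    def n_singletons(self) -> int:
        return int(self.positions.size)


def default_depth_bounds(mean_depth: float) -> tuple[float, float]:
    """Half-to-double the genome-wide mean site depth."""
    return 0.5 * mean_depth, 2.0 * mean_depth


def load_and_filter_snps(
    vcf_path,
    depth_bounds: tuple[float, float] | None = None,
    oars: Sequence[OarInterval] = (),
    min_call_rate: float = 0.9,
) -> dict[str, GenotypePanel]:
    """Read a VCF and return per-chromosome panels of clean biallelic SNPs.

    Sites are retained when they are biallelic SNPs, have mean per-sample
    read depth inside ``depth_bounds`` (default: 0.5-2x the genome-wide
    mean), have call rate >= ``min_call_rate``, and fall outside every
    supplied over-assembled region.  The masks for the independent filters
    are computed on the raw site set, so filter order cannot change the
    retained sites.  Counts removed per filter are recorded on each panel's
    ``filter_log``.
    """
    try:
        from cyvcf2 import VCF
        vcf = VCF(str(vcf_path))
    except Exception as exc:  # unreadable or malformed header
        raise ValueError(f"cannot read VCF {vcf_path}: {exc}") from exc

    samples = list(vcf.samples)
    seqlens = dict(zip(vcf.seqnames, vcf.seqlens)) if vcf.seqlens else {}

    per_chrom: dict[str, dict[str, list]] = {}
    n_input = 0
    n_not_biallelic_snp = 0
    for v in vcf:
        n_input += 1
        if (
            len(v.ALT) != 1
            or len(v.REF) != 1
            or len(v.ALT[0]) != 1
            or v.REF.upper() not in _NUCLEOTIDES
            or v.ALT[0].upper() not in _NUCLEOTIDES
        ):
            n_not_biallelic_snp += 1
            continue
        rec = per_chrom.setdefault(
            v.CHROM,
            {"pos": [], "dos": [], "depth": [], "ad": [], "ref": [], "alt": []},
        )
        # cyvcf2 gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = v.gt_types
        dos = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING).astype(np.int8)
        ad = v.format("AD")
        if ad is not None:
            ad = np.asarray(ad, dtype=np.int64)[:, :2]
            ad[ad < 0] = 0
            depth = float(ad.sum(axis=1).mean())
        else:
            depths = np.asarray(v.gt_depths, dtype=float)
            depth = float(np.mean(np.clip(depths, 0, None)))
        rec["pos"].append(v.POS)
        rec["dos"].append(dos)
        rec["depth"].append(depth)
        rec["ad"].append(ad)
        rec["ref"].append(v.REF.upper())
        rec["alt"].append(v.ALT[0].upper())
    vcf.close()

    if not per_chrom:
        if n_input:
            warnings.warn("no biallelic SNPs found in VCF; returning no panels")
        return {}

    all_depths = np.concatenate([np.asarray(rec["depth"]) for rec in per_chrom.values()])
    if depth_bounds is None:
        depth_bounds = default_depth_bounds(float(all_depths.mean()))
    lo, hi = depth_bounds
    if lo <= 0 or hi <= 0 or lo > hi:
        raise ValueError(f"depth bounds must be a positive interval, got {depth_bounds}")

    oars_by_chrom: dict[str, list[OarInterval]] = {}
    for oar in oars:
        oars_by_chrom.setdefault(oar.chromosome, []).append(oar)

    panels: dict[str, GenotypePanel] = {}
    total_retained = 0
    for chrom in sorted(per_chrom):
        rec = per_chrom[chrom]
        pos = np.asarray(rec["pos"], dtype=np.int64)
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        dos = np.asarray(rec["dos"])[order]
        depth = np.asarray(rec["depth"], dtype=float)[order]
        ads = rec["ad"]
        have_ad = all(a is not None for a in ads)
        ad = np.stack([ads[i] for i in order]) if have_ad else None
        ref = np.asarray(rec["ref"], dtype=object)[order]
        alt = np.asarray(rec["alt"], dtype=object)[order]

        depth_ok = (depth >= lo) & (depth <= hi)
        call_rate = (dos != MISSING).mean(axis=1)
        call_ok = call_rate >= min_call_rate
        oar_ok = np.ones(pos.size, dtype=bool)
        for oar in oars_by_chrom.get(chrom, []):
            oar_ok &= ~((pos >= oar.start) & (pos <= oar.end))
        keep = depth_ok & call_ok & oar_ok

        flog = {
            "n_input": int(pos.size),
            "n_removed_depth": int((~depth_ok).sum()),
            "n_removed_oar": int((~oar_ok).sum()),
            "n_removed_call_rate": int((~call_ok).sum()),
            "n_retained": int(keep.sum()),
            "depth_bounds": (float(lo), float(hi)),
            "n_not_biallelic_snp_total": n_not_biallelic_snp,
        }
        logger.info("chromosome %s: %s", chrom, flog)

        panel = GenotypePanel(
            chromosome=chrom,
            positions=pos[keep],
            samples=samples,
            dosage=dos[keep],
            site_depth=depth[keep],
            allele_depths=None if ad is None else ad[keep],
            chrom_length=int(seqlens.get(chrom, pos.max() if pos.size else 0)),
            ref=ref[keep],
            alt=alt[keep],
            filter_log=flog,
        )
        total_retained += panel.n_sites
        panels[chrom] = panel

    if total_retained == 0:
        warnings.warn("all sites removed by filtering; panels are empty")
    return panels


def detect_oars(
    panel: GenotypePanel,
    window_bp: int = 10_000,
    step_bp: int = 5_000,
    depth_z: float = 3.0,
    het_z: float = 3.0,
    return_windows: bool = False,
):
    """Sliding-window detection of over-assembled regions.

    Windows whose mean site depth AND mean per-site heterozygote fraction
    both exceed the genome-wide window mean + z*SD are flagged; overlapping
    or adjacent flagged windows are merged.  Both criteria must co-occur:
    collapsed duplications inflate depth and apparent heterozygosity
    together, and either signal alone is common in clean data.
    """
    if not (window_bp >= step_bp > 0):
        raise ValueError("require window_bp >= step_bp > 0")

    length = max(panel.chrom_length, int(panel.positions.max()) if panel.n_sites else 0)
    starts = np.arange(1, max(length - window_bp + 2, 2), step_bp, dtype=np.int64)
    if starts.size == 0:
        starts = np.array([1], dtype=np.int64)

    pos = panel.positions
    depth = np.asarray(panel.site_depth, dtype=float)
    called = panel.dosage != MISSING
    n_called = called.sum(axis=1)
    n_het = (panel.dosage == 1).sum(axis=1)
    with np.errstate(invalid="ignore"):
        het_frac = np.where(n_called > 0, n_het / np.maximum(n_called, 1), np.nan)

    rows = []
    for s in starts:
        e = min(s + window_bp - 1, length)
        i0, i1 = np.searchsorted(pos, [s, e + 1])
        if i1 <= i0:
            continue
        rows.append((int(s), int(e), float(depth[i0:i1].mean()), float(np.nanmean(het_frac[i0:i1]))))
    if not rows:
        warnings.warn("no window contains data; no OARs detectable")
        return ([], pd.DataFrame(columns=["start", "end", "depth", "het"])) if return_windows else []

    win = pd.DataFrame(rows, columns=["start", "end", "depth", "het"])
    depth_cut = win["depth"].mean() + depth_z * win["depth"].std(ddof=0)
    het_cut = win["het"].mean() + het_z * win["het"].std(ddof=0)
    win["flagged"] = (win["depth"] > depth_cut) & (win["het"] > het_cut)

    intervals: list[OarInterval] = []
    cur: list[pd.Series] = []
    for _, row in win[win["flagged"]].iterrows():
        if cur and row["start"] <= cur[-1]["end"] + 1:
            cur.append(row)
        else:
            if cur:
                intervals.append(_merge_windows(panel.chromosome, cur))
            cur = [row]
    if cur:
        intervals.append(_merge_windows(panel.chromosome, cur))
    return (intervals, win) if return_windows else intervals


def _merge_windows(chrom: str, rows: list[pd.Series]) -> OarInterval:
    return OarInterval(
        chromosome=chrom,
        start=int(rows[0]["start"]),
        end=int(max(r["end"] for r in rows)),
        mean_depth=float(np.mean([r["depth"] for r in rows])),
        mean_heterozygosity=float(np.mean([r["het"] for r in rows])),
    )


def read_outgroup_tsv(path) -> dict[tuple[str, int], tuple[str, ...]]:
    """Outgroup allele table: columns chrom, pos, allele (extra allele
    columns are read as additional outgroups).  '.'/'N' mean missing."""
    df = pd.read_csv(path, sep="\t", dtype={0: str}, comment="#")
    if df.shape[1] < 3:
        raise ValueError("outgroup TSV needs at least chrom, pos, allele columns")
    table: dict[tuple[str, int], tuple[str, ...]] = {}
    for vals in df.itertuples(index=False, name=None):
        table[(str(vals[0]), int(vals[1]))] = tuple(str(a).upper() for a in vals[2:])
    return table


def polarize_snps(
    panel: GenotypePanel,
    outgroup_alleles: Mapping[tuple[str, int], tuple[str, ...] | str],
    min_agree: int = 1,
) -> GenotypePanel:
    """Recode the panel so dosage counts derived alleles.

    The ancestral allele at each site is the allele on which at least
    ``min_agree`` outgroups agree, provided it is one of the two panel
    alleles and no supplied outgroup disagrees (conservative: any
    discordance drops the site).  Sites with missing or third-allele
    outgroup states are dropped.  When the ancestral allele is ALT, the
    dosage is flipped (d -> 2-d) and allele-depth columns are swapped.
    """
    if panel.ref is None or panel.alt is None:
        raise ValueError("panel must carry REF/ALT alleles to be polarized")

    keep = np.zeros(panel.n_sites, dtype=bool)
    flip = np.zeros(panel.n_sites, dtype=bool)
    for i, p in enumerate(panel.positions):
        calls = outgroup_alleles.get((panel.chromosome, int(p)))
        if calls is None:
            continue
        if isinstance(calls, str):
            calls = (calls,)
        observed = [c.upper() for c in calls if c and c.upper() in _NUCLEOTIDES]
        if len(observed) < min_agree or len(set(observed)) != 1:
            continue
        anc = observed[0]
        if anc == panel.ref[i]:
            keep[i] = True
        elif anc == panel.alt[i]:
            keep[i] = True
            flip[i] = True
        # third allele: drop

    if not keep.any():
        warnings.warn("no sites could be polarized against the outgroup table")

    out = panel.subset(keep)
    flip = flip[keep]
    dos = out.dosage.copy()
    flipped = dos[flip]
    flipped[flipped != MISSING] = 2 - flipped[flipped != MISSING]
    dos[flip] = flipped
    out.dosage = dos
    if out.allele_depths is not None:
        ad = out.allele_depths.copy()
        ad[flip] = ad[flip][:, :, ::-1]
        out.allele_depths = ad
    if out.ref is not None:
        ref = out.ref.copy()
        alt = out.alt.copy()
        ref[flip], alt[flip] = out.alt[flip], out.ref[flip]
        # after polarization ref column = ancestral, alt column = derived
        out.ref, out.alt = ref, alt
    out.polarized = True
    out.compute_daf()
    out.filter_log = dict(out.filter_log)
    out.filter_log["n_polarized"] = int(keep.sum())
    out.filter_log["n_dropped_polarization"] = int((~keep).sum())
    return out


def extract_singletons(
    panel: GenotypePanel,
    balance_bounds: tuple[float, float] = (0.25, 0.75),
    depth_bounds: tuple[float, float] | None = None,
    min_reads_per_allele: int = 3,
) -> SingletonSet:
    """Singletons: derived allele count exactly 1, carried heterozygously.

    The carrier's derived-allele read fraction must lie inside
    ``balance_bounds`` with at least ``min_reads_per_allele`` reads per
    allele (both alleles equally well covered), and the site's mean depth
    inside ``depth_bounds`` (default 0.5-2x the panel mean).  Panels
    without allele-depth data (noise-free simulations) skip the read
    filters.
    """
    if not panel.polarized:
        raise ValueError("panel must be polarized before singleton extraction")
    if panel.n_sites == 0:
        return SingletonSet(panel.chromosome, [], [], None, panel.n_samples, panel.chrom_length)

    called = panel.dosage != MISSING
    derived_total = np.where(called, panel.dosage, 0).sum(axis=1)
    is_singleton = (derived_total == 1) & ((panel.dosage == 1).sum(axis=1) == 1)

    if depth_bounds is None:
        depth_bounds = default_depth_bounds(float(np.mean(panel.site_depth)))
    depth = np.asarray(panel.site_depth, dtype=float)
    is_singleton &= (depth >= depth_bounds[0]) & (depth <= depth_bounds[1])

    idx = np.flatnonzero(is_singleton)
    carriers = np.argmax(panel.dosage[idx] == 1, axis=1) if idx.size else np.array([], dtype=int)

    if panel.allele_depths is not None and idx.size:
        ad = panel.allele_depths[idx, carriers]  # (k, 2) ancestral, derived
        total = ad.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, ad[:, 1] / np.maximum(total, 1), np.nan)
        ok = (
            (frac >= balance_bounds[0])
            & (frac <= balance_bounds[1])
            & (ad.min(axis=1) >= min_reads_per_allele)
        )
        idx, carriers, ad = idx[ok], carriers[ok], ad[ok]
    else:
        ad = None

    return SingletonSet(
        chromosome=panel.chromosome,
        positions=panel.positions[idx],
        carriers=carriers,
        allele_depths=ad,
        n_samples=panel.n_samples,
        chrom_length=panel.chrom_length,
    )


def oars_to_bed(oars: Iterable[OarInterval], path) -> None:
    with open(path, "w") as fh:
        for oar in oars:
            chrom, start, end = oar.to_bed_fields()
            fh.write(f"{chrom}\t{start}\t{end}\t{oar.mean_depth:.3f}\t{oar.mean_heterozygosity:.4f}\n")


def singletons_to_tsv(singleton_sets: Mapping[str, SingletonSet], samples: Sequence[str], path) -> None:
    rows = []
    for chrom in sorted(singleton_sets):
        ss = singleton_sets[chrom]
        for p, c in zip(ss.positions, ss.carriers):
            rows.append((chrom, int(p), samples[int(c)]))
    pd.DataFrame(rows, columns=["chrom", "pos", "sample"]).to_csv(path, sep="\t", index=False)


def panel_summary(panels: Mapping[str, GenotypePanel]) -> pd.DataFrame:
    rows = []
    for chrom in sorted(panels):
        p = panels[chrom]
        row = {"chrom": chrom, "n_sites": p.n_sites, "chrom_length": p.chrom_length}
        row.update({k: v for k, v in p.filter_log.items() if isinstance(v, (int, float))})
        rows.append(row)
    return pd.DataFrame(rows)
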