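"""Readers and writers: VCF 4.2 cohorts, manifest/annotation TSVs, BED tracks.

The VCF reader keeps biallelic SNVs only, takes the ancestral allele from the
``AA`` INFO tag (a sidecar annotation column overrides it), and produces a
:class:`~afroscan.datamodel.HaplotypeMatrix` only when every genotype in the
file is phased.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datamodel import (
    MISSING,
    GenotypeMatrix,
    HaplotypeMatrix,
    PopulationManifest,
    SiteTable,
    WindowScoreTrack,
)

logger = logging.getLogger(__name__)

_BASES = {"A", "C", "G", "T"}


def _split_set(value) -> frozenset:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return frozenset()
    return frozenset(str(value).split(","))


def read_manifest(path: str | Path) -> PopulationManifest:
    """Read a single cohort manifest TSV.

    One row per sample; population-level fields (lat, lon, mortality_*) are
    repeated on every row of the population and collapsed on read.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "population": str})
    df = df.set_index("sample")
    df["affected"] = [_split_set(v) for v in df.get("affected", [""] * len(df))]
    pop_cols = ["lat", "lon"] + [c for c in df.columns if c.startswith("mortality_")]
    pops = df.groupby("population", sort=False)[pop_cols].first()
    sample_cols = ["population", "sex", "affected"] + [
        c for c in df.columns if c.startswith("anc_")
    ]
    sample_cols = [c for c in sample_cols if c in df.columns]
    return PopulationManifest(samples=df[sample_cols].copy(), populations=pops)


def write_manifest(manifest: PopulationManifest, path: str | Path) -> None:
    df = manifest.samples.copy()
    df["affected"] = [",".join(sorted(v)) for v in df["affected"]]
    df = df.join(manifest.populations, on="population")
    df.index.name = "sample"
    df.to_csv(path, sep="\t")


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Sidecar per-site annotation TSV keyed on (chrom, pos)."""
    ann = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("catalogue_flags", "region_labels"):
        if col in ann.columns:
            ann[col] = [_split_set(v) for v in ann[col]]
    return ann


def write_annotations(sites: SiteTable, path: str | Path) -> None:
    df = sites.df.copy()
    for col in ("catalogue_flags", "region_labels"):
        df[col] = [",".join(sorted(v)) for v in df[col]]
    df.to_csv(path, sep="\t", index=False)


def read_cohort(
    vcf_path: str | Path,
    manifest_path: str | Path,
    annotation_path: str | Path | None = None,
):
    """Load a phased/unphased cohort VCF plus manifest (and annotations).

    Returns ``(sites, geno, haps_or_None, manifest)``.  Non-SNV and
    multiallelic records are skipped (count logged); every VCF sample must
    appear in the manifest.
    """
    manifest = read_manifest(manifest_path)
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    missing = [s for s in samples if s not in manifest.samples.index]
    if missing:
        raise ValueError(f"VCF sample(s) not in manifest: {missing}")

    rows, calls, hap_rows = [], [], []
    all_phased = True
    n_skipped = 0
    for rec in vcf:
        alts = rec.ALT
        if len(alts) != 1 or rec.REF not in _BASES or alts[0] not in _BASES:
            n_skipped += 1
            continue
        aa = rec.INFO.get("AA")
        ancestral = aa if aa in (rec.REF, alts[0]) else "."
        rows.append((rec.CHROM, rec.POS, rec.REF, alts[0], ancestral))
        gts = rec.genotype.array()  # (n_samples, 3): allele_a, allele_b, phased
        a, b = gts[:, 0], gts[:, 1]
        dose = np.where((a < 0) | (b < 0), MISSING, (a > 0).astype(int) + (b > 0))
        calls.append(dose)
        if all_phased and not bool(np.all(gts[:, 2] == 1)):
            all_phased = False
        hap_rows.append(np.stack([a, b], axis=1))
    if n_skipped:
        logger.info("skipped %d non-biallelic-SNV records", n_skipped)

    site_df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "ancestral"])
    if annotation_path is not None:
        ann = read_annotations(annotation_path)
        site_df = site_df.merge(ann, on=["chrom", "pos"], how="left", suffixes=("", "_ann"))
        if "ancestral_ann" in site_df.columns:  # sidecar overrides AA tag
            override = site_df["ancestral_ann"].notna()
            site_df.loc[override, "ancestral"] = site_df.loc[override, "ancestral_ann"]
            site_df = site_df.drop(columns=["ancestral_ann"])
        for col in ("catalogue_flags", "region_labels"):
            if col in site_df.columns:
                site_df[col] = [
                    v if isinstance(v, frozenset) else frozenset()
                    for v in site_df[col]
                ]
    sites = SiteTable(site_df)
    geno = GenotypeMatrix(
        sites,
        samples,
        np.array(calls, dtype=np.int8).reshape(len(sites), len(samples)),
        sex=manifest.samples.loc[samples, "sex"].to_numpy(),
    )

    haps = None
    if all_phased and len(sites) > 0:
        hap = np.stack(hap_rows)  # (sites, samples, 2), ref/alt coded
        hap = hap.transpose(1, 2, 0).reshape(2 * len(samples), len(sites))
        # polarize 0=ancestral 1=derived; unknown-ancestral sites keep alt coding
        flip = sites.ancestral_is_alt
        hap = np.where(flip[None, :], 1 - hap, hap).astype(np.uint8)
        cm_per_bp = 1e-6  # constant 1 cM/Mb map unless a real map is attached
        pos = sites.df["pos"].to_numpy()
        haps = HaplotypeMatrix(hap, samples, pos * cm_per_bp, pos)
    elif not all_phased:
        logger.warning("unphased genotypes present; no HaplotypeMatrix produced")

    return sites, geno, haps, manifest


def write_vcf(
    sites: SiteTable,
    geno: GenotypeMatrix,
    path: str | Path,
    haps: HaplotypeMatrix | None = None,
) -> None:
    """Emit a minimal VCF 4.2 with AA INFO tags; phased GT when haps given."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in sites.df["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.samples)
            + "\n"
        )
        flip = sites.ancestral_is_alt
        for i, row in enumerate(sites.df.itertuples(index=False)):
            info = f"AA={row.ancestral}" if row.ancestral != "." else "AA=."
            if haps is not None:
                gt = []
                for j in range(len(geno.samples)):
                    a, b = haps.haps[2 * j, i], haps.haps[2 * j + 1, i]
                    if flip[i]:  # back to ref/alt coding
                        a, b = 1 - a, 1 - b
                    gt.append(f"{a}|{b}")
            else:
                gt = []
                for dose in geno.calls[i]:
                    if dose == MISSING:
                        gt.append("./.")
                    else:
                        gt.append(["0/0", "0/1", "1/1"][dose])
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t"
                f"{info}\tGT\t" + "\t".join(gt) + "\n"
            )


TRACK_HEADER = "#chrom\tstart\tend\tscore\tn_snvs\toutlier\n"


def write_track(track: WindowScoreTrack, path: str | Path) -> None:
    """Write a window track as BED-like TSV (0-based half-open)."""
    df = track.df.sort_values(["chrom", "start"]).reset_index(drop=True)
    WindowScoreTrack(track.population, df)  # re-validates non-overlap
    with open(path, "w") as fh:
        fh.write(f"#population={track.population}\n")
        fh.write(TRACK_HEADER)
        for r in df.itertuples(index=False):
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.score:.6g}\t{r.n_snvs}\t"
                f"{int(r.outlier)}\n"
            )


def read_track(path: str | Path) -> WindowScoreTrack:
    population = "unknown"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#population="):
            population = first.strip().split("=", 1)[1]
    df = pd.read_csv(
        path,
        sep="\t",
        comment=None,
        skiprows=2,
        names=["chrom", "start", "end", "score", "n_snvs", "outlier"],
        dtype={"chrom": str},
    )
    df["outlier"] = df["outlier"].astype(bool)
    return WindowScoreTrack(population, df)


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED3(+name) intervals, 0-based half-open."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end", 3: "name"})
    return df
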