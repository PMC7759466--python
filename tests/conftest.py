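import numpy as np
import pandas as pd
import pytest

from afroscan.datamodel import PopulationManifest, SiteTable
from afroscan.simulate import SimConfig, SweepSpec, simulate_cohort


def make_sites(n=5, chrom="1", spacing=100, ancestral=None, **cols):
    """Small SiteTable with non-ambiguous alleles by default."""
    ref = ["A"] * n
    alt = ["C"] * n
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(1, n + 1) * spacing,
            "ref": cols.pop("ref", ref),
            "alt": cols.pop("alt", alt),
            "ancestral": ancestral if ancestral is not None else ["A"] * n,
        }
    )
    for k, v in cols.items():
        df[k] = v
    return SiteTable(df)


def make_manifest(pops, members_per_pop, lat=None, lon=None, **pop_cols):
    rows = []
    for p in pops:
        for j in range(members_per_pop):
            rows.append((f"{p}_s{j}", p))
    sdf = pd.DataFrame(rows, columns=["sample", "population"]).set_index("sample")
    sdf["sex"] = "unknown"
    sdf["affected"] = [frozenset()] * len(sdf)
    pdf = pd.DataFrame(
        {
            "lat": lat if lat is not None else np.linspace(0, 10, len(pops)),
            "lon": lon if lon is not None else np.linspace(0, 10, len(pops)),
        },
        index=pd.Index(pops, name="population"),
    )
    for k, v in pop_cols.items():
        pdf[k] = v
    return PopulationManifest(samples=sdf, populations=pdf)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest 3-population cohort with a planted sweep, reused across tests."""
    cfg = SimConfig(
        seed=11,
        n_populations=3,
        samples_per_pop=20,
        n_sites=3000,
        chrom_length_bp=1_000_000,
        fst=(0.05, 0.1, 0.15),
        admixture=np.eye(3),
        sweep=SweepSpec(population="P1"),
    )
    sites, geno, haps, manifest, truth = simulate_cohort(cfg)
    return {
        "cfg": cfg,
        "sites": sites,
        "geno": geno,
        "haps": haps,
        "manifest": manifest,
        "truth": truth,
    }
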