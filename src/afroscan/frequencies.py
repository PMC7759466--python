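"""Derived-allele frequency computation, polarized by ancestral state.

DAF is the frequency of the non-ancestral allele among non-missing calls.
Sites with unknown ancestral state, or with no non-missing calls in the
population, get NaN (never 0).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeMatrix, PopulationManifest, SiteTable


def derived_counts(
    geno: GenotypeMatrix, sites: SiteTable, sample_ids: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """(derived allele count, total called alleles) per site for a sample set.

    Unknown-ancestral sites get count NaN (total still reported).
    """
    idx = geno.sample_index(sample_ids)
    calls = geno.calls[:, idx]
    obs = calls != MISSING
    n_alleles = 2 * obs.sum(axis=1)
    alt = np.where(obs, calls, 0).sum(axis=1).astype(float)
    derived = np.where(sites.ancestral_is_alt, n_alleles - alt, alt)
    derived = np.where(sites.ancestral_known, derived, np.nan)
    return derived, n_alleles


def derived_allele_frequency(
    geno: GenotypeMatrix,
    sites: SiteTable,
    manifest: PopulationManifest,
    population: str,
) -> np.ndarray:
    """Per-site DAF within one population (NaN where undefined)."""
    derived, n_alleles = derived_counts(geno, sites, manifest.members(population))
    with np.errstate(invalid="ignore", divide="ignore"):
        daf = derived / n_alleles
    return np.where(n_alleles > 0, daf, np.nan)


def population_daf(
    geno: GenotypeMatrix, sites: SiteTable, manifest: PopulationManifest
) -> pd.DataFrame:
    """Sites x populations DAF table (columns are population ids)."""
    return pd.DataFrame(
        {
            pop: derived_allele_frequency(geno, sites, manifest, pop)
            for pop in manifest.population_ids
        }
    )
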