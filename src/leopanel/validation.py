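"""Calibration and recovery experiments on the synthetic presets.

These are the package's end-to-end self-checks, run by the test suite and
the reproduction script:

* D-statistic calibration (false-positive rate under the no-admixture
  discovery demography) and power (under a 30% migrant fraction on 20% of
  sites, the configured gene-flow pulse).  Replicates are simulated at
  genome scale (1e5 sites, the order of the real analysis' ~1e5 SNP input)
  because the pulse produces a true D of only ~0.02; the bootstrap uses
  50-site blocks, which for unlinked sites estimates the same sampling
  variance as single-site resampling at a fraction of the cost.
* Basal-dichotomy recovery: how often the neighbor-joining dendrogram of
  the 10-sample discovery preset contains the bipartition separating the
  northern clades (West & Central Africa + India) from the southern ones.
* Cohort assignment recovery: panel design on the discovery preset, panel
  genotyping of the 211-sample cohort, QC, and supervised clade assignment,
  scoring how many non-admixed samples recover their true clade with
  posterior > 0.9; plus per-clade panel heterozygosity.
* Allelic-dropout bias: the observed-heterozygosity deflation of the
  lambda = 0.5 individual against its closed form,
  ``1 - 2 (e^{-lam/2} - e^{-lam}) / (1 - e^{-lam})``.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import assign, filters, panel, simulate as sim, stats
from .datamodel import CLADES, MISSING, NORTHERN_CLADES

#: Default gene-flow pulse for the power study: donor = the P3 lineage
#: (West & Central Africa), recipient = P2 (Southern Africa).
POWER_GENE_FLOW = sim.GeneFlowSpec(
    donor="West & Central Africa",
    recipient="Southern Africa",
    migrant_fraction=0.3,
    site_fraction=0.2,
)

#: Group configuration with an exact null: P1 and P2 are the two southern
#: sister clades (exchangeable under the demography), P3 the northern test
#: lineage, outgroup fixed for the reference allele (tiger proxy).
DSTAT_GROUPS = {
    "p1": ["Somalia", "Kenya"],
    "p2": ["Zambia1", "Zambia2", "RSA", "Namibia"],
    "p3": ["Cameroon", "DRC"],
    "outgroup": None,
}


def dstat_replicate(
    seed: int,
    gene_flow: bool = False,
    n_sites: int = 100_000,
    n_boot: int = 1000,
    block: int | None = 50,
) -> stats.DStatResult:
    """One simulated D-statistic test on a fresh discovery-preset replicate."""
    config = sim.discovery_config(
        seed=seed, n_sites=n_sites,
        gene_flow=POWER_GENE_FLOW if gene_flow else None,
    )
    freqs = sim.simulate_allele_frequencies(config)
    truth = sim.simulate_genotypes(freqs, config)
    observed = sim.simulate_coverage_and_calls(truth, config)
    return stats.d_statistic(
        observed, DSTAT_GROUPS["p1"], DSTAT_GROUPS["p2"], DSTAT_GROUPS["p3"],
        DSTAT_GROUPS["outgroup"], n_boot=n_boot, block=block, seed=seed,
    )


def dstat_calibration(
    n_replicates: int,
    seed: int = 0,
    gene_flow: bool = False,
    n_sites: int = 100_000,
    n_boot: int = 1000,
    block: int | None = 50,
) -> np.ndarray:
    """Z scores across seeded replicates (null or gene-flow demography)."""
    return np.array(
        [
            dstat_replicate(seed + i, gene_flow, n_sites, n_boot, block).z
            for i in range(n_replicates)
        ]
    )


def dichotomy_recovery(
    n_seeds: int, seed: int = 0, n_sites: int = 5000
) -> float:
    """Fraction of discovery replicates whose NJ tree splits north from south."""
    northern = {
        s.id for s in sim.discovery_samples() if s.clade in NORTHERN_CLADES
    }
    hits = 0
    for i in range(n_seeds):
        config = sim.discovery_config(seed=seed + i, n_sites=n_sites)
        freqs = sim.simulate_allele_frequencies(config)
        truth = sim.simulate_genotypes(freqs, config)
        observed = sim.simulate_coverage_and_calls(truth, config)
        frame = pd.DataFrame(observed.genotypes.T, index=observed.samples)
        newick = assign.distance_tree(frame)
        hits += assign.has_bipartition(newick, northern)
    return hits / n_seeds


def design_panel_from_discovery(
    config: sim.DemographyConfig, target_autosomal: int = 125
) -> panel.PanelDefinition:
    """Run the full design stage (masking, attribution, criteria, greedy
    selection) on a discovery-preset simulation."""
    freqs = sim.simulate_allele_frequencies(config)
    truth = sim.simulate_genotypes(freqs, config)
    observed = sim.simulate_coverage_and_calls(truth, config)
    flanks = sim.simulate_flanks(observed, config)
    masked = filters.mask_low_coverage(observed, 3)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    _, scaffold_map = sim._make_sites(config, rng)
    attributed = filters.attribute_chromosomes(masked, scaffold_map)
    candidates = panel.evaluate_candidates(
        panel.build_candidates(attributed, flanks)
    )
    return panel.select_autosomal_panel(candidates, target_autosomal)


def cohort_assignment_study(seed: int = 0, n_sites: int = 5000) -> dict:
    """Design the panel, genotype the 211-sample cohort, QC and assign.

    The cohort preset shares the discovery preset's allele frequencies when
    simulated at the same seed and site count, so the designed panel applies
    directly.  Returns accuracy and heterozygosity summaries.
    """
    discovery = sim.discovery_config(seed=seed, n_sites=n_sites)
    pdef = design_panel_from_discovery(discovery)

    cohort = sim.cohort_config(seed=seed, n_sites=n_sites)
    freqs = sim.simulate_allele_frequencies(cohort)
    truth = sim.simulate_genotypes(freqs, cohort)
    observed = sim.simulate_coverage_and_calls(truth, cohort)
    calls = panel.apply_panel(observed, pdef)
    sheet = sim.sample_sheet_frame(cohort).set_index("sample")

    retained, excluded, _ = assign.qc_exclude_missing(calls, 0.25)
    non_admixed = [s for s in retained if not s.startswith("ADMIX")]
    admixed = [s for s in retained if s.startswith("ADMIX")]
    auto = calls.autosomal()
    assigner = assign.CladeAssigner().fit(
        auto.loc[non_admixed], sheet.loc[non_admixed, "region"]
    )
    proba = pd.DataFrame(
        assigner.predict_proba(auto.loc[retained]),
        index=retained, columns=assigner.classes_,
    )
    correct = np.array(
        [proba.loc[s, sheet.loc[s, "region"]] > 0.9 for s in non_admixed]
    )
    het_by_clade = {}
    for clade in CLADES:
        members = [
            s.id for s in cohort.samples
            if s.clade == clade and max(s.q) == 1.0 and s.id in set(retained)
        ]
        het_by_clade[clade] = stats.het_population(auto, members, min_called=5)
    return {
        "panel": pdef,
        "n_retained": len(retained),
        "n_excluded": len(excluded),
        "recovery_fraction": float(correct.mean()),
        "n_non_admixed": len(non_admixed),
        "n_admixed_retained": len(admixed),
        "max_posterior_admixed": proba.loc[admixed].max(axis=1) if admixed else None,
        "het_by_clade": pd.Series(het_by_clade),
    }


def expected_dropout_factor(lam: float) -> float:
    """Closed-form observed/true heterozygosity ratio at Poisson depth
    ``lam``, conditional on the site being called (depth >= 1):
    ``E[1 - 2^(1-d) | d >= 1]``."""
    return 1 - 2 * (math.exp(-lam / 2) - math.exp(-lam)) / (1 - math.exp(-lam))


def dropout_bias_study(
    seed: int = 0, n_sites: int = 20_000, sample: str = "Benin"
) -> dict:
    """Measured vs expected heterozygosity deflation of the low-coverage
    discovery individual."""
    config = sim.discovery_config(seed=seed, n_sites=n_sites)
    freqs = sim.simulate_allele_frequencies(config)
    truth = sim.simulate_genotypes(freqs, config)
    observed = sim.simulate_coverage_and_calls(truth, config)
    het_truth = stats.het_individual(truth, sample)
    het_observed = stats.het_individual(observed, sample)
    lam = next(s.depth for s in config.samples if s.id == sample)
    return {
        "het_truth": het_truth,
        "het_observed": het_observed,
        "measured_ratio": het_observed / het_truth,
        "expected_ratio": expected_dropout_factor(lam),
        "lambda": lam,
    }
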