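"""Post-calling filters for low-coverage genotype matrices.

Canonical order: per-cell low-coverage masking first (cells with depth
below the threshold become missing), then site-level filtering by the
number of individuals with a retained call.  The default ladder of
min-called levels is {1, 3, 5, 8, all}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import MISSING, PanelCalls, VariantDataset

logger = logging.getLogger(__name__)

DEFAULT_LADDER: tuple[int | None, ...] = (1, 3, 5, 8, None)  # None = all samples


def mask_low_coverage(dataset: VariantDataset, min_depth: int = 3) -> VariantDataset:
    """Replace calls with depth < ``min_depth`` by the missing state.

    Masking is per cell (per sample per site); the ``masked`` flag channel
    records which cells were ambiguous-after-masking as opposed to missing
    in the input.
    """
    if min_depth < 0:
        raise ValueError(f"min_depth must be non-negative, got {min_depth}")
    out = dataset.copy()
    low = out.depths < min_depth
    newly_masked = low & (out.genotypes != MISSING)
    out.genotypes[low] = MISSING
    out.masked = newly_masked if out.masked is None else (out.masked | newly_masked)
    return out


def filter_by_min_called(
    dataset: VariantDataset, min_called: int
) -> VariantDataset:
    """Keep sites with at least ``min_called`` non-missing calls."""
    if min_called > dataset.n_samples:
        logger.warning(
            "min_called=%d exceeds sample count %d; result is empty",
            min_called,
            dataset.n_samples,
        )
    called = (dataset.genotypes != MISSING).sum(axis=1)
    return dataset.subset_sites(called >= min_called)


@dataclass
class FilterReport:
    """Surviving-site counts per ladder level and per-sample missingness."""

    levels: pd.DataFrame  # columns: label, min_called, n_sites
    missingness: pd.Series  # per sample, fraction of missing cells

    def to_csv(self, levels_path, missingness_path) -> None:
        self.levels.to_csv(levels_path, index=False)
        out = self.missingness.rename("missing_fraction")
        out.index.name = "sample"
        out.to_csv(missingness_path)


def filter_ladder(
    dataset: VariantDataset,
    levels: tuple[int | None, ...] = DEFAULT_LADDER,
) -> tuple[dict[int, VariantDataset], FilterReport]:
    """Apply the min-called ladder; ``None`` means "called in all samples".

    Returns the filtered dataset per resolved level and a report whose
    surviving counts are non-increasing with stricter thresholds.
    """
    resolved = [dataset.n_samples if lv is None else lv for lv in levels]
    results: dict[int, VariantDataset] = {}
    rows = []
    for raw, lv in zip(levels, resolved):
        filtered = filter_by_min_called(dataset, lv)
        results[lv] = filtered
        label = "all samples" if raw is None else f">= {lv} samples"
        rows.append({"label": label, "min_called": lv, "n_sites": filtered.n_sites})
    report = FilterReport(
        levels=pd.DataFrame(rows), missingness=sample_missingness(dataset)
    )
    return results, report


def attribute_chromosomes(
    dataset: VariantDataset, scaffold_map: dict[str, str]
) -> VariantDataset:
    """Assign each site's chromosome from a scaffold -> chromosome map.

    Scaffolds absent from the map are labelled ``"unplaced"`` (count
    logged).  The map itself must be duplicate-free; :func:`leopanel.io.
    read_scaffold_map` enforces this for CSV input.
    """
    out = dataset.copy()
    n_unplaced = 0
    sites = []
    for site in out.sites:
        chromosome = scaffold_map.get(site.scaffold)
        if chromosome is None:
            chromosome = "unplaced"
            n_unplaced += 1
        sites.append(site.with_chromosome(chromosome))
    out.sites = sites
    if n_unplaced:
        logger.info("%d site(s) on scaffolds absent from the map -> 'unplaced'", n_unplaced)
    return out


def chromosome_tallies(dataset: VariantDataset) -> pd.Series:
    """SNP count per attributed chromosome."""
    labels = [s.chromosome or "unplaced" for s in dataset.sites]
    return pd.Series(labels).value_counts().sort_index()


def sample_missingness(data: VariantDataset | PanelCalls | pd.DataFrame) -> pd.Series:
    """Fraction of missing cells per sample, over any call matrix."""
    if isinstance(data, VariantDataset):
        matrix = data.genotypes
        index = data.samples
    elif isinstance(data, PanelCalls):
        matrix = data.calls.to_numpy().T
        index = data.samples
    else:
        matrix = data.to_numpy().T
        index = list(data.index)
    if matrix.shape[0] == 0:
        raise ValueError("cannot compute missingness with zero sites")
    frac = (matrix == MISSING).mean(axis=0)
    return pd.Series(frac, index=index)
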