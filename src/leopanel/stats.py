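"""Observed heterozygosity and the ABBA-BABA D-statistic.

Observed heterozygosity is the proportion of heterozygous genotypes among
scored (non-missing) genotypes — per individual over all SNPs, or per
population over panel SNPs called in at least five population members.

The D-statistic is computed in allele-frequency form so that single
diploid individuals and multi-sample groups share one code path: with
``p_k`` the alternate-allele frequency of group ``k`` at a site,

    D = sum[(1-p1) p2 p3 (1-p4) - p1 (1-p2) p3 (1-p4)]
        / sum[(1-p1) p2 p3 (1-p4) + p1 (1-p2) p3 (1-p4)]

summing over sites where all four groups have at least one call.
Significance comes from a site (or site-block) bootstrap:
``Z = D / sd(bootstrap replicates)``, with |Z| >= 3 flagged significant by
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .datamodel import HET, MISSING, PanelCalls, VariantDataset


def _matrix_and_samples(data: VariantDataset | pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Return a (sites x samples) dosage matrix and the sample list."""
    if isinstance(data, VariantDataset):
        return data.genotypes, list(data.samples)
    return data.to_numpy().T, list(data.index)


def het_individual(data: VariantDataset | pd.DataFrame, sample: str) -> float:
    """Observed heterozygosity of one individual: het / scored sites."""
    matrix, samples = _matrix_and_samples(data)
    j = samples.index(sample)
    column = matrix[:, j]
    scored = column != MISSING
    n_scored = int(scored.sum())
    if n_scored == 0:
        raise ValueError(f"sample {sample!r} has zero scored sites")
    return float((column[scored] == HET).sum() / n_scored)


def het_individual_all(data: VariantDataset | pd.DataFrame) -> pd.Series:
    """Observed heterozygosity for every sample with >= 1 scored site."""
    matrix, samples = _matrix_and_samples(data)
    scored = matrix != MISSING
    n_scored = scored.sum(axis=0)
    if (n_scored == 0).any():
        bad = [s for s, n in zip(samples, n_scored) if n == 0]
        raise ValueError(f"sample(s) with zero scored sites: {bad}")
    het = ((matrix == HET) & scored).sum(axis=0)
    return pd.Series(het / n_scored, index=samples)


def het_population(
    calls: PanelCalls | pd.DataFrame,
    members: list[str],
    min_called: int = 5,
) -> float:
    """Population-level observed heterozygosity on panel SNPs.

    Mean over SNPs called in at least ``min_called`` members of
    (het calls / called members); SNPs below the threshold are excluded.
    """
    frame = calls.autosomal() if isinstance(calls, PanelCalls) else calls
    sub = frame.loc[members].to_numpy()
    called = sub != MISSING
    n_called = called.sum(axis=0)
    qualifying = n_called >= min_called
    if not qualifying.any():
        raise ValueError(
            f"no SNP called in >= {min_called} of the {len(members)} members"
        )
    het_frac = ((sub == HET) & called).sum(axis=0)[qualifying] / n_called[qualifying]
    return float(het_frac.mean())


@dataclass
class HetCorrelation:
    pearson: float
    spearman: float
    defined: bool  # False when either vector is constant


def het_correlation(a: pd.Series, b: pd.Series) -> HetCorrelation:
    """Pearson and Spearman correlation of two heterozygosity reports over
    their shared individuals or populations."""
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared units, got {len(shared)}")
    x, y = a[shared].to_numpy(float), b[shared].to_numpy(float)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return HetCorrelation(float("nan"), float("nan"), defined=False)
    pearson = float(sp_stats.pearsonr(x, y).statistic)
    spearman = float(sp_stats.spearmanr(x, y).statistic)
    return HetCorrelation(pearson, spearman, defined=True)


@dataclass
class DStatResult:
    """ABBA-BABA test result with bootstrap significance."""

    d: float
    z: float
    significant: bool
    n_sites_used: int
    replicates: np.ndarray = field(repr=False)
    undefined: bool = False
    config: dict = field(default_factory=dict)


def _group_frequencies(
    dataset: VariantDataset, group: list[str] | None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site alternate-allele frequency of a sample group.

    Returns ``(freq, has_call)``.  ``group=None`` (or empty) denotes an
    outgroup fixed for the reference allele — the ancestral-state proxy
    used when no outgroup sample is in the dataset.
    """
    if not group:
        n = dataset.n_sites
        return np.zeros(n), np.ones(n, dtype=bool)
    idx = [dataset.sample_index(s) for s in group]
    sub = dataset.genotypes[:, idx].astype(float)
    called = sub != MISSING
    n_called = called.sum(axis=1)
    dose = np.where(called, sub, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_called > 0, dose / (2 * n_called), np.nan)
    return freq, n_called > 0


def d_statistic(
    dataset: VariantDataset,
    p1: list[str],
    p2: list[str],
    p3: list[str],
    outgroup: list[str] | None,
    n_boot: int = 1000,
    block: int | None = None,
    seed: int | None = None,
    z_threshold: float = 3.0,
) -> DStatResult:
    """Four-taxon ABBA-BABA test with a site (or block) bootstrap.

    ``p1``/``p2`` are the ingroup pair, ``p3`` the test lineage and
    ``outgroup`` polarizes the alleles (``None`` = fixed reference).
    Swapping ``p1`` and ``p2`` negates D exactly.
    """
    freqs, called = [], []
    for group in (p1, p2, p3, outgroup):
        f, c = _group_frequencies(dataset, group)
        freqs.append(f)
        called.append(c)
    usable = np.logical_and.reduce(called)
    if not usable.any():
        raise ValueError("no site has calls in all four groups")
    f1, f2, f3, f4 = (f[usable] for f in freqs)
    abba = (1 - f1) * f2 * f3 * (1 - f4)
    baba = f1 * (1 - f2) * f3 * (1 - f4)
    num = abba - baba
    den = abba + baba
    n_used = int(usable.sum())
    config = {
        "p1": list(p1),
        "p2": list(p2),
        "p3": list(p3),
        "outgroup": list(outgroup) if outgroup else [],
        "n_boot": n_boot,
        "block": block,
        "seed": seed,
        "z_threshold": z_threshold,
    }
    den_total = float(den.sum())
    if den_total == 0:
        return DStatResult(
            d=float("nan"), z=float("nan"), significant=False,
            n_sites_used=n_used, replicates=np.empty(0), undefined=True,
            config=config,
        )
    d = float(num.sum() / den_total)

    rng = np.random.default_rng(seed)
    if block and block > 1:
        n_blocks = -(-n_used // block)
        pad = n_blocks * block - n_used
        num_b = np.pad(num, (0, pad)).reshape(n_blocks, block).sum(axis=1)
        den_b = np.pad(den, (0, pad)).reshape(n_blocks, block).sum(axis=1)
    else:
        n_blocks, num_b, den_b = n_used, num, den
    weights = rng.multinomial(n_blocks, np.full(n_blocks, 1 / n_blocks), size=n_boot)
    rep_num = weights @ num_b
    rep_den = weights @ den_b
    with np.errstate(invalid="ignore", divide="ignore"):
        replicates = np.where(rep_den != 0, rep_num / rep_den, np.nan)
    sd = float(np.nanstd(replicates, ddof=1))
    z = d / sd if sd > 0 else float("inf") if d != 0 else 0.0
    return DStatResult(
        d=d,
        z=float(z),
        significant=bool(abs(z) >= z_threshold),
        n_sites_used=n_used,
        replicates=replicates,
        config=config,
    )
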