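"""Panel-based cohort analysis: sample QC, mtDNA haplogroup assignment,
supervised clade assignment, PCA and a distance dendrogram.

The clade assigner is a supervised Hardy-Weinberg likelihood classifier
(scikit-learn estimator API): per-clade allele frequencies are estimated
from reference samples with a pseudocount, and each query sample's
posterior over the four clades is the normalized product of HWE genotype
probabilities over its called SNPs under a uniform prior.

Haplogroup calls follow the grading rules of the panel protocol: with
call-rate ``r`` over the 14 mtDNA SNPs, ``r < 0.60`` yields an unknown
('?') call, ``0.60 <= r <= 0.85`` a qualified call, and ``r > 0.85`` a
confident call; the label is the haplogroup matching the most called SNPs,
with conflicts flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .datamodel import MISSING, PanelCalls
from .filters import sample_missingness

GRADE_CONFIDENT = "confident"
GRADE_QUALIFIED = "qualified"
GRADE_UNKNOWN = "unknown"


def qc_exclude_missing(
    calls: PanelCalls, max_missing: float = 0.25
) -> tuple[list[str], list[str], pd.Series]:
    """Partition samples by autosomal missingness.

    A sample is excluded iff its missing fraction over the autosomal panel
    SNPs exceeds ``max_missing`` (strict inequality: exactly 25% missing is
    retained).  Returns ``(retained, excluded, missing_fraction)``.
    """
    frac = sample_missingness(calls.autosomal())
    excluded = list(frac.index[frac > max_missing])
    retained = list(frac.index[frac <= max_missing])
    return retained, excluded, frac


@dataclass
class HaplogroupCall:
    label: str  # haplogroup name, "?" when unknown, "A|B" on ties
    grade: str  # confident / qualified / unknown
    n_called: int
    n_matched: int
    n_conflicts: int


def assign_haplogroup(
    sample_calls: pd.Series,
    key: pd.DataFrame,
    qual_lo: float = 0.60,
    qual_hi: float = 0.85,
) -> HaplogroupCall:
    """Assign a mtDNA haplogroup from diagnostic-SNP calls.

    ``sample_calls`` holds haploid states (0/1, -1 missing) at the panel's
    mtDNA SNPs; ``key`` is the haplogroup x SNP expected-state table.  The
    best match maximizes agreement over called SNPs.  Grading is a pure
    function of the call rate: below ``qual_lo`` the haplogroup is unknown
    ('?'); within ``[qual_lo, qual_hi]`` (both ends inclusive) the call is
    qualified; above ``qual_hi`` it is confident.  A tie between
    haplogroups labels both and forces the qualified grade.
    """
    snps = list(key.columns)
    calls = sample_calls[snps]
    called = calls != MISSING
    n_called = int(called.sum())
    r = n_called / len(snps)
    if r < qual_lo:
        return HaplogroupCall("?", GRADE_UNKNOWN, n_called, 0, 0)
    matches = (key.loc[:, called].eq(calls[called], axis=1)).sum(axis=1)
    best = int(matches.max())
    winners = list(matches.index[matches == best])
    n_conflicts = n_called - best
    if len(winners) > 1:
        return HaplogroupCall(
            "|".join(winners), GRADE_QUALIFIED, n_called, best, n_conflicts
        )
    grade = GRADE_QUALIFIED if r <= qual_hi else GRADE_CONFIDENT
    return HaplogroupCall(winners[0], grade, n_called, best, n_conflicts)


def reference_frequencies(
    calls: PanelCalls | pd.DataFrame,
    sheet: pd.DataFrame,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-clade alternate-allele frequencies at the autosomal panel SNPs.

    ``freq = (alt count + pseudocount) / (2 * n_called + 2 * pseudocount)``
    per clade per SNP; with pseudocount >= 1 frequencies stay inside (0, 1).
    """
    frame = calls.autosomal() if isinstance(calls, PanelCalls) else calls
    sheet = sheet.set_index("sample") if "sample" in sheet.columns else sheet
    clades = sorted(sheet["region"].unique())
    rows = {}
    for clade in clades:
        members = [s for s in sheet.index[sheet["region"] == clade] if s in frame.index]
        if not members:
            raise ValueError(f"clade {clade!r} has zero reference samples")
        sub = frame.loc[members].to_numpy(float)
        called = sub != MISSING
        alt = np.where(called, sub, 0.0).sum(axis=0)
        n_called = called.sum(axis=0)
        rows[clade] = (alt + pseudocount) / (2 * n_called + 2 * pseudocount)
    return pd.DataFrame(rows, index=frame.columns).T


class CladeAssigner(BaseEstimator, ClassifierMixin):
    """Supervised HWE-likelihood clade classifier.

    Parameters
    ----------
    pseudocount :
        Added to allele counts when estimating per-clade frequencies;
        keeps genotype probabilities strictly positive.

    Attributes
    ----------
    classes_ : ndarray of clade labels seen in ``fit``.
    frequencies_ : DataFrame (clade x SNP) of alternate-allele frequencies.
    """

    def __init__(self, pseudocount: float = 1.0):
        self.pseudocount = pseudocount

    def fit(self, X, y):
        """Estimate per-clade allele frequencies from reference samples.

        ``X`` is a (samples x SNPs) dosage matrix (DataFrame or array,
        missing = -1), ``y`` the clade label per sample.
        """
        X = pd.DataFrame(X)
        y = np.asarray(y)
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        self.classes_ = np.array(sorted(set(y)))
        sheet = pd.DataFrame({"sample": X.index, "region": y})
        self.frequencies_ = reference_frequencies(
            X, sheet, pseudocount=self.pseudocount
        ).loc[self.classes_]
        return self

    def _log_likelihoods(self, X: pd.DataFrame) -> np.ndarray:
        freqs = self.frequencies_.to_numpy()  # (n_clades, n_snps)
        geno = X.to_numpy(float)  # (n_samples, n_snps)
        if geno.shape[1] != freqs.shape[1]:
            raise ValueError("SNP count differs between query and reference")
        log_p = np.stack(
            [2 * np.log1p(-freqs), np.log(2 * freqs * (1 - freqs)), 2 * np.log(freqs)]
        )  # genotype x clade x snp
        called = geno != MISSING
        if not called.any(axis=1).all():
            bad = list(X.index[~called.any(axis=1)])
            raise ValueError(f"sample(s) with all panel calls missing: {bad}")
        ll = np.zeros((geno.shape[0], freqs.shape[0]))
        for g in (0, 1, 2):
            mask = called & (geno == g)  # samples x snps
            ll += mask.astype(float) @ log_p[g].T
        return ll

    def predict_proba(self, X):
        """Posterior over clades under a uniform prior; missing SNPs skipped."""
        check_is_fitted(self, "frequencies_")
        X = pd.DataFrame(X)
        ll = self._log_likelihoods(X)
        ll -= ll.max(axis=1, keepdims=True)
        post = np.exp(ll)
        return post / post.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def assign_clade(
    sample_calls: pd.Series, frequencies: pd.DataFrame
) -> pd.Series:
    """Posterior over clades for one sample given a reference frequency
    table (thin wrapper over :class:`CladeAssigner`)."""
    assigner = CladeAssigner()
    assigner.classes_ = np.asarray(frequencies.index)
    assigner.frequencies_ = frequencies
    proba = assigner.predict_proba(pd.DataFrame([sample_calls]))
    return pd.Series(proba[0], index=frequencies.index)


class PanelPCA(BaseEstimator, TransformerMixin):
    """PCA of a panel genotype matrix with per-SNP mean imputation.

    Missing cells are imputed with the SNP mean dosage, columns are
    centered, and the sign of each component is fixed so its
    largest-magnitude loading is positive (sample-order invariant).
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        if len(X) < 2:
            raise ValueError("PCA needs at least 2 samples")
        matrix = X.to_numpy(float)
        matrix[matrix == MISSING] = np.nan
        self.means_ = np.nanmean(matrix, axis=0)
        self.means_ = np.nan_to_num(self.means_)  # all-missing SNP -> 0
        filled = np.where(np.isnan(matrix), self.means_, matrix)
        n_comp = min(self.n_components, len(X) - 1, filled.shape[1])
        self._pca = PCA(n_components=n_comp)
        self._pca.fit(filled)  # PCA centers columns itself
        flip = np.sign(
            self._pca.components_[
                np.arange(n_comp), np.abs(self._pca.components_).argmax(axis=1)
            ]
        )
        flip[flip == 0] = 1.0
        self._flip = flip
        self.explained_variance_ratio_ = self._pca.explained_variance_ratio_
        return self

    def transform(self, X):
        check_is_fitted(self, "_pca")
        X = pd.DataFrame(X)
        matrix = X.to_numpy(float)
        matrix[matrix == MISSING] = np.nan
        filled = np.where(np.isnan(matrix), self.means_, matrix)
        return self._pca.transform(filled) * self._flip


def pca_panel(
    calls: PanelCalls | pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample coordinates on the leading components plus explained-variance
    fractions (thin wrapper over :class:`PanelPCA`)."""
    frame = calls.autosomal() if isinstance(calls, PanelCalls) else calls
    pca = PanelPCA(n_components=n_components)
    coords = pca.fit(frame).transform(frame)
    columns = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return (
        pd.DataFrame(coords, index=frame.index, columns=columns),
        pca.explained_variance_ratio_,
    )


def allele_sharing_distance(frame: pd.DataFrame) -> pd.DataFrame:
    """Pairwise distance ``1 - shared-allele fraction`` over jointly called
    SNPs; for diploid dosages the shared fraction is ``1 - |g_i - g_j| / 2``.
    """
    matrix = frame.to_numpy(float)
    matrix[matrix == MISSING] = np.nan
    n = len(frame)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            joint = ~np.isnan(matrix[i]) & ~np.isnan(matrix[j])
            if not joint.any():
                raise ValueError(
                    f"samples {frame.index[i]!r} and {frame.index[j]!r} share no calls"
                )
            d = float(np.abs(matrix[i, joint] - matrix[j, joint]).mean() / 2)
            dist[i, j] = dist[j, i] = d
    return pd.DataFrame(dist, index=frame.index, columns=frame.index)


def distance_tree(calls: PanelCalls | pd.DataFrame) -> str:
    """Neighbor-joining tree on allele-sharing distances, as newick."""
    frame = calls.autosomal() if isinstance(calls, PanelCalls) else calls
    if len(frame) < 3:
        raise ValueError("need >= 3 samples for a tree")
    dist = allele_sharing_distance(frame)
    dm = DistanceMatrix(dist.to_numpy(), [str(s) for s in frame.index])
    tree = nj(dm)
    return str(tree).strip()


def tree_bipartitions(newick: str) -> set[frozenset[str]]:
    """All non-trivial bipartitions of an unrooted tree, each given as the
    smaller-or-equal side's tip set (complement-normalized)."""
    tree = TreeNode.read([newick])
    tips = frozenset(t.name for t in tree.tips())
    splits: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(tips) - 1:
            other = tips - side
            splits.add(side if len(side) <= len(other) else frozenset(other))
    return splits


def has_bipartition(newick: str, group: set[str]) -> bool:
    """True iff the tree contains the bipartition separating ``group`` from
    the remaining tips."""
    tree = TreeNode.read([newick])
    tips = frozenset(t.name for t in tree.tips())
    group_f = frozenset(group)
    other = tips - group_f
    normalized = group_f if len(group_f) <= len(other) else frozenset(other)
    return normalized in tree_bipartitions(newick)
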