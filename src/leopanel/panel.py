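"""Diagnostic SNP-panel design.

Autosomal candidates are screened by six criteria mirroring the KASP-assay
constraints of the study protocol:

1. combined read depth across all samples >= 20 at every position of the
   101-nt window (50 bp either side of the SNP);
2. at most one other variable position across the two 50-bp flanks
   (conservative total reading; a per-flank reading is available);
3. clean mapping of the flanking region — an automated proxy for a by-eye
   browser check, passing with an "unassessed" flag when no auxiliary
   mapping statistics are supplied;
4. a genotype call in at least eight individuals at the focal site;
5. at most one SNP per scaffold, spread across chromosomes round-robin;
6. sites where every scored individual is heterozygous are excluded
   (possible collapsed duplications); sites showing both heterozygous and
   homozygous genotypes earn a soft scoring bonus.

Mitochondrial panel SNPs are chosen from the haplogroup key so that every
haplogroup is distinguished, exactly two SNPs are diagnostic for the
northern/southern subspecies split, and no selected SNP sits in a nuclear
mitochondrial copy (numt), screened by local alignment of its flank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

from .datamodel import (
    HAPLOGROUPS,
    HET,
    MISSING,
    SiteRecord,
    VariantDataset,
)
from .simulate import FlankInfo, mt_flank

logger = logging.getLogger(__name__)

HARD_CRITERIA = (
    "flank_coverage",
    "flank_variants",
    "mapping_quality",
    "min_individuals",
    "not_all_het",
)


@dataclass
class PanelCandidate:
    """One autosomal candidate SNP with its selection context."""

    site: SiteRecord
    flank_seq: str
    flank_variant_offsets: tuple[int, ...]  # 1-based window offsets, focal (51) excluded
    calls: np.ndarray  # per-sample codes at the focal site
    depths: np.ndarray
    window_depth: np.ndarray  # combined depth per window position (101,)
    mapping_stats: dict | None = None  # e.g. {"softclip_frac": .., "indel_distance": ..}
    criteria: dict[str, bool] = field(default_factory=dict)
    flags: set[str] = field(default_factory=set)
    soft_bonus: int = 0
    score: float | None = None

    @property
    def hard_pass(self) -> bool:
        return all(self.criteria.get(c, False) for c in HARD_CRITERIA)


@dataclass
class PanelDefinition:
    """Selected autosomal + mtDNA panel SNPs with selection provenance."""

    autosomal: pd.DataFrame
    mtdna: pd.DataFrame
    params: dict = field(default_factory=dict)

    @property
    def autosomal_ids(self) -> list[str]:
        return list(self.autosomal["snp_id"])

    @property
    def mtdna_ids(self) -> list[str]:
        return list(self.mtdna["snp_id"])

    def to_csv(self, path) -> None:
        auto = self.autosomal.assign(marker="autosomal")
        mito = self.mtdna.assign(marker="mtdna")
        pd.concat([auto, mito], ignore_index=True).to_csv(path, index=False)


def check_flank_coverage(
    candidate: PanelCandidate, min_combined: int = 20, window: int = 50
) -> bool:
    """Criterion 1: minimum summed depth across samples >= ``min_combined``
    at every position of the (2*window + 1)-nt window."""
    profile = candidate.window_depth
    if len(profile) != 2 * window + 1:
        candidate.flags.add("edge")
        return False
    return bool(profile.min() >= min_combined)


def check_flank_variants(
    candidate: PanelCandidate, max_variants: int = 1, per_flank: bool = False
) -> bool:
    """Criterion 2: at most ``max_variants`` other variable positions in the
    flanks — totalled across both flanks by default, or per flank."""
    offsets = [o for o in candidate.flank_variant_offsets if o != 51]
    if per_flank:
        upstream = sum(o < 51 for o in offsets)
        downstream = sum(o > 51 for o in offsets)
        return max(upstream, downstream) <= max_variants
    return len(offsets) <= max_variants


def check_mapping_quality_proxy(
    candidate: PanelCandidate,
    max_softclip_frac: float = 0.1,
    max_indel_near: int = 5,
) -> bool:
    """Criterion 3 proxy: deterministic pass/fail on per-window mapping
    statistics; passes with an "unassessed" flag when stats are absent."""
    stats = candidate.mapping_stats
    if stats is None:
        candidate.flags.add("unassessed")
        return True
    if stats.get("softclip_frac", 0.0) > max_softclip_frac:
        return False
    indel_distance = stats.get("indel_distance")
    if indel_distance is not None and indel_distance <= max_indel_near:
        return False
    return True


def check_min_individuals(candidate: PanelCandidate, min_called: int = 8) -> bool:
    """Criterion 4: non-missing calls at the focal site in >= ``min_called``
    individuals."""
    return int((candidate.calls != MISSING).sum()) >= min_called


def check_genotype_composition(candidate: PanelCandidate) -> tuple[bool, int]:
    """Criterion 6: hard-fail sites where every scored call is heterozygous;
    soft bonus 1 when both het and homozygote genotypes are present."""
    scored = candidate.calls[candidate.calls != MISSING]
    n_het = int((scored == HET).sum())
    all_het = len(scored) > 0 and n_het == len(scored)
    bonus = 1 if 0 < n_het < len(scored) else 0
    return (not all_het, bonus)


def evaluate_candidates(
    candidates: list[PanelCandidate],
    min_combined: int = 20,
    window: int = 50,
    max_flank_variants: int = 1,
    per_flank: bool = False,
    min_called: int = 8,
    max_softclip_frac: float = 0.1,
    max_indel_near: int = 5,
) -> list[PanelCandidate]:
    """Evaluate every criterion on every candidate and compute scores.

    Score = called-sample count + composition bonus, defined only for
    candidates passing all hard criteria.
    """
    for cand in candidates:
        cand.criteria["flank_coverage"] = check_flank_coverage(cand, min_combined, window)
        cand.criteria["flank_variants"] = check_flank_variants(
            cand, max_flank_variants, per_flank
        )
        cand.criteria["mapping_quality"] = check_mapping_quality_proxy(
            cand, max_softclip_frac, max_indel_near
        )
        cand.criteria["min_individuals"] = check_min_individuals(cand, min_called)
        hard_ok, bonus = check_genotype_composition(cand)
        cand.criteria["not_all_het"] = hard_ok
        cand.soft_bonus = bonus
        if cand.hard_pass:
            cand.score = float((cand.calls != MISSING).sum() + bonus)
        else:
            cand.score = None
    return candidates


def build_candidates(
    dataset: VariantDataset, flanks: dict[str, FlankInfo]
) -> list[PanelCandidate]:
    """Assemble candidates from a (chromosome-attributed) dataset plus the
    per-site flank context."""
    candidates = []
    for i, site in enumerate(dataset.sites):
        info = flanks[site.snp_id]
        candidates.append(
            PanelCandidate(
                site=site,
                flank_seq=info.sequence,
                flank_variant_offsets=info.variant_offsets,
                calls=dataset.genotypes[i].copy(),
                depths=dataset.depths[i].copy(),
                window_depth=np.asarray(info.window_depth),
            )
        )
    return candidates


def _sort_key(cand: PanelCandidate) -> tuple:
    # descending score, then (chromosome, position) lexicographic
    return (-(cand.score or 0), cand.site.chromosome or "unplaced",
            cand.site.scaffold, cand.site.position)


def select_autosomal_panel(
    candidates: list[PanelCandidate], target_n: int = 125
) -> PanelDefinition:
    """Greedy selection of the autosomal panel.

    Only hard-pass candidates are eligible; at most one SNP per scaffold
    (the best-scoring); chromosomes are then filled round-robin by
    descending within-chromosome score until ``target_n`` is reached or
    candidates are exhausted (fewer returned with a warning).
    """
    eligible = [c for c in candidates if c.hard_pass]
    if not eligible:
        raise ValueError("no candidate passes all hard criteria")

    best_per_scaffold: dict[str, PanelCandidate] = {}
    for cand in sorted(eligible, key=_sort_key):
        best_per_scaffold.setdefault(cand.site.scaffold, cand)

    by_chromosome: dict[str, list[PanelCandidate]] = {}
    for cand in best_per_scaffold.values():
        by_chromosome.setdefault(cand.site.chromosome or "unplaced", []).append(cand)
    for chrom in by_chromosome:
        by_chromosome[chrom].sort(key=_sort_key)

    selected: list[PanelCandidate] = []
    queues = {chrom: list(cands) for chrom, cands in sorted(by_chromosome.items())}
    while len(selected) < target_n and any(queues.values()):
        for chrom in sorted(queues):
            if queues[chrom] and len(selected) < target_n:
                selected.append(queues[chrom].pop(0))
    if len(selected) < target_n:
        logger.warning(
            "only %d eligible candidate(s) for a target of %d", len(selected), target_n
        )
    rows = [
        {
            "snp_id": c.site.snp_id,
            "scaffold": c.site.scaffold,
            "position": c.site.position,
            "chromosome": c.site.chromosome or "unplaced",
            "ref": c.site.ref,
            "alt": c.site.alt,
            "score": c.score,
            "soft_bonus": c.soft_bonus,
            "flank": c.flank_seq,
            "flags": ";".join(sorted(c.flags)),
        }
        for c in selected
    ]
    autosomal = pd.DataFrame(rows).sort_values(
        ["chromosome", "scaffold", "position"], ignore_index=True
    )
    return PanelDefinition(
        autosomal=autosomal,
        mtdna=pd.DataFrame(
            columns=["snp_id", "position", "ref", "alt", "branch", "subspecies_diagnostic"]
        ),
        params={"target_autosomal": target_n},
    )


_aligner = Align.PairwiseAligner(
    mode="local",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-2,
    extend_gap_score=-2,
)


def screen_numts(
    flank: str,
    numts: dict[str, str],
    min_identity: float = 0.8,
    min_length: int = 40,
    focal_index: int = 50,
) -> tuple[bool, set[str]]:
    """Numt-contamination screen for a mitochondrial candidate flank.

    Locally aligns the 101-nt flank against each numt sequence; the
    candidate is at risk iff some alignment covers the focal position with
    identity >= ``min_identity`` over >= ``min_length`` aligned columns.
    Returns ``(risk, flags)``; an empty numt set yields ``(False,
    {"unscreened"})``.
    """
    if not numts:
        return False, {"unscreened"}
    for seq in numts.values():
        alignments = _aligner.align(seq, flank)
        if len(alignments) == 0:
            continue
        aln = alignments[0]
        target_ranges, query_ranges = aln.aligned
        covers = any(start <= focal_index < end for start, end in query_ranges)
        if not covers:
            continue
        counts = aln.counts()
        aligned_cols = counts.identities + counts.mismatches
        if aligned_cols < min_length:
            continue
        identity = counts.identities / aligned_cols
        if identity >= min_identity:
            return True, set()
    return False, set()


def select_mtdna_panel(
    key: pd.DataFrame,
    numts: dict[str, str],
    mt_genome: str,
    target_n: int = 14,
    min_identity: float = 0.8,
    min_length: int = 40,
) -> PanelDefinition:
    """Select the mitochondrial panel from the haplogroup candidate key.

    Picks exactly two numt-clean subspecies-diagnostic SNPs plus
    branch-private SNPs allocated round-robin over the six haplogroups
    until ``target_n``; every haplogroup must end up distinguished by at
    least one selected SNP.  Raises when a branch has no numt-clean
    candidate or ``target_n`` is infeasible.
    """
    meta = key.attrs["site_meta"]
    branches = list(HAPLOGROUPS)
    if target_n < len(branches) + 2:
        raise ValueError(
            f"target_n={target_n} infeasible: need >= {len(branches) + 2} "
            "(one SNP per haplogroup plus two subspecies-diagnostic SNPs)"
        )
    clean: dict[str, list[str]] = {role: [] for role in ["subspecies"] + branches}
    flags: dict[str, set[str]] = {}
    for snp_id, row in meta.iterrows():
        risk, snp_flags = screen_numts(
            mt_flank(mt_genome, row["position"]), numts, min_identity, min_length
        )
        flags[snp_id] = snp_flags
        if not risk:
            clean[row["branch"]].append(snp_id)

    contaminated = [b for b in branches if not clean[b]]
    if contaminated:
        raise ValueError(
            "haplogroup branch(es) without a numt-clean diagnostic candidate: "
            + ", ".join(contaminated)
        )
    if len(clean["subspecies"]) < 2:
        raise ValueError(
            "fewer than two numt-clean subspecies-diagnostic candidates"
        )

    selected: list[str] = clean["subspecies"][:2]
    queues = {b: list(clean[b]) for b in branches}
    while len(selected) < target_n and any(queues.values()):
        for branch in branches:
            if queues[branch] and len(selected) < target_n:
                selected.append(queues[branch].pop(0))
    if len(selected) < target_n:
        raise ValueError(
            f"only {len(selected)} numt-clean candidates for target {target_n}"
        )

    sub_key = key[selected]
    for i, a in enumerate(HAPLOGROUPS):
        for b in HAPLOGROUPS[i + 1 :]:
            if (sub_key.loc[a] == sub_key.loc[b]).all():
                raise ValueError(f"selected SNPs cannot separate {a!r} from {b!r}")

    rows = [
        {
            "snp_id": snp_id,
            "position": meta.loc[snp_id, "position"],
            "ref": meta.loc[snp_id, "ref"],
            "alt": meta.loc[snp_id, "alt"],
            "branch": meta.loc[snp_id, "branch"],
            "subspecies_diagnostic": meta.loc[snp_id, "branch"] == "subspecies",
            "flags": ";".join(sorted(flags[snp_id])),
        }
        for snp_id in selected
    ]
    return PanelDefinition(
        autosomal=pd.DataFrame(
            columns=["snp_id", "scaffold", "position", "chromosome", "ref", "alt",
                     "score", "soft_bonus", "flank", "flags"]
        ),
        mtdna=pd.DataFrame(rows),
        params={"target_mtdna": target_n},
    )


def combine_panels(autosomal: PanelDefinition, mtdna: PanelDefinition) -> PanelDefinition:
    return PanelDefinition(
        autosomal=autosomal.autosomal,
        mtdna=mtdna.mtdna,
        params={**autosomal.params, **mtdna.params},
    )


def apply_panel(
    dataset: VariantDataset,
    panel: PanelDefinition,
    mt_calls: pd.DataFrame | None = None,
) -> "PanelCalls":
    """Extract panel-SNP genotypes from a cohort dataset as PanelCalls.

    Autosomal columns come from the dataset's calls at the panel sites;
    mitochondrial columns come from ``mt_calls`` (samples x mt SNP ids,
    haploid 0/1 states, -1 missing) restricted to the selected mtDNA SNPs.
    """
    from .datamodel import PanelCalls

    site_index = {s.snp_id: i for i, s in enumerate(dataset.sites)}
    missing_ids = [sid for sid in panel.autosomal_ids if sid not in site_index]
    if missing_ids:
        raise KeyError(f"panel SNP(s) absent from dataset: {missing_ids[:5]}")
    auto = pd.DataFrame(
        {sid: dataset.genotypes[site_index[sid]] for sid in panel.autosomal_ids},
        index=dataset.samples,
        dtype="int8",
    )
    frames = [auto]
    mito_ids: list[str] = []
    if mt_calls is not None and panel.mtdna_ids:
        mito_ids = panel.mtdna_ids
        frames.append(mt_calls.loc[dataset.samples, mito_ids].astype("int8"))
    calls = pd.concat(frames, axis=1)
    is_mtdna = pd.Series(
        [c in set(mito_ids) for c in calls.columns], index=calls.columns
    )
    return PanelCalls(calls=calls, is_mtdna=is_mtdna)


def read_panel_csv(path) -> PanelDefinition:
    """Load a PanelDefinition written by :meth:`PanelDefinition.to_csv`."""
    frame = pd.read_csv(path, keep_default_na=False, na_values=[""])
    auto = frame[frame["marker"] == "autosomal"].drop(columns=["marker"])
    mito = frame[frame["marker"] == "mtdna"].drop(columns=["marker"])
    auto = auto.dropna(axis=1, how="all").reset_index(drop=True)
    mito = mito.dropna(axis=1, how="all").reset_index(drop=True)
    if "position" in auto.columns:
        auto["position"] = auto["position"].astype(int)
    if "position" in mito.columns:
        mito["position"] = mito["position"].astype(int)
    if "subspecies_diagnostic" in mito.columns:
        mito["subspecies_diagnostic"] = mito["subspecies_diagnostic"].astype(str).str.lower().eq("true")
    return PanelDefinition(autosomal=auto, mtdna=mito)
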