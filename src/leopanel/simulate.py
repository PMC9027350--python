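"""Synthetic structured-population generator.

Emulates the statistical structure of a range-wide lion cohort so the whole
pipeline can be exercised without sequencing data:

* a hierarchical Balding-Nichols allele-frequency model — an ancestral
  frequency drifts first into the two subspecies (northern *P. leo leo*,
  southern *P. leo melanochaita*) and then into two clades per subspecies,
  with a separately elevated drift coefficient for the India clade to mimic
  its bottleneck;
* admixed individuals via mixture dosages ``Binomial(2, sum_c q_c p_c)``;
* a low-coverage sequencing observation model: per-cell Poisson depth,
  depth 0 = missing, and allelic dropout of heterozygotes (a het with depth
  ``d`` is observed het only with probability ``1 - 2**(1 - d)``);
* 101-nt flanking sequences with truth-tracked extra variable positions and
  combined-depth window profiles for the panel-design criteria;
* mitochondrial haplotypes over six haplogroups keyed by 14 diagnostic
  sites, plus nuclear-copy (numt) decoy sequences at configurable
  divergence.

All generators are deterministic under the config seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    CLADES,
    HAPLOGROUPS,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    NORTHERN_HAPLOGROUPS,
    NUCLEOTIDES,
    SUBSPECIES_OF,
    PanelCalls,
    SiteRecord,
    VariantDataset,
)
from . import io as lio

#: Felid autosomes (tiger karyotype: 18 autosome pairs), used to spread
#: synthetic scaffolds across chromosomes.
TIGER_AUTOSOMES = (
    "A1", "A2", "A3",
    "B1", "B2", "B3", "B4",
    "C1", "C2",
    "D1", "D2", "D3", "D4",
    "E1", "E2", "E3",
    "F1", "F2",
)

#: Length of the reference lion mitogenome the synthetic model mimics.
MT_GENOME_LENGTH = 16756

#: Nominal depth recorded in truth datasets (no observation noise applied).
TRUTH_DEPTH = 100

#: clade -> mitochondrial haplogroups plausibly carried by its members.
#: North East Africa is a northern-lineage haplogroup that co-occurs with
#: East/Southern Africa haplotypes in the East Africa clade.
CLADE_HAPLOGROUPS = {
    "West & Central Africa": ("West Africa", "Central Africa"),
    "India": ("India",),
    "East Africa": ("East/Southern Africa", "North East Africa"),
    "Southern Africa": ("East/Southern Africa", "South West Africa"),
}


@dataclass(frozen=True)
class SampleSpec:
    """One simulated individual: clade, admixture vector and mean depth."""

    id: str
    clade: str
    q: tuple[float, ...]  # admixture proportions over CLADES, sums to 1
    depth: float  # mean per-cell sequencing depth (lambda)

    def __post_init__(self) -> None:
        if self.clade not in CLADES:
            raise ValueError(f"unknown clade {self.clade!r}")
        if len(self.q) != len(CLADES):
            raise ValueError(f"q must have {len(CLADES)} entries")
        if abs(sum(self.q) - 1.0) > 1e-9:
            raise ValueError(f"q must sum to 1, got {sum(self.q)}")
        if self.depth <= 0:
            raise ValueError("mean depth must be > 0")


@dataclass(frozen=True)
class GeneFlowSpec:
    """Post-split migration: donor-clade alleles enter the recipient clade
    at ``migrant_fraction`` on a random ``site_fraction`` of sites."""

    donor: str
    recipient: str
    migrant_fraction: float
    site_fraction: float

    def __post_init__(self) -> None:
        for clade in (self.donor, self.recipient):
            if clade not in CLADES:
                raise ValueError(f"unknown clade {clade!r}")
        if not 0 <= self.migrant_fraction <= 1:
            raise ValueError("migrant_fraction must be in [0, 1]")
        if not 0 <= self.site_fraction <= 1:
            raise ValueError("site_fraction must be in [0, 1]")


@dataclass
class DemographyConfig:
    """Parameters of the hierarchical Balding-Nichols demography."""

    n_sites: int
    samples: list[SampleSpec]
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    f_subspecies: float = 0.15
    f_clade: dict[str, float] = field(
        default_factory=lambda: {
            "West & Central Africa": 0.05,
            "India": 0.5,  # bottlenecked, low-diversity clade
            "East Africa": 0.05,
            "Southern Africa": 0.05,
        }
    )
    seed: int = 0
    sites_per_scaffold: int = 5
    flank_variant_rate: float = 0.5  # Poisson mean per 50-bp flank
    gene_flow: GeneFlowSpec | None = None

    def __post_init__(self) -> None:
        lo, hi = self.ancestral_maf_range
        if not (0 < lo <= hi < 1):
            raise ValueError("ancestral_maf_range must lie within (0, 1)")
        for name, f in [("f_subspecies", self.f_subspecies)] + [
            (f"f_clade[{c}]", self.f_clade[c]) for c in CLADES
        ]:
            if not 0 <= f < 1:
                raise ValueError(f"{name} must be in [0, 1); F=1 is rejected")
        if set(self.f_clade) != set(CLADES):
            raise ValueError(f"f_clade must cover exactly the clades {CLADES}")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not self.samples:
            raise ValueError("at least one sample is required")


@dataclass
class MtDNAModel:
    """Mitochondrial haplogroup key and numt decoy parameters.

    The key spans ``2 + 2 * len(HAPLOGROUPS)`` candidate diagnostic sites by
    default: per haplogroup, ``candidates_per_branch`` private sites (alt
    state in that haplogroup only) and ``subspecies_candidates`` sites split
    by the northern/southern dichotomy, of which two end up in the panel.
    """

    candidates_per_branch: int = 3
    subspecies_candidates: int = 4
    numt_count: int = 3
    numt_length: int = 800
    numt_divergence: float = 0.15
    genome_length: int = MT_GENOME_LENGTH
    clade_haplogroups: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(CLADE_HAPLOGROUPS)
    )

    def __post_init__(self) -> None:
        if not 0 <= self.numt_divergence < 1:
            raise ValueError("numt_divergence must be in [0, 1)")
        missing = set(CLADES) - set(self.clade_haplogroups)
        if missing:
            raise ValueError(f"clade->haplogroup map incomplete: missing {sorted(missing)}")
        for clade, groups in self.clade_haplogroups.items():
            unknown = set(groups) - set(HAPLOGROUPS)
            if unknown:
                raise ValueError(f"unknown haplogroup(s) for {clade}: {sorted(unknown)}")

    @property
    def n_candidates(self) -> int:
        return self.subspecies_candidates + self.candidates_per_branch * len(HAPLOGROUPS)


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    """Draw drifted frequencies around ``p`` with coefficient ``f``.

    ``f = 0`` is the no-drift limit (frequencies copied); ``f = 1`` is
    rejected at config validation.  Parent frequencies are clipped away from
    the {0, 1} boundary so the Beta parameters stay positive.
    """
    if f == 0:
        return p.copy()
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    scale = (1 - f) / f
    return rng.beta(p * scale, (1 - p) * scale)


def simulate_allele_frequencies(config: DemographyConfig) -> pd.DataFrame:
    """Draw the per-clade allele-frequency table.

    Returns a frame with columns ``ancestral``, ``northern``, ``southern``
    and one per clade; ``attrs["gene_flow_sites"]`` records the indices of
    sites modified by gene flow (empty if none).
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.ancestral_maf_range
    ancestral = rng.uniform(lo, hi, size=config.n_sites)
    freqs = pd.DataFrame({"ancestral": ancestral})
    for subspecies in ("northern", "southern"):
        freqs[subspecies] = _balding_nichols(rng, ancestral, config.f_subspecies)
    for clade in CLADES:
        parent = freqs[SUBSPECIES_OF[clade]].to_numpy()
        freqs[clade] = _balding_nichols(rng, parent, config.f_clade[clade])
    flow_sites = np.array([], dtype=int)
    if config.gene_flow is not None:
        gf = config.gene_flow
        n_flow = int(round(gf.site_fraction * config.n_sites))
        flow_sites = rng.choice(config.n_sites, size=n_flow, replace=False)
        donor = freqs[gf.donor].to_numpy()
        recipient = freqs[gf.recipient].to_numpy().copy()
        recipient[flow_sites] = (
            (1 - gf.migrant_fraction) * recipient[flow_sites]
            + gf.migrant_fraction * donor[flow_sites]
        )
        freqs[gf.recipient] = recipient
    freqs.attrs["gene_flow_sites"] = flow_sites
    return freqs


def _make_sites(config: DemographyConfig, rng: np.random.Generator) -> tuple[list[SiteRecord], dict[str, str]]:
    """Invent scaffolds, positions and alleles; map scaffolds to autosomes."""
    n_scaffolds = max(1, -(-config.n_sites // config.sites_per_scaffold))
    scaffold_names = [f"scaffold_{i:05d}" for i in range(n_scaffolds)]
    scaffold_map = {
        name: TIGER_AUTOSOMES[i % len(TIGER_AUTOSOMES)]
        for i, name in enumerate(scaffold_names)
    }
    sites: list[SiteRecord] = []
    for j in range(config.n_sites):
        scaffold = scaffold_names[j // config.sites_per_scaffold]
        within = j % config.sites_per_scaffold
        position = 1000 + within * 500  # >= 101 nt apart: flanks never overlap
        ref, alt = rng.choice(4, size=2, replace=False)
        sites.append(SiteRecord(scaffold, position, NUCLEOTIDES[ref], NUCLEOTIDES[alt]))
    return sites, scaffold_map


def simulate_genotypes(
    freqs: pd.DataFrame, config: DemographyConfig
) -> VariantDataset:
    """Draw truth genotypes: dosage ~ Binomial(2, sum_c q_c p_c) per cell."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    sites, _ = _make_sites(config, rng)
    clade_freqs = freqs[list(CLADES)].to_numpy()  # (n_sites, 4)
    q = np.array([s.q for s in config.samples])  # (n_samples, 4)
    mixed = clade_freqs @ q.T  # (n_sites, n_samples)
    genotypes = rng.binomial(2, mixed).astype(np.int8)
    depths = np.full(genotypes.shape, TRUTH_DEPTH, dtype=np.int32)
    return VariantDataset(
        sites=sites,
        samples=[s.id for s in config.samples],
        genotypes=genotypes,
        depths=depths,
    )


def simulate_coverage_and_calls(
    truth: VariantDataset, config: DemographyConfig
) -> VariantDataset:
    """Apply the low-coverage observation model to truth genotypes.

    Depth ``d ~ Poisson(lambda_i)`` per cell; ``d = 0`` is missing.  A true
    heterozygote with ``d >= 1`` is observed het only if both alleles appear
    among ``d`` uniform allele draws (probability ``1 - 2**(1-d)``), else it
    is called homozygous for the sampled allele (each direction equally
    likely).  True homozygotes are observed as-is whenever ``d >= 1``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    lam = np.array([s.depth for s in config.samples])
    depths = rng.poisson(lam, size=truth.genotypes.shape).astype(np.int32)
    observed = truth.genotypes.copy()
    observed[depths == 0] = MISSING

    het = (truth.genotypes == HET) & (depths >= 1)
    with np.errstate(over="ignore"):
        p_dropout = np.where(depths >= 1, 2.0 ** (1 - depths.astype(float)), 0.0)
    dropout = het & (rng.random(depths.shape) < p_dropout)
    hom_direction = np.where(rng.random(depths.shape) < 0.5, HOM_REF, HOM_ALT)
    observed[dropout] = hom_direction[dropout].astype(np.int8)
    return VariantDataset(
        sites=list(truth.sites),
        samples=list(truth.samples),
        genotypes=observed,
        depths=depths,
    )


@dataclass
class FlankInfo:
    """101-nt context of one candidate SNP: sequence, truth-injected extra
    variable positions (1-based window offsets, focal excluded) and the
    combined read-depth profile across samples at each window position."""

    sequence: str
    variant_offsets: tuple[int, ...]
    window_depth: np.ndarray

    @property
    def focal_base(self) -> str:
        return self.sequence[50]  # window offset 51, 1-based


def simulate_flanks(
    dataset: VariantDataset, config: DemographyConfig
) -> dict[str, FlankInfo]:
    """Generate flanking context per site: 50 nt either side of the SNP.

    Extra variable positions are injected per flank as Poisson(rate) with
    truth recorded; combined depth per window position is Poisson with mean
    equal to the summed per-sample mean depths.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    total_lambda = sum(s.depth for s in config.samples)
    flanks: dict[str, FlankInfo] = {}
    for site in dataset.sites:
        seq = rng.choice(4, size=101)
        sequence = "".join(NUCLEOTIDES[b] for b in seq)
        sequence = sequence[:50] + site.ref + sequence[51:]
        offsets: list[int] = []
        for flank_positions in (range(1, 51), range(52, 102)):
            k = rng.poisson(config.flank_variant_rate)
            if k > 0:
                k = min(k, len(flank_positions))
                offsets.extend(
                    sorted(rng.choice(list(flank_positions), size=k, replace=False))
                )
        window_depth = rng.poisson(total_lambda, size=101).astype(np.int32)
        flanks[site.snp_id] = FlankInfo(sequence, tuple(offsets), window_depth)
    return flanks


def _build_haplogroup_key(
    model: MtDNAModel, rng: np.random.Generator
) -> pd.DataFrame:
    """Candidate mtDNA diagnostic sites: haplogroup x site 0/1 state table.

    Columns carry a ``branch`` attr frame with each site's position, role
    (haplogroup name or ``"subspecies"``) and alleles.
    """
    n = model.n_candidates
    positions = np.sort(rng.choice(np.arange(101, model.genome_length - 101), size=n, replace=False))
    roles: list[str] = ["subspecies"] * model.subspecies_candidates
    for hg in HAPLOGROUPS:
        roles.extend([hg] * model.candidates_per_branch)
    key = pd.DataFrame(
        0, index=list(HAPLOGROUPS), columns=[f"mt_{p}" for p in positions], dtype=np.int8
    )
    order = rng.permutation(n)  # shuffle role->position assignment
    site_meta = []
    for slot, role in zip(order, roles):
        snp_id = key.columns[slot]
        if role == "subspecies":
            for hg in HAPLOGROUPS:
                key.loc[hg, snp_id] = 1 if hg in NORTHERN_HAPLOGROUPS else 0
        else:
            key.loc[role, snp_id] = 1
        site_meta.append((snp_id, int(positions[slot]), role))
    meta = pd.DataFrame(site_meta, columns=["snp_id", "position", "branch"]).set_index("snp_id")
    meta = meta.loc[key.columns]
    meta.index.name = "snp_id"
    key.attrs["site_meta"] = meta
    return key


def simulate_mtdna(
    model: MtDNAModel,
    samples: list[SampleSpec],
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str], str]:
    """Simulate mitochondrial data for a set of samples.

    Returns ``(haplotype_calls, key, numts, genome)`` where

    * ``haplotype_calls`` — samples x candidate-site 0/1 states (no
      missingness: haplotypes follow the haplogroup key exactly);
    * ``key`` — the haplogroup x site state table with per-site metadata in
      ``key.attrs["site_meta"]`` and per-sample haplogroups in
      ``key.attrs["sample_haplogroups"]``;
    * ``numts`` — decoy nuclear-copy sequences (mtDNA segments mutated at
      the configured divergence);
    * ``genome`` — the synthetic mitogenome the segments were copied from.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    key = _build_haplogroup_key(model, rng)
    meta = key.attrs["site_meta"]

    genome_arr = rng.choice(4, size=model.genome_length)
    genome = "".join(NUCLEOTIDES[b] for b in genome_arr)
    # write reference (state-0) alleles into the genome; alt = any other base
    ref_alleles, alt_alleles = {}, {}
    for snp_id, row in meta.iterrows():
        pos = row["position"]
        ref = genome[pos - 1]
        alt = NUCLEOTIDES[(NUCLEOTIDES.index(ref) + 1 + rng.integers(3)) % 4]
        ref_alleles[snp_id], alt_alleles[snp_id] = ref, alt
    meta["ref"] = pd.Series(ref_alleles)
    meta["alt"] = pd.Series(alt_alleles)

    assigned = {}
    for spec in samples:
        choices = model.clade_haplogroups[spec.clade]
        if not choices:
            raise ValueError(f"clade->haplogroup map incomplete for {spec.clade!r}")
        assigned[spec.id] = choices[rng.integers(len(choices))]
    calls = pd.DataFrame(
        [key.loc[assigned[s.id]].to_numpy() for s in samples],
        index=[s.id for s in samples],
        columns=key.columns,
        dtype=np.int8,
    )
    key.attrs["sample_haplogroups"] = pd.Series(assigned)

    numts: dict[str, str] = {}
    for i in range(model.numt_count):
        start = int(rng.integers(0, model.genome_length - model.numt_length))
        segment = list(genome[start : start + model.numt_length])
        mutate = rng.random(model.numt_length) < model.numt_divergence
        for j in np.flatnonzero(mutate):
            segment[j] = NUCLEOTIDES[(NUCLEOTIDES.index(segment[j]) + 1 + rng.integers(3)) % 4]
        numts[f"numt_{i}|mt:{start + 1}-{start + model.numt_length}"] = "".join(segment)
    return calls, key, numts, genome


def mt_flank(genome: str, position: int) -> str:
    """101-nt mitogenome context centred on a 1-based position."""
    return genome[position - 51 : position + 50]


def apply_mt_missingness(
    calls: pd.DataFrame, samples: list[SampleSpec], seed: int = 0
) -> pd.DataFrame:
    """Knock out mtDNA calls with per-sample probability exp(-lambda), the
    same zero-depth mass as the autosomal observation model."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    out = calls.copy()
    for spec in samples:
        p_miss = float(np.exp(-spec.depth))
        mask = rng.random(calls.shape[1]) < p_miss
        out.loc[spec.id, mask] = MISSING
    return out


# ---------------------------------------------------------------------------
# Presets


def discovery_samples() -> list[SampleSpec]:
    """Ten whole-genome discovery individuals spanning the four clades:
    three West & Central Africa (one very low coverage), one India, two East
    Africa and four Southern Africa, at ~3.8x mean depth."""

    def pure(clade: str) -> tuple[float, ...]:
        return tuple(1.0 if c == clade else 0.0 for c in CLADES)

    wca, ind, ea, sa = CLADES
    return [
        SampleSpec("Benin", wca, pure(wca), 0.5),  # ~90% missing after masking
        SampleSpec("Cameroon", wca, pure(wca), 3.8),
        SampleSpec("DRC", wca, pure(wca), 3.8),
        SampleSpec("India", ind, pure(ind), 3.8),
        SampleSpec("Somalia", ea, pure(ea), 3.8),
        SampleSpec("Kenya", ea, pure(ea), 3.8),
        SampleSpec("Zambia1", sa, pure(sa), 3.8),
        SampleSpec("Zambia2", sa, pure(sa), 3.8),
        SampleSpec("RSA", sa, pure(sa), 3.8),
        SampleSpec("Namibia", sa, pure(sa), 3.8),
    ]


def discovery_config(seed: int = 0, n_sites: int = 5000, **kwargs) -> DemographyConfig:
    """Default discovery preset: 10 samples, 4 clades, low coverage."""
    return DemographyConfig(
        n_sites=n_sites, samples=discovery_samples(), seed=seed, **kwargs
    )


def cohort_samples(seed: int = 0) -> list[SampleSpec]:
    """211 panel-genotyped individuals: 50 West & Central Africa, 20 India,
    60 East Africa, 66 Southern Africa and 15 admixed (q = 0.5/0.5 between
    East Africa and West & Central Africa, the Ethiopia/Kenya contact-zone
    analogue).  Most samples assay cleanly (lambda 3.0, ~5% missing); a
    low-quality tail (lambda 0.8, ~45% missing) exercises the QC exclusion.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 6]))
    wca, ind, ea, sa = CLADES

    def pure(clade: str) -> tuple[float, ...]:
        return tuple(1.0 if c == clade else 0.0 for c in CLADES)

    groups = [("WCA", wca, 50, 5), ("IND", ind, 20, 3), ("EA", ea, 60, 10), ("SA", sa, 66, 13)]
    samples: list[SampleSpec] = []
    for prefix, clade, count, n_low in groups:
        low = set(rng.choice(count, size=n_low, replace=False).tolist())
        for i in range(count):
            depth = 0.8 if i in low else 3.0
            samples.append(SampleSpec(f"{prefix}_{i:03d}", clade, pure(clade), depth))
    q_admix = tuple(
        0.5 if c in (ea, wca) else 0.0 for c in CLADES
    )
    for i in range(15):
        samples.append(SampleSpec(f"ADMIX_{i:03d}", ea, q_admix, 3.0))
    return samples


def cohort_config(seed: int = 0, n_sites: int = 5000, **kwargs) -> DemographyConfig:
    """Default cohort preset: 211 samples including admixed individuals."""
    return DemographyConfig(
        n_sites=n_sites, samples=cohort_samples(seed), seed=seed, **kwargs
    )


# ---------------------------------------------------------------------------
# On-disk bundle


def sample_sheet_frame(config: DemographyConfig) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [s.id for s in config.samples],
            "population": [s.id.split("_")[0] for s in config.samples],
            "region": [s.clade for s in config.samples],
            "lat": 0.0,
            "lon": 0.0,
        }
    )


def generate_dataset(
    config: DemographyConfig,
    mt_model: MtDNAModel | None = None,
    out_dir: str | Path = ".",
    force: bool = False,
) -> dict[str, Path]:
    """Write a complete synthetic bundle consumable by every downstream stage.

    Produces: observed and truth VCFs, flank FASTA, flank-variant and
    window-depth tables, numt FASTA, mtDNA candidate key and haplotype
    calls, sample sheet, scaffold map and the truth allele-frequency table.
    Identical bytes under identical seed.  Refuses a non-empty ``out_dir``
    unless ``force`` is set.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"{out_dir} is not empty (pass force=True to overwrite)")
    mt_model = mt_model or MtDNAModel()

    freqs = simulate_allele_frequencies(config)
    truth = simulate_genotypes(freqs, config)
    observed = simulate_coverage_and_calls(truth, config)
    flanks = simulate_flanks(observed, config)
    mt_calls, mt_key, numts, mt_genome = simulate_mtdna(mt_model, config.samples, config.seed)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    _, scaffold_map = _make_sites(config, rng)

    snapshot = {"seed": str(config.seed), "n_sites": str(config.n_sites)}
    paths = {
        "vcf": out_dir / "discovery.vcf",
        "truth_vcf": out_dir / "truth.vcf",
        "flanks": out_dir / "flanks.fa",
        "flank_variants": out_dir / "flank_variants.csv",
        "window_depth": out_dir / "window_depth.csv",
        "numts": out_dir / "numts.fa",
        "mt_genome": out_dir / "mt_genome.fa",
        "mt_key": out_dir / "mt_key.csv",
        "mt_calls": out_dir / "mt_calls.csv",
        "samples": out_dir / "samples.csv",
        "scaffold_map": out_dir / "scaffold_map.csv",
        "frequencies": out_dir / "truth_frequencies.csv",
    }
    lio.write_vcf(observed, paths["vcf"], header_comments=snapshot)
    lio.write_vcf(truth, paths["truth_vcf"], header_comments=snapshot)
    lio.write_fasta({sid: fi.sequence for sid, fi in flanks.items()}, paths["flanks"])
    pd.DataFrame(
        [
            {"snp_id": sid, "offsets": ";".join(map(str, fi.variant_offsets))}
            for sid, fi in flanks.items()
        ]
    ).to_csv(paths["flank_variants"], index=False)
    depth_frame = pd.DataFrame(
        {sid: fi.window_depth for sid, fi in flanks.items()}
    ).T
    depth_frame.index.name = "snp_id"
    depth_frame.to_csv(paths["window_depth"])
    lio.write_fasta(numts, paths["numts"])
    lio.write_fasta({"mt_genome": mt_genome}, paths["mt_genome"])
    key_out = mt_key.copy()
    key_out.index.name = "haplogroup"
    key_out.to_csv(paths["mt_key"])
    mt_key.attrs["site_meta"].to_csv(out_dir / "mt_site_meta.csv")
    paths["mt_site_meta"] = out_dir / "mt_site_meta.csv"
    mt_calls_out = mt_calls.copy()
    mt_calls_out.index.name = "sample"
    mt_calls_out.to_csv(paths["mt_calls"])
    lio.write_sample_sheet(sample_sheet_frame(config), paths["samples"])
    lio.write_scaffold_map(scaffold_map, paths["scaffold_map"])
    freqs.to_csv(paths["frequencies"], index_label="site_index")
    return paths
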