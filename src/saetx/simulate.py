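"""Synthetic cohorts with known ground truth.

The generator emulates the statistical structure of a bulk RNA-seq study
of the small airway epithelium: 5 nonsmokers and 6 smokers, 43-nt
single-end reads, gene abundances spread over several decades of RPKM,
multiplicative between-subject noise with a coefficient of variation of
0.25, a low intergenic read background, smoking effects on a subset of
genes, junction-spanning reads, and mutated gene-family sequences.

Counts are generated by inverting the RPKM definition: the expected
number of exon reads for a gene is RPKM x exon_kb x depth_millions, and
reads are placed uniformly within the exon model.  ``total_mapped`` of
each simulated subject equals the configured depth (the library size);
the placed records cover only the simulated loci, so quantification with
that denominator is unbiased for the true RPKM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm, truncnorm

from .model import AlignmentSet, Gene, GenomeAnnotation, NONSMOKER, SMOKER


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the study design: 5 vs 6 subjects, between-subject
    CV 0.25, log10 RPKM ~ Normal(0.5, 1.0) truncated to [-2, 4.6], and
    an intergenic background at 1/50 of the mean exonic read density.
    """

    n_genes: int = 500
    exons_per_gene_mean: float = 5.0  # exon count = 1 + Poisson(mean - 1)
    exon_length_log_mean: float = np.log(170.0)
    exon_length_log_sd: float = 0.6
    min_exon_length: int = 50
    intron_length_log_mean: float = np.log(1000.0)
    intron_length_log_sd: float = 0.8
    min_intron_length: int = 60
    gap_log_mean: float = np.log(5000.0)
    gap_log_sd: float = 0.7
    min_gap: int = 500
    chromosome_length: int | None = None  # None: chromosome grows as needed
    n_nonsmokers: int = 5
    n_smokers: int = 6
    abundance_log10_mean: float = 0.5
    abundance_log10_sd: float = 1.0
    abundance_log10_range: tuple[float, float] = (-2.0, 4.6)
    cv: float = 0.25
    depth: int = 5_000_000
    background_relative_density: float = 0.02  # vs mean exon density
    responsive_fraction: float = 0.1
    effect_log2_mean: float = 1.5
    effect_log2_sd: float = 0.5
    effect_up_probability: float = 0.5
    junction_usage_log10_sd: float = 0.2
    read_length: int = 43
    min_overlap: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_nonsmokers <= 0 or self.n_smokers <= 0:
            raise ValueError("counts must be positive")
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        if self.depth <= 0:
            raise ValueError("sequencing depth must be positive")

    def subjects(self) -> tuple[list[str], dict[str, str]]:
        ns = [f"ns{i + 1}" for i in range(self.n_nonsmokers)]
        sm = [f"sm{i + 1}" for i in range(self.n_smokers)]
        groups = {s: NONSMOKER for s in ns} | {s: SMOKER for s in sm}
        return ns + sm, groups


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    base_rpkm: pd.Series  # per gene, nonsmoker scale
    rpkm: pd.DataFrame  # gene x subject true RPKM
    effects: pd.Series  # multiplicative smoking effect per gene (1 = null)
    groups: dict[str, str]
    junction_usage: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    families: dict[str, str] = field(default_factory=dict)

    @property
    def responsive_genes(self) -> list[str]:
        return sorted(self.effects.index[self.effects != 1.0])


def make_annotation(config: SimulationConfig, seed: int | None = None) -> GenomeAnnotation:
    """Lay out ``n_genes`` multi-exon genes along one chromosome.

    Genes are separated by intergenic gaps; exon and intron lengths are
    lognormal.  Deterministic under the seed.  Raises ``ValueError`` when
    a fixed chromosome length cannot hold the layout.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genes: dict[str, Gene] = {}
    pos = int(
        config.min_gap
        + rng.lognormal(config.gap_log_mean, config.gap_log_sd)
    )
    width = len(str(config.n_genes))
    for i in range(config.n_genes):
        sym = f"G{i + 1:0{width}d}"
        n_exons = 1 + rng.poisson(max(config.exons_per_gene_mean - 1.0, 0.0))
        exons = []
        for j in range(n_exons):
            if j:
                pos += config.min_intron_length + int(
                    rng.lognormal(config.intron_length_log_mean,
                                  config.intron_length_log_sd)
                )
            length = config.min_exon_length + int(
                rng.lognormal(config.exon_length_log_mean, config.exon_length_log_sd)
            )
            exons.append((pos, pos + length))
            pos += length
        strand = "+" if rng.random() < 0.5 else "-"
        genes[sym] = Gene(sym, "chr1", strand, exons)
        pos += config.min_gap + int(
            rng.lognormal(config.gap_log_mean, config.gap_log_sd)
        )
    if config.chromosome_length is not None and pos > config.chromosome_length:
        raise ValueError(
            f"infeasible packing: layout needs {pos} nt but the chromosome "
            f"is {config.chromosome_length} nt"
        )
    return GenomeAnnotation(genes)


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative noise with sd/mean = cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), size)


def simulate_expression(
    config: SimulationConfig,
    annotation: GenomeAnnotation,
    seed: int | None = None,
) -> GroundTruth:
    """Draw true per-subject RPKM with smoking effects on a gene subset."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genes = annotation.gene_symbols()
    lo, hi = config.abundance_log10_range
    a = (lo - config.abundance_log10_mean) / config.abundance_log10_sd
    b = (hi - config.abundance_log10_mean) / config.abundance_log10_sd
    log10_base = truncnorm.rvs(
        a, b,
        loc=config.abundance_log10_mean,
        scale=config.abundance_log10_sd,
        size=len(genes),
        random_state=rng,
    )
    base = pd.Series(10.0**log10_base, index=genes)

    effects = pd.Series(1.0, index=genes)
    n_resp = int(round(config.responsive_fraction * len(genes)))
    if n_resp:
        chosen = rng.choice(len(genes), size=n_resp, replace=False)
        log2 = rng.normal(config.effect_log2_mean, config.effect_log2_sd, n_resp)
        log2 = np.abs(log2)
        sign = np.where(rng.random(n_resp) < config.effect_up_probability, 1.0, -1.0)
        effects.iloc[chosen] = 2.0 ** (sign * log2)

    subjects, groups = config.subjects()
    values = {}
    for s in subjects:
        noise = _lognormal_noise(rng, config.cv, len(genes))
        mean = base * (effects if groups[s] == SMOKER else 1.0)
        values[s] = mean * noise
    rpkm = pd.DataFrame(values, index=genes)

    usage = _junction_usage_truth(config, annotation, rng)
    return GroundTruth(
        base_rpkm=base, rpkm=rpkm, effects=effects, groups=groups,
        junction_usage=usage,
    )


def _junction_usage_truth(
    config: SimulationConfig, annotation: GenomeAnnotation, rng: np.random.Generator
) -> pd.Series:
    ids = []
    for sym in annotation.gene_symbols():
        n_j = len(annotation.genes[sym].exons) - 1
        ids.extend(f"{sym}:j{i + 1}" for i in range(n_j))
    vals = 10.0 ** rng.normal(0.0, config.junction_usage_log10_sd, len(ids))
    return pd.Series(vals, index=ids)


def _place_in_exon_model(
    rng: np.random.Generator, gene: Gene, n: int, read_length: int
) -> np.ndarray:
    """Genomic start positions for reads starting uniformly in the exon model."""
    lengths = np.array([e - s for s, e in gene.exons])
    starts = np.array([s for s, _ in gene.exons])
    offsets = rng.integers(0, lengths.sum(), size=n)
    cum = np.concatenate([[0], np.cumsum(lengths)])
    which = np.searchsorted(cum, offsets, side="right") - 1
    return starts[which] + (offsets - cum[which])


def simulate_reads(
    truth: GroundTruth,
    annotation: GenomeAnnotation,
    depth: int,
    seed: int,
    read_length: int = 43,
    background_relative_density: float = 0.02,
) -> list[AlignmentSet]:
    """Place exonic and background reads for every subject.

    Exon read counts per gene are Poisson(RPKM x exon_kb x depth/1e6);
    background reads fall on introns and intergenic regions at a uniform
    per-nucleotide rate equal to ``background_relative_density`` times
    the cohort-mean exonic density.
    """
    if depth <= 0:
        raise ValueError("sequencing depth must be positive")
    rng = np.random.default_rng(seed)
    genes = [annotation.genes[s] for s in annotation.gene_symbols()]
    exon_nt = sum(g.exon_length for g in genes)
    depth_m = depth / 1e6
    mean_rpkm = truth.rpkm.mean(axis=1)
    expected_exon_reads = float(
        sum(mean_rpkm[g.symbol] * g.exon_length / 1000.0 * depth_m for g in genes)
    )
    bg_rate = background_relative_density * expected_exon_reads / max(exon_nt, 1)
    bg_regions = list(annotation.introns) + list(annotation.intergenic)

    out = []
    for subject in truth.rpkm.columns:
        chroms, starts = [], []
        for g in genes:
            lam = truth.rpkm.at[g.symbol, subject] * g.exon_length / 1000.0 * depth_m
            n = rng.poisson(lam)
            if n:
                pos = _place_in_exon_model(rng, g, n, read_length)
                starts.append(pos)
                chroms.extend([g.chrom] * n)
        for r in bg_regions:
            n = rng.poisson(bg_rate * r.length)
            if n:
                pos = r.start + rng.integers(0, r.length, size=n)
                starts.append(pos)
                chroms.extend([r.chrom] * n)
        pos = np.concatenate(starts) if starts else np.array([], dtype=np.int64)
        records = pd.DataFrame(
            {
                "chrom": chroms,
                "start": pos,
                "end": pos + read_length,
                "strand": np.where(rng.random(len(pos)) < 0.5, "+", "-"),
            }
        )
        out.append(
            AlignmentSet(
                subject_id=subject,
                records=records,
                total_mapped=max(depth, len(records)),
                read_length=read_length,
            )
        )
    return out


def simulate_junction_reads(
    truth: GroundTruth,
    annotation: GenomeAnnotation,
    depth: int,
    seed: int,
    read_length: int = 43,
    min_overlap: int = 3,
) -> pd.DataFrame:
    """Junction-spanning reads for every subject.

    Counts per junction are Poisson(usage x E_flank x L_j/1000 x M/1e6)
    with E_flank the subject's true gene RPKM (uniform coverage makes the
    two flanking exons share it).  Read starts are uniform over the
    L_j = R - 2k + 1 offsets that overlap each exon by >= k nt, reported
    relative to the boundary (start = -k means k nt on the donor side).
    """
    from .splicing import build_junction_db  # local import avoids a cycle

    if read_length < 2 * min_overlap:
        raise ValueError("read length must be at least twice the minimum overlap")
    rng = np.random.default_rng(seed)
    junctions = build_junction_db(annotation, read_length, min_overlap)
    depth_m = depth / 1e6
    lo, hi = -(read_length - min_overlap), -min_overlap  # inclusive start range
    rows: dict[str, list] = {"subject": [], "junction_id": [], "start": []}
    for subject in truth.rpkm.columns:
        for j in junctions:
            usage = truth.junction_usage.get(j.junction_id, 0.0)
            if usage == 0.0:
                continue
            e_flank = truth.rpkm.at[j.gene, subject]
            lam = usage * e_flank * j.effective_length / 1000.0 * depth_m
            n = rng.poisson(lam)
            if n:
                starts = rng.integers(lo, hi + 1, size=n)
                rows["subject"].extend([subject] * n)
                rows["junction_id"].extend([j.junction_id] * n)
                rows["start"].extend(starts.tolist())
    return pd.DataFrame(rows)


def simulate_family_sequences(
    n_families: int = 6,
    members: int = 3,
    target_identity: float = 92.0,
    seed: int = 0,
    length_range: tuple[int, int] = (500, 1500),
) -> tuple[dict[str, str], dict[str, str]]:
    """Mutated paralog families plus unrelated singleton decoys.

    Each family derives its members from one random ancestral sequence by
    independent substitutions at a rate chosen so the expected pairwise
    identity between members equals ``target_identity`` percent.  Returns
    (sequences, true membership map); membership values are family ids.
    """
    if not 0 < target_identity <= 100:
        raise ValueError("target_identity must be in (0, 100]")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    # expected pairwise difference between two members mutated at rate r:
    #   d = 2 r (1 - r) + (2/3) r^2  ->  solve 2 r - (4/3) r^2 = d
    d = 1.0 - target_identity / 100.0
    r = 0.0 if d == 0 else (2.0 - np.sqrt(4.0 - 16.0 * d / 3.0)) / (8.0 / 3.0)
    seqs: dict[str, str] = {}
    membership: dict[str, str] = {}
    for f in range(n_families):
        fam = f"fam{f + 1}"
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        ancestor = rng.choice(4, size=length)
        for m in range(members):
            seq = ancestor.copy()
            mut = rng.random(length) < r
            shift = rng.integers(1, 4, size=int(mut.sum()))
            seq[mut] = (seq[mut] + shift) % 4
            name = f"{fam}_m{m + 1}"
            seqs[name] = "".join(bases[seq])
            membership[name] = fam
    # unrelated decoys: random sequences that should stay unclustered
    for s in range(n_families):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        name = f"solo{s + 1}"
        seqs[name] = "".join(bases[rng.choice(4, size=length)])
        membership[name] = name
    return seqs, membership


def threshold_mixture(
    n_exons: int = 4000,
    n_intergenic: int = 4000,
    seed: int = 0,
    cross_at: float = 0.125,
    expressed_log10: tuple[float, float] = (0.5, 1.0),
    background_log10: tuple[float, float] = (-1.3, 0.35),
    null_exon_fraction: float = 0.15,
) -> tuple[np.ndarray, np.ndarray]:
    """Exon/intergenic RPKM mixtures whose FDR and FNR curves cross at a target.

    Expressed exons are lognormal; unexpressed exons and intergenic
    regions share a background law that is zero (no reads) with
    probability 1 - w, else lognormal.  The nonzero-background weight w
    is solved so the large-sample FDR and FNR curves intersect exactly at
    ``cross_at``, then finite samples are drawn.  Returns
    (exon_rpkm, intergenic_rpkm).
    """
    mu_e, sd_e = expressed_log10
    mu_g, sd_g = background_log10
    p0 = null_exon_fraction
    x = np.log10(cross_at)
    e = norm.sf(x, mu_e, sd_e)  # expressed survival at the target
    g = norm.sf(x, mu_g, sd_g)  # nonzero-background survival at the target

    def gap(w: float) -> float:
        fdr = w * g / ((1 - p0) * e + p0 * w * g)
        fnr = max(0.0, 1.0 - (e - w * g) / (1.0 - w))
        return fdr - fnr

    w = brentq(gap, 1e-9, 0.999)
    rng = np.random.default_rng(seed)

    def background(n: int) -> np.ndarray:
        vals = np.zeros(n)
        nonzero = rng.random(n) < w
        vals[nonzero] = 10.0 ** rng.normal(mu_g, sd_g, int(nonzero.sum()))
        return vals

    exon = np.empty(n_exons)
    is_null = rng.random(n_exons) < p0
    exon[is_null] = background(int(is_null.sum()))
    exon[~is_null] = 10.0 ** rng.normal(mu_e, sd_e, int((~is_null).sum()))
    intergenic = background(n_intergenic)
    return exon, intergenic
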