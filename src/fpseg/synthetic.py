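"""Synthetic genomes, Hi-C matrices, methylomes and expression tables.

The generator states a minimal world with the statistical structure the
analysis pipeline assumes, so every statistic can be verified against
planted ground truth:

* a single chromosome tiled by alternating forest/prairie domains whose
  lengths are drawn uniformly from a bin range;
* CGIs laid densely in forests (one per 20 kb) and sparsely in prairies
  (one per 500 kb), so the open-sea mask and CpG density tracks are
  consistent with the domain labels;
* Hi-C counts with power-law distance decay ``(d+1)^(−α)`` and a
  multiplicative same-type affinity ``(1 + s)`` — negative-binomially
  dispersed, symmetric, scaled to a sequencing depth;
* open-sea CpG methylation Beta-distributed around a forest level ``m_F``
  and a prairie level ``m_P`` with Poisson coverage;
* expression tables with uniform background and planted tissue-restricted
  genes (high in one sample, trace leakage elsewhere).

Everything is deterministic given (spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .domains import FOREST, PRAIRIE, DomainSet, domain_keys, label_bins
from .hic import ContactMatrix

CGI_WIDTH_BP = 500


@dataclass(frozen=True)
class Stage:
    """One stage of a developmental schedule.

    ``affinity`` is the same-type contact boost s at this stage; ``flips``
    lists domain ids whose *effective* type is inverted (a prairie domain
    behaving as forest/A-environment models a switchable/mixing prairie).
    """

    name: str
    affinity: float
    flips: tuple[int, ...] = ()


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the stated synthetic world (defaults are the analysis regime).

    Hi-C: ``alpha`` is the contact decay exponent, ``affinity`` the same-type
    boost s (expected contact ∝ (d+1)^(−α) · (1+s·same_type)), ``dispersion``
    the negative-binomial overdispersion, ``depth`` the total expected count.
    Methylation: open-sea CpG fractions Beta-centered on ``m_forest`` /
    ``m_prairie`` with concentration ``meth_concentration``; coverage ~
    Poisson(``coverage_lambda``).  Expression: ``n_samples`` samples,
    planted specific genes at ``effect_multiplier``× background in one
    sample with ``off_target_leak``× background elsewhere; 78.5% of genes
    placed in forests, matching the genomic gene distribution.
    """

    n_domains: int = 20
    domain_length_bins: tuple[int, int] = (5, 15)
    resolution_bp: int = 40_000
    chrom: str = "chrS"
    # Hi-C
    alpha: float = 1.0
    affinity: float = 1.0
    dispersion: float = 0.1
    depth: float = 1_000_000.0
    stages: tuple[Stage, ...] | None = None
    # methylation
    m_forest: float = 0.75
    m_prairie: float = 0.55
    meth_concentration: float = 50.0
    coverage_lambda: float = 30.0
    cpg_spacing_bp: int = 2_000
    # genome annotation
    sine_rho: float = 0.8
    cgi_spacing_forest_bp: int = 20_000
    cgi_spacing_prairie_bp: int = 500_000
    # expression
    n_samples: int = 8
    n_genes: int = 500
    specific_fraction: float = 0.1
    effect_multiplier: float = 10.0
    off_target_leak: float = 0.02
    forest_gene_fraction: float = 0.785

    def __post_init__(self) -> None:
        if self.n_domains < 2:
            raise ValueError("need at least 2 domains")
        lo, hi = self.domain_length_bins
        if lo < 1 or hi < lo:
            raise ValueError("invalid domain length range")
        if self.alpha <= 0 or self.affinity < 0 or self.dispersion < 0:
            raise ValueError("invalid Hi-C parameters")
        for m in (self.m_forest, self.m_prairie):
            if not 0 <= m <= 1:
                raise ValueError("methylation levels must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticGenome:
    """Genome-side outputs: domains, CGIs, per-bin density tracks."""

    domains: DomainSet
    cgi: pd.DataFrame
    cpg_density: np.ndarray
    sine_density: np.ndarray
    chrom_sizes: dict[str, int]

    def bin_labels(self, resolution_bp: int) -> np.ndarray:
        chrom = self.domains.chroms[0]
        n_bins = self.chrom_sizes[chrom] // resolution_bp
        return label_bins(self.domains, resolution_bp, chrom,
                          n_bins=n_bins)["label"].to_numpy()


def generate_genome(spec: SyntheticSpec, seed: int) -> SyntheticGenome:
    """Alternating F/P domains with CGI placement and density tracks.

    SINE density per bin is ``ρ·[bin is forest] + (1−ρ)·U(0,1)`` plus a tiny
    tie-breaking jitter, so at ρ = 1 the high-SINE median class coincides
    with forest bins (for balanced bin counts).
    """
    rng = np.random.default_rng(seed)
    lo, hi = spec.domain_length_bins
    lengths = rng.integers(lo, hi + 1, size=spec.n_domains) * spec.resolution_bp
    starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    ends = np.cumsum(lengths)
    labels = [FOREST if i % 2 == 0 else PRAIRIE for i in range(spec.n_domains)]
    domains = DomainSet.from_intervals(spec.chrom, list(zip(starts, ends)), labels)
    size = int(ends[-1])
    chrom_sizes = {spec.chrom: size}

    cgi_rows = []
    for s, e, lab in zip(starts, ends, labels):
        spacing = spec.cgi_spacing_forest_bp if lab == FOREST else spec.cgi_spacing_prairie_bp
        pos = np.arange(s + spacing // 2, e - CGI_WIDTH_BP, spacing)
        for p in pos:
            cgi_rows.append({"chrom": spec.chrom, "start": int(p), "end": int(p + CGI_WIDTH_BP)})
    cgi = pd.DataFrame(cgi_rows, columns=["chrom", "start", "end"])

    n_bins = size // spec.resolution_bp
    bins = label_bins(domains, spec.resolution_bp, spec.chrom, n_bins=n_bins)
    is_f = (bins["label"] == FOREST).to_numpy().astype(float)
    # CpG density: CGI coverage fraction per bin plus mild noise
    cov = np.zeros(n_bins)
    for row in cgi.itertuples(index=False):
        b0, b1 = row.start // spec.resolution_bp, (row.end - 1) // spec.resolution_bp
        for b in range(b0, b1 + 1):
            lo_bp = max(row.start, b * spec.resolution_bp)
            hi_bp = min(row.end, (b + 1) * spec.resolution_bp)
            cov[b] += (hi_bp - lo_bp) / spec.resolution_bp
    cpg_density = cov + rng.uniform(0, 1e-4, size=n_bins)
    sine_density = (spec.sine_rho * is_f
                    + (1 - spec.sine_rho) * rng.uniform(size=n_bins)
                    + 1e-9 * rng.uniform(size=n_bins))
    return SyntheticGenome(domains, cgi, cpg_density, sine_density, chrom_sizes)


def _expected_contacts(bin_types: np.ndarray, alpha: float, affinity: float) -> np.ndarray:
    n = len(bin_types)
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    mu = (d + 1.0) ** (-alpha)
    same = np.equal.outer(bin_types, bin_types)
    mu = mu * (1.0 + affinity * same)
    return mu


def generate_hic(domains: DomainSet, spec: SyntheticSpec, seed: int,
                 affinity: float | None = None,
                 effective_labels: np.ndarray | None = None) -> ContactMatrix:
    """Raw Hi-C counts with planted same-type affinity.

    ``effective_labels`` (per-bin "F"/"P") overrides the genomic labels to
    model stage-specific environment flips.  Counts are negative binomial
    (variance μ + dispersion·μ²; Poisson at dispersion 0) on the upper
    triangle, symmetrized, with expected total equal to ``depth``.
    """
    rng = np.random.default_rng(seed)
    chrom = domains.chroms[0]
    sub = domains.for_chrom(chrom)
    n_bins = int(sub["end"].max()) // spec.resolution_bp
    if effective_labels is None:
        bins = label_bins(domains, spec.resolution_bp, chrom, n_bins=n_bins)
        effective_labels = bins["label"].to_numpy()
    s = spec.affinity if affinity is None else affinity
    mu = _expected_contacts(np.asarray(effective_labels, dtype=object), spec.alpha, s)
    iu = np.triu_indices(n_bins)
    mu *= spec.depth / mu[iu].sum()
    counts = np.zeros_like(mu)
    mu_u = mu[iu]
    if spec.dispersion > 0:
        r = 1.0 / spec.dispersion
        p = r / (r + mu_u)
        draw = rng.negative_binomial(r, p)
    else:
        draw = rng.poisson(mu_u)
    counts[iu] = draw
    counts = counts + counts.T - np.diag(np.diag(counts))
    return ContactMatrix(chrom, spec.resolution_bp, counts)


def effective_bin_labels(domains: DomainSet, resolution_bp: int,
                         flips: tuple[int, ...]) -> np.ndarray:
    """Per-bin effective F/P labels after flipping the given domain ids."""
    chrom = domains.chroms[0]
    sub = domains.for_chrom(chrom)
    n_bins = int(sub["end"].max()) // resolution_bp
    bins = label_bins(domains, resolution_bp, chrom, n_bins=n_bins)
    lab = bins["label"].to_numpy(dtype=object).copy()
    flip = bins["domain_id"].isin(flips).to_numpy()
    lab[flip & (lab == FOREST)] = PRAIRIE
    lab[flip & (lab == PRAIRIE)] = FOREST
    return lab


def generate_stage_series(domains: DomainSet, spec: SyntheticSpec,
                          seed: int) -> dict[str, dict]:
    """One matrix per scheduled stage plus per-stage ground truth.

    Each stage entry maps to ``{"matrix": ContactMatrix, "truth": {...}}``
    where the truth records the stage affinity, flipped domain ids, per-bin
    effective labels and the implied compartment truth (effective F → A).
    """
    if not spec.stages:
        raise ValueError("spec.stages is empty")
    rng = np.random.default_rng(seed)
    out: dict[str, dict] = {}
    sub = domains.for_chrom(domains.chroms[0])
    keys = dict(zip(sub["id"], domain_keys(sub)))
    for stage in spec.stages:
        eff = effective_bin_labels(domains, spec.resolution_bp, stage.flips)
        m = generate_hic(domains, spec, int(rng.integers(0, 2**31 - 1)),
                         affinity=stage.affinity, effective_labels=eff)
        eff_domain = {keys[i]: (PRAIRIE if lab == FOREST else FOREST) if i in stage.flips else lab
                      for i, lab in zip(sub["id"], sub["label"])}
        out[stage.name] = {
            "matrix": m,
            "truth": {
                "affinity": stage.affinity,
                "flips": list(stage.flips),
                "effective_bin_labels": eff,
                "compartment": np.where(eff == FOREST, "A", "B"),
                "effective_domain_labels": eff_domain,
            },
        }
    return out


def generate_methylome(genome: SyntheticGenome, spec: SyntheticSpec, seed: int,
                       m_forest: float | None = None,
                       m_prairie: float | None = None) -> pd.DataFrame:
    """CpG-level methylation calls at fixed spacing across the chromosome.

    Each CpG draws its fraction from a Beta centered on the domain-type
    level with concentration κ (Beta(mκ, (1−m)κ)) and its coverage from
    Poisson(λ).  Returns ``chrom, pos, meth, cov``.
    """
    rng = np.random.default_rng(seed)
    mf = spec.m_forest if m_forest is None else m_forest
    mp = spec.m_prairie if m_prairie is None else m_prairie
    chrom = genome.domains.chroms[0]
    size = genome.chrom_sizes[chrom]
    pos = np.arange(spec.cpg_spacing_bp // 2, size, spec.cpg_spacing_bp)
    sub = genome.domains.for_chrom(chrom)
    starts = sub["start"].to_numpy()
    labels = sub["label"].to_numpy()
    idx = np.searchsorted(starts, pos, side="right") - 1
    level = np.where(labels[idx] == FOREST, mf, mp)
    kappa = spec.meth_concentration
    a = np.clip(level * kappa, 1e-6, None)
    b = np.clip((1 - level) * kappa, 1e-6, None)
    meth = rng.beta(a, b)
    cov = rng.poisson(spec.coverage_lambda, size=len(pos))
    return pd.DataFrame({"chrom": chrom, "pos": pos, "meth": meth, "cov": cov})


def generate_expression(genome: SyntheticGenome, spec: SyntheticSpec,
                        seed: int) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Expression table with planted tissue-restricted genes.

    Background FPKM ~ U(0.5, 2) per gene per sample.  A ``specific_fraction``
    of genes is tissue-restricted: their target-sample FPKM is multiplied by
    ``effect_multiplier`` and off-target FPKM by ``off_target_leak`` (trace
    leakage — restricted genes are near-silent outside their lineage).
    Gene TSSs fall in forest domains with probability
    ``forest_gene_fraction``.

    Returns ``(table, gene_coords, truth)``: the genes × samples frame, the
    ``gene, chrom, tss`` coordinates, and per-gene truth with the planted
    target sample (or None).
    """
    rng = np.random.default_rng(seed)
    samples = [f"S{k}" for k in range(spec.n_samples)]
    genes = [f"g{k:04d}" for k in range(spec.n_genes)]
    fpkm = rng.uniform(0.5, 2.0, size=(spec.n_genes, spec.n_samples))

    n_spec = int(round(spec.specific_fraction * spec.n_genes))
    specific = rng.choice(spec.n_genes, size=n_spec, replace=False)
    target = rng.integers(0, spec.n_samples, size=n_spec)
    for g, t in zip(specific, target):
        off = fpkm[g] * spec.off_target_leak
        off[t] = fpkm[g, t] * spec.effect_multiplier
        fpkm[g] = off
    table = pd.DataFrame(fpkm, index=genes, columns=samples)

    sub = genome.domains.for_chrom(genome.domains.chroms[0])
    is_f = (sub["label"] == FOREST).to_numpy()
    len_bp = (sub["end"] - sub["start"]).to_numpy().astype(float)
    w_f = np.where(is_f, len_bp, 0)
    w_p = np.where(~is_f, len_bp, 0)
    coords = []
    for g in range(spec.n_genes):
        in_forest = rng.random() < spec.forest_gene_fraction
        w = w_f if (in_forest and w_f.sum() > 0) else w_p
        k = rng.choice(len(sub), p=w / w.sum())
        tss = int(rng.integers(sub["start"].iloc[k], sub["end"].iloc[k]))
        coords.append({"gene": genes[g], "chrom": genome.domains.chroms[0], "tss": tss})
    gene_coords = pd.DataFrame(coords)

    truth = pd.DataFrame({"gene": genes, "specific_sample": None})
    truth = truth.set_index("gene")
    for g, t in zip(specific, target):
        truth.loc[genes[g], "specific_sample"] = samples[t]
    return table, gene_coords, truth.reset_index()


def write_synthetic_dataset(outdir, spec: SyntheticSpec, seed: int) -> dict:
    """Generate and write a full dataset in the text formats the pipeline reads.

    Emits fp_domains.bed, cgi.bed, chrom.sizes, hic_raw.txt (sparse
    triplets), methylome.tsv, expression.tsv, gene_coords.tsv and
    ground_truth.json under ``outdir``; returns the ground-truth dict.
    """
    import os

    from .hic import write_matrix

    os.makedirs(outdir, exist_ok=True)
    genome = generate_genome(spec, seed)
    m = generate_hic(genome.domains, spec, seed + 1)
    meth = generate_methylome(genome, spec, seed + 2)
    table, gene_coords, truth = generate_expression(genome, spec, seed + 3)

    genome.domains.to_bed(os.path.join(outdir, "fp_domains.bed"))
    genome.cgi.to_csv(os.path.join(outdir, "cgi.bed"), sep="\t", header=False, index=False)
    with open(os.path.join(outdir, "chrom.sizes"), "w") as fh:
        for c, s in genome.chrom_sizes.items():
            fh.write(f"{c}\t{s}\n")
    write_matrix(m, os.path.join(outdir, "hic_raw.txt"), fmt="sparse")
    meth.to_csv(os.path.join(outdir, "methylome.tsv"), sep="\t", header=False, index=False)
    table.to_csv(os.path.join(outdir, "expression.tsv"), sep="\t")
    gene_coords.to_csv(os.path.join(outdir, "gene_coords.tsv"), sep="\t", index=False)
    gt = {
        "seed": seed,
        "spec": {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in asdict(spec).items() if k != "stages"},
        "affinity": spec.affinity,
        "specific_genes": truth.dropna(subset=["specific_sample"]) \
                               .set_index("gene")["specific_sample"].to_dict(),
    }
    with open(os.path.join(outdir, "ground_truth.json"), "w") as fh:
        json.dump(gt, fh, indent=1)
    return gt
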