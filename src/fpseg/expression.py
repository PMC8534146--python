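"""Shannon-entropy lineage-specific genes and prairie expression-change groups.

A gene expressed in a single sample out of T carries zero entropy over its
relative expression profile p_t = FPKM_t / Σ FPKM_t; a uniformly expressed
gene carries log2(T) bits.  Lineage-specific candidates are low-entropy
genes (H < 1.7 bits) that are also well expressed in the target stage
(FPKM ≥ 1), dominated by it (p_target > 1/7), and up relative to a reference
stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .domains import FOREST, PRAIRIE, DomainSet, domain_keys
from .segregation import SegMixResult


def entropy_scores(table: pd.DataFrame) -> pd.Series:
    """Shannon entropy (bits) of each gene's relative expression profile.

    ``table`` is genes × samples, FPKM ≥ 0.  0·log 0 ≡ 0; genes with zero
    total expression get NaN.
    """
    if table.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    x = table.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("negative FPKM")
    total = x.sum(axis=1)
    h = np.full(len(table), np.nan)
    pos = total > 0
    p = x[pos] / total[pos, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    h[pos] = -terms.sum(axis=1)
    return pd.Series(h, index=table.index, name="H")


def assign_genes_to_domains(gene_coords: pd.DataFrame, domains: DomainSet) -> pd.DataFrame:
    """Map genes to domains by TSS position (point-in-interval).

    ``gene_coords`` needs ``gene, chrom, tss``.  Returns ``gene, domain,
    label`` with NaN for genes outside every domain.
    """
    rows = []
    for chrom, sub in gene_coords.groupby("chrom", sort=False):
        dsub = domains.for_chrom(chrom)
        keys = domain_keys(dsub).to_numpy()
        starts = dsub["start"].to_numpy()
        ends = dsub["end"].to_numpy()
        labels = dsub["label"].to_numpy()
        for g in sub.itertuples(index=False):
            hit = np.flatnonzero((starts <= g.tss) & (g.tss < ends))
            if len(hit):
                rows.append({"gene": g.gene, "domain": keys[hit[0]],
                             "label": labels[hit[0]]})
            else:
                rows.append({"gene": g.gene, "domain": np.nan, "label": np.nan})
    return pd.DataFrame(rows)


def select_lineage_specific(table: pd.DataFrame, target_stage: str,
                            reference_stage: str, h_max: float = 1.7,
                            fpkm_min: float = 1.0, rel_min: float = 1 / 7,
                            gene_domains: pd.DataFrame | None = None) -> pd.DataFrame:
    """Lineage-specific genes for a target stage.

    A gene is selected when H < ``h_max``, FPKM_target ≥ ``fpkm_min``
    (non-strict), relative expression p_target > ``rel_min`` (strict) and
    FPKM_target > FPKM_reference (strict).  Output is sorted by gene id and
    carries H, p_target and the two FPKM columns; with ``gene_domains`` a
    forest/prairie label column is attached.
    """
    for stage in (target_stage, reference_stage):
        if stage not in table.columns:
            raise ValueError(f"stage {stage!r} not in expression table")
    h = entropy_scores(table)
    total = table.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_target = table[target_stage] / total
    sel = (
        (h < h_max)
        & (table[target_stage] >= fpkm_min)
        & (p_target > rel_min)
        & (table[target_stage] > table[reference_stage])
    )
    out = pd.DataFrame({
        "gene": table.index[sel],
        "H": h[sel].to_numpy(),
        "p_target": p_target[sel].to_numpy(),
        "fpkm_target": table.loc[sel, target_stage].to_numpy(),
        "fpkm_reference": table.loc[sel, reference_stage].to_numpy(),
    }).sort_values("gene").reset_index(drop=True)
    if gene_domains is not None:
        out = out.merge(gene_domains, on="gene", how="left")
    return out


@dataclass(frozen=True)
class ExpressionChangeResult:
    """Prairie genes split by expression direction, with host-domain DRs test.

    ``increased``/``decreased`` are sorted gene lists; ``t``/``p`` compare
    the DRs log-ratios of the host domains of the two groups (two-sample
    t-test, two-sided; None when a group is empty or degenerate).
    """

    increased: list
    decreased: list
    t: float | None
    p: float | None
    mean_log_ratio_increased: float | None
    mean_log_ratio_decreased: float | None


def expression_change_groups(table: pd.DataFrame, stage_early: str, stage_late: str,
                             gene_domains: pd.DataFrame, calls: SegMixResult | pd.Series,
                             min_fold: float = 1.0) -> ExpressionChangeResult:
    """Group prairie genes by expression change and compare host-domain mixing.

    A prairie gene is *increased* when FPKM_late > min_fold · FPKM_early
    (strict), *decreased* when FPKM_early > min_fold · FPKM_late.  Host
    domains' DRs log-ratios (from seg/mix calls) are compared between the
    two groups.
    """
    for stage in (stage_early, stage_late):
        if stage not in table.columns:
            raise ValueError(f"stage {stage!r} not in expression table")
    log_ratio = (calls.calls.set_index("domain")["log_ratio"]
                 if isinstance(calls, SegMixResult) else calls)
    gd = gene_domains.set_index("gene")
    prairie = gd.index[(gd["label"] == PRAIRIE) & gd["domain"].notna()]
    prairie = [g for g in prairie if g in table.index]
    early = table.loc[prairie, stage_early]
    late = table.loc[prairie, stage_late]
    inc = sorted(g for g in prairie if late[g] > min_fold * early[g])
    dec = sorted(g for g in prairie if early[g] > min_fold * late[g])
    lr_inc = log_ratio.reindex(gd.loc[inc, "domain"]).dropna() if inc else pd.Series(dtype=float)
    lr_dec = log_ratio.reindex(gd.loc[dec, "domain"]).dropna() if dec else pd.Series(dtype=float)
    t = p = None
    if len(lr_inc) >= 2 and len(lr_dec) >= 2:
        t, p = stats.ttest_ind(lr_inc, lr_dec, equal_var=True)
        t, p = float(t), float(p)
    return ExpressionChangeResult(
        inc, dec, t, p,
        float(lr_inc.mean()) if len(lr_inc) else None,
        float(lr_dec.mean()) if len(lr_dec) else None,
    )
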