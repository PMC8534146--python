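"""Forest/prairie segregation statistics.

All statistics quantify how strongly same-type genomic domains (forest–forest,
prairie–prairie) contact each other relative to cross-type (forest–prairie)
contact, at several granularities:

* ``ORs`` — one genome-wide ratio per domain type (overall segregation ratio);
* ``DRs`` — one ratio per domain (domain segregation ratio);
* ``Rs(d)`` — the ratio restricted to bin pairs a fixed genomic distance apart;
* ``TC10(d)`` — among the top 10% of contacts at each distance, the F–F / F–P
  / P–P proportions, and the *critical genomic distance* beyond which they
  vanish;
* ``Ror`` — a log count ratio comparing per-domain segregation between two
  samples;
* seg/mix calls — domains whose DRs log-ratio between two conditions exceeds
  a threshold calibrated from the replicate-to-replicate null.

Pair-counting convention: same-type numerators run over *ordered* pairs (each
unordered same-type pair counted twice) while cross-type sums count each
unordered pair once, reading the defining index ranges literally.  Every
statistic is a ratio, so the convention is harmless as long as it is fixed;
it is fixed here.

Inter-domain contact tables (``D_ij``) come from
:func:`fpseg.hic.aggregate_domain_contacts` on ICE-normalized matrices and
may be concatenated across chromosomes before any function here is applied —
sums then pool over chromosomes (cis contacts only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .domains import FOREST, PRAIRIE, BinClassTrack, DomainSet
from .hic import ContactMatrix

SEG, MIX, NEUTRAL, UNDEFINED = "seg", "mix", "neutral", "undefined"


def _other(label: str) -> str:
    if label == FOREST:
        return PRAIRIE
    if label == PRAIRIE:
        return FOREST
    raise ValueError(f"label must be F or P, got {label!r}")


def _inter(dct: pd.DataFrame) -> pd.DataFrame:
    return dct[~dct["intra"]]


def compute_ors(dct: pd.DataFrame, label: str) -> float:
    """Overall segregation ratio for one domain type.

    ``ORs(F) = Σ_{i,j∈F, i≠j} D_ij / Σ_{i∈F, j∈P} D_ij`` — ordered same-type
    pairs over single-counted cross-type pairs.  Raises on zero cross-type
    contact (degenerate input).
    """
    other = _other(label)
    inter = _inter(dct)
    same = inter[(inter["label_i"] == label) & (inter["label_j"] == label)]
    cross = inter[inter["label_i"] != inter["label_j"]]
    num = 2.0 * same["D"].sum()
    den = float(cross["D"].sum())
    if den == 0:
        raise ValueError("no cross-type contact")
    return float(num) / den


def compute_drs(dct: pd.DataFrame) -> pd.DataFrame:
    """Per-domain segregation ratio DRs.

    For a forest domain i: ``Σ_{j∈F, j≠i} D_ij / Σ_{j∈P} D_ij`` (symmetric
    for prairie).  A zero cross-type denominator yields NaN (undefined); a
    zero numerator with positive denominator yields 0.

    Returns ``domain (key), label, drs`` with one row per domain in the table.
    """
    inter = _inter(dct)
    # symmetric long view: one row per (domain, partner)
    fwd = inter[["key_i", "key_j", "label_i", "label_j", "D"]].rename(
        columns={"key_i": "domain", "key_j": "partner",
                 "label_i": "label", "label_j": "partner_label"})
    rev = inter[["key_j", "key_i", "label_j", "label_i", "D"]].rename(
        columns={"key_j": "domain", "key_i": "partner",
                 "label_j": "label", "label_i": "partner_label"})
    long = pd.concat([fwd, rev], ignore_index=True)

    doms = pd.concat([
        dct[["key_i", "label_i"]].rename(columns={"key_i": "domain", "label_i": "label"}),
        dct[["key_j", "label_j"]].rename(columns={"key_j": "domain", "label_j": "label"}),
    ]).drop_duplicates("domain").reset_index(drop=True)

    same_sum = (long[long["label"] == long["partner_label"]]
                .groupby("domain")["D"].sum())
    cross_sum = (long[long["label"] != long["partner_label"]]
                 .groupby("domain")["D"].sum())
    doms["same"] = doms["domain"].map(same_sum).fillna(0.0)
    doms["cross"] = doms["domain"].map(cross_sum).fillna(0.0)
    doms["drs"] = np.where(doms["cross"] > 0, doms["same"] / doms["cross"], np.nan)
    return doms[["domain", "label", "drs"]]


def drs_series(drs: pd.DataFrame) -> pd.Series:
    """DRs frame → Series indexed by domain key."""
    return drs.set_index("domain")["drs"]


def compute_rs_distance(m: ContactMatrix, bin_labels, label: str) -> pd.Series:
    """Distance-resolved segregation ratio Rs(d) for one domain type.

    ``Rs^F(d) = Σ_{i∈F, j=i±d ∈F} C_ij / Σ_{i∈F, j=i±d ∈P} C_ij``: both
    directions are scanned per bin, so same-type pairs count twice and
    cross-type pairs once per same-type endpoint.  Unassigned or masked bins
    are excluded; a zero denominator yields NaN at that distance.

    ``bin_labels`` is a per-bin sequence of "F"/"P"/None (e.g. the ``label``
    column from :func:`fpseg.domains.label_bins`).  Index of the returned
    series is the offset in bins (1 … n−1).
    """
    other = _other(label)
    lab = np.asarray(bin_labels, dtype=object)
    n = m.n_bins
    if len(lab) != n:
        raise ValueError("bin label track does not match matrix size")
    ok = m.unmasked & np.array([x in (FOREST, PRAIRIE) for x in lab])
    out = {}
    for d in range(1, n):
        i = np.arange(n - d)
        j = i + d
        valid = ok[i] & ok[j]
        if not valid.any():
            out[d] = np.nan
            continue
        c = m.values[i[valid], j[valid]]
        li, lj = lab[i[valid]], lab[j[valid]]
        num = 2.0 * c[(li == label) & (lj == label)].sum()
        den = c[((li == label) & (lj == other)) | ((li == other) & (lj == label))].sum()
        out[d] = num / den if den > 0 else np.nan
    s = pd.Series(out)
    s.index.name = "offset_bins"
    return s


@dataclass(frozen=True)
class Tc10Result:
    """TC10(d) proportions and the critical genomic distance.

    ``proportions`` is indexed by offset in bins with columns pFF, pFP, pPP;
    a row of zeros marks an offset where the top tier contained a zero entry
    (or no classifiable pairs).  ``critical_distance_bp`` is the largest
    offset with a nonzero triple, times the resolution; ``interleaved`` flags
    zero triples occurring below that distance.
    """

    proportions: pd.DataFrame
    critical_distance_bp: int
    interleaved: bool
    resolution_bp: int


def compute_tc10(m: ContactMatrix, bin_labels, top_frac: float = 0.1) -> Tc10Result:
    """Top-decile contact composition per genomic distance.

    At each offset d the ⌈top_frac·n_d⌉ largest diagonal entries (ties broken
    by lower bin index) are selected among pairs whose two endpoints are
    labeled and unmasked.  If any selected entry is zero the triple is
    (0,0,0); otherwise the selected pairs are classified F–F / F–P / P–P by
    endpoint labels and proportions reported.
    """
    lab = np.asarray(bin_labels, dtype=object)
    n = m.n_bins
    ok = m.unmasked & np.array([x in (FOREST, PRAIRIE) for x in lab])
    rows = []
    for d in range(1, n):
        i = np.arange(n - d)
        j = i + d
        valid = ok[i] & ok[j]
        if not valid.any():
            continue
        iv, jv = i[valid], j[valid]
        c = m.values[iv, jv]
        k = int(np.ceil(top_frac * len(c)))
        order = np.lexsort((iv, -c))[:k]
        if (c[order] == 0).any():
            rows.append((d, 0.0, 0.0, 0.0))
            continue
        li, lj = lab[iv[order]], lab[jv[order]]
        ff = int(((li == FOREST) & (lj == FOREST)).sum())
        pp = int(((li == PRAIRIE) & (lj == PRAIRIE)).sum())
        fp = k - ff - pp
        rows.append((d, ff / k, fp / k, pp / k))
    props = pd.DataFrame(rows, columns=["offset_bins", "pFF", "pFP", "pPP"])
    props = props.set_index("offset_bins")
    nonzero = props[(props.sum(axis=1) > 0)]
    if len(nonzero):
        d_crit = int(nonzero.index.max())
        zero_below = props.loc[props.index < d_crit].sum(axis=1) == 0
        interleaved = bool(zero_below.any())
    else:
        d_crit = 0
        interleaved = False
    return Tc10Result(props, d_crit * m.resolution_bp, interleaved, m.resolution_bp)


# ---------------------------------------------------------------------------
# Replicate-calibrated seg/mix calls


def calibrate_threshold(drs_rep1: pd.Series, drs_rep2: pd.Series,
                        tail: float = 0.025, min_domains: int = 40) -> float:
    """Symmetric seg/mix threshold from a pair of replicate DRs profiles.

    Takes the per-domain log-ratios ``ln(DRs1/DRs2)`` over domains with
    positive, defined DRs in both replicates and returns
    ``T = max(|Q(1−tail)|, |Q(tail)|)`` with linearly interpolated empirical
    quantiles.  Calls then use the symmetric band ±T.
    """
    both = pd.concat({"a": drs_rep1, "b": drs_rep2}, axis=1, join="inner").dropna()
    both = both[(both["a"] > 0) & (both["b"] > 0)]
    if len(both) < min_domains:
        raise ValueError(
            f"insufficient replicate support: {len(both)} valid domains < {min_domains}")
    r = np.log(both["a"].to_numpy() / both["b"].to_numpy())
    hi = np.quantile(r, 1 - tail)
    lo = np.quantile(r, tail)
    return float(max(abs(hi), abs(lo)))


@dataclass(frozen=True)
class SegMixResult:
    """Per-domain seg/mix calls plus per-label summary fractions.

    ``calls`` has columns ``domain, label, log_ratio, call``; ``summary`` maps
    e.g. ``"P_mix"`` to the fraction of prairie domains (with a defined call)
    in the mix class, and ``"n_F"``/``"n_P"`` to defined-call counts.
    """

    calls: pd.DataFrame
    threshold: float
    summary: dict = field(default_factory=dict)


def call_seg_mix(drs_early: pd.DataFrame, drs_late: pd.DataFrame, threshold: float) -> SegMixResult:
    """Call domains significantly more segregated/mixed between two conditions.

    ``log_ratio = ln(DRs_late / DRs_early)``; call is ``seg`` above +T,
    ``mix`` below −T, ``neutral`` in between, and ``undefined`` when either
    DRs is zero or missing.  Fractions are over defined-call domains per label.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    e = drs_early.set_index("domain")
    l = drs_late.set_index("domain")
    shared = e.index.intersection(l.index)
    de = e.loc[shared, "drs"].to_numpy()
    dl = l.loc[shared, "drs"].to_numpy()
    labels = e.loc[shared, "label"].to_numpy()
    defined = np.isfinite(de) & np.isfinite(dl) & (de > 0) & (dl > 0)
    log_ratio = np.full(len(shared), np.nan)
    log_ratio[defined] = np.log(dl[defined] / de[defined])
    call = np.full(len(shared), UNDEFINED, dtype=object)
    call[defined & (log_ratio > threshold)] = SEG
    call[defined & (log_ratio < -threshold)] = MIX
    call[defined & (np.abs(log_ratio) <= threshold)] = NEUTRAL
    calls = pd.DataFrame({"domain": shared, "label": labels,
                          "log_ratio": log_ratio, "call": call})
    summary: dict[str, float] = {"threshold": float(threshold)}
    for lab in (FOREST, PRAIRIE):
        sub = calls[(calls["label"] == lab) & (calls["call"] != UNDEFINED)]
        summary[f"n_{lab}"] = int(len(sub))
        for c in (SEG, MIX, NEUTRAL):
            frac = (sub["call"] == c).mean() if len(sub) else np.nan
            summary[f"{lab}_{c}"] = float(frac)
    return SegMixResult(calls, float(threshold), summary)


@dataclass(frozen=True)
class RorResult:
    """Relative segregation between two samples: ``ror = ln(n_ij / n_ji)``.

    ``n_ij`` counts shared domains with strictly higher DRs in the first
    sample; ties and undefined domains are excluded from both counts.
    Positive ``ror`` means the first sample is more segregated.
    """

    n_ij: int
    n_ji: int
    ror: float


def compute_ror(drs_i: pd.Series, drs_j: pd.Series) -> RorResult:
    both = pd.concat({"i": drs_i, "j": drs_j}, axis=1, join="inner").dropna()
    n_ij = int((both["i"] > both["j"]).sum())
    n_ji = int((both["i"] < both["j"]).sum())
    if n_ij == 0 or n_ji == 0:
        warnings.warn("one-sided domain counts: Ror is infinite")
        ror = np.inf if n_ji == 0 else -np.inf
        if n_ij == 0 and n_ji == 0:
            ror = np.nan
    else:
        # log-difference form: antisymmetric under swap to the last ulp
        ror = float(np.log(n_ij) - np.log(n_ji))
    return RorResult(n_ij, n_ji, ror)


def segregation_extent(m: ContactMatrix, cls: BinClassTrack,
                       group_x: str, group_y: str) -> tuple[float, float]:
    """Within-class vs cross-class mean contact for two CpG/SINE bin classes.

    ``extentX = mean C over X–X bin pairs / mean C over X–Y pairs`` (distinct
    unmasked bins, all genomic offsets pooled), and symmetrically for Y.
    """
    bx = cls.bins_in(group_x)
    by = cls.bins_in(group_y)
    bx = bx[m.unmasked[bx]]
    by = by[m.unmasked[by]]
    if len(bx) == 0 or len(by) == 0:
        raise ValueError("empty bin class")

    def within_mean(b):
        if len(b) < 2:
            raise ValueError("bin class too small for within-class pairs")
        sub = m.values[np.ix_(b, b)]
        iu = np.triu_indices(len(b), k=1)
        return sub[iu].mean()

    cross = m.values[np.ix_(bx, by)].mean()
    if cross == 0:
        raise ValueError("zero cross-class contact")
    return float(within_mean(bx) / cross), float(within_mean(by) / cross)


# ---------------------------------------------------------------------------
# LAD overlap analysis


@dataclass(frozen=True)
class LadReport:
    """Association between lamina attachment (LAD) and domain segregation.

    Fields are None when the corresponding comparison lacked data.
    ``membership`` gives per-domain LAD calls (≥ overlap-fraction of the
    domain's bp inside LADs) per stage; ``prairie_lad_tests`` holds Welch
    t-tests of DRs for LAD vs non-LAD prairie domains per stage;
    ``fisher_table``/``fisher_p`` test whether forests leaving the inter-LAD
    state (iLAD→LAD) are enriched in the mix class; ``ilad_to_lad_ttest``
    compares early vs late DRs of those forests (two-sample t-test).
    """

    membership: pd.DataFrame
    prairie_lad_tests: dict | None
    fisher_table: np.ndarray | None
    fisher_odds: float | None
    fisher_p: float | None
    ilad_to_lad_ttest: dict | None


def _overlap_bp(starts, ends, iv_starts, iv_ends) -> np.ndarray:
    """bp overlap of each [start,end) with a set of sorted disjoint intervals."""
    out = np.zeros(len(starts), dtype=float)
    for k, (s, e) in enumerate(zip(starts, ends)):
        ov = np.minimum(iv_ends, e) - np.maximum(iv_starts, s)
        out[k] = ov[ov > 0].sum()
    return out


def domain_lad_membership(domains: DomainSet, lads: pd.DataFrame,
                          min_overlap: float = 0.5) -> pd.Series:
    """True where ≥ ``min_overlap`` of the domain's bp lies inside LADs."""
    df = domains.df
    member = np.zeros(len(df), dtype=bool)
    for chrom, sub in df.groupby("chrom", sort=False):
        lsub = lads[lads["chrom"] == chrom].sort_values("start")
        if not len(lsub):
            continue
        ov = _overlap_bp(sub["start"].to_numpy(), sub["end"].to_numpy(),
                         lsub["start"].to_numpy(), lsub["end"].to_numpy())
        frac = ov / (sub["end"] - sub["start"]).to_numpy()
        member[sub.index] = frac >= min_overlap
    return pd.Series(member, index=domains.keys().to_numpy(), name="in_lad")


def lad_overlap_analysis(domains: DomainSet, lad_early: pd.DataFrame,
                         lad_late: pd.DataFrame, drs_early: pd.DataFrame,
                         drs_late: pd.DataFrame, calls: SegMixResult,
                         min_overlap: float = 0.5) -> LadReport:
    """LAD/iLAD dynamics vs segregation changes across two stages."""
    if not len(lad_early) and not len(lad_late):
        return LadReport(pd.DataFrame(), None, None, None, None, None)
    mem_e = domain_lad_membership(domains, lad_early, min_overlap)
    mem_l = domain_lad_membership(domains, lad_late, min_overlap)
    labels = pd.Series(domains.df["label"].to_numpy(), index=domains.keys().to_numpy())
    membership = pd.DataFrame({"label": labels, "lad_early": mem_e, "lad_late": mem_l})

    de = drs_series(drs_early)
    dl = drs_series(drs_late)

    prairie_tests: dict = {}
    for stage, mem, drs in (("early", mem_e, de), ("late", mem_l, dl)):
        pr = membership.index[membership["label"] == PRAIRIE]
        x = drs.reindex(pr[mem.reindex(pr).fillna(False)]).dropna()
        y = drs.reindex(pr[~mem.reindex(pr).fillna(False)]).dropna()
        if len(x) >= 2 and len(y) >= 2:
            t, p = stats.ttest_ind(x, y, equal_var=False)
            prairie_tests[stage] = {"t": float(t), "p": float(p),
                                    "n_lad": len(x), "n_non_lad": len(y),
                                    "mean_lad": float(x.mean()), "mean_non_lad": float(y.mean())}

    call_of = calls.calls.set_index("domain")["call"]
    forests = membership.index[(membership["label"] == FOREST) & ~mem_e]
    to_lad = mem_l.reindex(forests).fillna(False)
    is_mix = call_of.reindex(forests) == MIX
    has_call = call_of.reindex(forests).isin([SEG, MIX, NEUTRAL])
    forests = forests[has_call]
    to_lad = to_lad.reindex(forests)
    is_mix = is_mix.reindex(forests)
    fisher_table = fisher_p = fisher_odds = None
    if len(forests):
        table = np.array([
            [int((to_lad & is_mix).sum()), int((to_lad & ~is_mix).sum())],
            [int((~to_lad & is_mix).sum()), int((~to_lad & ~is_mix).sum())],
        ])
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        fisher_table, fisher_odds, fisher_p = table, float(odds), float(p)

    ttest = None
    switchers = forests[to_lad]
    x = de.reindex(switchers).dropna()
    y = dl.reindex(switchers).dropna()
    if len(x) >= 2 and len(y) >= 2:
        t, p = stats.ttest_ind(x, y, equal_var=True)
        ttest = {"t": float(t), "p": float(p), "n": len(switchers),
                 "mean_early": float(x.mean()), "mean_late": float(y.mean())}

    return LadReport(membership, prairie_tests or None, fisher_table,
                     fisher_odds, fisher_p, ttest)
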