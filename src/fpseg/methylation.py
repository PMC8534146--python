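"""Open-sea methylation and the methylation difference index (MDI).

CpG methylation inside CpG islands and their flanking shores/shelves follows
its own regulatory logic, so forest/prairie contrasts use *open-sea* CpGs
only: the genome minus CGIs extended by a shore (2 kb) and a shelf (a
further 2 kb) on each side.

Per domain the open-sea methylation level q is the unweighted mean fraction
over qualifying CpGs; the MDI contrasts a domain against its two genomic
neighbors,

    MDI_i = (q_i − (q_{i−1} + q_{i+1})/2) / ((q_{i−1} + q_i + q_{i+1})/3),

so alternating forest/prairie methylation offsets produce positive MDI on
the hypermethylated type and negative on the other; |MDI| summarizes how
different adjacent domains are, independent of overall methylation scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .domains import FOREST, PRAIRIE, DomainSet, domain_keys

METH_COLUMNS = ["chrom", "pos", "meth", "cov"]


def read_methylome(path) -> pd.DataFrame:
    """Read CpG calls from a position/fraction/coverage TSV (or 4-col bedGraph)."""
    df = pd.read_csv(path, sep="\t", header=None)
    if df.shape[1] == 4 and (df.iloc[:, 2] - df.iloc[:, 1]).eq(1).all():
        # bedGraph-like chrom/start/end/fraction with unit intervals, no coverage
        df = pd.DataFrame({"chrom": df.iloc[:, 0].astype(str), "pos": df.iloc[:, 1],
                           "meth": df.iloc[:, 3], "cov": 1})
    else:
        df = df.iloc[:, :4]
        df.columns = METH_COLUMNS
        df["chrom"] = df["chrom"].astype(str)
    return df[METH_COLUMNS]


def merge_intervals(iv: np.ndarray) -> np.ndarray:
    """Union of [start, end) intervals, returned sorted and disjoint."""
    if len(iv) == 0:
        return iv.reshape(0, 2)
    iv = iv[np.argsort(iv[:, 0])]
    out = [iv[0].tolist()]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out)


def build_open_sea_mask(cgi_intervals: pd.DataFrame, chrom_sizes: dict[str, int],
                        shore_bp: int = 2000, shelf_bp: int = 2000) -> pd.DataFrame:
    """Open-sea intervals: genome minus CGIs extended by shore+shelf each side."""
    pad = shore_bp + shelf_bp
    rows = []
    for chrom, size in chrom_sizes.items():
        sub = cgi_intervals[cgi_intervals["chrom"] == chrom]
        iv = np.column_stack([
            np.maximum(sub["start"].to_numpy() - pad, 0),
            np.minimum(sub["end"].to_numpy() + pad, size),
        ]) if len(sub) else np.empty((0, 2), dtype=int)
        merged = merge_intervals(iv)
        cursor = 0
        for s, e in merged:
            if s > cursor:
                rows.append({"chrom": chrom, "start": int(cursor), "end": int(s)})
            cursor = int(e)
        if cursor < size:
            rows.append({"chrom": chrom, "start": int(cursor), "end": int(size)})
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _in_intervals(pos: np.ndarray, iv: np.ndarray) -> np.ndarray:
    """Membership of positions in sorted disjoint [start, end) intervals."""
    if len(iv) == 0:
        return np.zeros(len(pos), dtype=bool)
    k = np.searchsorted(iv[:, 0], pos, side="right") - 1
    ok = k >= 0
    out = np.zeros(len(pos), dtype=bool)
    out[ok] = pos[ok] < iv[k[ok], 1]
    return out


def domain_open_sea_methylation(meth: pd.DataFrame, domains: DomainSet,
                                open_sea: pd.DataFrame, min_cov: int = 3,
                                min_cpg: int = 10) -> pd.DataFrame:
    """Per-domain mean open-sea methylation q.

    CpGs must lie in the domain and in open sea and have coverage ≥
    ``min_cov``; q is their unweighted mean methylation fraction, NaN
    (undefined) for domains with fewer than ``min_cpg`` qualifying CpGs.

    Returns ``domain, chrom, id, label, n_cpg, q`` in genomic order.
    """
    rows = []
    for chrom in domains.chroms:
        sub = domains.for_chrom(chrom)
        msub = meth[meth["chrom"] == chrom]
        osea = open_sea[open_sea["chrom"] == chrom]
        iv = osea[["start", "end"]].to_numpy() if len(osea) else np.empty((0, 2))
        pos = msub["pos"].to_numpy()
        good = _in_intervals(pos, iv) & (msub["cov"].to_numpy() >= min_cov)
        pos_g = pos[good]
        frac_g = msub["meth"].to_numpy()[good]
        keys = domain_keys(sub)
        for k, row in enumerate(sub.itertuples(index=False)):
            inside = (pos_g >= row.start) & (pos_g < row.end)
            n = int(inside.sum())
            q = float(frac_g[inside].mean()) if n >= min_cpg else np.nan
            rows.append({"domain": keys.iloc[k], "chrom": chrom, "id": row.id,
                         "label": row.label, "n_cpg": n, "q": q})
    return pd.DataFrame(rows)


def compute_mdi(q: pd.DataFrame) -> pd.DataFrame:
    """MDI per domain from ordered per-domain q values.

    The first/last domain of a chromosome and any domain with an undefined
    flank are NaN; an all-zero q triple gives NaN with a diagnostic warning.
    Returns the input frame with an ``mdi`` column appended.
    """
    out = q.copy()
    out["mdi"] = np.nan
    zero_denominator = 0
    for chrom, sub in out.groupby("chrom", sort=False):
        sub = sub.sort_values("id")
        qq = sub["q"].to_numpy()
        for k in range(1, len(qq) - 1):
            tri = qq[k - 1], qq[k], qq[k + 1]
            if not all(np.isfinite(tri)):
                continue
            denom = sum(tri) / 3.0
            if denom == 0:
                zero_denominator += 1
                continue
            out.loc[sub.index[k], "mdi"] = (tri[1] - (tri[0] + tri[2]) / 2.0) / denom
    if zero_denominator:
        warnings.warn(f"{zero_denominator} domains with all-zero q triples: MDI undefined")
    return out


@dataclass(frozen=True)
class MdiSummary:
    """Across-sample |MDI| summaries and group comparisons.

    ``per_sample``: sample × label rows with mean |MDI|, mean signed MDI and
    n.  ``group_tests``: pairwise two-sample t-tests (two-sided) of mean
    |MDI| between metadata groups, per label.  ``age_trend``: least-squares
    slope of mean |MDI| vs age per label.
    """

    per_sample: pd.DataFrame
    group_tests: pd.DataFrame | None = None
    age_trend: pd.DataFrame | None = None


def mdi_summary(mdi_by_sample: dict[str, pd.DataFrame],
                metadata: pd.DataFrame | None = None) -> MdiSummary:
    """Summarize |MDI| per sample and compare across metadata groups.

    ``metadata`` (optional) has columns ``sample, group`` and optionally
    ``age``; groups with no usable samples are dropped with a warning.
    """
    rows = []
    for sample, df in mdi_by_sample.items():
        for lab in (FOREST, PRAIRIE):
            vals = df.loc[df["label"] == lab, "mdi"].dropna()
            if len(vals) < 2:
                warnings.warn(f"sample {sample}: < 2 defined MDI values for {lab}")
                continue
            rows.append({"sample": sample, "label": lab, "n": len(vals),
                         "mean_abs_mdi": float(vals.abs().mean()),
                         "mean_mdi": float(vals.mean())})
    per_sample = pd.DataFrame(rows)
    group_tests = age_trend = None
    if metadata is not None and len(per_sample):
        merged = per_sample.merge(metadata, on="sample", how="left")
        if "group" in merged.columns:
            trows = []
            for lab in (FOREST, PRAIRIE):
                sub = merged[merged["label"] == lab]
                groups = [g for g in sub["group"].dropna().unique()]
                for i in range(len(groups)):
                    for j in range(i + 1, len(groups)):
                        x = sub.loc[sub["group"] == groups[i], "mean_abs_mdi"]
                        y = sub.loc[sub["group"] == groups[j], "mean_abs_mdi"]
                        if len(x) < 2 or len(y) < 2:
                            warnings.warn(f"group pair {groups[i]}/{groups[j]} "
                                          f"({lab}): too few samples, skipped")
                            continue
                        t, p = stats.ttest_ind(x, y, equal_var=True)
                        trows.append({"label": lab, "group_i": groups[i],
                                      "group_j": groups[j], "t": float(t), "p": float(p),
                                      "mean_i": float(x.mean()), "mean_j": float(y.mean())})
            group_tests = pd.DataFrame(trows) if trows else None
        if "age" in merged.columns and merged["age"].notna().any():
            arows = []
            for lab in (FOREST, PRAIRIE):
                sub = merged[(merged["label"] == lab) & merged["age"].notna()]
                if len(sub) < 3:
                    continue
                res = stats.linregress(sub["age"], sub["mean_abs_mdi"])
                arows.append({"label": lab, "slope": float(res.slope),
                              "intercept": float(res.intercept),
                              "r": float(res.rvalue), "p": float(res.pvalue)})
            age_trend = pd.DataFrame(arows) if arows else None
    return MdiSummary(per_sample, group_tests, age_trend)
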