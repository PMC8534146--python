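"""Forest/prairie domain partitioning and bin classification.

Mammalian genomes can be divided, from CpG-island (CGI) density alone, into
alternating megabase-scale sequence domains: CGI-dense *forests* (F) and
CGI-poor *prairies* (P).  The partition is a property of the genome sequence,
so it is shared by every cell type of a species and provides a fixed frame
against which Hi-C segregation, compartments, methylation and expression are
compared.

Two entry points produce a :class:`DomainSet`:

* :func:`partition_forest_prairie` — a parameterized inter-CGI-gap heuristic
  (CGIs closer than ``gap_threshold_bp`` are chained into forests; short
  domains are absorbed by their larger neighbor), for when only CGI
  coordinates are available;
* :func:`read_domains_bed` — the authoritative path: load a precomputed F/P
  partition from a BED4 file.

All coordinates are 0-based half-open (BED convention); bins are 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FOREST = "F"
PRAIRIE = "P"

#: columns of the DomainSet frame, in order
DOMAIN_COLUMNS = ["chrom", "start", "end", "label", "id"]


@dataclass(frozen=True)
class DomainSet:
    """Ordered forest/prairie domains, non-overlapping within each chromosome.

    ``df`` has columns ``chrom, start, end, label, id`` with ``label`` in
    {"F", "P"} and ``id`` a stable 0-based ordinal within its chromosome.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        missing = [c for c in DOMAIN_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"DomainSet frame missing columns {missing}")
        if (df["end"] <= df["start"]).any():
            raise ValueError("domain with non-positive length")
        bad = set(df["label"]) - {FOREST, PRAIRIE}
        if bad:
            raise ValueError(f"unknown domain labels {bad}")
        for chrom, sub in df.groupby("chrom", sort=False):
            s = sub.sort_values("start")
            if (s["start"].values[1:] < s["end"].values[:-1]).any():
                raise ValueError(f"overlapping domains on {chrom}")
        object.__setattr__(self, "df", df[DOMAIN_COLUMNS])

    @classmethod
    def from_intervals(cls, chrom: str, intervals, labels) -> "DomainSet":
        """Build from parallel ``(start, end)`` pairs and labels on one chromosome."""
        rows = [
            {"chrom": chrom, "start": int(s), "end": int(e), "label": lab, "id": i}
            for i, ((s, e), lab) in enumerate(zip(intervals, labels))
        ]
        return cls(pd.DataFrame(rows, columns=DOMAIN_COLUMNS))

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def for_chrom(self, chrom: str) -> pd.DataFrame:
        sub = self.df[self.df["chrom"] == chrom]
        return sub.sort_values("start").reset_index(drop=True)

    def length_bp(self) -> pd.Series:
        return self.df["end"] - self.df["start"]

    def keys(self) -> pd.Series:
        """Stable global domain keys, ``"<chrom>:<id>"``."""
        return domain_keys(self.df)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for row in self.df.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.label}\n")


def domain_keys(df: pd.DataFrame) -> pd.Series:
    return df["chrom"].astype(str) + ":" + df["id"].astype(str)


def read_domains_bed(path) -> DomainSet:
    """Load a precomputed F/P partition from a BED4 file (name column F|P)."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "label"],
        dtype={"chrom": str, "start": int, "end": int, "label": str},
    )
    df["id"] = df.groupby("chrom", sort=False).cumcount()
    return DomainSet(df[DOMAIN_COLUMNS])


def read_bed3(path, name: str | None = None) -> pd.DataFrame:
    """Read a BED3/BED4 file into a ``chrom, start, end`` frame (extra cols dropped)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    df["chrom"] = df["chrom"].astype(str)
    return df


def read_chrom_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


def _merge_short_domains(intervals: list[list], min_domain_bp: int) -> list[list]:
    """Absorb domains shorter than ``min_domain_bp`` into their longer neighbor.

    ``intervals`` is a list of ``[start, end, label]``, sorted, tiling a
    chromosome.  Shortest-first processing; after each absorption adjacent
    same-label runs are coalesced.
    """

    def coalesce(iv):
        out = [iv[0]]
        for s, e, lab in iv[1:]:
            if lab == out[-1][2]:
                out[-1][1] = e
            else:
                out.append([s, e, lab])
        return out

    iv = coalesce([list(x) for x in intervals])
    while len(iv) > 1:
        lengths = [e - s for s, e, _ in iv]
        order = int(np.argmin(lengths))
        if lengths[order] >= min_domain_bp:
            break
        left = iv[order - 1] if order > 0 else None
        right = iv[order + 1] if order < len(iv) - 1 else None
        if left is None:
            absorber = right
        elif right is None:
            absorber = left
        else:
            # merge into the neighbor sharing the longer boundary span
            absorber = left if (left[1] - left[0]) >= (right[1] - right[0]) else right
        absorber_is_left = absorber is left
        s, e, _ = iv[order]
        if absorber_is_left:
            left[1] = e
        else:
            right[0] = s
        del iv[order]
        iv = coalesce(iv)
    return iv


def partition_forest_prairie(
    cgi_intervals: pd.DataFrame,
    chrom_sizes: dict[str, int],
    gap_threshold_bp: int = 50_000,
    min_domain_bp: int = 1_000_000,
) -> DomainSet:
    """Partition each chromosome into forest/prairie domains from CGI positions.

    Consecutive CGIs separated by less than ``gap_threshold_bp`` are chained
    into one forest block spanning from the first CGI start to the last CGI
    end; everything else is prairie.  Domains shorter than ``min_domain_bp``
    are merged into the longer neighbor, which may join same-label runs.

    Parameters
    ----------
    cgi_intervals
        ``chrom, start, end`` frame of CGIs, sorted and non-overlapping per
        chromosome.
    chrom_sizes
        Chromosome name → length in bp.  Every chromosome listed here is
        covered by the returned partition.
    """
    if gap_threshold_bp <= 0 or min_domain_bp <= 0:
        raise ValueError("thresholds must be positive")
    rows = []
    for chrom, size in chrom_sizes.items():
        sub = cgi_intervals[cgi_intervals["chrom"] == chrom].sort_values("start")
        if len(sub):
            if (sub["start"].values < 0).any() or (sub["end"].values > size).any():
                raise ValueError(f"CGI interval outside bounds of {chrom} (size {size})")
            if (sub["start"].values[1:] < sub["end"].values[:-1]).any():
                raise ValueError(f"overlapping CGI intervals on {chrom}")
        if not len(sub):
            warnings.warn(f"no CGIs on {chrom}: whole chromosome labeled prairie")
            rows.append({"chrom": chrom, "start": 0, "end": size, "label": PRAIRIE, "id": 0})
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        # chain CGIs with gaps below threshold into forest blocks
        blocks = [[int(starts[0]), int(ends[0])]]
        for s, e in zip(starts[1:], ends[1:]):
            if s - blocks[-1][1] < gap_threshold_bp:
                blocks[-1][1] = int(e)
            else:
                blocks.append([int(s), int(e)])
        iv = []
        cursor = 0
        for s, e in blocks:
            if s > cursor:
                iv.append([cursor, s, PRAIRIE])
            iv.append([s, e, FOREST])
            cursor = e
        if cursor < size:
            iv.append([cursor, size, PRAIRIE])
        iv = _merge_short_domains(iv, min_domain_bp)
        for i, (s, e, lab) in enumerate(iv):
            rows.append({"chrom": chrom, "start": s, "end": e, "label": lab, "id": i})
    return DomainSet(pd.DataFrame(rows, columns=DOMAIN_COLUMNS))


def label_bins(domains: DomainSet, resolution_bp: int, chrom: str,
               n_bins: int | None = None) -> pd.DataFrame:
    """Assign each fixed-size bin of ``chrom`` to the domain covering most of it.

    A bin is labeled by the domain covering the majority of
    ``[b*res, (b+1)*res)``; an exact 50/50 tie goes to the domain containing
    the bin start.  Bins covered by no domain get label ``None`` and
    ``domain_id`` −1 and are excluded downstream.

    Returns a frame with columns ``bin, label, domain_id``.
    """
    if resolution_bp <= 0:
        raise ValueError("resolution must be positive")
    sub = domains.for_chrom(chrom)
    if n_bins is None:
        if not len(sub):
            raise ValueError(f"no domains on {chrom} and n_bins not given")
        n_bins = int(np.ceil(sub["end"].max() / resolution_bp))
    labels: list[str | None] = []
    ids: list[int] = []
    starts = sub["start"].to_numpy() if len(sub) else np.array([], dtype=int)
    ends = sub["end"].to_numpy() if len(sub) else np.array([], dtype=int)
    for b in range(n_bins):
        lo, hi = b * resolution_bp, (b + 1) * resolution_bp
        ov = np.minimum(ends, hi) - np.maximum(starts, lo)
        ov = np.where(ov > 0, ov, 0)
        if not len(ov) or ov.max() == 0:
            labels.append(None)
            ids.append(-1)
            continue
        best = int(np.argmax(ov))
        tied = np.flatnonzero(ov == ov[best])
        if len(tied) > 1:
            # tie: the domain containing the bin start wins
            containing = [t for t in tied if starts[t] <= lo < ends[t]]
            if containing:
                best = containing[0]
            else:
                best = int(tied[0])
        labels.append(sub["label"].iloc[best])
        ids.append(int(sub["id"].iloc[best]))
    return pd.DataFrame({"bin": np.arange(n_bins), "label": labels, "domain_id": ids})


# ---------------------------------------------------------------------------
# CpG / SINE bin classification


@dataclass(frozen=True)
class BinClassTrack:
    """40-kb bins classified by median splits of CpG and SINE density.

    ``cls`` holds one of ``hChS, hClS, lChS, lClS`` per bin ("h"/"l" = above /
    not-above the genome-wide median, strict ``>``).
    """

    cpg_density: np.ndarray
    sine_density: np.ndarray
    cls: np.ndarray = field(repr=False)
    cpg_median: float = 0.0
    sine_median: float = 0.0

    def bins_in(self, class_name: str) -> np.ndarray:
        return np.flatnonzero(self.cls == class_name)

    def to_frame(self, chrom: str = "chr1", resolution_bp: int = 40_000) -> pd.DataFrame:
        n = len(self.cls)
        return pd.DataFrame({
            "chrom": chrom,
            "start": np.arange(n) * resolution_bp,
            "end": (np.arange(n) + 1) * resolution_bp,
            "cpg": self.cpg_density,
            "sine": self.sine_density,
            "cls": self.cls,
        })


def classify_bins_cpg_sine(cpg_density, sine_density) -> BinClassTrack:
    """Median-split bins into the four high/low CpG × high/low SINE classes.

    Strictly-above-median is "high"; bins exactly at the median fall in the
    low class.  Rejects degenerate all-equal tracks.
    """
    cpg = np.asarray(cpg_density, dtype=float)
    sine = np.asarray(sine_density, dtype=float)
    if cpg.shape != sine.shape:
        raise ValueError("CpG and SINE tracks must share the bin grid")
    for name, x in (("CpG", cpg), ("SINE", sine)):
        if np.all(x == x.flat[0]):
            raise ValueError(f"degenerate {name} density track: all values equal")
    cpg_med = float(np.median(cpg))
    sine_med = float(np.median(sine))
    hc = cpg > cpg_med
    hs = sine > sine_med
    cls = np.array([
        ("h" if c else "l") + "C" + ("h" if s else "l") + "S"
        for c, s in zip(hc, hs)
    ])
    return BinClassTrack(cpg, sine, cls, cpg_med, sine_med)
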