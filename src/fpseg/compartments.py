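"""A/B compartments, the compartment index, and compartment dynamics.

Compartments are called the field-standard way: the leading eigenvector
(PC1) of the Pearson correlation matrix of a distance-normalized
(observed/expected) cis contact matrix, with the sign oriented so that
high-CpG bins — gene-dense, active chromatin — carry positive PC1 and are
labeled compartment A.

The *compartment index* (C-index) of a bin is the log-ratio of its mean
distance-normalized contact with all A bins over all B bins; it grades how
A-like each bin's contact environment is, independent of the hard A/B
threshold.  *Strict* compartments keep only concordant bins (A with positive
C-index, B with negative) to guard the A/B composition analysis against
borderline calls.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .domains import FOREST, PRAIRIE, DomainSet, domain_keys
from .hic import DISTANCE, ContactMatrix

A, B = 1.0, 0.0
STABLE_AP, STABLE_BP, SWITCHABLE_P = "stable_Ap", "stable_Bp", "switchable_p"


@dataclass(frozen=True)
class CompartmentTrack:
    """Per-bin compartment state on one chromosome.

    ``pc1`` and ``delta`` (1 = A, 0 = B) are NaN on masked/degenerate bins;
    ``cindex`` and ``strict`` are filled by :func:`compute_cindex` and
    :func:`strict_compartments`.
    """

    chrom: str
    resolution_bp: int
    pc1: np.ndarray
    delta: np.ndarray
    cindex: np.ndarray | None = None
    strict: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return len(self.delta)

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.delta)

    @property
    def n_a(self) -> int:
        return int(np.nansum(self.delta == A))

    @property
    def n_b(self) -> int:
        return int(np.nansum(self.delta == B))

    def to_frame(self) -> pd.DataFrame:
        n = self.n_bins
        return pd.DataFrame({
            "chrom": self.chrom,
            "start": np.arange(n) * self.resolution_bp,
            "end": (np.arange(n) + 1) * self.resolution_bp,
            "pc1": self.pc1,
            "AB": np.where(np.isfinite(self.delta),
                           np.where(self.delta == A, "A", "B"), ""),
            "cindex": self.cindex if self.cindex is not None else np.nan,
            "strict": self.strict if self.strict is not None else "",
        })


def call_compartments(m: ContactMatrix, cpg_density) -> CompartmentTrack:
    """PC1 compartment call on a distance-normalized matrix.

    Masked and zero-variance bins are removed before the correlation matrix
    and re-inserted as NaN.  Sign convention: bins with above-median CpG
    density get mean PC1 > 0; A (delta=1) where PC1 > 0.
    """
    if m.norm_state != DISTANCE:
        raise ValueError("compartment calling requires a distance-normalized matrix")
    cpg = np.asarray(cpg_density, dtype=float)
    if len(cpg) != m.n_bins:
        raise ValueError("CpG track length does not match matrix")
    use = m.unmasked & (m.values.std(axis=1) > 0)
    if use.sum() < 20:
        raise ValueError(f"only {use.sum()} usable bins; need >= 20")
    sub = m.values[np.ix_(use, use)]
    corr = np.corrcoef(sub)
    if not np.isfinite(corr).all():
        raise ValueError("degenerate correlation matrix (constant rows)")
    evals, evecs = np.linalg.eigh(corr)
    v = evecs[:, -1]
    hi = cpg[use] > np.median(cpg[use])
    if hi.any() and v[hi].mean() < 0:
        v = -v
    pc1 = np.full(m.n_bins, np.nan)
    pc1[use] = v
    delta = np.full(m.n_bins, np.nan)
    delta[use] = np.where(v > 0, A, B)
    return CompartmentTrack(m.chrom, m.resolution_bp, pc1, delta)


def compute_cindex(m: ContactMatrix, track: CompartmentTrack) -> CompartmentTrack:
    """C-index per bin: ``I_i = ln[(Σ_j C_ij δ_j / N_A) / (Σ_j C_ij (1−δ_j) / N_B)]``.

    Sums run over bins with a defined compartment call; bins with zero
    contact to either class get NaN.  Requires at least one A and one B bin.
    """
    if m.norm_state != DISTANCE:
        raise ValueError("C-index requires a distance-normalized matrix")
    if track.n_bins != m.n_bins:
        raise ValueError("track does not match matrix grid")
    defined = track.defined
    n_a, n_b = track.n_a, track.n_b
    if n_a == 0 or n_b == 0:
        raise ValueError("C-index needs both compartments populated")
    is_a = defined & (track.delta == A)
    is_b = defined & (track.delta == B)
    to_a = m.values[:, is_a].sum(axis=1) / n_a
    to_b = m.values[:, is_b].sum(axis=1) / n_b
    cindex = np.full(m.n_bins, np.nan)
    ok = m.unmasked & defined & (to_a > 0) & (to_b > 0)
    cindex[ok] = np.log(to_a[ok] / to_b[ok])
    return replace(track, cindex=cindex)


def strict_compartments(track: CompartmentTrack, bin_fp_labels) -> tuple[CompartmentTrack, dict]:
    """Strict compartment labels and sAf/sAp/sBf/sBp genome lengths in bp.

    sA = A bins with positive C-index; sB = B bins with negative C-index;
    everything else is "none".  Lengths split the strict bins by their
    forest/prairie label (unlabeled bins are skipped in the length tally).
    """
    if track.cindex is None:
        raise ValueError("compute_cindex must run first")
    lab = np.asarray(bin_fp_labels, dtype=object)
    strict = np.full(track.n_bins, "none", dtype=object)
    sa = track.defined & (track.delta == A) & (track.cindex > 0)
    sb = track.defined & (track.delta == B) & (track.cindex < 0)
    strict[sa] = "sA"
    strict[sb] = "sB"
    res = track.resolution_bp
    lengths = {
        "sAf": int((sa & (lab == FOREST)).sum()) * res,
        "sAp": int((sa & (lab == PRAIRIE)).sum()) * res,
        "sBf": int((sb & (lab == FOREST)).sum()) * res,
        "sBp": int((sb & (lab == PRAIRIE)).sum()) * res,
    }
    return replace(track, strict=strict), lengths


def fp_compartment_composition(track: CompartmentTrack, bin_fp_labels) -> dict:
    """Genome-length fractions of Af, Bf, Ap, Bp among classified bins.

    A bin is classified when it has both a compartment call and an F/P label;
    the four fractions sum to 1.
    """
    lab = np.asarray(bin_fp_labels, dtype=object)
    ok = track.defined & np.array([x in (FOREST, PRAIRIE) for x in lab])
    total = int(ok.sum())
    if total == 0:
        raise ValueError("no bins with both compartment and F/P labels")
    is_a = track.delta == A
    out = {
        "Af": int((ok & is_a & (lab == FOREST)).sum()) / total,
        "Bf": int((ok & ~is_a & (lab == FOREST)).sum()) / total,
        "Ap": int((ok & is_a & (lab == PRAIRIE)).sum()) / total,
        "Bp": int((ok & ~is_a & (lab == PRAIRIE)).sum()) / total,
    }
    return out


# ---------------------------------------------------------------------------
# Multi-stage dynamics


@dataclass(frozen=True)
class CompartmentDynamics:
    """Prairie-domain compartment trajectories across developmental stages.

    ``classes``: per prairie domain, stable_Ap (A at every stage), stable_Bp
    (B at every stage) or switchable_p.  ``stage_compartments``: domain ×
    stage majority compartment ("A"/"B").  ``boundary_distance_bp``: per
    domain and stage, distance from the domain midpoint to the nearest A–B
    boundary of that stage's track (NaN when the stage has no boundary).
    """

    classes: pd.Series
    stage_compartments: pd.DataFrame
    boundary_distance_bp: pd.DataFrame


def _domain_bins(domains: DomainSet, chrom: str, resolution_bp: int, n_bins: int) -> dict[str, np.ndarray]:
    from .domains import label_bins
    bins = label_bins(domains, resolution_bp, chrom, n_bins=n_bins)
    sub = domains.for_chrom(chrom)
    keys = dict(zip(sub["id"], domain_keys(sub)))
    out = {}
    dom_ids = bins["domain_id"].to_numpy()
    for did, key in keys.items():
        out[key] = np.flatnonzero(dom_ids == did)
    return out


def _majority_compartment(delta: np.ndarray, member: np.ndarray) -> str:
    """Majority A/B over a domain's defined bins; ties and empty go to B."""
    d = delta[member]
    d = d[np.isfinite(d)]
    if len(d) == 0:
        return "B"
    return "A" if (d == A).sum() > (d == B).sum() else "B"


def _ab_boundaries_bp(track: CompartmentTrack) -> np.ndarray:
    """Positions (bp) of transitions between consecutive defined A/B bins."""
    idx = np.flatnonzero(track.defined)
    d = track.delta[idx]
    change = np.flatnonzero(d[1:] != d[:-1])
    # boundary placed at the start of the later bin of the flipping pair
    return idx[change + 1] * float(track.resolution_bp)


def classify_prairie_dynamics(tracks: dict[str, CompartmentTrack],
                              domains: DomainSet) -> CompartmentDynamics:
    """Classify prairie domains as stable A, stable B or switchable across stages.

    Each prairie domain is assigned one compartment per stage by the majority
    of its bins' calls (ties → B); stages must share chromosome, bin count
    and resolution.
    """
    if len(tracks) < 2:
        raise ValueError("need at least two stages")
    items = list(tracks.items())
    ref = items[0][1]
    for _, t in items[1:]:
        if (t.chrom, t.n_bins, t.resolution_bp) != (ref.chrom, ref.n_bins, ref.resolution_bp):
            raise ValueError("stage tracks are on different grids")
    member = _domain_bins(domains, ref.chrom, ref.resolution_bp, ref.n_bins)
    sub = domains.for_chrom(ref.chrom)
    prairie_keys = domain_keys(sub)[sub["label"] == PRAIRIE].to_numpy()

    comp = pd.DataFrame(index=prairie_keys, columns=list(tracks), dtype=object)
    bdist = pd.DataFrame(index=prairie_keys, columns=list(tracks), dtype=float)
    mids = {}
    for key in prairie_keys:
        row = sub[domain_keys(sub) == key].iloc[0]
        mids[key] = (row["start"] + row["end"]) / 2.0
    for stage, track in tracks.items():
        bounds = _ab_boundaries_bp(track)
        for key in prairie_keys:
            comp.loc[key, stage] = _majority_compartment(track.delta, member[key])
            if len(bounds):
                bdist.loc[key, stage] = float(np.min(np.abs(bounds - mids[key])))
            else:
                bdist.loc[key, stage] = np.nan

    def classify(row) -> str:
        vals = set(row)
        if vals == {"A"}:
            return STABLE_AP
        if vals == {"B"}:
            return STABLE_BP
        return SWITCHABLE_P

    classes = comp.apply(classify, axis=1)
    classes.name = "class"
    return CompartmentDynamics(classes, comp, bdist)


def transition_composition(track1: CompartmentTrack, track2: CompartmentTrack) -> dict:
    """AA/AB/BA/BB genome-length ratios between two stages on the same grid."""
    if (track1.chrom, track1.n_bins, track1.resolution_bp) != \
            (track2.chrom, track2.n_bins, track2.resolution_bp):
        raise ValueError("tracks are on different grids")
    ok = track1.defined & track2.defined
    total = int(ok.sum())
    if total == 0:
        raise ValueError("no bins classified in both stages")
    a1 = track1.delta == A
    a2 = track2.delta == A
    return {
        "AA": int((ok & a1 & a2).sum()) / total,
        "AB": int((ok & a1 & ~a2).sum()) / total,
        "BA": int((ok & ~a1 & a2).sum()) / total,
        "BB": int((ok & ~a1 & ~a2).sum()) / total,
    }


# ---------------------------------------------------------------------------
# Signal aggregation over regions


def aggregate_signal(signal: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """bp-weighted mean of a bedGraph-style signal over each region.

    ``signal`` must have sorted, non-overlapping ``chrom, start, end, value``
    rows; uncovered bp contribute 0 to the mean and are reflected in the
    ``coverage`` fraction column of the output.
    """
    for col in ("chrom", "start", "end", "value"):
        if col not in signal.columns:
            raise ValueError(f"signal frame missing column {col!r}")
    if (signal["end"] <= signal["start"]).any():
        raise ValueError("malformed signal interval (end <= start)")
    for chrom, subsig in signal.groupby("chrom", sort=False):
        s = subsig.sort_values("start")
        if (s["start"].values[1:] < s["end"].values[:-1]).any():
            raise ValueError(f"overlapping signal intervals on {chrom}")
    rows = []
    for reg in regions.itertuples(index=False):
        subsig = signal[signal["chrom"] == reg.chrom]
        ov = np.minimum(subsig["end"].to_numpy(), reg.end) - \
            np.maximum(subsig["start"].to_numpy(), reg.start)
        keep = ov > 0
        length = reg.end - reg.start
        covered = float(ov[keep].sum())
        weighted = float((ov[keep] * subsig["value"].to_numpy()[keep]).sum())
        rows.append({"chrom": reg.chrom, "start": reg.start, "end": reg.end,
                     "mean": weighted / length, "coverage": covered / length})
    return pd.DataFrame(rows)


def compare_dynamics_signal(dynamics: CompartmentDynamics, signal_means: pd.Series) -> dict:
    """Welch t-test of a per-domain signal between switchable and stable-B prairies."""
    sw = signal_means.reindex(dynamics.classes.index[dynamics.classes == SWITCHABLE_P]).dropna()
    st = signal_means.reindex(dynamics.classes.index[dynamics.classes == STABLE_BP]).dropna()
    if len(sw) < 2 or len(st) < 2:
        raise ValueError("need >= 2 domains in each class")
    t, p = stats.ttest_ind(sw, st, equal_var=False)
    return {"t": float(t), "p": float(p),
            "mean_switchable": float(sw.mean()), "mean_stable_Bp": float(st.mean()),
            "n_switchable": len(sw), "n_stable_Bp": len(st)}
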