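"""Hi-C contact matrices: I/O, ICE and distance normalization, domain aggregation.

Only cis (intra-chromosomal) matrices are handled; every downstream statistic
in this package is distance- and domain-oriented.  Matrices live in dense
numpy arrays — the analyses operate at 40-kb/200-kb binning on single
chromosomes, where dense storage is cheap.

Normalization states form a one-way chain ``raw → ICE → distance``:

* :func:`ice_normalize` — iterative correction (matrix balancing) so that all
  unmasked rows carry equal total contact, rescaled to mean row sum 1;
* :func:`distance_normalize` — observed/expected: each diagonal divided by
  its mean over unmasked bin pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .domains import DomainSet, domain_keys, label_bins

RAW = "raw"
ICE = "ICE"
DISTANCE = "distance"


@dataclass(frozen=True)
class ContactMatrix:
    """Symmetric non-negative binned cis contact matrix for one chromosome.

    ``mask`` flags excluded (zero-coverage) bins; masked rows/columns are
    all-zero.  ``converged`` records ICE convergence.
    """

    chrom: str
    resolution_bp: int
    values: np.ndarray
    norm_state: str = RAW
    mask: np.ndarray | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("contact matrix must be square")
        if (v < 0).any():
            raise ValueError("negative contact counts")
        if not np.allclose(v, v.T, atol=1e-9, rtol=0):
            raise ValueError("contact matrix not symmetric within 1e-9")
        object.__setattr__(self, "values", v)
        mask = self.mask
        if mask is None:
            mask = np.zeros(v.shape[0], dtype=bool)
        object.__setattr__(self, "mask", np.asarray(mask, dtype=bool))

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def unmasked(self) -> np.ndarray:
        return ~self.mask

    def scaled(self, c: float) -> "ContactMatrix":
        return replace(self, values=self.values * c)


def read_matrix(path, chrom: str = "chr1", resolution_bp: int = 40_000,
                fmt: str = "auto", n_bins: int | None = None) -> ContactMatrix:
    """Read a contact matrix from sparse triplet or dense whitespace text.

    Sparse rows are ``bin_i  bin_j  count``; only one triangle need be given
    (entries are mirrored).  ``fmt="auto"`` treats any 3-column file as
    sparse — pass ``fmt="dense"`` for a literal 3×3 dense matrix.
    """
    arr = np.loadtxt(path, ndmin=2)
    if fmt == "auto":
        fmt = "sparse" if arr.shape[1] == 3 else "dense"
    if fmt == "sparse":
        i = arr[:, 0].astype(int)
        j = arr[:, 1].astype(int)
        c = arr[:, 2].astype(float)
        if (c < 0).any():
            raise ValueError("negative contact counts")
        n = n_bins if n_bins is not None else int(max(i.max(), j.max())) + 1
        m = np.zeros((n, n))
        filled = np.zeros((n, n), dtype=bool)
        for a, b, v in zip(i, j, c):
            for x, y in ((a, b), (b, a)):
                if filled[x, y] and m[x, y] != v:
                    raise ValueError(f"conflicting duplicate entry at ({a},{b})")
                m[x, y] = v
                filled[x, y] = True
        values = m
    elif fmt == "dense":
        values = arr
        if not np.allclose(values, values.T, atol=1e-9, rtol=0):
            raise ValueError("asymmetric dense matrix beyond 1e-9 tolerance")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return ContactMatrix(chrom, resolution_bp, values)


def write_matrix(m: ContactMatrix, path, fmt: str = "sparse") -> None:
    """Write a matrix as sparse upper-triangle triplets or dense text."""
    if fmt == "sparse":
        iu, ju = np.nonzero(np.triu(m.values))
        with open(path, "w") as fh:
            for i, j in zip(iu, ju):
                fh.write(f"{i}\t{j}\t{m.values[i, j]:.17g}\n")
    elif fmt == "dense":
        np.savetxt(path, m.values, fmt="%.17g", delimiter="\t")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def mask_zero_bins(m: ContactMatrix) -> ContactMatrix:
    """Mask bins with zero raw marginal (standard pre-ICE filtering)."""
    marg = m.values.sum(axis=1)
    mask = m.mask | (marg == 0)
    v = m.values.copy()
    v[mask, :] = 0.0
    v[:, mask] = 0.0
    return replace(m, values=v, mask=mask)


def ice_normalize(m: ContactMatrix, tol: float = 1e-5, max_iter: int = 200) -> ContactMatrix:
    """Iterative correction: equalize unmasked row sums, then rescale to mean 1.

    Convergence when the maximum relative deviation of unmasked row sums from
    their mean drops below ``tol`` (hence row-sum CV < tol).  Non-convergence
    returns the matrix with ``converged=False`` and a warning.
    """
    if m.norm_state != RAW:
        raise ValueError(f"ICE requires a raw matrix, got {m.norm_state!r}")
    m = mask_zero_bins(m)
    un = m.unmasked
    if not un.any():
        raise ValueError("all-zero matrix cannot be balanced")
    w = m.values.copy()
    converged = False
    for _ in range(max_iter):
        s = w.sum(axis=1)
        sm = s[un]
        mean = sm.mean()
        if mean == 0:
            raise ValueError("all-zero matrix cannot be balanced")
        if np.max(np.abs(sm - mean)) / mean < tol:
            converged = True
            break
        f = np.ones(m.n_bins)
        f[un] = sm / mean
        w /= np.outer(f, f)
        w[m.mask, :] = 0.0
        w[:, m.mask] = 0.0
    if not converged:
        warnings.warn(f"ICE did not converge in {max_iter} iterations")
    mean_row = w.sum(axis=1)[un].mean()
    w /= mean_row
    return replace(m, values=w, norm_state=ICE, converged=converged)


def distance_normalize(m: ContactMatrix) -> ContactMatrix:
    """Observed/expected: divide each diagonal by its mean over unmasked pairs.

    Diagonals whose unmasked mean is zero are left at zero.  Idempotent.
    """
    n = m.n_bins
    un = m.unmasked
    w = m.values.copy()
    for d in range(n):
        i = np.arange(n - d)
        j = i + d
        valid = un[i] & un[j]
        if not valid.any():
            continue
        mean = w[i[valid], j[valid]].mean()
        if mean == 0:
            continue
        w[i, j] = w[i, j] / mean
        if d:
            w[j, i] = w[i, j]
        w[i[~valid], j[~valid]] = 0.0
        if d:
            w[j[~valid], i[~valid]] = 0.0
    w[m.mask, :] = 0.0
    w[:, m.mask] = 0.0
    return replace(m, values=w, norm_state=DISTANCE)


def aggregate_domain_contacts(m: ContactMatrix, domains: DomainSet) -> pd.DataFrame:
    """Length-normalized inter-domain contact table D_ij.

    For domains i, j the entry ``D`` is the summed bin-level contact between
    them divided by the product of their lengths *in unmasked bins of this
    matrix*, so D equals the mean per-bin-pair contact.  Intra-domain rows
    (``intra=True``) use the upper triangle including the diagonal and are
    excluded from all segregation ratios.  Masked or unassigned bins count
    neither toward sums nor lengths; domains with no unmasked bin are dropped
    with a warning.

    Returns a frame with one row per ordered-free pair (dom_i ≤ dom_j):
    ``chrom, dom_i, dom_j, key_i, key_j, label_i, label_j, n_bins_i,
    n_bins_j, contact_sum, D, intra``.
    """
    bins = label_bins(domains, m.resolution_bp, m.chrom, n_bins=m.n_bins)
    sub = domains.for_chrom(m.chrom)
    keys = domain_keys(sub)
    assigned = (bins["domain_id"].to_numpy() >= 0) & m.unmasked
    rows = []
    members: dict[int, np.ndarray] = {}
    for dom_id in sub["id"]:
        mem = np.flatnonzero(assigned & (bins["domain_id"].to_numpy() == dom_id))
        if len(mem) == 0:
            warnings.warn(f"domain {m.chrom}:{dom_id} has no unmasked bins; excluded")
            continue
        members[int(dom_id)] = mem
    ids = sorted(members)
    label_of = dict(zip(sub["id"], sub["label"]))
    key_of = dict(zip(sub["id"], keys))
    for a_pos, di in enumerate(ids):
        mi = members[di]
        for dj in ids[a_pos:]:
            mj = members[dj]
            block = m.values[np.ix_(mi, mj)]
            if di == dj:
                s = (block.sum() + np.trace(block)) / 2.0  # upper triangle incl. diagonal
                denom = len(mi) * len(mj)
                intra = True
            else:
                s = block.sum()
                denom = len(mi) * len(mj)
                intra = False
            rows.append({
                "chrom": m.chrom, "dom_i": di, "dom_j": dj,
                "key_i": key_of[di], "key_j": key_of[dj],
                "label_i": label_of[di], "label_j": label_of[dj],
                "n_bins_i": len(mi), "n_bins_j": len(mj),
                "contact_sum": float(s), "D": float(s) / denom, "intra": intra,
            })
    return pd.DataFrame(rows)


def write_domain_contacts(dct: pd.DataFrame, path) -> None:
    dct.to_csv(path, sep="\t", index=False)


def read_domain_contacts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
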