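"""Binned contact matrices: ICE balancing, downsampling, differentials,
and density-plot export.

Raw matrices are symmetric bin-pair counts of unique ligation junctions.
ICE (iterative correction) equalizes bin coverage by factorizing the
observed counts into a per-bin bias vector and a balanced matrix with
uniform row sums; bins with zero marginal are masked.  Condition
comparisons first downsample every junction table to the smallest table's
size so matrices are directly comparable, then subtract balanced matrices.
Display convention: linear colour scale at 500 bp resolution, log10 scale
at 20-50 bp.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import BinGrid, bin_index
from .junctions import JunctionTable

__all__ = [
    "ContactMatrix",
    "bin_junctions",
    "ice_balance",
    "downsample",
    "differential_matrix",
    "density_points",
    "write_matrix",
]


@dataclass
class ContactMatrix:
    grid: BinGrid
    counts: np.ndarray
    balanced: np.ndarray | None = None
    bias: np.ndarray | None = None
    mask: np.ndarray | None = None  # True = bin masked (excluded)
    scale: str = "linear"

    def __post_init__(self) -> None:
        n = self.grid.n_bins
        if self.counts.shape != (n, n):
            raise ValueError("counts shape does not match grid")
        if self.mask is None:
            self.mask = np.zeros(n, dtype=bool)

    def display_matrix(self) -> np.ndarray:
        """Balanced (or raw) matrix on the configured display scale.

        The log scale uses log10(x + pseudocount) with the pseudocount set
        to the smallest positive entry, so zeros stay at the bottom of the
        colour range without producing -inf.
        """
        m = self.balanced if self.balanced is not None else self.counts
        if self.scale == "linear":
            return m
        positive = m[m > 0]
        pseudo = positive.min() if positive.size else 1.0
        return np.log10(m + pseudo)


def bin_junctions(
    table: JunctionTable,
    grid: BinGrid,
    scale: str = "linear",
) -> tuple[ContactMatrix, dict]:
    """Accumulate junctions into a symmetric raw matrix.

    Each junction increments counts[b1, b2] and counts[b2, b1]; a junction
    with both ends in the same bin increments the diagonal once.  Junctions
    outside the grid's region are skipped and counted in the log.
    """
    region = grid.region
    n = grid.n_bins
    counts = np.zeros((n, n), dtype=float)
    stats = {"junctions_in": len(table), "binned": 0, "outside_region": 0}
    for j in table.junctions:
        if (
            j.chrom1 != region.chrom
            or j.chrom2 != region.chrom
            or not region.interval.contains(j.pos1)
            or not region.interval.contains(j.pos2)
        ):
            stats["outside_region"] += 1
            continue
        b1 = bin_index(j.pos1, grid)
        b2 = bin_index(j.pos2, grid)
        counts[b1, b2] += 1
        if b1 != b2:
            counts[b2, b1] += 1
        stats["binned"] += 1
    return ContactMatrix(grid, counts, scale=scale), stats


def ice_balance(
    matrix: ContactMatrix,
    max_iter: int = 200,
    tol: float = 1e-5,
) -> ContactMatrix:
    """Iterative correction: equalize row sums over unmasked bins.

    Bins with zero marginal are masked.  Each iteration divides the working
    matrix by the outer product of its mean-normalized row sums and
    accumulates those factors into the bias vector, stopping when every
    unmasked row sum is within ``tol`` of the mean.  The balanced matrix is
    rescaled so its total unmasked mass equals the raw mass, keeping raw
    and balanced matrices on comparable count scales.
    """
    counts = matrix.counts.astype(float)
    marginal = counts.sum(axis=1)
    mask = marginal == 0
    if mask.all():
        raise ValueError("cannot balance: all bins have zero coverage")
    work = counts.copy()
    work[mask, :] = 0.0
    work[:, mask] = 0.0
    n = counts.shape[0]
    bias = np.ones(n)
    for _ in range(max_iter):
        s = work.sum(axis=1)
        s_unmasked = s[~mask]
        s = s / s_unmasked.mean()
        s[mask] = 1.0
        if np.abs(s[~mask] - 1.0).max() < tol:
            break
        bias *= s
        work /= np.outer(s, s)
    raw_mass = counts[np.ix_(~mask, ~mask)].sum()
    bal_mass = work[np.ix_(~mask, ~mask)].sum()
    if bal_mass > 0:
        work *= raw_mass / bal_mass
    work[mask, :] = 0.0
    work[:, mask] = 0.0
    bias_out = bias.copy()
    bias_out[mask] = np.nan
    return ContactMatrix(
        matrix.grid, matrix.counts, balanced=work, bias=bias_out,
        mask=mask, scale=matrix.scale,
    )


def downsample(
    tables: dict[str, JunctionTable], seed: int
) -> dict[str, JunctionTable]:
    """Sample every table down to the smallest table's junction count.

    Uniform sampling without replacement, deterministic for a fixed seed;
    this is what makes matrices of different conditions (or replicates)
    directly comparable.
    """
    if len(tables) < 2:
        raise ValueError("downsampling needs at least two tables")
    for name, t in tables.items():
        if len(t) == 0:
            raise ValueError(f"condition {name!r} has an empty junction table")
    min_n = min(len(t) for t in tables.values())
    rng = np.random.default_rng(seed)
    out = {}
    for name in sorted(tables):
        t = tables[name]
        if len(t) == min_n:
            out[name] = JunctionTable(
                list(t.junctions), t.sample,
                {**t.stage_counts, "downsampled": min_n},
            )
            continue
        idx = rng.choice(len(t), size=min_n, replace=False)
        idx.sort()
        out[name] = JunctionTable(
            [t.junctions[i] for i in idx], t.sample,
            {**t.stage_counts, "downsampled": min_n},
        )
    return out


def differential_matrix(a: ContactMatrix, b: ContactMatrix) -> ContactMatrix:
    """Signed per-bin difference of two balanced matrices (A - B).

    Both inputs must be ICE-balanced on the same grid (and should come from
    equally downsampled tables); bins masked in either input are masked in
    the output.
    """
    if a.grid.binsize != b.grid.binsize or a.grid.n_bins != b.grid.n_bins \
            or a.grid.region.interval != b.grid.region.interval:
        raise ValueError("differential requires matrices on the same grid")
    if a.balanced is None or b.balanced is None:
        raise ValueError("differential requires ICE-balanced inputs")
    mask = a.mask | b.mask
    diff = a.balanced - b.balanced
    diff[mask, :] = 0.0
    diff[:, mask] = 0.0
    out = ContactMatrix(a.grid, a.counts - b.counts, balanced=diff,
                        mask=mask, scale=a.scale)
    return out


def density_points(
    table: JunctionTable,
    cell: int = 20,
    bandwidth: float = 3.0,
) -> list[tuple[int, int, float]]:
    """Local point density at each junction's exact coordinates.

    Junctions are counted on a 2-D grid of ``cell`` bp cells which is
    smoothed with a Gaussian kernel (sigma = ``bandwidth`` cells); each
    point reports the smoothed density of its cell.  The output is sorted
    ascending by density so that dense points are drawn last in a scatter
    plot.  The caller is expected to have applied the >= 10 bp minimum
    distance filter upstream.
    """
    pts = [
        (j.pos1, j.pos2) for j in table.junctions if j.chrom1 == j.chrom2
    ]
    if not pts:
        return []
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    x0, y0 = xs.min(), ys.min()
    cx = (xs - x0) // cell
    cy = (ys - y0) // cell
    nx, ny = int(cx.max()) + 1, int(cy.max()) + 1
    hist = np.zeros((nx, ny))
    np.add.at(hist, (cx, cy), 1.0)
    smooth = gaussian_filter(hist, sigma=bandwidth, mode="constant")
    dens = smooth[cx, cy]
    order = np.argsort(dens, kind="stable")
    return [(int(xs[i]), int(ys[i]), float(dens[i])) for i in order]


# ---------------------------------------------------------------------------
# text export


def write_matrix(matrix: ContactMatrix, out_prefix: str | Path) -> None:
    """Write dense TSV, COO triplets, and a JSON sidecar."""
    out_prefix = Path(out_prefix)
    m = matrix.balanced if matrix.balanced is not None else matrix.counts
    np.savetxt(out_prefix.with_suffix(".dense.tsv"), m, delimiter="\t",
               fmt="%.6g")
    with open(out_prefix.with_suffix(".coo.tsv"), "w") as fh:
        fh.write("bin1\tbin2\tvalue\n")
        for i, k in zip(*np.nonzero(np.triu(m))):
            fh.write(f"{i}\t{k}\t{m[i, k]:.6g}\n")
    sidecar = {
        "region": str(matrix.grid.region.interval),
        "region_name": matrix.grid.region.name,
        "binsize": matrix.grid.binsize,
        "n_bins": matrix.grid.n_bins,
        "scale": matrix.scale,
        "balanced": matrix.balanced is not None,
        "mask": matrix.mask.astype(int).tolist(),
        "bias": None if matrix.bias is None else [
            None if np.isnan(b) else b for b in matrix.bias
        ],
    }
    with open(out_prefix.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)
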