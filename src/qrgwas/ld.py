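"""LD decay estimation and QTL detection-window calibration.

Pairwise r² (squared Pearson correlation of marker dosages) is computed
for all same-chromosome marker pairs, a local polynomial regression of r²
on genetic distance is fitted (tricube weights, span 0.75, degree 2 —
the defaults of the classical LOESS smoother), and the detection-window
half-width *w* is the smallest distance at which the fitted curve crosses
the critical level r² = 0.20.  Markers within *w* of a target QTL are
"associated" with it; everything else feeds the false-positive-rate
denominator.

The smoother exploits the regular marker grid: pairs at the same distance
receive the same tricube weight, so r² values are aggregated per distinct
distance (mean + multiplicity) before the weighted least-squares fits,
which is exact and makes the fit cost independent of the pair count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeMap
from .popgen import Population

logger = logging.getLogger(__name__)

R2_THRESHOLD = 0.20


class NoWindowError(RuntimeError):
    """The fitted decay curve does not cross the critical r² level."""


def pairwise_r2(pop: Population, gmap: GenomeMap | None = None,
                max_pairs: int | None = None,
                seed: int | np.random.SeedSequence | None = 0) -> pd.DataFrame:
    """r² for same-chromosome marker pairs.

    Returns a frame with columns (chrom, i, j, dist_cM, r2) where i, j are
    genome-order marker indices.  Monomorphic markers are skipped (their
    correlation is undefined); the skipped count is logged and stored in
    ``frame.attrs["n_monomorphic"]``.  ``max_pairs`` optionally subsamples
    pairs (seeded) to bound memory/cost on denser maps.
    """
    gmap = gmap or pop.gmap
    D = pop.marker_dosages.astype(float)
    chroms, i_all, j_all, d_all, r2_all = [], [], [], [], []
    n_mono = 0
    offset = 0
    for c in range(gmap.n_chromosomes):
        pos = np.asarray(gmap.marker_positions[c])
        m = pos.size
        block = D[:, offset:offset + m]
        sd = block.std(axis=0)
        keep = sd > 0
        n_mono += int(np.sum(~keep))
        idx = np.flatnonzero(keep)
        if idx.size >= 2:
            corr = np.corrcoef(block[:, idx], rowvar=False)
            iu, ju = np.triu_indices(idx.size, k=1)
            chroms.append(np.full(iu.size, c))
            i_all.append(offset + idx[iu])
            j_all.append(offset + idx[ju])
            d_all.append(pos[idx[ju]] - pos[idx[iu]])
            r2_all.append(corr[iu, ju] ** 2)
        offset += m
    if not r2_all:
        raise ValueError("no polymorphic same-chromosome marker pairs")
    if n_mono:
        logger.info("pairwise_r2: skipped %d monomorphic markers", n_mono)
    out = pd.DataFrame({
        "chrom": np.concatenate(chroms),
        "i": np.concatenate(i_all),
        "j": np.concatenate(j_all),
        "dist_cM": np.concatenate(d_all),
        "r2": np.concatenate(r2_all),
    })
    if max_pairs is not None and len(out) > max_pairs:
        rng = np.random.default_rng(seed)
        out = out.iloc[np.sort(rng.choice(len(out), max_pairs, replace=False))]
        out = out.reset_index(drop=True)
    out.attrs["n_monomorphic"] = n_mono
    return out


# ---------------------------------------------------------------------------
# local polynomial smoother

def _loess_fit_at(x0: float, x: np.ndarray, y: np.ndarray, w: np.ndarray,
                  span_mass: float, degree: int) -> float:
    """Weighted local polynomial estimate at one point.

    x are distinct sorted abscissae with prior weights w (multiplicities);
    the neighbourhood is the smallest symmetric-in-rank window holding a
    fraction ``span_mass`` of the total weight, tricube-weighted by
    distance from x0.
    """
    total = w.sum()
    need = span_mass * total
    order = np.argsort(np.abs(x - x0), kind="stable")
    cum = np.cumsum(w[order])
    k = int(np.searchsorted(cum, need) + 1)
    k = min(max(k, degree + 1), x.size)
    sel = order[:k]
    xs, ys, ws = x[sel], y[sel], w[sel]
    dmax = np.abs(xs - x0).max()
    if dmax == 0:
        return float(np.average(ys, weights=ws))
    tri = (1.0 - (np.abs(xs - x0) / dmax) ** 3) ** 3
    wt = ws * np.maximum(tri, 1e-12)
    V = np.vander(xs - x0, degree + 1, increasing=True)
    WV = V * wt[:, None]
    beta, *_ = np.linalg.lstsq(WV.T @ V, WV.T @ ys, rcond=None)
    return float(beta[0])


@dataclass
class DecayCurve:
    """Fitted r²(distance) smooth, evaluable over the observed range."""

    x: np.ndarray            # distinct distances, sorted
    y: np.ndarray            # mean r² per distance
    w: np.ndarray            # pair multiplicity per distance
    span: float = 0.75
    degree: int = 2
    _grid: tuple = field(default=None, repr=False)

    def __call__(self, d):
        d = np.atleast_1d(np.asarray(d, float))
        out = np.array([_loess_fit_at(v, self.x, self.y, self.w,
                                      self.span, self.degree) for v in d])
        return out if out.size > 1 else float(out[0])

    @property
    def dmin(self) -> float:
        return float(self.x[0])

    @property
    def dmax(self) -> float:
        return float(self.x[-1])


def fit_decay_curve(pairs: pd.DataFrame, span: float = 0.75,
                    degree: int = 2) -> DecayCurve:
    """LOESS-style fit of r² on distance (deterministic given inputs).

    Pairs sharing a distance are aggregated to (mean r², multiplicity)
    first; this is exact for locally weighted least squares because the
    tricube weight depends only on the distance value.
    """
    grouped = pairs.groupby("dist_cM", sort=True)["r2"].agg(["mean", "count"])
    x = grouped.index.to_numpy(float)
    if x.size < degree + 2:
        raise ValueError("need at least degree + 2 distinct distances")
    return DecayCurve(x=x, y=grouped["mean"].to_numpy(float),
                      w=grouped["count"].to_numpy(float),
                      span=span, degree=degree)


def window_distance(curve: DecayCurve, threshold: float = R2_THRESHOLD,
                    n_grid: int = 512) -> float:
    """Smallest distance where the fitted curve crosses the threshold.

    Located by a sign change on a dense grid followed by bisection; raises
    :class:`NoWindowError` when the curve stays on one side of the
    threshold over the whole observed range.
    """
    from scipy.optimize import brentq

    grid = np.linspace(curve.dmin, curve.dmax, n_grid)
    vals = np.array([_loess_fit_at(v, curve.x, curve.y, curve.w,
                                   curve.span, curve.degree) for v in grid])
    f = vals - threshold
    if f[0] <= 0:  # already below the threshold at the closest distance
        raise NoWindowError("decay curve starts below the critical r2 level")
    sign_change = np.flatnonzero((f[:-1] > 0) & (f[1:] <= 0))
    if sign_change.size == 0:
        raise NoWindowError("decay curve never crosses the critical r2 level")
    k = sign_change[0]
    return float(brentq(lambda v: curve(v) - threshold, grid[k], grid[k + 1],
                        xtol=1e-6))


# ---------------------------------------------------------------------------
# marker/QTL association map

@dataclass(frozen=True)
class AssociationMap:
    """Partition of markers into QTL-associated and non-associated."""

    window_cM: float
    associated: np.ndarray          # bool per marker, genome order
    windows: tuple                  # per target QTL: array of marker indices
    target_qtls: np.ndarray         # QTL indices (genome order among QTLs)

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def nonassociated_markers(self) -> np.ndarray:
        return np.flatnonzero(~self.associated)


def qtl_marker_association(gmap: GenomeMap, window_cM: float,
                           targets: np.ndarray | None = None) -> AssociationMap:
    """Flag markers lying within ``window_cM`` of a target QTL.

    ``targets`` are QTL indices (genome order); default is all QTLs.  A
    marker is associated iff it sits on the same chromosome within the
    window of at least one target; one window (possibly empty) is recorded
    per target QTL.
    """
    if window_cM <= 0:
        raise ValueError("window distance must be positive")
    targets = np.arange(gmap.n_qtls) if targets is None \
        else np.asarray(targets, int)
    if targets.size == 0:
        raise ValueError("empty target QTL set")
    m_chrom, m_pos = gmap.marker_chrom, gmap.marker_pos
    q_chrom, q_pos = gmap.qtl_chrom, gmap.qtl_pos
    associated = np.zeros(gmap.n_markers, dtype=bool)
    windows = []
    for t in targets:
        hit = (m_chrom == q_chrom[t]) & (np.abs(m_pos - q_pos[t]) <= window_cM)
        windows.append(np.flatnonzero(hit))
        associated |= hit
    return AssociationMap(window_cM=float(window_cM), associated=associated,
                          windows=tuple(windows), target_qtls=targets)
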