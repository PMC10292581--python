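"""PCA of standardized spectra, interannual trait correlations, quantile picks.

The nine standardized band proportions are commensurable, so the default PCA
is on the covariance matrix (no per-band rescaling).  The first component
typically captures the green-versus-red/brown leaf contrast; its sign is
pinned so that a positive score means redder leaves (positive 676-nm
loading), keeping plots and downstream QTL signs stable across platforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PCAResult",
    "run_pca",
    "annual_correlations",
    "correlate_traits",
    "quantile_representatives",
]


@dataclass
class PCAResult:
    loadings: np.ndarray                 # B×K, orthonormal columns
    scores: np.ndarray                   # N×K
    explained_variance_ratio: np.ndarray  # K, sums to 1
    mean: np.ndarray                     # B column means

    def reconstruct(self) -> np.ndarray:
        return self.scores @ self.loadings.T + self.mean


def run_pca(spectra: pd.DataFrame | np.ndarray, scale: bool = False,
            sign_band: int | str = 676) -> PCAResult:
    """Principal component analysis of spectra (rows = plants, cols = bands).

    Parameters
    ----------
    spectra
        N×B matrix; if a DataFrame, columns are band labels.
    scale
        False (default) → covariance PCA; True → correlation PCA.
    sign_band
        PC1's sign is fixed so this band's loading is positive; other
        components get their largest-magnitude loading positive.
    """
    if isinstance(spectra, pd.DataFrame):
        cols = [str(c) for c in spectra.columns]
        X = spectra.to_numpy(dtype=float)
    else:
        X = np.asarray(spectra, dtype=float)
        cols = [str(i) for i in range(X.shape[1])]
    n, b = X.shape
    if n < 3:
        raise ValueError("PCA needs at least 3 rows")
    mean = X.mean(axis=0)
    Xc = X - mean
    if np.allclose(Xc, 0):
        raise ValueError("constant matrix: no variance to decompose")
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n - 1, b)
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    loadings = Vt.T
    scores = U * S
    var = S**2
    evr = var / var.sum()

    # deterministic sign convention
    sign_col = str(sign_band)
    j676 = cols.index(sign_col) if sign_col in cols else None
    for comp in range(k):
        if comp == 0 and j676 is not None and loadings[j676, 0] != 0:
            s = np.sign(loadings[j676, 0])
        else:
            s = np.sign(loadings[np.argmax(np.abs(loadings[:, comp])), comp]) or 1.0
        loadings[:, comp] *= s
        scores[:, comp] *= s
    return PCAResult(loadings=loadings, scores=scores,
                     explained_variance_ratio=evr, mean=mean)


def correlate_traits(x: np.ndarray, y: np.ndarray,
                     method: str = "pearson") -> tuple[float, float, float]:
    """Correlation between two trait vectors: returns (R, R², p).

    Pearson by default (two-sided t-test p-value); Spearman available.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(r) ** 2, float(p)


def annual_correlations(table_y1: pd.DataFrame, table_y2: pd.DataFrame,
                        method: str = "pearson") -> pd.DataFrame:
    """All-pairs trait correlations between two measurement dates.

    Rows are plants (index = plant id), columns traits.  Plants are matched
    by id (inner join); every (trait in year 1) × (trait in year 2) pair gets
    a correlation.  The matched-trait diagonal is each trait's interannual
    repeatability.  Zero-variance traits give NaN with a warning.
    """
    shared = table_y1.index.intersection(table_y2.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared plants")
    a = table_y1.loc[shared]
    b = table_y2.loc[shared]
    out = pd.DataFrame(index=a.columns, columns=b.columns, dtype=float)
    for t1 in a.columns:
        x = a[t1].to_numpy(dtype=float)
        for t2 in b.columns:
            y = b[t2].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                warnings.warn(f"zero-variance trait in pair ({t1}, {t2})",
                              RuntimeWarning)
                out.loc[t1, t2] = np.nan
                continue
            out.loc[t1, t2] = correlate_traits(x, y, method=method)[0]
    return out


def quantile_representatives(values: pd.Series,
                             q: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0),
                             ) -> dict[float, str]:
    """For each quantile level, the plant whose value is nearest the empirical
    quantile (ties broken toward the lower plant id — deterministic).

    Used to pick visually representative individuals across a trait's range.
    """
    if len(values) == 0:
        raise ValueError("empty input")
    if len(values) < 5:
        raise ValueError("need at least 5 plants for quartile representatives")
    v = values.to_numpy(dtype=float)
    ids = values.index.to_numpy()
    order = np.lexsort((ids, ))  # stable by id for ties below
    out: dict[float, str] = {}
    for level in q:
        target = np.quantile(v, level)  # type-7 linear interpolation
        dist = np.abs(v - target)
        best = np.min(dist)
        cand = sorted(ids[dist == best])
        out[level] = cand[0]
    return out
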