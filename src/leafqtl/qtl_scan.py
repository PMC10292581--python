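"""Haley–Knott interval mapping on a pseudo-testcross, with CIM and
permutation thresholds.

A testcross progeny has two genotype classes at any locus (A/H), so the
model is a two-state Markov chain along each linkage group.  Conditional
genotype probabilities are computed on a pseudomarker grid (2 cM steps,
marker positions included) from the nearest observed flanking markers,
assuming error-free genotyping; the phenotype is then regressed on P(H) at
each grid point (Haley–Knott), giving

    LOD = (n/2) · log10(RSS0 / RSS1)

where RSS0 omits the genotype regressor.  Composite interval mapping (CIM)
adds forward-selected marker cofactors, dropping any cofactor within a
window of the scanned position on the same group.  Genome-wide significance
is by permutation of the phenotype over individuals, with cofactors
re-selected in every permutation (a valid null), and empirical type-7
quantile thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .band_io import MarkerGenotypes
from .linkage_map import GeneticMap, distance_to_rf, estimate_rf

__all__ = [
    "GroupProbabilities",
    "GenotypeProbabilities",
    "ScanResult",
    "PermutationThresholds",
    "genotype_probabilities",
    "hk_scan",
    "cim_scan",
    "permutation_thresholds",
    "significant_qtls",
    "classify_by_qtl_markers",
    "compare_groups_anova",
]


@dataclass
class GroupProbabilities:
    group_id: str
    positions_cM: np.ndarray      # grid incl. marker positions
    prob_h: np.ndarray            # N × n_positions, P(state 1)
    marker_names: list[str]
    marker_positions: np.ndarray
    marker_coded: np.ndarray      # N × M phase-aligned {0,1,nan}


@dataclass
class GenotypeProbabilities:
    individuals: list[str]
    groups: dict[str, GroupProbabilities]
    step_cM: float
    map_function: str

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)


@dataclass
class ScanResult:
    trait: str
    table: pd.DataFrame           # columns: group, position_cM, lod
    cofactors: list[str] = field(default_factory=list)
    threshold_5: float | None = None
    threshold_10: float | None = None

    @property
    def max_lod(self) -> float:
        return float(self.table["lod"].max()) if len(self.table) else 0.0


@dataclass
class PermutationThresholds:
    n_permutations: int
    null_max_lods: np.ndarray
    threshold_5: float
    threshold_10: float
    seed: int
    alphas: tuple[float, ...] = (0.05, 0.10)

    def __post_init__(self) -> None:
        if self.threshold_10 > self.threshold_5:
            raise ValueError("10% threshold cannot exceed 5% threshold")


def _code(col: np.ndarray) -> np.ndarray:
    return np.where(col == "H", 1.0, np.where(col == "A", 0.0, np.nan))


def genotype_probabilities(genetic_map: GeneticMap, g: MarkerGenotypes,
                           step_cM: float = 2.0) -> GenotypeProbabilities:
    """Conditional P(genotype) on a cM grid along every linkage group.

    With zero genotyping error the chain is Markov, so the probability at a
    grid point depends only on the nearest observed flanking markers of each
    individual.  Marker codings are phase-aligned along the group (repulsion
    pairs flipped) so one consistent binary state runs the chromosome; at a
    non-flipped fully observed marker the mass sits on the observed class.

    Individuals untyped on an entire group get a flat 0.5 (with a warning).
    """
    individuals = list(g.f1_genotypes.index.astype(str))
    n = len(individuals)
    out: dict[str, GroupProbabilities] = {}
    mfun = genetic_map.map_function

    for gi, lg in enumerate(genetic_map.groups, start=1):
        gid = f"{gi}.{lg.parent_of_origin}"
        mpos = np.asarray(lg.positions_cM, dtype=float)
        coded = np.column_stack([_code(g.f1_genotypes[m].to_numpy())
                                 for m in lg.markers])

        # phase-align along the map order: flip columns in repulsion with
        # their predecessor so the chain state is consistent
        flip = np.zeros(len(lg.markers), dtype=bool)
        for j in range(1, len(lg.markers)):
            _, _, phase = estimate_rf(
                g.f1_genotypes[lg.markers[j - 1]].to_numpy(),
                g.f1_genotypes[lg.markers[j]].to_numpy(), min_informative=1)
            flip[j] = flip[j - 1] ^ (phase == "repulsion")
        for j in np.nonzero(flip)[0]:
            coded[:, j] = 1.0 - coded[:, j]

        grid = np.unique(np.concatenate([
            np.arange(0.0, mpos[-1] + 1e-9, step_cM), mpos]))
        probs = np.full((n, len(grid)), 0.5)

        for i in range(n):
            obs_idx = np.nonzero(~np.isnan(coded[i]))[0]
            if obs_idx.size == 0:
                warnings.warn(
                    f"individual {individuals[i]} untyped on group {gid}; "
                    "flat 0.5 used", RuntimeWarning)
                continue
            opos = mpos[obs_idx]
            oval = coded[i, obs_idx]
            left = np.searchsorted(opos, grid, side="right") - 1
            right = np.searchsorted(opos, grid, side="left")
            for k, t in enumerate(grid):
                li, ri = left[k], right[k]
                has_l = li >= 0
                has_r = ri < opos.size
                if has_l and opos[li] == t:
                    probs[i, k] = oval[li]
                    continue
                if has_l and has_r:
                    rl = distance_to_rf(t - opos[li], mfun)
                    rr = distance_to_rf(opos[ri] - t, mfun)
                    gl, gr = oval[li], oval[ri]
                    # P(state=1 | flanks) over the two-interval classes
                    p1 = (rl if gl == 0 else 1 - rl) * (rr if gr == 0 else 1 - rr)
                    p0 = ((1 - rl) if gl == 0 else rl) * ((1 - rr) if gr == 0 else rr)
                    probs[i, k] = p1 / (p1 + p0)
                elif has_l:
                    rl = distance_to_rf(t - opos[li], mfun)
                    probs[i, k] = (1 - rl) if oval[li] == 1 else rl
                elif has_r:
                    rr = distance_to_rf(opos[ri] - t, mfun)
                    probs[i, k] = (1 - rr) if oval[ri] == 1 else rr
        out[gid] = GroupProbabilities(
            group_id=gid, positions_cM=grid, prob_h=probs,
            marker_names=list(lg.markers), marker_positions=mpos,
            marker_coded=coded)
    return GenotypeProbabilities(individuals=individuals, groups=out,
                                 step_cM=step_cM, map_function=mfun)


def _residualize(y: np.ndarray, Z: np.ndarray | None) -> np.ndarray:
    """Residuals of y on [1, Z] (Z may be None → just centering)."""
    if Z is None or Z.size == 0:
        return y - y.mean()
    X = np.column_stack([np.ones(len(y)), Z])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _lod_columns(P: np.ndarray, y_res: np.ndarray, n: int) -> np.ndarray:
    """LOD at each column of P after both sides are residualised on the same
    covariates: LOD = −(n/2)·log10(1 − r²) with r the partial correlation."""
    Pc = P - P.mean(axis=0)
    denom_p = np.einsum("ij,ij->j", Pc, Pc)
    denom_y = float(y_res @ y_res)
    num = Pc.T @ y_res
    if np.any(denom_p <= 1e-24):
        warnings.warn("constant genotype probability column: LOD set to 0",
                      RuntimeWarning)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = num**2 / (denom_p * denom_y)
    r2 = np.where((denom_p <= 1e-24) | (denom_y <= 0), 0.0, r2)
    r2 = np.clip(r2, 0.0, 1.0 - 1e-15)
    return -(n / 2.0) * np.log10(1.0 - r2)


def _complete_case(probs: GenotypeProbabilities, y: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    if len(y) != probs.n_individuals:
        raise ValueError("phenotype not aligned to individuals")
    keep = np.isfinite(y)
    return keep, y[keep]


def hk_scan(probs: GenotypeProbabilities, y: np.ndarray,
            covariates: np.ndarray | None = None, trait: str = "trait",
            ) -> ScanResult:
    """Haley–Knott regression scan of one trait over the pseudomarker grid.

    At each grid point the trait is regressed on [1, covariates, P(H)];
    LOD compares against the same model without P(H).  Complete-case on the
    trait; a constant P(H) column gives LOD 0.
    """
    keep, yk = _complete_case(probs, y)
    n = int(keep.sum())
    if n < 20:
        raise ValueError("need at least 20 phenotyped individuals")
    Z = covariates[keep] if covariates is not None else None
    y_res = _residualize(yk, Z)
    rows = []
    for gid, gp in probs.groups.items():
        P = gp.prob_h[keep]
        if Z is not None:
            X = np.column_stack([np.ones(n), Z])
            beta, *_ = np.linalg.lstsq(X, P, rcond=None)
            P = P - X @ beta
        lods = _lod_columns(P, y_res, n)
        for pos, lod in zip(gp.positions_cM, lods):
            rows.append((gid, float(pos), float(lod)))
    table = pd.DataFrame(rows, columns=["group", "position_cM", "lod"])
    return ScanResult(trait=trait, table=table)


def _marker_matrix(probs: GenotypeProbabilities
                   ) -> tuple[np.ndarray, list[tuple[str, str, float]]]:
    """All mapped markers as one N×M coded matrix (missing → column mean),
    with (marker, group, position) metadata."""
    cols, meta = [], []
    for gid, gp in probs.groups.items():
        for j, m in enumerate(gp.marker_names):
            c = gp.marker_coded[:, j].copy()
            mu = np.nanmean(c) if np.isfinite(c).any() else 0.5
            c[np.isnan(c)] = mu
            cols.append(c)
            meta.append((m, gid, float(gp.marker_positions[j])))
    return np.column_stack(cols), meta


def _forward_select(M: np.ndarray, y: np.ndarray, k: int) -> list[int]:
    """Forward selection of up to k columns of M by largest incremental R²."""
    chosen: list[int] = []
    y_res = y - y.mean()
    for _ in range(k):
        best, best_r2 = None, 1e-9
        Mc = M - M.mean(axis=0)
        if chosen:
            Z = M[:, chosen]
            X = np.column_stack([np.ones(len(y)), Z])
            beta, *_ = np.linalg.lstsq(X, M, rcond=None)
            Mc = M - X @ beta
        denom_y = float(y_res @ y_res)
        if denom_y <= 0:
            break
        d = np.einsum("ij,ij->j", Mc, Mc)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = (Mc.T @ y_res) ** 2 / (d * denom_y)
        r2[~np.isfinite(r2)] = 0.0
        r2[chosen] = 0.0
        j = int(np.argmax(r2))
        if r2[j] <= best_r2:
            break
        chosen.append(j)
        yb, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(len(y)), M[:, chosen]]), y, rcond=None)
        y_res = y - np.column_stack([np.ones(len(y)), M[:, chosen]]) @ yb
    return chosen


def cim_scan(probs: GenotypeProbabilities, y: np.ndarray,
             window_cM: float = 30.0, n_cofactors: int = 3,
             trait: str = "trait") -> ScanResult:
    """Composite interval mapping: HK scan with marker cofactors.

    Up to ``n_cofactors`` cofactors are picked by forward regression of the
    trait on the mapped markers.  At each scanned position, cofactors lying
    within ``window_cM`` of it on the same group are dropped (a cofactor is
    always dropped at its own location).  With ``n_cofactors=0`` this reduces
    exactly to :func:`hk_scan`.
    """
    if n_cofactors == 0:
        return hk_scan(probs, y, trait=trait)
    keep, yk = _complete_case(probs, y)
    n = int(keep.sum())
    if n < 20:
        raise ValueError("need at least 20 phenotyped individuals")
    M, meta = _marker_matrix(probs)
    M = M[keep]
    chosen = _forward_select(M, yk, n_cofactors)
    cof_meta = [meta[j] for j in chosen]
    cof_cols = M[:, chosen]

    rows = []
    cache: dict[frozenset, tuple[np.ndarray, np.ndarray | None]] = {}
    for gid, gp in probs.groups.items():
        P_all = gp.prob_h[keep]
        # surviving-cofactor subset per position
        for k_pos, pos in enumerate(gp.positions_cM):
            surv = frozenset(
                j for j, (_, cg, cp) in enumerate(cof_meta)
                if not (cg == gid and abs(cp - pos) < window_cM))
            if surv not in cache:
                Z = cof_cols[:, sorted(surv)] if surv else None
                cache[surv] = (_residualize(yk, Z), Z)
            y_res, Z = cache[surv]
            P = P_all[:, [k_pos]]
            if Z is not None:
                X = np.column_stack([np.ones(n), Z])
                beta, *_ = np.linalg.lstsq(X, P, rcond=None)
                P = P - X @ beta
            lod = float(_lod_columns(P, y_res, n)[0])
            rows.append((gid, float(pos), lod))
    table = pd.DataFrame(rows, columns=["group", "position_cM", "lod"])
    return ScanResult(trait=trait, table=table,
                      cofactors=[m for m, _, _ in cof_meta])


def permutation_thresholds(probs: GenotypeProbabilities, y: np.ndarray,
                           n: int = 1000, alphas: tuple[float, float] = (0.05, 0.10),
                           seed: int = 0, method: str = "hk",
                           **scan_kwargs) -> PermutationThresholds:
    """Genome-wide significance thresholds by phenotype permutation.

    The trait is shuffled over individuals (genotypes fixed), the full scan
    re-run — including cofactor re-selection for CIM — and the genome-wide
    maximum LOD recorded; thresholds are empirical (1−α) quantiles
    (type-7 linear interpolation).  Reproducible for a given seed.
    """
    if n < 100:
        warnings.warn("fewer than 100 permutations: unstable threshold tail",
                      RuntimeWarning)
    scan = {"hk": hk_scan, "cim": cim_scan}[method]
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    if method == "hk" and not scan_kwargs and np.isfinite(y).all():
        # plain HK with complete data: all permutation scans reduce to one
        # correlation matrix product (identical values to the scan loop)
        P = np.hstack([gp.prob_h for gp in probs.groups.values()])
        Pc = P - P.mean(axis=0)
        dp = np.einsum("ij,ij->j", Pc, Pc)
        Y = np.column_stack([rng.permutation(y) for _ in range(n)])
        Yc = Y - y.mean()
        dy = float((y - y.mean()) @ (y - y.mean()))
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = (Pc.T @ Yc) ** 2 / (dp[:, None] * dy)
        r2[dp <= 1e-24, :] = 0.0
        r2 = np.clip(r2, 0.0, 1.0 - 1e-15)
        lods = -(len(y) / 2.0) * np.log10(1.0 - r2)
        max_lods = lods.max(axis=0)
        t5, t10 = (float(np.quantile(max_lods, 1 - a)) for a in alphas)
        return PermutationThresholds(n_permutations=n, null_max_lods=max_lods,
                                     threshold_5=t5, threshold_10=t10,
                                     seed=seed, alphas=tuple(alphas))
    max_lods = np.empty(n)
    for b in range(n):
        yp = rng.permutation(y)
        max_lods[b] = scan(probs, yp, **scan_kwargs).max_lod
    t5, t10 = (float(np.quantile(max_lods, 1 - a)) for a in alphas)
    return PermutationThresholds(n_permutations=n, null_max_lods=max_lods,
                                 threshold_5=t5, threshold_10=t10, seed=seed,
                                 alphas=tuple(alphas))


def significant_qtls(scan: ScanResult, thr: PermutationThresholds,
                     ) -> pd.DataFrame:
    """Collapse supra-threshold runs of the LOD curve into QTL peaks.

    Each contiguous run above the 10% threshold within a group yields one
    record at its LOD argmax; peaks that also clear the 5% threshold are
    labelled "5%", the rest "10%" (marginal).
    """
    rows = []
    for gid, sub in scan.table.groupby("group", sort=False):
        sub = sub.sort_values("position_cM")
        above = (sub["lod"] >= thr.threshold_10).to_numpy()
        lod = sub["lod"].to_numpy()
        pos = sub["position_cM"].to_numpy()
        start = None
        for i in range(len(above) + 1):
            if i < len(above) and above[i]:
                if start is None:
                    start = i
            elif start is not None:
                seg = slice(start, i)
                j = start + int(np.argmax(lod[seg]))
                level = "5%" if lod[j] >= thr.threshold_5 else "10%"
                rows.append({"trait": scan.trait, "group": gid,
                             "position_cM": float(pos[j]),
                             "lod": float(lod[j]), "level": level})
                start = None
    return pd.DataFrame(rows, columns=["trait", "group", "position_cM",
                                       "lod", "level"])


def classify_by_qtl_markers(g: MarkerGenotypes, marker_q1: str,
                            marker_q2: str) -> pd.Series:
    """Two-letter genotype class per F1 from the markers nearest two QTLs.

    The first letter is the genotype at ``marker_q1``, the second at
    ``marker_q2`` — giving the four classes AH, AA, HH, HA.  Individuals
    missing either genotype are omitted (logged via warning).
    """
    for m in (marker_q1, marker_q2):
        if m not in g.marker_names:
            raise KeyError(f"unknown marker {m!r}")
    g1 = g.f1_genotypes[marker_q1]
    g2 = g.f1_genotypes[marker_q2]
    ok = (g1 != "-") & (g2 != "-")
    n_drop = int((~ok).sum())
    if n_drop:
        warnings.warn(f"{n_drop} individuals missing a QTL-marker genotype, "
                      "omitted from classes", RuntimeWarning)
    return (g1[ok] + g2[ok]).rename("qtl_class")


def _compact_letters(groups: list[str], means: dict[str, float],
                     sig_pairs: set[tuple[str, str]]) -> dict[str, str]:
    """Insert-and-absorb compact letter display; the group with the highest
    mean gets 'a'.  Deterministic for fixed inputs."""
    order = sorted(groups, key=lambda k: (-means[k], k))
    letters: list[set[str]] = [set(order)]
    for a, b in sorted(sig_pairs):
        new = []
        for s in letters:
            if a in s and b in s:
                new.extend([s - {a}, s - {b}])
            else:
                new.append(s)
        # absorb subsets
        letters = []
        for s in sorted(new, key=len, reverse=True):
            if s and not any(s <= t for t in letters):
                letters.append(s)
    # order letter sets by their best (highest-mean) member
    letters.sort(key=lambda s: min(order.index(m) for m in s))
    out: dict[str, str] = {}
    for li, s in enumerate(letters):
        ch = chr(ord("a") + li)
        for m in s:
            out[m] = out.get(m, "") + ch
    return {m: "".join(sorted(v)) for m, v in out.items()}


def compare_groups_anova(classes: pd.Series, y: pd.Series,
                         alpha: float = 0.01) -> dict:
    """One-way ANOVA of a trait across QTL genotype classes, with Tukey HSD
    post-hoc letters.

    Classes with fewer than 2 members are dropped (warning).  Returns the
    omnibus F and p, per-class means/counts, and a compact letter display
    (highest mean = 'a'); classes sharing no letter differ at ``alpha``.
    """
    df = pd.DataFrame({"cls": classes, "y": y.loc[classes.index]}).dropna()
    counts = df["cls"].value_counts()
    small = counts[counts < 2].index.tolist()
    if small:
        warnings.warn(f"classes {small} have <2 members, dropped", RuntimeWarning)
        df = df[~df["cls"].isin(small)]
    kept = sorted(df["cls"].unique())
    if len(kept) < 2:
        raise ValueError("need at least 2 classes with at least 2 members")
    samples = [df.loc[df["cls"] == c, "y"].to_numpy() for c in kept]
    if np.allclose(np.concatenate(samples), np.concatenate(samples)[0]):
        F, p = 0.0, 1.0
        letters = {c: "a" for c in kept}
    else:
        F, p = stats.f_oneway(*samples)
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        tk = pairwise_tukeyhsd(df["y"].to_numpy(), df["cls"].to_numpy(),
                               alpha=alpha)
        sig = set()
        res = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
        for _, row in res.iterrows():
            if bool(row["reject"]):
                sig.add((str(row["group1"]), str(row["group2"])))
        means = {c: float(np.mean(s)) for c, s in zip(kept, samples)}
        letters = _compact_letters(kept, means, sig)
    return {
        "F": float(F),
        "p": float(p),
        "classes": kept,
        "n": {c: int(len(s)) for c, s in zip(kept, samples)},
        "means": {c: float(np.mean(s)) for c, s in zip(kept, samples)},
        "letters": letters,
        "alpha": alpha,
    }
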