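"""Morphological divergence: character tests, Ward clustering, and the
morphology-vs-genetics regression.

Individuals are scored on nine binary characters (a–i; 0 absent, 1 present,
0.5 uncertain).  Sexes are analysed strictly separately throughout, because
several characters are sexually dimorphic.  Species comparisons use
Mann–Whitney U tests per character per sex (18 tests, Bonferroni threshold
0.05/18), similarity structure is summarised by Ward clustering on Euclidean
distances over the nine scores, and each landlocked population's mean
Euclidean distance from the source species is regressed on its genetic
distance (two regressions, Bonferroni threshold 0.05/2).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import f as f_dist
from scipy.stats import mannwhitneyu, rankdata, ttest_ind_from_stats

CHARACTERS = tuple("abcdefghi")
VALID_SCORES = (0.0, 0.5, 1.0)
BONFERRONI_U = 0.05 / 18
BONFERRONI_REGRESSION = 0.05 / 2


def validate_scores(records: pd.DataFrame) -> pd.DataFrame:
    """Check a morphology table: 9 characters in {0, 0.5, 1}, sex present."""
    missing = [c for c in CHARACTERS if c not in records.columns]
    if missing:
        raise ValueError(f"missing character columns: {missing}")
    if "sex" not in records.columns or records["sex"].isna().any():
        raise ValueError("sex must be recorded for every individual")
    scores = records.loc[:, list(CHARACTERS)].to_numpy(dtype=float)
    if not np.isin(scores, VALID_SCORES).all():
        raise ValueError("scores must be 0, 0.5 or 1")
    return records


def mannwhitney_exact(x, y) -> tuple[float, float]:
    """Exact two-sided Mann–Whitney U by enumeration (handles ties).

    Enumerates all C(n1+n2, n1) assignments of the pooled (mid-ranked) values
    to the first group; the two-sided p is the probability of a U at least as
    far from its null mean as observed.  Intended for small groups (the 0.5
    scores create ties that break the classical exact distribution).
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = ranks[:n1].sum()
    u_obs = r1 - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    dev = abs(u_obs - mu)
    total = comb(n1 + n2, n1)
    hits = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
        if abs(u - mu) >= dev - 1e-9:
            hits += 1
    return float(u_obs), hits / total


def character_u_tests(records: pd.DataFrame, species_a: str, species_b: str,
                      exact_max_n: int = 10) -> pd.DataFrame:
    """Mann–Whitney U per character per sex, Bonferroni-flagged.

    Exact enumeration is used when both groups have at most ``exact_max_n``
    individuals, otherwise the normal approximation with tie correction.
    A character constant across both groups is untestable (p = 1, flagged).

    Returns a DataFrame with one row per (sex, character).
    """
    validate_scores(records)
    rows = []
    for sex in sorted(records["sex"].unique()):
        sub = records[records["sex"] == sex]
        ga = sub[sub["species"] == species_a]
        gb = sub[sub["species"] == species_b]
        if ga.empty or gb.empty:
            raise ValueError(f"both species required for sex {sex!r}")
        for ch in CHARACTERS:
            x = ga[ch].to_numpy(dtype=float)
            y = gb[ch].to_numpy(dtype=float)
            if np.unique(np.concatenate([x, y])).size == 1:
                rows.append({"sex": sex, "character": ch, "U": np.nan,
                             "p": 1.0, "significant": False, "untestable": True})
                continue
            if x.size <= exact_max_n and y.size <= exact_max_n:
                u, p = mannwhitney_exact(x, y)
            else:
                u, p = mannwhitneyu(x, y, alternative="two-sided",
                                    method="asymptotic")
            rows.append({"sex": sex, "character": ch, "U": float(u),
                         "p": float(p), "significant": bool(p < BONFERRONI_U),
                         "untestable": False})
    return pd.DataFrame(rows)


@dataclass
class WardClustering:
    linkage_matrix: np.ndarray
    labels: list[str]
    two_cluster: np.ndarray  # cluster index (1/2) per individual
    purity: float  # best label-matching of the 2-cut vs species


def _ward_d1_linkage(d: np.ndarray) -> np.ndarray:
    """Lance–Williams Ward agglomeration applied to unsquared distances.

    The conventional Ward criterion squares dissimilarities inside the update
    (Ward.D2, what :func:`scipy.cluster.hierarchy.linkage` does); this variant
    feeds the raw distances through the same recurrence, the behaviour of the
    historical clustering routines that did not square their input.
    """
    d = d.astype(float).copy()
    n = d.shape[0]
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    next_id = n
    out = []
    while len(active) > 1:
        best = None
        for ii, i in enumerate(active):
            for j in active[ii + 1:]:
                if best is None or d[i, j] < best[0] - 1e-15:
                    best = (d[i, j], i, j)
        h, i, j = best
        ni, nj = sizes[i], sizes[j]
        out.append([i, j, h, ni + nj])
        new = {}
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            new[k] = ((ni + nk) * d[i, k] + (nj + nk) * d[j, k] - nk * h) / (ni + nj + nk)
        d = np.pad(d, ((0, 1), (0, 1)))
        for k, v in new.items():
            d[next_id, k] = d[k, next_id] = v
        sizes[next_id] = ni + nj
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1
    return np.asarray(out, dtype=float)


def ward_cluster(records: pd.DataFrame, sex: str, variant: str = "D2") -> WardClustering:
    """Ward clustering of one sex's score vectors, with the 2-cluster cut.

    ``variant="D2"`` (default) is the usual Ward-on-squared-Euclidean
    criterion; ``variant="D"`` runs the same Lance–Williams recurrence on the
    raw distances.  Purity is the best achievable agreement between the
    2-cluster cut and the species labels.
    """
    validate_scores(records)
    sub = records[records["sex"] == sex].reset_index(drop=True)
    if len(sub) < 2:
        raise ValueError(f"need >= 2 individuals of sex {sex!r}")
    x = sub.loc[:, list(CHARACTERS)].to_numpy(dtype=float)
    if variant == "D2":
        lk = linkage(x, method="ward")
    elif variant == "D":
        lk = _ward_d1_linkage(squareform(pdist(x)))
    else:
        raise ValueError("variant must be 'D2' or 'D'")
    cut = fcluster(lk, t=2, criterion="maxclust")
    species = sub["species"].to_numpy()
    labs = pd.unique(species)
    purity = 0.0
    if labs.size == 2:
        match = ((cut == 1) == (species == labs[0])).mean()
        purity = float(max(match, 1 - match))
    return WardClustering(
        linkage_matrix=lk,
        labels=list(sub["individual_id"]),
        two_cluster=cut,
        purity=purity,
    )


def linkage_to_newick(lk: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}

    def node(i: int) -> str:
        if i < n:
            return labels[i]
        a, b, h, _ = lk[i - n]
        a, b = int(a), int(b)
        return (
            f"({node(a)}:{h - heights[a]:.6g},{node(b)}:{h - heights[b]:.6g})"
        )

    for k, (_, _, h, _) in enumerate(lk):
        heights[n + k] = h
    return node(n + len(lk) - 1) + ";"


def morph_distance_to_reference(
    records: pd.DataFrame, reference_species: str, sex: str
) -> pd.Series:
    """Per-site mean Euclidean morphological distance from the reference.

    For every focal (non-reference) individual of the given sex, the Euclidean
    distances to all same-sex reference individuals are averaged; those
    per-individual means are then averaged per population.
    """
    validate_scores(records)
    sub = records[records["sex"] == sex]
    ref = sub[sub["species"] == reference_species]
    foc = sub[sub["species"] != reference_species]
    if ref.empty:
        raise ValueError("reference group empty for this sex")
    ref_x = ref.loc[:, list(CHARACTERS)].to_numpy(dtype=float)
    foc_x = foc.loc[:, list(CHARACTERS)].to_numpy(dtype=float)
    diff = foc_x[:, None, :] - ref_x[None, :, :]
    per_ind = np.sqrt((diff**2).sum(axis=2)).mean(axis=1)
    return (
        pd.Series(per_ind, index=foc["population"].to_numpy(), name="morph_distance")
        .groupby(level=0)
        .mean()
    )


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    F: float
    df: tuple[int, int]
    p: float
    significant: bool  # at the Bonferroni-adjusted regression threshold

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["df"] = list(self.df)
        return d


def simple_regression(x, y, alpha: float = BONFERRONI_REGRESSION) -> RegressionResult:
    """OLS of y on x with the slope F-test (used by both regressions and the clock)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("regression needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance")
    xc, yc = x - x.mean(), y - y.mean()
    slope = float((xc * yc).sum() / (xc**2).sum())
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    ss_res = float((resid**2).sum())
    ss_tot = float((yc**2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    df = (1, n - 2)
    if ss_res == 0.0:
        F, p = float("inf"), 0.0
    else:
        F = (ss_tot - ss_res) / (ss_res / df[1])
        p = float(f_dist.sf(F, *df))
    return RegressionResult(
        slope=slope, intercept=intercept, r_squared=r2, F=float(F),
        df=df, p=p, significant=bool(p < alpha),
    )


def regress_morph_on_genetic(
    site_morph: pd.Series, site_genetic: pd.Series
) -> RegressionResult:
    """Regress per-site morphological distance on genetic distance (one sex)."""
    joined = pd.concat([site_morph, site_genetic], axis=1, join="inner")
    return simple_regression(joined.iloc[:, 1], joined.iloc[:, 0])


@dataclass
class SizeSummary:
    """Summary of total length for one group and sex (mm)."""

    group: str
    sex: str
    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def size_t_test(a: SizeSummary, b: SizeSummary) -> tuple[float, int, float]:
    """Pooled-variance two-sample t from summary statistics: (t, df, p)."""
    res = ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=True
    )
    return float(res.statistic), a.n + b.n - 2, float(res.pvalue)
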