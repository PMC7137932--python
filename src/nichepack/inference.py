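"""Inferential readouts: Wilcoxon signed-rank tests of SES against zero,
type-II ANCOVA of metrics/SES on richness x ecoregion, and the
correlation analyses (SES vs richness per ecoregion; functional
centrality vs average abundance)."""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import ModelError
from .funcspace import TraitSpace, centroid_distances
from .io_model import CommunityData
from .nullmodels import NullModelResult

_EXACT_WILCOXON_MAX_N = 25
_EXACT_SPEARMAN_MAX_N = 10


@dataclass
class WilcoxonResult:
    n: int
    statistic: float  # W+ (sum of positive ranks)
    p_value: float
    direction: int  # sign of the median difference
    method: str  # {"exact", "approx", "degenerate"}
    group: str = ""
    label: str = ""


@dataclass
class AncovaTerm:
    ss: float
    df: int
    f: float
    p: float


@dataclass
class AncovaResult:
    terms: dict[str, AncovaTerm]  # keys: "S", "E", "S:E", "Residual"
    n: int


@dataclass
class CorrelationResult:
    kind: str  # {"pearson", "spearman"}
    coefficient: float
    p_value: float
    n: int
    group: str = ""
    defined: bool = True


def _signed_rank_exact_sf(ranks2: np.ndarray) -> np.ndarray:
    """Distribution of 2*W+ over all sign assignments (counts per value).

    ``ranks2`` are doubled midranks (integers). Returns an array c where
    c[w] = number of sign patterns with 2*W+ == w.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(
    values: Sequence[float],
    mu0: float = 0.0,
    group: str = "",
    label: str = "",
    method: str = "auto",
) -> WilcoxonResult:
    """Two-sided one-sample Wilcoxon signed-rank test against ``mu0``.

    Zero differences are dropped before ranking; ties get midranks. The
    null distribution is enumerated exactly for n <= 25 (dynamic
    programming over doubled ranks); larger samples use the normal
    approximation with tie and continuity corrections. ``method`` forces
    one branch ("exact"/"approx") regardless of n.
    """
    diffs = np.asarray(values, dtype=float) - mu0
    diffs = diffs[np.isfinite(diffs)]
    direction = int(np.sign(np.median(diffs))) if diffs.size else 0
    diffs = diffs[diffs != 0]
    n = diffs.size
    if n == 0:
        return WilcoxonResult(0, 0.0, 1.0, 0, "degenerate", group, label)
    ranks = stats.rankdata(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())
    use_exact = method == "exact" or (method == "auto" and n <= _EXACT_WILCOXON_MAX_N)
    if use_exact:
        ranks2 = np.round(2 * ranks).astype(int)
        counts = _signed_rank_exact_sf(ranks2)
        total = counts.sum()
        w2 = int(round(2 * w_plus))
        p_le = counts[: w2 + 1].sum() / total
        p_ge = counts[w2:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        tie_term = sum(
            (t**3 - t) for t in np.unique(ranks, return_counts=True)[1]
        )
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term / 48.0
        if var <= 0:
            return WilcoxonResult(n, w_plus, 1.0, direction, "degenerate", group, label)
        z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / math.sqrt(var)
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
        method = "approx"
    return WilcoxonResult(n, w_plus, float(p), direction, method, group, label)


def ancova_type2(
    response: Sequence[float],
    richness: Sequence[float],
    ecoregion: Sequence[str],
) -> AncovaResult:
    """Fully factorial ANCOVA (response ~ S * E) with type-II sums of squares.

    S is the richness covariate, E the categorical ecoregion factor. F and p
    for every term use the full-model residual mean square.
    """
    df = pd.DataFrame(
        {"y": np.asarray(response, float), "S": np.asarray(richness, float),
         "E": list(ecoregion)}
    ).dropna()
    n = len(df)
    levels = df["E"].nunique()
    if levels < 2:
        raise ModelError("need >= 2 ecoregion levels")
    if n <= 5:
        raise ModelError("need n > 5 observations")
    if (df.groupby("E")["S"].nunique() < 2).any():
        raise ModelError("need >= 2 distinct richness values per ecoregion level")
    model = smf.ols("y ~ S * C(E)", data=df).fit()
    if model.df_resid <= 0 or np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ModelError("rank-deficient design (collinear S and E terms)")
    table = sm.stats.anova_lm(model, typ=2)
    rename = {"S": "S", "C(E)": "E", "S:C(E)": "S:E", "Residual": "Residual"}
    terms: dict[str, AncovaTerm] = {}
    for raw, name in rename.items():
        row = table.loc[raw]
        terms[name] = AncovaTerm(
            ss=float(row["sum_sq"]),
            df=int(row["df"]),
            f=float(row["F"]) if np.isfinite(row["F"]) else math.nan,
            p=float(row["PR(>F)"]) if np.isfinite(row["PR(>F)"]) else math.nan,
        )
    return AncovaResult(terms=terms, n=n)


def ses_richness_correlation(
    results: Sequence[NullModelResult],
    community: CommunityData,
    metric: str = "MNND",
    pool: str | None = None,
    variant: str = "constrained",
) -> list[CorrelationResult]:
    """Pearson correlation of SES with site richness, within each ecoregion.

    ``pool=None`` selects the total pool. Groups with < 3 defined SES values
    or constant richness are flagged undefined.
    """
    pool_name = pool or "total"
    rows = [
        r for r in results
        if r.metric == metric and r.variant == variant and r.pool == pool_name
        and math.isfinite(r.ses)
    ]
    by_region: dict[str, list[NullModelResult]] = {}
    for r in rows:
        by_region.setdefault(community.ecoregion[r.site_id], []).append(r)
    out: list[CorrelationResult] = []
    for region in sorted(by_region):
        rs = by_region[region]
        ses_vals = np.array([r.ses for r in rs])
        rich = np.array([r.richness for r in rs], dtype=float)
        if len(rs) < 3 or np.unique(rich).size < 2:
            out.append(CorrelationResult("pearson", math.nan, math.nan, len(rs), region, False))
            continue
        res = stats.pearsonr(ses_vals, rich)
        out.append(CorrelationResult("pearson", float(res.statistic), float(res.pvalue), len(rs), region))
    return out


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt((rx**2).sum() * (ry**2).sum())
    return float((rx * ry).sum() / denom) if denom else math.nan


def spearman(x: Sequence[float], y: Sequence[float], group: str = "") -> CorrelationResult:
    """Spearman rank correlation with midranks for ties.

    p-value by exact permutation for n <= 10, t-approximation otherwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n < 3:
        return CorrelationResult("spearman", math.nan, math.nan, n, group, False)
    rho = _spearman_rho(x, y)
    if not math.isfinite(rho):
        return CorrelationResult("spearman", math.nan, math.nan, n, group, False)
    if n <= _EXACT_SPEARMAN_MAX_N:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        ry = ry - ry.mean()
        rxc = rx - rx.mean()
        denom = math.sqrt((rxc**2).sum() * (ry**2).sum())
        obs = abs((rxc * ry).sum())
        count = 0
        total = 0
        perms = np.array(list(itertools.permutations(rx)))
        sums = np.abs((perms - rx.mean()) @ ry)
        count = int((sums >= obs - 1e-12).sum())
        total = len(perms)
        p = count / total
    else:
        t = rho * math.sqrt((n - 2) / max(1e-300, 1 - rho**2))
        p = float(min(1.0, 2.0 * stats.t.sf(abs(t), df=n - 2)))
    return CorrelationResult("spearman", rho, float(p), n, group)


def average_abundance(
    community: CommunityData, within_ecoregion: bool = True, occupied_only: bool = False
) -> dict[str, float]:
    """Mean abundance per species, zeros included by default.

    With ``within_ecoregion`` the mean is taken over the sites of the
    ecoregion(s) where the species occurs; ``occupied_only`` restricts to
    occupied sites instead.
    """
    ab = community.abundance
    out: dict[str, float] = {}
    for j, sp in enumerate(community.species):
        col = ab[:, j]
        if occupied_only:
            mask = col > 0
        elif within_ecoregion:
            regions = {
                community.ecoregion[community.sites[i]] for i in np.nonzero(col > 0)[0]
            }
            mask = np.array(
                [community.ecoregion[s] in regions for s in community.sites]
            )
        else:
            mask = np.ones(len(community.sites), dtype=bool)
        out[sp] = float(col[mask].mean()) if mask.any() else math.nan
    return out


def centrality_abundance_correlation(
    space: TraitSpace,
    community: CommunityData,
    within_ecoregion: bool = True,
    occupied_only: bool = False,
) -> CorrelationResult:
    """Spearman correlation between distance-to-centroid and average abundance."""
    dists = centroid_distances(space)
    abund = average_abundance(community, within_ecoregion, occupied_only)
    species = [sp for sp in space.species if sp in abund and math.isfinite(abund[sp])]
    if len(species) < 3:
        return CorrelationResult("spearman", math.nan, math.nan, len(species), defined=False)
    return spearman([dists[sp] for sp in species], [abund[sp] for sp in species])


def occupancy(community: CommunityData, ecoregion: str | None = None) -> dict[str, float]:
    """Fraction of sites occupied per species, optionally within one ecoregion."""
    if ecoregion is None:
        mask = np.ones(len(community.sites), dtype=bool)
    else:
        mask = np.array([community.ecoregion[s] == ecoregion for s in community.sites])
    n_sites = int(mask.sum())
    if n_sites == 0:
        raise ModelError(f"no sites in ecoregion {ecoregion!r}")
    occ = (community.abundance[mask] > 0).sum(axis=0) / n_sites
    return dict(zip(community.species, occ.astype(float)))
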