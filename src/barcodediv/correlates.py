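"""Per-unit genetic diversity and trait/rate correlates.

Tajima's pairwise estimator of nucleotide diversity per unit, a PCA of
the ten niche-width variables, and regressions of tip-level speciation
rates (or diversity) against niche scores, latitude or spore size —
ordinary least squares, Brownian phylogenetic GLS, or a latitude-band
jackknife that rebalances occurrence records across 20-degree slices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.decomposition import PCA

from .alignment import SequenceAlignment, N_BASES
from .trees import TimeTree

__all__ = [
    "tajima_pi",
    "unit_diversity_table",
    "NichePCAResult",
    "niche_pca",
    "RegressionResult",
    "rate_correlation",
]


def tajima_pi(aln: SequenceAlignment) -> float:
    """Nucleotide diversity theta-pi per site for one unit's members.

    Mean over all unordered sequence pairs of the per-site p-distance,
    counted over columns where both symbols are unambiguous bases.
    Duplicate haplotypes are *not* collapsed: the estimator is defined on
    the sample, so abundant haplotypes weigh accordingly.
    """
    n = aln.n_sequences
    if n < 2:
        raise ValueError("theta-pi is undefined for fewer than 2 sequences")
    codes = aln.codes
    valid = codes < N_BASES
    total = 0.0
    for i in range(n - 1):
        both = valid[i] & valid[i + 1 :]
        mism = ((codes[i] != codes[i + 1 :]) & both).sum(axis=1)
        sites = both.sum(axis=1)
        with np.errstate(invalid="ignore"):
            pd_ij = np.where(sites > 0, mism / np.maximum(sites, 1), 0.0)
        total += float(pd_ij.sum())
    return total / (n * (n - 1) / 2.0)


def unit_diversity_table(
    aln: SequenceAlignment,
    unit_of: dict[str, str],
    min_n: int = 10,
) -> pd.DataFrame:
    """theta-pi per unit, restricted to units with >= ``min_n`` sequences.

    ``unit_of`` maps sequence name -> unit id.  Units below the size
    filter (or with a single sequence) are excluded with a warning.
    """
    groups: dict[str, list[str]] = {}
    for name in aln.names:
        unit = unit_of.get(name)
        if unit is not None:
            groups.setdefault(unit, []).append(name)
    rows, skipped = [], 0
    for unit, names in groups.items():
        if len(names) < max(min_n, 2):
            skipped += 1
            continue
        rows.append(
            {
                "unit": unit,
                "n_seq": len(names),
                "theta_pi": tajima_pi(aln.subset(names)),
            }
        )
    if skipped:
        warnings.warn(f"{skipped} unit(s) below the {min_n}-sequence filter excluded")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# niche-width PCA
# ---------------------------------------------------------------------


@dataclass
class NichePCAResult:
    loadings: pd.DataFrame  # variables x components
    scores: pd.DataFrame  # units x components
    explained_variance_ratio: np.ndarray
    dropped: list[str] = field(default_factory=list)


def niche_pca(
    meta: pd.DataFrame,
    variables: list[str] | None = None,
    min_n: int = 10,
    n_components: int = 2,
    anchor: str = "nb_continent",
) -> NichePCAResult:
    """PCA of standardized niche variables for well-sampled units.

    Rows with ``n_seq`` below ``min_n`` are filtered out; constant
    variables are dropped with a warning.  Axis signs are fixed
    deterministically: PC1 correlates positively with the anchor variable
    (number of continents); any other axis has its largest-magnitude
    loading positive.
    """
    from .synthdata import NICHE_VARIABLES

    if variables is None:
        variables = [v for v in NICHE_VARIABLES if v in meta.columns]
    tab = meta
    if "n_seq" in meta.columns and min_n > 1:
        tab = meta[meta["n_seq"] >= min_n]
    if len(tab) < 3:
        raise ValueError("need at least 3 units passing the size filter")
    X = tab[variables].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    dropped = [v for v, s in zip(variables, sd) if s == 0]
    if dropped:
        warnings.warn(f"constant variable(s) dropped: {dropped}")
        keep = [i for i, s in enumerate(sd) if s > 0]
        variables = [variables[i] for i in keep]
        X, sd = X[:, keep], sd[keep]
    Z = (X - X.mean(axis=0)) / sd
    ncomp = min(n_components, len(variables))
    pca = PCA(n_components=ncomp)
    scores = pca.fit_transform(Z)
    loadings = pca.components_.T  # variables x components
    for j in range(ncomp):
        if j == 0 and anchor in variables:
            flip = loadings[variables.index(anchor), 0] < 0
        else:
            flip = loadings[np.argmax(np.abs(loadings[:, j])), j] < 0
        if flip:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{j + 1}" for j in range(ncomp)]
    index = tab["unit"] if "unit" in tab.columns else tab.index
    return NichePCAResult(
        loadings=pd.DataFrame(loadings, index=variables, columns=comp_names),
        scores=pd.DataFrame(scores, index=index, columns=comp_names),
        explained_variance_ratio=pca.explained_variance_ratio_,
        dropped=dropped,
    )


# ---------------------------------------------------------------------
# regressions
# ---------------------------------------------------------------------


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    pvalue: float
    method: str
    n: int
    notes: str = ""
    jackknife_slopes: np.ndarray | None = field(repr=False, default=None)


_LAT_EDGES = np.arange(-90.0, 91.0, 20.0)  # [-90,-70), ..., [70,90]


def _ols(y: np.ndarray, x: np.ndarray):
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    slope, p = float(fit.params[1]), float(fit.pvalues[1])
    if np.isnan(p):  # zero residual variance: no evidence against flatness
        p = 1.0 if slope == 0 else 0.0
    return slope, float(fit.params[0]), p


def rate_correlation(
    response: pd.Series,
    predictor: pd.Series,
    mode: str = "ordinary",
    tree: TimeTree | None = None,
    occurrences: pd.DataFrame | None = None,
    log_response: bool = True,
    n_per_band: int = 1000,
    n_resamples: int = 100,
    seed: int | None = None,
) -> RegressionResult:
    """Regress a per-unit response on a predictor.

    Modes
    -----
    ``ordinary``
        least-squares slope with a two-sided t-test.
    ``pgls``
        phylogenetic GLS with Brownian covariance from ``tree`` (tip
        labels must match the unit index).  Replaces Bayesian phylogenetic
        mixed models; noted in ``notes``.
    ``latitude-jackknife``
        ``occurrences`` (columns ``unit``, ``latitude``) are resampled
        ``n_per_band`` times per 20-degree latitude band to balance the
        latitudinal gradient; the slope of response ~ latitude is refit on
        each of ``n_resamples`` balanced draws and the two-sided p-value
        is the empirical sign test of the slope distribution.

    Positive responses are log-transformed by default (speciation rates
    are right-skewed); disable with ``log_response=False``.
    """
    response = pd.Series(response).dropna()
    if log_response:
        if (response <= 0).any():
            raise ValueError("log transform requires a strictly positive response")
        response = np.log(response)

    if mode == "latitude-jackknife":
        if occurrences is None:
            raise ValueError("latitude-jackknife mode requires occurrences")
        rng = np.random.default_rng(seed)
        occ = occurrences.merge(
            response.rename("response"), left_on="unit", right_index=True
        ).dropna(subset=["latitude", "response"])
        band = np.digitize(occ["latitude"].to_numpy(), _LAT_EDGES[1:-1])
        groups = [np.flatnonzero(band == b) for b in range(len(_LAT_EDGES) - 1)]
        empty = sum(1 for g in groups if g.size == 0)
        if empty:
            warnings.warn(f"{empty} latitude band(s) without occurrences skipped")
        groups = [g for g in groups if g.size > 0]
        if not groups:
            raise ValueError("no occupied latitude band")
        y_all = occ["response"].to_numpy()
        x_all = occ["latitude"].to_numpy()
        slopes = np.empty(n_resamples)
        for r in range(n_resamples):
            take = np.concatenate(
                [rng.choice(g, size=n_per_band, replace=True) for g in groups]
            )
            slopes[r], _, _ = _ols(y_all[take], x_all[take])
        mean_slope = float(slopes.mean())
        p_lo = (np.sum(slopes <= 0) + 1) / (n_resamples + 1)
        p_hi = (np.sum(slopes >= 0) + 1) / (n_resamples + 1)
        return RegressionResult(
            slope=mean_slope,
            intercept=float("nan"),
            pvalue=float(min(1.0, 2 * min(p_lo, p_hi))),
            method=mode,
            n=len(occ),
            notes=f"{len(groups)} occupied 20-degree bands, "
            f"{n_per_band} draws each, {n_resamples} resamples",
            jackknife_slopes=slopes,
        )

    predictor = pd.Series(predictor)
    common = response.index.intersection(predictor.dropna().index)
    if len(common) < 4:
        raise ValueError("need at least 4 complete cases")
    y = response.loc[common].to_numpy(dtype=float)
    x = predictor.loc[common].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("singular design: constant predictor")

    if mode == "ordinary":
        slope, intercept, p = _ols(y, x)
        return RegressionResult(slope, intercept, p, mode, len(common))
    if mode == "pgls":
        if tree is None:
            raise ValueError("pgls mode requires a tree")
        missing = set(common) - set(tree.tip_labels)
        if missing:
            raise ValueError(f"units missing from tree: {sorted(missing)[:5]}")
        sub = tree.prune_to(list(common)) if set(tree.tip_labels) != set(common) else tree
        order = sub.tip_labels
        V = sub.brownian_vcv()
        y_o = response.loc[order].to_numpy(dtype=float)
        x_o = predictor.loc[order].to_numpy(dtype=float)
        X = sm.add_constant(x_o)
        fit = sm.GLS(y_o, X, sigma=V).fit()
        return RegressionResult(
            slope=float(fit.params[1]),
            intercept=float(fit.params[0]),
            pvalue=float(fit.pvalues[1]),
            method=mode,
            n=len(order),
            notes="Brownian GLS (substitute for Bayesian phylogenetic mixed models)",
        )
    raise ValueError(f"unknown mode {mode!r}")
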