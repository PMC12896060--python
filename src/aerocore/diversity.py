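"""Alpha/beta diversity and multivariate significance testing.

Alpha diversity is the Shannon index (natural log) with Tukey-HSD compact
letter display over groups; beta diversity is PCA and a seeded 2-D UMAP
embedding of the log-normalized table. The influence of study factors on
community structure is assessed with a forward-stepwise MANOVA on the top
principal-component scores, using Pillai's trace converted to an approximate
F statistic; continuous covariates are binarised (temperature at 25 °C,
relative humidity at 65%, travellers at 100) and interaction terms with CITY
are eligible once their components are in the model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .tables import NormalizedTable, TableError, TaxonCountTable

# binarisation thresholds for continuous covariates (strictly greater -> 1)
TEMPERATURE_SPLIT = 25.0  # °C
HUMIDITY_SPLIT = 65.0  # % RH
TRAVELLERS_SPLIT = 100  # persons

#: canonical term name -> (metadata column, kind)
TERM_REGISTRY: dict[str, tuple[str, str]] = {
    "CITY": ("city", "categorical"),
    "YEAR": ("year", "categorical"),
    "GROUNDLEVEL": ("ground_level", "categorical"),
    "TEMPERATURE": ("temperature", "binary_gt_25"),
    "HUMIDITY": ("humidity", "binary_gt_65"),
    "TRAVELLERS": ("travellers", "binary_gt_100"),
}

DEFAULT_TERMS = (
    "CITY",
    "YEAR",
    "GROUNDLEVEL",
    "TEMPERATURE",
    "HUMIDITY",
    "TRAVELLERS",
    "CITY:GROUNDLEVEL",
    "CITY:TEMPERATURE",
    "CITY:HUMIDITY",
    "CITY:TRAVELLERS",
)


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------


def shannon(counts_row: Sequence[float]) -> float:
    """Shannon diversity H = -sum p_i ln p_i of one sample's counts (nats)."""
    x = np.asarray(counts_row, dtype=float)
    if (x < 0).any():
        raise ValueError("negative counts")
    total = x.sum()
    if total <= 0:
        raise ValueError("sample has no reads")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def shannon_per_sample(table: TaxonCountTable | NormalizedTable) -> pd.Series:
    values = table.counts if isinstance(table, TaxonCountTable) else table.values
    return pd.Series(
        [shannon(row) for row in values.to_numpy()], index=values.index, name="shannon"
    )


def tukey_letters(
    values: Sequence[float], groups: Sequence[str], alpha: float = 0.05
) -> dict[str, str]:
    """Compact letter display for Tukey's HSD over group means.

    The pairwise test (Tukey–Kramer for unbalanced groups) is delegated to
    statsmodels; letters are assigned with the insert-and-absorb procedure,
    so two groups share a letter exactly when their difference is not
    significant at ``alpha``. Letters are ordered by descending group mean.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if counts.min() < 2:
        small = labels[counts < 2].tolist()
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    res = pairwise_tukeyhsd(values, groups, alpha=alpha)
    pairs = list(itertools.combinations(res.groupsunique, 2))
    significant = {
        frozenset(pair) for pair, reject in zip(pairs, res.reject) if bool(reject)
    }
    # insert-and-absorb over the non-significance relation
    columns: list[set[str]] = [set(labels)]
    for pair in significant:
        a, b = tuple(pair)
        new_columns: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_columns.append(col - {a})
                new_columns.append(col - {b})
            else:
                new_columns.append(col)
        # absorb: drop columns contained in another
        columns = [
            c
            for i, c in enumerate(new_columns)
            if not any(c < other or (c == other and i > j)
                       for j, other in enumerate(new_columns))
        ]
    labels = [str(lab) for lab in labels]
    groups = groups.astype(str)
    columns = [set(str(g) for g in col) for col in columns]
    means = {lab: values[groups == lab].mean() for lab in labels}
    columns.sort(key=lambda col: -max(means[g] for g in col))
    assignment: dict[str, str] = {lab: "" for lab in labels}
    for letter, col in zip(_letter_stream(), columns):
        for lab in sorted(col, key=lambda g: -means[g]):
            assignment[lab] += letter
    return {lab: "".join(sorted(assignment[lab])) for lab in labels}


def _letter_stream():
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for size in itertools.count(1):
        for combo in itertools.product(alphabet, repeat=size):
            yield "".join(combo)


@dataclass
class AlphaResult:
    """Per-sample Shannon diversity with Tukey letter display per group."""

    shannon: pd.Series
    group_means: pd.Series
    letters: dict[str, str]
    group_by: str
    alpha: float


def alpha_diversity(
    table: TaxonCountTable | NormalizedTable,
    metadata: pd.DataFrame,
    group_by: str = "city",
    alpha: float = 0.05,
) -> AlphaResult:
    h = shannon_per_sample(table)
    groups = metadata.loc[h.index, group_by].astype(str)
    return AlphaResult(
        shannon=h,
        group_means=h.groupby(groups).mean(),
        letters=tukey_letters(h.to_numpy(), groups.to_numpy(), alpha=alpha),
        group_by=group_by,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Ordination
# ---------------------------------------------------------------------------


def pca_scores(
    table: NormalizedTable | pd.DataFrame, k: int = 10
) -> tuple[pd.DataFrame, np.ndarray]:
    """Top-k principal-component scores of the (column-centered) table.

    Returns ``(scores, variance_explained)`` where scores is samples x k and
    ``variance_explained`` the per-component fraction of total variance.
    """
    from sklearn.decomposition import PCA

    values = table.values if isinstance(table, NormalizedTable) else table
    k_eff = min(k, values.shape[0] - 1, values.shape[1])
    if k_eff < 1:
        raise TableError("not enough samples/taxa for PCA")
    pca = PCA(n_components=k_eff, svd_solver="full")
    scores = pca.fit_transform(values.to_numpy(dtype=float))
    frame = pd.DataFrame(
        scores, index=values.index, columns=[f"PC{i + 1}" for i in range(k_eff)]
    )
    return frame, pca.explained_variance_ratio_


@dataclass
class EmbeddingResult:
    coordinates: pd.DataFrame  # samples x (x, y)
    method: str
    seed: int


def umap_embed(
    table: NormalizedTable | pd.DataFrame,
    seed: int = 42,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> EmbeddingResult:
    """Seeded 2-D UMAP embedding of the log-normalized table."""
    import umap

    values = table.values if isinstance(table, NormalizedTable) else table
    if values.shape[0] < 3:
        raise TableError("UMAP needs at least 3 samples")
    n_neighbors = min(n_neighbors, values.shape[0] - 1)
    reducer = umap.UMAP(
        n_components=2, n_neighbors=n_neighbors, min_dist=min_dist, random_state=seed
    )
    coords = reducer.fit_transform(values.to_numpy(dtype=float))
    frame = pd.DataFrame(coords, index=values.index, columns=["x", "y"])
    return EmbeddingResult(coordinates=frame, method="umap", seed=seed)


def knn_city_purity(
    coordinates: pd.DataFrame, cities: pd.Series, k: int = 15
) -> float:
    """Fraction of samples whose k nearest embedded neighbours share their city."""
    ids = list(coordinates.index)
    coords = coordinates.to_numpy(dtype=float)
    labels = cities.loc[ids].to_numpy()
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    k_eff = min(k, len(ids) - 1)
    hits = 0
    for i in range(len(ids)):
        nbr = np.argsort(d2[i])[:k_eff]
        majority = pd.Series(labels[nbr]).value_counts().idxmax()
        hits += majority == labels[i]
    return hits / len(ids)


# ---------------------------------------------------------------------------
# MANOVA with forward selection on Pillai's trace
# ---------------------------------------------------------------------------


@dataclass
class TermResult:
    name: str
    pillai: float
    f_value: float
    df1: int
    df2: float
    p_value: float


@dataclass
class ManovaModel:
    """Forward-selected MANOVA over PC scores.

    ``steps`` holds the term added at each step with its Pillai trace,
    approximate F and p-value at the moment of inclusion (added-term test
    against the candidate model's error matrix); ``included`` is the final
    term set in order of inclusion.
    """

    steps: list[TermResult]
    included: list[str]
    alpha_include: float
    n_rows: int
    n_dropped: int
    k: int
    variance_explained: float | None = None
    notes: list[str] = field(default_factory=list)


def binarise_covariates(metadata: pd.DataFrame) -> pd.DataFrame:
    """Apply the study binarisation to continuous covariates.

    Values strictly above the split map to ``above``; boundary values and
    everything below map to ``below_eq``. Missing stays missing.
    """
    out = metadata.copy()
    for col, split in (
        ("temperature", TEMPERATURE_SPLIT),
        ("humidity", HUMIDITY_SPLIT),
        ("travellers", TRAVELLERS_SPLIT),
    ):
        if col in out.columns:
            vals = pd.to_numeric(out[col], errors="coerce")
            out[col] = pd.Series(
                np.where(vals.isna(), None, np.where(vals > split, "above", "below_eq")),
                index=out.index,
                dtype=object,
            )
    return out


def _term_columns(term: str, meta: pd.DataFrame) -> pd.DataFrame:
    """Dummy-coded design columns for one canonical term (no intercept)."""
    def main(name: str) -> pd.DataFrame:
        col, _kind = TERM_REGISTRY[name]
        series = meta[col].astype(str)
        dummies = pd.get_dummies(series, prefix=name, drop_first=True, dtype=float)
        return dummies

    if ":" in term:
        left, right = term.split(":", 1)
        a, b = main(left), main(right)
        cols = {}
        for ca in a.columns:
            for cb in b.columns:
                cols[f"{ca}*{cb}"] = a[ca] * b[cb]
        return pd.DataFrame(cols, index=meta.index)
    if term not in TERM_REGISTRY:
        raise ValueError(f"unknown term {term!r}")
    return main(term)


def _residual_sscp(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, int]:
    """Residual cross-product matrix and design rank via least squares."""
    coef, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    return resid.T @ resid, rank


def pillai_f_test(
    H: np.ndarray, E: np.ndarray, q: int, ve: int
) -> tuple[float, float, int, float, float]:
    """Pillai's trace V and its standard approximate F.

    V = trace(H (H + E)^-1); with k responses, hypothesis df q and error df
    ve: s = min(q, k), m = (|k - q| - 1)/2, n = (ve - k - 1)/2,
    F = ((2n + s + 1) / (2m + s + 1)) * (V / s) / (1 - V / s) on
    (s(2m + s + 1), s(2n + s + 1)) df.
    """
    k = H.shape[0]
    HE = H + E
    try:
        V = float(np.trace(np.linalg.solve(HE, H)))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular H + E matrix") from exc
    s = min(q, k)
    m = (abs(k - q) - 1) / 2.0
    n = (ve - k - 1) / 2.0
    df1 = int(s * (2 * m + s + 1))
    df2 = s * (2 * n + s + 1)
    if df2 <= 0 or s == 0:
        raise ValueError("insufficient error degrees of freedom for Pillai F")
    ratio = (V / s) / max(1.0 - V / s, np.finfo(float).tiny)
    F = (2 * n + s + 1) / (2 * m + s + 1) * ratio
    p = float(stats.f.sf(F, df1, df2))
    return V, float(F), df1, float(df2), p


def manova_forward_select(
    scores: pd.DataFrame,
    metadata: pd.DataFrame,
    candidate_terms: Sequence[str] = DEFAULT_TERMS,
    alpha: float = 0.001,
    variance_explained: float | None = None,
) -> ManovaModel:
    """Forward-stepwise MANOVA of PC scores on study factors (Pillai's trace).

    At each step every eligible candidate is added to the current model; its
    added-term hypothesis SSCP is H = E_current - E_candidate and the test
    uses the candidate model's error SSCP. The candidate with the largest F
    among those with p < ``alpha`` enters. Interaction terms become eligible
    only once both components are included. Rows with missing values in any
    candidate covariate are dropped (count reported on the model).
    """
    meta = binarise_covariates(metadata)
    main_terms = sorted(
        {t for term in candidate_terms for t in term.split(":")},
        key=lambda t: list(TERM_REGISTRY).index(t),
    )
    needed_cols = [TERM_REGISTRY[t][0] for t in main_terms]
    rows = scores.index.intersection(meta.index)
    meta = meta.loc[rows, needed_cols]
    complete = meta[needed_cols].notna().all(axis=1)
    meta = meta[complete]
    Y = scores.loc[meta.index].to_numpy(dtype=float)
    n, k = Y.shape
    n_dropped = len(rows) - n
    if n <= k + 2:
        raise ValueError("too few complete-case rows for the MANOVA")

    term_designs = {t: _term_columns(t, meta) for t in candidate_terms}
    X_current = np.ones((n, 1))
    E_current, rank_current = _residual_sscp(Y, X_current)
    included: list[str] = []
    steps: list[TermResult] = []
    notes: list[str] = []

    while True:
        best: TermResult | None = None
        best_design: np.ndarray | None = None
        best_E: np.ndarray | None = None
        best_rank: int | None = None
        for term in candidate_terms:
            if term in included:
                continue
            if ":" in term and not all(p in included for p in term.split(":")):
                continue
            add = term_designs[term].to_numpy(dtype=float)
            X_cand = np.hstack([X_current, add])
            E_cand, rank_cand = _residual_sscp(Y, X_cand)
            q = rank_cand - rank_current
            if q == 0:
                notes.append(f"term {term} collinear with current model; skipped")
                continue
            ve = n - rank_cand
            if ve <= k:
                raise np.linalg.LinAlgError(
                    f"singular error matrix adding term {term} (error df {ve} <= {k})"
                )
            H = E_current - E_cand
            V, F, df1, df2, p = pillai_f_test(H, E_cand, q, ve)
            result = TermResult(term, V, F, df1, df2, p)
            if p < alpha and (best is None or F > best.f_value):
                best, best_design, best_E, best_rank = result, X_cand, E_cand, rank_cand
        if best is None:
            break
        included.append(best.name)
        steps.append(best)
        X_current, E_current, rank_current = best_design, best_E, best_rank

    return ManovaModel(
        steps=steps,
        included=included,
        alpha_include=alpha,
        n_rows=n,
        n_dropped=n_dropped,
        k=k,
        variance_explained=variance_explained,
        notes=notes,
    )
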